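"""Full-scale food and contaminant catalogs.

The study schema crosses 119 food types with 227 contaminant types, giving
27,013 indicator columns.  Food names are grouped by class (cereals, beans,
vegetables, fruits, meats and eggs, aquatic products); contaminants by class
(inorganic, organic, pathogenic organisms).  For contaminant classes reported
only by count (66 pesticides, 18 herbicides, 68 endocrine disruptors) the
catalog enumerates numbered identifiers.  One fruit name was unrecoverable
from the source tables and one vegetable entry is a placeholder; both are
labeled as such so the published class totals hold exactly.  Heavy metals are
listed with 16 slots (nickel appears twice in the published list); the second
listing is disambiguated as "Ni (2)" so names stay unique.
"""

from __future__ import annotations

from .data import ContaminantSchema

_CEREALS = ["rice", "wheat", "barley", "corn", "millet", "black rice", "sticky rice"]

_BEANS = [
    "soybean", "mung soybean", "red bean", "black bean", "broad bean", "pea",
    "cow pea", "hyacinth bean", "kidney bean", "sword bean",
]

_VEGETABLES = [
    "cabbage", "pak choi cabbage", "baby cabbage", "celery cabbage", "celery",
    "lettuce", "broccoli", "Chinese broccoli", "mustard leaf", "leaf lettuce",
    "okra", "rape", "spinach", "water spinach", "potherb mustard", "amaranth",
    "cauliflower", "purslane", "yam", "carrot", "celtuce", "summer radish",
    "loofah", "tomato", "cucumber", "lappa", "radish", "potato", "sweet potato",
    "pumpkin", "bitter gourd", "white gourd", "chilli pepper", "bell pepper",
    "green pepper", "sweet pepper", "pod pepper", "pea sprout", "soybean sprout",
    "mung bean sprout", "Chinese toon sprout", "shiitake", "button mushroom",
    "oyster mushroom", "needle mushroom", "agaric", "day lily", "tremella",
    "spring onion", "Chinese onion", "ginger", "caraway", "garlic",
    "fragrant-flowered garlic", "garlic sprouts",
    "vegetable (unrecovered name)",  # placeholder: name lost in source table
]

_FRUITS = [
    "apple", "gala apple", "bergamot pear", "snow pear", "mili pear",
    "pineapple", "orange", "navel orange",
    "fruit (unrecovered name)",  # placeholder: corrupted entry in source table
    "pomelo", "peach", "nectarine", "melon", "watermelon", "Hami melon",
    "apricot", "plum", "cherry", "bayberry", "grape", "longan", "lychee",
    "winter jujube", "red jujube", "sugarcane", "pitaya",
]

_MEATS_EGGS = ["pork", "beef", "mutton", "chicken", "duck", "egg", "duck egg", "quail egg"]

_AQUATIC = [
    "kelp", "laver", "carp", "grass carp", "yellow croaker", "perch", "crucian",
    "prawn", "river prawn", "crab", "river crab", "river snail",
]

FOOD_CLASSES: dict[str, list[str]] = {
    "cereals": _CEREALS,
    "beans": _BEANS,
    "vegetables": _VEGETABLES,
    "fruits": _FRUITS,
    "meats and eggs": _MEATS_EGGS,
    "aquatic": _AQUATIC,
}

FOODS: list[str] = [f for cls in FOOD_CLASSES.values() for f in cls]

_HEAVY_METALS = ["Pb", "Cd", "Hg", "Cu", "Ni", "As", "Be", "Bi", "Sb", "Tl",
                 "Cr", "Mo", "Ni (2)", "Zn", "F", "V"]
_INORGANIC_OTHERS = ["cyanide", "nitrate", "nitrite", "sulfate", "carbonate"]
_HYDROCARBONS = ["benzene series", "polycyclic aromatic hydrocarbons",
                 "total petroleum hydrocarbon"]
_HALOGENATED = ["hydrochlorofluorocarbons", "chlorinated solvents",
                "polychlorinated biphenyls", "dioxin"]
_OXYGENATED = ["alcohols", "phenols", "ethers", "esters", "phthalate"]
_DYES = ["azo dyes", "quaternary ammonium compounds", "benzidine", "naphthylamine"]
_PLASTICS = ["polypropylene", "polyphenyl ether", "polystyrene", "phthalic acid esters"]
_PESTICIDES = [f"pesticide {i:02d}" for i in range(1, 67)]
_HERBICIDES = [f"herbicide {i:02d}" for i in range(1, 19)]
_ENDOCRINE = [f"endocrine disruptor {i:02d}" for i in range(1, 69)]
_ORGANIC_OTHERS = ["trichloroethylene", "organochlorine pesticide"]
_BACTERIA = [
    "salmonella", "shigella", "dysentery bacillus", "plague bacillus",
    "tubercle bacillus", "typhoid bacillus", "diphtheria bacillus",
    "Francisella tularensis", "Brucella", "vibrio parahaemolyticus",
    "vibrio cholerae", "vibrio mimicus", "vibrio fluvialis",
    "clostridium tetani", "clostridium botulinum", "clostridium perfringens",
    "staphylococcus aureus", "Bacillus anthracis", "Escherichia coli",
    "Yersinia", "helicobacter pylori", "campylobacter jejuni",
    "aeromonas hydrophila", "roundworm eggs", "hookworm eggs",
]
_FUNGI = ["candida albicans", "aspergillus fumigatus", "mucor racemosus"]
_VIRUSES = ["rotavirus", "norovirus", "sapovirus", "astrovirus"]

CONTAMINANT_CLASSES: dict[str, list[str]] = {
    "heavy metals": _HEAVY_METALS,
    "inorganic others": _INORGANIC_OTHERS,
    "hydrocarbons": _HYDROCARBONS,
    "halogenated": _HALOGENATED,
    "oxygenated": _OXYGENATED,
    "dyes": _DYES,
    "plastics": _PLASTICS,
    "pesticides": _PESTICIDES,
    "herbicides": _HERBICIDES,
    "endocrine disruptors": _ENDOCRINE,
    "organic others": _ORGANIC_OTHERS,
    "bacteria": _BACTERIA,
    "fungi": _FUNGI,
    "viruses": _VIRUSES,
}

CONTAMINANTS: list[str] = [c for cls in CONTAMINANT_CLASSES.values() for c in cls]

N_FOODS = 119
N_CONTAMINANTS = 227
N_INDICATORS = N_FOODS * N_CONTAMINANTS  # 27,013
N_REGIONS = 10
N_WEEKS = 178

REGIONS: list[str] = [f"region-{i:02d}" for i in range(1, N_REGIONS + 1)]

DISEASES: tuple[str, ...] = (
    "acute gastroenteritis",
    "chronic gastroenteritis",
    "gastrointestinal ulcers",
    "gastrointestinal tumors",
    "food poisoning",
    "other gastrointestinal infections",
)


def full_scale_contaminant_schema() -> ContaminantSchema:
    """The 119-food x 227-contaminant schema (27,013 indicator columns)."""
    assert len(FOODS) == N_FOODS, f"food catalog has {len(FOODS)} entries"
    assert len(CONTAMINANTS) == N_CONTAMINANTS, (
        f"contaminant catalog has {len(CONTAMINANTS)} entries")
    return ContaminantSchema(tuple(FOODS), tuple(CONTAMINANTS))
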