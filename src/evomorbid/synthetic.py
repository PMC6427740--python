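"""Synthetic surveillance-data generator.

Emulates the statistical structure the prediction models assume: a sparse set
of truly influential contaminant indicators acting on morbidity through a
(possibly nonlinear) link with a disease-specific time lag, heavy missingness
in the indicator table, and a near-zero-signal "tumor-like" disease whose
morbidity is essentially noise.

Contamination levels follow a per-region, per-column AR(1) latent process
(weekly environmental levels are autocorrelated, which is what makes the true
lag identifiable); the stored feature table is the latent level plus
measurement noise, with an independent Bernoulli observation mask.  Morbidity
is computed from the *uncorrupted* latent features, converted to integer
incidence counts against a per-region resident population.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import catalog
from .data import ContaminantSchema, PredictionDataset
from .errors import ValidationError

__all__ = ["SyntheticConfig", "GroundTruth", "generate_dataset",
           "full_scale_schema", "FullScaleSkeleton", "true_response",
           "default_config"]

_DEFAULT_DISEASES = catalog.DISEASES


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for the generator.

    Defaults are a desk-scale analogue of the full study: 12 x 20 = 240
    indicator columns, 4 regions x 60 weeks, observed fraction 0.18
    (matching roughly 4955/27013 observed indicators per tuple at full
    scale).  ``signal_scale`` near zero for the tumor-like disease encodes
    its much weaker coupling to food contamination.
    """

    n_foods: int = 12
    n_contaminants: int = 20
    n_regions: int = 4
    n_weeks: int = 60
    observed_fraction: float = 0.18
    n_active: int = 8
    diseases: tuple[str, ...] = _DEFAULT_DISEASES
    lag_true: tuple[int, ...] = (1, 3, 3, 4, 1, 1)
    signal_scale: tuple[float, ...] = (0.25, 0.20, 0.20, 0.004, 0.30, 0.22)
    link: str = "sigmoid"                   # "linear" or "sigmoid"
    noise_sd: float = 0.02
    population_range: tuple[int, int] = (50_000, 150_000)
    ar_coef: float = 0.7
    measurement_noise_sd: float = 0.3
    effect_weights: tuple[tuple[float, ...], ...] | None = None
    seed: int = 0

    def __post_init__(self):
        n = self.n_foods * self.n_contaminants
        if not 0 < self.observed_fraction <= 1:
            raise ValidationError("observed_fraction must be in (0, 1]")
        if self.n_active > n:
            raise ValidationError("n_active exceeds number of indicator columns")
        if len(self.lag_true) != len(self.diseases):
            raise ValidationError("one true lag per disease required")
        if len(self.signal_scale) != len(self.diseases):
            raise ValidationError("one signal scale per disease required")
        if any(l < 1 for l in self.lag_true):
            raise ValidationError("true lags must be >= 1")
        if self.link not in ("linear", "sigmoid"):
            raise ValidationError(f"unknown link {self.link!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``noiseless_targets`` holds the exact pre-noise, pre-quantization
    morbidity per (tuple, disease); dataset morbidity additionally carries
    observation noise and count quantization at 1/population.
    """

    config: SyntheticConfig
    active_columns: np.ndarray      # (n_diseases, n_active)
    weights: np.ndarray             # (n_diseases, n_active)
    lags: tuple[int, ...]
    noiseless_targets: np.ndarray   # (n_tuples, n_diseases); NaN where lag precedes study start
    exact_targets: np.ndarray       # noiseless + noise, clipped; same shape
    latent: np.ndarray              # (n_regions, n_weeks, n_columns)

    def disease_index(self, disease: str) -> int:
        try:
            return self.config.diseases.index(disease)
        except ValueError as exc:
            raise ValidationError(f"unknown disease {disease!r}") from exc


def _link_fn(name: str):
    if name == "linear":
        return lambda u: u
    return lambda u: 1.0 / (1.0 + np.exp(-np.clip(u, -700, 700)))


def true_response(gt: GroundTruth, x: np.ndarray, disease: str) -> float:
    """Noiseless morbidity the generator would produce for feature vector ``x``."""
    d = gt.disease_index(disease)
    x = np.asarray(x, dtype=float)
    n = gt.config.n_foods * gt.config.n_contaminants
    if x.shape != (n,):
        raise ValidationError(f"expected feature vector of length {n}, got {x.shape}")
    u = float(gt.weights[d] @ x[gt.active_columns[d]])
    y = gt.config.signal_scale[d] * _link_fn(gt.config.link)(u)
    return float(np.clip(y, 0.0, 1.0))


def generate_dataset(cfg: SyntheticConfig) -> tuple[PredictionDataset, GroundTruth]:
    """Draw a complete region-week dataset plus its generating ground truth.

    Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_foods * cfg.n_contaminants
    R, W = cfg.n_regions, cfg.n_weeks
    n_dis = len(cfg.diseases)
    link = _link_fn(cfg.link)

    # AR(1) latent contamination levels, stationary start
    stat_sd = 1.0 / np.sqrt(1.0 - cfg.ar_coef ** 2)
    latent = np.empty((R, W, n))
    latent[:, 0, :] = rng.normal(0.0, stat_sd, size=(R, n))
    innov = rng.normal(0.0, 1.0, size=(R, W - 1, n))
    for t in range(1, W):
        latent[:, t, :] = cfg.ar_coef * latent[:, t - 1, :] + innov[:, t - 1, :]

    # planted effects
    active = np.empty((n_dis, cfg.n_active), dtype=int)
    weights = np.empty((n_dis, cfg.n_active))
    for d in range(n_dis):
        active[d] = rng.choice(n, size=cfg.n_active, replace=False)
    if cfg.effect_weights is not None:
        weights[:] = np.asarray(cfg.effect_weights, dtype=float)
        if weights.shape != (n_dis, cfg.n_active):
            raise ValidationError("effect_weights must be (n_diseases, n_active)")
    else:
        # signs mixed, magnitudes scaled so the link argument has O(1) spread
        mag = rng.uniform(0.5, 1.0, size=(n_dis, cfg.n_active))
        sign = rng.choice([-1.0, 1.0], size=(n_dis, cfg.n_active))
        weights[:] = mag * sign / np.sqrt(cfg.n_active) * (1.0 / stat_sd) * 2.0

    # targets from uncorrupted latent features
    noiseless = np.full((R, W, n_dis), np.nan)
    exact = np.full((R, W, n_dis), np.nan)
    target_noise = rng.normal(0.0, cfg.noise_sd, size=(R, W, n_dis))
    for d in range(n_dis):
        lag = cfg.lag_true[d]
        for t in range(lag, W):
            u = latent[:, t - lag, :][:, active[d]] @ weights[d]
            clean = np.clip(cfg.signal_scale[d] * link(u), 0.0, 1.0)
            noiseless[:, t, d] = clean
            if cfg.noise_sd > 0:
                exact[:, t, d] = np.clip(clean + target_noise[:, t, d], 0.0, 1.0)
            else:
                exact[:, t, d] = clean
        # weeks before the lag horizon: background level (no planted signal)
        for t in range(lag):
            base = np.clip(cfg.signal_scale[d] * link(np.zeros(R)), 0.0, 1.0)
            noiseless[:, t, d] = base
            exact[:, t, d] = np.clip(base + target_noise[:, t, d], 0.0, 1.0) \
                if cfg.noise_sd > 0 else base

    # observed feature table: latent + measurement noise, Bernoulli mask
    meas = latent + rng.normal(0.0, cfg.measurement_noise_sd, size=latent.shape) \
        if cfg.measurement_noise_sd > 0 else latent.copy()
    mask = rng.random(size=(R, W, n)) < cfg.observed_fraction
    features = np.where(mask, meas, np.nan)

    # populations constant per region over the study window
    populations = rng.integers(cfg.population_range[0], cfg.population_range[1] + 1,
                               size=R)

    schema = ContaminantSchema(
        tuple(f"food-{i:03d}" for i in range(cfg.n_foods)),
        tuple(f"contaminant-{j:03d}" for j in range(cfg.n_contaminants)),
    )
    region_names = [f"region-{r:02d}" for r in range(R)]

    region_ids = np.repeat(np.array(region_names, dtype=object), W)
    weeks = np.tile(np.arange(W), R)
    X = features.reshape(R * W, n)
    pop = np.repeat(populations, W)
    y_exact = exact.reshape(R * W, n_dis)
    incid = np.rint(y_exact * pop[:, None]).astype(int)
    incid = np.clip(incid, 0, pop[:, None])

    ds = PredictionDataset(
        schema=schema, diseases=cfg.diseases,
        region_ids=region_ids, weeks=weeks,
        features=X, incidences=incid, population=pop,
        meta={"generator": "evomorbid.synthetic", "seed": cfg.seed},
    )
    gt = GroundTruth(
        config=cfg, active_columns=active, weights=weights,
        lags=cfg.lag_true,
        noiseless_targets=noiseless.reshape(R * W, n_dis),
        exact_targets=y_exact,
        latent=latent,
    )
    return ds, gt


def default_config(seed: int = 0) -> SyntheticConfig:
    """The default desk-scale benchmark configuration."""
    return SyntheticConfig(seed=seed)


@dataclass(frozen=True)
class FullScaleSkeleton:
    """The full study grid: schema plus empty region-week tuple slots.

    Holds no feature storage (27,013 columns x 1,780 tuples dense would be
    needlessly large); downstream code fills slots from long-format tables.
    """

    schema: ContaminantSchema
    region_ids: tuple[str, ...]
    weeks: tuple[int, ...]
    diseases: tuple[str, ...]

    @property
    def n_slots(self) -> int:
        return len(self.region_ids) * len(self.weeks)

    @property
    def slots(self) -> list[tuple[str, int]]:
        return [(r, w) for r in self.region_ids for w in self.weeks]


def full_scale_schema() -> FullScaleSkeleton:
    """The study-scale schema (119 foods x 227 contaminants) and 10x178 tuple grid."""
    return FullScaleSkeleton(
        schema=catalog.full_scale_contaminant_schema(),
        region_ids=tuple(catalog.REGIONS),
        weeks=tuple(range(catalog.N_WEEKS)),
        diseases=catalog.DISEASES,
    )


def config_to_dict(cfg: SyntheticConfig) -> dict:
    return asdict(cfg)


def config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    for key in ("diseases", "lag_true", "signal_scale", "population_range"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if d.get("effect_weights") is not None:
        d["effect_weights"] = tuple(tuple(row) for row in d["effect_weights"])
    return SyntheticConfig(**d)
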