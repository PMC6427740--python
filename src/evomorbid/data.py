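"""Region-week surveillance data model.

A surveillance dataset is a grid of weekly tuples, one per (region, week).
Each tuple carries a high-dimensional contaminant-indicator vector (one
component per food x contaminant pair, mostly missing) and, per disease,
an incidence count and the resident population.  Morbidity — the regression
target — is the incidence/population ratio, always in [0, 1].

Missing feature values are represented as NaN throughout; the observed mask
is simply ``~isnan``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "ContaminantSchema",
    "WeeklyTuple",
    "PredictionDataset",
    "LaggedPairs",
    "Preprocessor",
    "aggregate_measurements",
    "compute_morbidity",
    "impute_missing",
    "make_lagged_pairs",
    "split_kfold",
    "read_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class ContaminantSchema:
    """Bijection between (food, contaminant) pairs and feature-column ids.

    Column ids are assigned row-major: food index * n_contaminants +
    contaminant index, so every pair maps to exactly one column in
    ``[0, n_columns)`` and vice versa.
    """

    foods: tuple[str, ...]
    contaminants: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.foods)) != len(self.foods):
            raise ValidationError("food names must be unique")
        if len(set(self.contaminants)) != len(self.contaminants):
            raise ValidationError("contaminant names must be unique")
        if not self.foods or not self.contaminants:
            raise ValidationError("schema must have at least one food and one contaminant")

    @property
    def n_columns(self) -> int:
        return len(self.foods) * len(self.contaminants)

    def column_of(self, food: str, contaminant: str) -> int:
        try:
            fi = self.foods.index(food)
            ci = self.contaminants.index(contaminant)
        except ValueError as exc:
            raise SchemaError(f"unknown food/contaminant pair ({food!r}, {contaminant!r})") from exc
        return fi * len(self.contaminants) + ci

    def pair_of(self, column: int) -> tuple[str, str]:
        if not 0 <= column < self.n_columns:
            raise SchemaError(f"column id {column} out of range [0, {self.n_columns})")
        fi, ci = divmod(column, len(self.contaminants))
        return self.foods[fi], self.contaminants[ci]


@dataclass(frozen=True)
class WeeklyTuple:
    """One region-week observation: features with mask, counts, population."""

    region_id: str
    week: int
    features: np.ndarray          # length n, NaN = missing
    incidences: np.ndarray        # length n_diseases, nonnegative ints
    population: int

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.features)

    @property
    def morbidity(self) -> np.ndarray:
        return self.incidences / self.population


@dataclass
class PredictionDataset:
    """A collection of weekly tuples sharing one contaminant schema.

    Stored columnar: ``features[i]`` is the indicator vector of tuple i
    (NaN marking unobserved cells), ``incidences[i, d]`` the weekly count of
    disease d, ``population[i]`` the resident population.  (region_id, week)
    pairs are unique.
    """

    schema: ContaminantSchema
    diseases: tuple[str, ...]
    region_ids: np.ndarray        # object array of str, shape (n_tuples,)
    weeks: np.ndarray             # int array, shape (n_tuples,)
    features: np.ndarray          # float array, shape (n_tuples, n_columns)
    incidences: np.ndarray        # int array, shape (n_tuples, n_diseases)
    population: np.ndarray        # int array, shape (n_tuples,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.region_ids)
        if not (len(self.weeks) == self.features.shape[0] == self.incidences.shape[0]
                == len(self.population) == n):
            raise ValidationError("tuple arrays have inconsistent lengths")
        if self.features.shape[1] != self.schema.n_columns:
            raise ValidationError(
                f"feature width {self.features.shape[1]} != schema width {self.schema.n_columns}")
        if self.incidences.shape[1] != len(self.diseases):
            raise ValidationError("incidence width does not match disease list")
        keys = list(zip(self.region_ids.tolist(), self.weeks.tolist()))
        if len(set(keys)) != n:
            raise ValidationError("(region_id, week) pairs must be unique")
        if np.any(self.population <= 0):
            raise ValidationError("population must be positive")
        if np.any(self.incidences < 0):
            raise ValidationError("incidence counts must be nonnegative")
        if np.any(self.weeks < 0):
            raise ValidationError("weeks are indexed from 0")

    def __len__(self) -> int:
        return len(self.region_ids)

    @property
    def morbidity(self) -> np.ndarray:
        """Per-tuple, per-disease incidence / population, in [0, 1]."""
        return self.incidences / self.population[:, None]

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.region_ids.tolist():
            seen.setdefault(r, None)
        return list(seen)

    def tuple_at(self, i: int) -> WeeklyTuple:
        return WeeklyTuple(
            region_id=self.region_ids[i],
            week=int(self.weeks[i]),
            features=self.features[i],
            incidences=self.incidences[i],
            population=int(self.population[i]),
        )

    def disease_index(self, disease: str) -> int:
        try:
            return self.diseases.index(disease)
        except ValueError as exc:
            raise ValidationError(f"unknown disease {disease!r}") from exc


def compute_morbidity(incidences: int, population: int) -> float:
    """Weekly morbidity: incidence count divided by resident population."""
    if population <= 0:
        raise ValidationError(f"population must be positive, got {population}")
    if incidences < 0:
        raise ValidationError(f"incidences must be nonnegative, got {incidences}")
    return incidences / population


def aggregate_measurements(
    raw: Iterable[tuple[str, int, int, float]],
    schema: ContaminantSchema,
) -> pd.DataFrame:
    """Collapse repeated within-week measurements to one value per cell.

    ``raw`` yields (region_id, week, column_id, value) records; an indicator
    measured more than once in a region-week is replaced by the arithmetic
    mean of its measurements.  Cells with no measurement simply do not appear
    in the output (missing).

    Returns a long-format frame with columns
    ``region_id, week, column_id, value``, one row per observed cell, sorted.
    """
    df = pd.DataFrame(list(raw), columns=["region_id", "week", "column_id", "value"])
    if len(df):
        cols = df["column_id"].to_numpy()
        if cols.min() < 0 or cols.max() >= schema.n_columns:
            bad = cols[(cols < 0) | (cols >= schema.n_columns)][0]
            raise SchemaError(f"column id {bad} not in schema of width {schema.n_columns}")
        if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
            raise ValidationError("measurement values must be finite")
    out = (
        df.groupby(["region_id", "week", "column_id"], as_index=False)["value"]
        .mean()
        .sort_values(["region_id", "week", "column_id"], ignore_index=True)
    )
    return out


def features_from_long(
    agg: pd.DataFrame,
    region_ids: Sequence[str],
    weeks: Sequence[int],
    n_columns: int,
) -> np.ndarray:
    """Densify a long-format aggregated table onto a given tuple grid (NaN = missing)."""
    index = {(r, int(w)): i for i, (r, w) in enumerate(zip(region_ids, weeks))}
    X = np.full((len(index), n_columns), np.nan)
    for r, w, c, v in agg.itertuples(index=False):
        key = (r, int(w))
        if key not in index:
            raise ValidationError(f"measurement for unknown tuple {key}")
        X[index[key], int(c)] = v
    return X


def impute_missing(
    train: np.ndarray, apply_to: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing (NaN) cells with the per-column mean of observed *training* cells.

    Columns with no observed training entry are filled with 0 (the
    standardized prior mean).  Statistics are never taken from ``apply_to``.
    Observed cells are returned unchanged.
    """
    import warnings

    train = np.asarray(train, dtype=float)
    apply_to = np.asarray(apply_to, dtype=float)
    if train.shape[1] != apply_to.shape[1]:
        raise ValidationError("train and apply_to must share column count")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(train, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)

    def _fill(M: np.ndarray) -> np.ndarray:
        out = M.copy()
        miss = np.isnan(out)
        out[miss] = np.broadcast_to(col_mean, out.shape)[miss]
        return out

    return _fill(train), _fill(apply_to)


class Preprocessor:
    """Mean imputation followed by per-column z-scoring, fit on training data only.

    Columns with zero observed training variance (or no observed training
    entries at all) map to the constant 0 after transform.
    """

    def __init__(self):
        self.col_mean_: np.ndarray | None = None
        self.col_sd_: np.ndarray | None = None

    def fit(self, train: np.ndarray) -> "Preprocessor":
        import warnings

        train = np.asarray(train, dtype=float)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # all-NaN columns are legal: they fall back to 0 below
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(train, axis=0)
            sd = np.nanstd(train, axis=0)
        self.col_mean_ = np.where(np.isnan(mean), 0.0, mean)
        self.col_sd_ = np.where(np.isnan(sd) | (sd == 0.0), 0.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.col_mean_ is None:
            raise ValidationError("Preprocessor not fitted")
        X = np.asarray(X, dtype=float)
        filled = X.copy()
        miss = np.isnan(filled)
        filled[miss] = np.broadcast_to(self.col_mean_, filled.shape)[miss]
        sd = self.col_sd_
        out = np.zeros_like(filled)
        nz = sd > 0
        out[:, nz] = (filled[:, nz] - self.col_mean_[nz]) / sd[nz]
        return out

    def fit_transform(self, train: np.ndarray) -> np.ndarray:
        return self.fit(train).transform(train)


@dataclass
class LaggedPairs:
    """Supervised pairs (features at week t-lag, morbidity at week t) for one disease.

    ``X`` keeps raw features with NaN missing marks; imputation and
    standardization happen per cross-validation fold so that test folds never
    contribute statistics.
    """

    X: np.ndarray             # (n_pairs, n_columns), NaN = missing
    y: np.ndarray             # (n_pairs,) morbidity at target week
    region_ids: np.ndarray    # (n_pairs,)
    target_weeks: np.ndarray  # (n_pairs,)
    disease: str
    lag: int

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "LaggedPairs":
        return LaggedPairs(
            X=self.X[idx], y=self.y[idx],
            region_ids=self.region_ids[idx], target_weeks=self.target_weeks[idx],
            disease=self.disease, lag=self.lag,
        )


def make_lagged_pairs(ds: PredictionDataset, disease: str, lag: int) -> LaggedPairs:
    """Pair each week-t morbidity with the feature vector lag weeks earlier.

    Pairs never cross regions; a pair exists only when the region has a tuple
    at both t and t-lag.  Output is ordered by (region, target_week).  A lag
    exceeding every region's span yields an empty result.
    """
    if lag < 1:
        raise ValidationError(f"lag must be >= 1, got {lag}")
    d = ds.disease_index(disease)
    morbidity = ds.morbidity[:, d]
    index = {(r, int(w)): i for i, (r, w) in enumerate(zip(ds.region_ids, ds.weeks))}
    rows_x, rows_y, rows_r, rows_t = [], [], [], []
    keys = sorted(index, key=lambda k: (str(k[0]), k[1]))
    for r, t in keys:
        src = index.get((r, t - lag))
        if src is None:
            continue
        tgt = index[(r, t)]
        rows_x.append(ds.features[src])
        rows_y.append(morbidity[tgt])
        rows_r.append(r)
        rows_t.append(t)
    n = ds.schema.n_columns
    X = np.array(rows_x) if rows_x else np.empty((0, n))
    return LaggedPairs(
        X=X,
        y=np.array(rows_y, dtype=float),
        region_ids=np.array(rows_r, dtype=object),
        target_weeks=np.array(rows_t, dtype=int),
        disease=disease,
        lag=lag,
    )


def split_kfold(n_pairs: int, k: int, seed: int) -> list[np.ndarray]:
    """Random disjoint test folds of near-equal size (sizes differ by <= 1).

    Deterministic for a fixed seed; every index lands in exactly one fold.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if n_pairs < k:
        raise ValidationError(f"need at least k={k} pairs, got {n_pairs}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_pairs)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


# ---------------------------------------------------------------------------
# On-disk layout: a directory with schema.tsv, features.csv (long format),
# targets.csv and meta.yaml.  A missing cell is an absent row in features.csv.
# ---------------------------------------------------------------------------

def write_dataset(ds: PredictionDataset, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    rows = []
    for c in range(ds.schema.n_columns):
        food, cont = ds.schema.pair_of(c)
        rows.append((c, food, cont))
    pd.DataFrame(rows, columns=["column_id", "food", "contaminant"]).to_csv(
        path / "schema.tsv", sep="\t", index=False)

    obs_i, obs_c = np.nonzero(~np.isnan(ds.features))
    feat = pd.DataFrame({
        "region_id": ds.region_ids[obs_i],
        "week": ds.weeks[obs_i],
        "column_id": obs_c,
        "value": ds.features[obs_i, obs_c],
    }).sort_values(["region_id", "week", "column_id"], ignore_index=True)
    # shortest-exact reprs so write -> read round-trips bit-for-bit
    feat["value"] = [repr(float(v)) for v in feat["value"]]
    feat.to_csv(path / "features.csv", index=False)

    tgt_rows = []
    order = np.lexsort((ds.weeks, ds.region_ids.astype(str)))
    for i in order:
        for d, disease in enumerate(ds.diseases):
            tgt_rows.append((ds.region_ids[i], int(ds.weeks[i]), disease,
                             int(ds.incidences[i, d]), int(ds.population[i])))
    pd.DataFrame(
        tgt_rows, columns=["region_id", "week", "disease", "incidences", "population"]
    ).to_csv(path / "targets.csv", index=False)

    meta = dict(ds.meta)
    meta["diseases"] = list(ds.diseases)
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_dataset(path: str | Path) -> PredictionDataset:
    path = Path(path)
    schema_df = pd.read_csv(path / "schema.tsv", sep="\t")
    foods, contaminants = [], []
    for _, row in schema_df.iterrows():
        if row["food"] not in foods:
            foods.append(row["food"])
        if row["contaminant"] not in contaminants:
            contaminants.append(row["contaminant"])
    schema = ContaminantSchema(tuple(foods), tuple(contaminants))
    expected = {(schema.pair_of(int(r.column_id))): int(r.column_id)
                for r in schema_df.itertuples()}
    for (food, cont), cid in expected.items():
        if schema.column_of(food, cont) != cid:
            raise ParseError(f"schema.tsv column ids are not row-major ({food}, {cont})")

    with open(path / "meta.yaml") as fh:
        meta = yaml.safe_load(fh) or {}
    diseases = tuple(meta.pop("diseases"))

    tgt = pd.read_csv(path / "targets.csv")
    seen: dict[tuple[str, int], int] = {}
    region_ids, weeks, pops = [], [], []
    inc_rows: dict[int, dict[str, int]] = {}
    for line_no, row in enumerate(tgt.itertuples(index=False), start=2):
        key = (str(row.region_id), int(row.week))
        if key not in seen:
            seen[key] = len(region_ids)
            region_ids.append(key[0])
            weeks.append(key[1])
            pops.append(int(row.population))
            inc_rows[seen[key]] = {}
        i = seen[key]
        if row.disease in inc_rows[i]:
            raise ParseError(
                f"duplicate (region, week, disease) row {key + (row.disease,)}", line=line_no)
        if int(row.population) != pops[i]:
            raise ParseError(f"inconsistent population for tuple {key}", line=line_no)
        inc_rows[i][row.disease] = int(row.incidences)

    incidences = np.zeros((len(region_ids), len(diseases)), dtype=int)
    for i, dmap in inc_rows.items():
        for d, disease in enumerate(diseases):
            if disease not in dmap:
                raise ParseError(f"missing disease {disease!r} for tuple "
                                 f"({region_ids[i]}, {weeks[i]})")
            incidences[i, d] = dmap[disease]

    region_arr = np.array(region_ids, dtype=object)
    week_arr = np.array(weeks, dtype=int)

    feat = pd.read_csv(path / "features.csv", float_precision="round_trip")
    index = {(r, int(w)): i for i, (r, w) in enumerate(zip(region_ids, weeks))}
    X = np.full((len(region_ids), schema.n_columns), np.nan)
    for line_no, row in enumerate(feat.itertuples(index=False), start=2):
        key = (str(row.region_id), int(row.week))
        if key not in index:
            raise ParseError(f"feature row for unknown tuple {key}", line=line_no)
        c = int(row.column_id)
        if not 0 <= c < schema.n_columns:
            raise ParseError(f"column id {c} out of schema range", line=line_no)
        if not np.isnan(X[index[key], c]):
            raise ParseError(f"duplicate feature cell {key + (c,)}", line=line_no)
        X[index[key], c] = float(row.value)

    return PredictionDataset(
        schema=schema, diseases=diseases,
        region_ids=region_arr, weeks=week_arr,
        features=X, incidences=incidences,
        population=np.array(pops, dtype=int),
        meta=meta,
    )
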