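"""Trait tables and their preprocessing.

A trait table holds one row per (metric, species, population) measurement.
Before any diversity computation, each metric's pooled values are Box-Cox
transformed towards normality and standardized by the population (divisor-n)
standard deviation, so the total quadratic-entropy diversity of the values
placed on a tree equals exactly 1 and node contributions read as proportions
of trait variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TraitTable",
    "PreparedTrait",
    "TraitValidationError",
    "read_trait_table",
    "write_trait_table",
    "boxcox_transform",
    "standardize",
    "species_means",
    "prepare_metric",
]

REQUIRED_COLUMNS = ("metric", "species", "value")


class TraitValidationError(ValueError):
    """Raised for malformed or degenerate trait data."""


@dataclass(frozen=True)
class TraitTable:
    """Validated long-format trait measurements.

    ``data`` has columns ``metric, species, population, value``; the
    population id is a synthetic ``"p1"`` when the source had none.  The
    (metric, species, population) triples are unique and values finite.
    """

    data: pd.DataFrame

    @property
    def metrics(self) -> tuple[str, ...]:
        return tuple(self.data["metric"].unique())

    def for_metric(self, metric: str) -> pd.DataFrame:
        if metric not in set(self.data["metric"]):
            raise TraitValidationError(f"unknown metric {metric!r}")
        return self.data[self.data["metric"] == metric].reset_index(drop=True)

    def replicate_design(self, metric: str) -> dict[str, list[str]]:
        """species -> ordered list of population ids, for one metric."""
        sub = self.for_metric(metric)
        return {
            sp: list(grp["population"])
            for sp, grp in sub.groupby("species", sort=False)
        }


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraitValidationError(f"missing required column(s): {missing}")
    df = df.copy()
    if "population" not in df.columns:
        df["population"] = "p1"
    df["population"] = df["population"].fillna("p1")
    for col in ("metric", "species", "population"):
        df[col] = df[col].astype(str).str.strip()

    blank = df.index[df["value"].isna()].tolist()
    if blank:
        rows = [i + 2 for i in blank]  # +2: header + 1-based
        raise TraitValidationError(f"empty trait value in row(s): {rows}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna() | ~np.isfinite(values)].tolist()
    if bad:
        rows = [i + 2 for i in bad]
        raise TraitValidationError(f"non-numeric or non-finite value in row(s): {rows}")
    df["value"] = values.astype(float)

    dup = df.duplicated(subset=["metric", "species", "population"], keep=False)
    if dup.any():
        rows = [i + 2 for i in df.index[dup].tolist()]
        raise TraitValidationError(
            f"duplicate (metric, species, population) triples in rows {rows}"
        )
    for metric, grp in df.groupby("metric"):
        if grp["species"].nunique() < 2:
            raise TraitValidationError(
                f"metric {metric!r} has fewer than 2 distinct species"
            )
    return df[["metric", "species", "population", "value"]].reset_index(drop=True)


def read_trait_table(path) -> TraitTable:
    """Read and validate a CSV trait table (metric, species, population, value)."""
    df = pd.read_csv(path, dtype={"metric": str, "species": str, "population": str})
    return TraitTable(data=_validate_frame(df))


def from_records(records: pd.DataFrame | Sequence[Mapping]) -> TraitTable:
    """Build a validated TraitTable from an in-memory frame or record list."""
    df = pd.DataFrame(records)
    return TraitTable(data=_validate_frame(df))


def write_trait_table(table: TraitTable, path) -> None:
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Transformations


def boxcox_transform(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform a value vector towards normality.

    Non-positive inputs are first shifted by ``-min + eps`` (eps = 1e-6 of the
    range); the exponent lambda maximizes the Box-Cox profile log-likelihood
    over [-5, 5].  Returns ``(transformed, lambda, shift)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise TraitValidationError("Box-Cox needs at least 3 values")
    if np.ptp(x) == 0:
        raise TraitValidationError("Box-Cox undefined for constant values")
    shift = 0.0
    if x.min() <= 0:
        shift = -x.min() + 1e-6 * np.ptp(x)
    xs = x + shift

    neg_llf = lambda lam: -stats.boxcox_llf(lam, xs)
    res = optimize.minimize_scalar(
        neg_llf, bounds=(-5.0, 5.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(res.x)
    transformed = stats.boxcox(xs, lmbda=lam)
    return np.asarray(transformed, dtype=float), lam, shift


def standardize(values: Sequence[float]) -> tuple[np.ndarray, float]:
    """Center and scale to unit population variance (divisor n).

    Returns ``(scaled, scale)`` where ``scale`` is the divisor-n standard
    deviation of the input.  Exact unit variance of the output makes node
    contributions sum to 1 on a full decomposition.
    """
    x = np.asarray(values, dtype=float)
    sd = float(x.std(ddof=0))
    if sd == 0:
        raise TraitValidationError("cannot standardize constant values")
    return (x - x.mean()) / sd, sd


@dataclass(frozen=True)
class PreparedTrait:
    """One metric's values after Box-Cox + standardization, keyed by tip label.

    ``tip_values`` maps enlarged-tree tip labels (``species`` for singletons,
    ``species::population`` for replicated species) to standardized values
    with exact unit divisor-n variance.
    """

    tip_values: Mapping[str, float]
    lam: float
    shift: float
    scale: float

    @property
    def values(self) -> np.ndarray:
        return np.array(list(self.tip_values.values()), dtype=float)


def species_means(table: TraitTable, metric: str) -> dict[str, float]:
    """Arithmetic mean trait value per species for one metric."""
    sub = table.for_metric(metric)
    return sub.groupby("species", sort=False)["value"].mean().to_dict()


def prepare_metric(
    table: TraitTable,
    metric: str,
    *,
    boxcox: bool = True,
    tip_label_fn=None,
) -> PreparedTrait:
    """Apply the preprocessing chain to one metric's pooled values.

    Values are pooled across species and populations, optionally Box-Cox
    transformed, then standardized to unit divisor-n variance.  Tip labels
    follow the enlarged-tree convention: a species with a single measurement
    keeps its species name, a replicated species contributes one
    ``species::population`` virtual tip per record.
    """
    from .phylo import virtual_tip_label

    sub = table.for_metric(metric)
    raw = sub["value"].to_numpy(dtype=float)
    lam, shift = 1.0, 0.0
    vals = raw
    if boxcox:
        vals, lam, shift = boxcox_transform(raw)
    scaled, scale = standardize(vals)

    counts = sub.groupby("species")["species"].transform("size")
    labels = [
        sp if c == 1 else virtual_tip_label(sp, pop)
        for sp, pop, c in zip(sub["species"], sub["population"], counts)
    ]
    tip_values = dict(zip(labels, scaled.tolist()))
    return PreparedTrait(tip_values=tip_values, lam=lam, shift=shift, scale=scale)
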