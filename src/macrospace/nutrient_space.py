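"""Nutrient-space phenotype statistics for diet-grid pupariation assays.

Larvae are reared in replicate vials on a yeast x sucrose diet grid and the
cumulative number of pupariated larvae is scored at fixed observation times.
This module turns those cumulative series into per-vial phenotype metrics:

* the pupariation index (pupind), ``max_t p_t / t`` — a single rate statistic
  that rewards both fast development and high survival;
* survival to pupariation (final count / larvae seeded) and a median
  development time under 24-h interval censoring;
* diet caloric content, Pearson correlations of metrics against the diet
  axes, omega-squared ANOVA effect sizes, and genotype difference surfaces
  over the diet grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "GRID_ASSAY_COLUMNS",
    "GridAssay",
    "PupindResult",
    "SurvivalDevResult",
    "CorrelationResult",
    "EffectSizeResult",
    "DietSurface",
    "compute_pupind",
    "compute_survival_devtime",
    "vial_metrics",
    "diet_calories",
    "correlate_metric",
    "omega_squared",
    "metric_surface",
    "difference_surface",
]

GRID_ASSAY_COLUMNS = [
    "genotype",
    "yeast_pct",
    "sucrose_pct",
    "vial",
    "time_h",
    "cum_pupae",
    "n_larvae",
]

#: kcal per gram of dry baker's yeast and of sucrose used for diet calories.
YEAST_KCAL_PER_G = Decimal("3.25")
SUCROSE_KCAL_PER_G = Decimal("4.06")


@dataclass
class GridAssay:
    """Cumulative pupariation counts over a yeast x sucrose diet grid.

    Wraps a tidy table with one row per (genotype, diet, vial, observation
    time).  Counts are cumulative: ``cum_pupae`` at time ``time_h`` is the
    number of larvae (out of ``n_larvae`` seeded) that have pupariated by
    that time.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GRID_ASSAY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"GridAssay table missing columns: {missing}")
        df = self.data
        if len(df) == 0:
            raise ValueError("GridAssay table is empty")
        if (df["cum_pupae"] < 0).any() or (df["cum_pupae"] > df["n_larvae"]).any():
            raise ValueError("cum_pupae must lie in [0, n_larvae]")
        for _, series in df.sort_values("time_h").groupby(
            ["genotype", "yeast_pct", "sucrose_pct", "vial"], sort=False
        ):
            if (np.diff(series["cum_pupae"].to_numpy()) < 0).any():
                raise ValueError("cumulative counts must be non-decreasing within a vial")

    @property
    def vial_groups(self):
        """Iterate (keys, sorted sub-table) per vial."""
        return self.data.sort_values("time_h").groupby(
            ["genotype", "yeast_pct", "sucrose_pct", "vial"], sort=True
        )

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GridAssay":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class PupindResult:
    """Pupariation index of one vial: max over t of p_t/t (larvae/hour)."""

    pupind: float
    t_star: float  # earliest observation time attaining the max


@dataclass(frozen=True)
class SurvivalDevResult:
    survival: float
    dev_time_h: float  # NaN when no larva pupariated


@dataclass(frozen=True)
class CorrelationResult:
    metric: str
    axis: str
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class EffectSizeResult:
    trait: str
    effect: str
    sum_sq: float
    df: float
    omega_squared: float


@dataclass
class DietSurface:
    """A value per diet cell, indexed by the grid's yeast and sucrose levels."""

    yeast_levels: np.ndarray
    sucrose_levels: np.ndarray
    values: np.ndarray  # shape (len(yeast_levels), len(sucrose_levels))

    def __post_init__(self) -> None:
        self.yeast_levels = np.asarray(self.yeast_levels, dtype=float)
        self.sucrose_levels = np.asarray(self.sucrose_levels, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.yeast_levels), len(self.sucrose_levels)):
            raise ValueError("surface matrix shape must match the diet axes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.yeast_levels, columns=self.sucrose_levels
        ).rename_axis(index="yeast_pct", columns="sucrose_pct")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DietSurface":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.index.to_numpy(float), df.columns.to_numpy(float), df.to_numpy())


# ---------------------------------------------------------------------------
# per-vial metrics


def compute_pupind(times, counts) -> PupindResult:
    """Pupariation index: ``max({p_t / t})`` over the observation times.

    Returns the maximum rate and the earliest time attaining it.  Times must
    be strictly increasing and positive; counts are the cumulative pupae.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(counts, dtype=float)
    if t.size == 0:
        raise ValueError("empty observation series")
    if t.shape != p.shape:
        raise ValueError("times and counts must have equal length")
    if (t <= 0).any() or (np.diff(t) <= 0).any():
        raise ValueError("observation times must be positive and strictly increasing")
    rates = p / t
    i = int(np.argmax(rates))  # argmax returns the first (earliest) maximum
    return PupindResult(pupind=float(rates[i]), t_star=float(t[i]))


def compute_survival_devtime(times, counts, n_larvae) -> SurvivalDevResult:
    """Survival fraction and median development time of one vial.

    Survival is the final cumulative count over larvae seeded.  Development
    time is the earliest observation time at which the cumulative count
    reaches half the final count — the median of survivors under interval
    censoring at the observation spacing.  Undefined (NaN) when nothing
    pupariated.
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(counts, dtype=float)
    if t.size == 0:
        raise ValueError("empty observation series")
    p_final = p[-1]
    survival = float(p_final / n_larvae)
    if p_final == 0:
        return SurvivalDevResult(survival=0.0, dev_time_h=float("nan"))
    dev = float(t[np.nonzero(p >= p_final / 2.0)[0][0]])
    return SurvivalDevResult(survival=survival, dev_time_h=dev)


def vial_metrics(assay: GridAssay) -> pd.DataFrame:
    """Tidy per-vial metric table: pupind, t*, survival, development time."""
    rows = []
    for (genotype, yeast, suc, vial), g in assay.vial_groups:
        t = g["time_h"].to_numpy(float)
        p = g["cum_pupae"].to_numpy(float)
        n = int(g["n_larvae"].iloc[0])
        pi = compute_pupind(t, p)
        sd = compute_survival_devtime(t, p, n)
        rows.append(
            {
                "genotype": genotype,
                "yeast_pct": yeast,
                "sucrose_pct": suc,
                "vial": vial,
                "pupind": pi.pupind,
                "t_star": pi.t_star,
                "survival": sd.survival,
                "dev_time_h": sd.dev_time_h,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diet calories


def diet_calories(yeast_pct: float, sucrose_pct: float) -> float:
    """Estimated caloric content (kcal/100 g) of a yeast/sucrose diet.

    A diet of y% w/v yeast and s% w/v sucrose contributes y grams of yeast
    and s grams of sucrose per 100 g of medium, at 3.25 kcal/g (yeast) and
    4.06 kcal/g (sucrose).  Rounded half-away-from-zero to one decimal.
    """
    if yeast_pct < 0 or sucrose_pct < 0:
        raise ValueError("diet percentages must be non-negative")
    total = (
        Decimal(repr(float(yeast_pct))) * YEAST_KCAL_PER_G
        + Decimal(repr(float(sucrose_pct))) * SUCROSE_KCAL_PER_G
    )
    return float(total.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# correlations and effect sizes

_AXIS_COLUMNS = {"yeast": "yeast_pct", "sucrose": "sucrose_pct"}


def correlate_metric(
    metrics: pd.DataFrame, metric: str, axis: str, level: str = "vial"
) -> CorrelationResult:
    """Pearson correlation of a per-vial metric against a diet axis.

    ``level='vial'`` correlates vial-level points; ``level='cell'`` first
    averages vials within each diet cell.  Rows with undefined metric values
    (e.g. development time of all-dead vials) are dropped.
    """
    if axis not in _AXIS_COLUMNS:
        raise ValueError(f"axis must be one of {sorted(_AXIS_COLUMNS)}")
    col = _AXIS_COLUMNS[axis]
    df = metrics[[col, metric]].dropna()
    if level == "cell":
        df = df.groupby(col, as_index=False)[metric].mean()
    elif level != "vial":
        raise ValueError("level must be 'vial' or 'cell'")
    x = df[col].to_numpy(float)
    y = df[metric].to_numpy(float)
    if x.size < 3:
        raise ValueError("need at least 3 finite points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance on one side")
    r, p = scipy.stats.pearsonr(x, y)
    return CorrelationResult(metric=metric, axis=axis, r=float(r), p_value=float(p), n=x.size)


def omega_squared(
    data: pd.DataFrame, response: str, factors: list[str], clamp: bool = True
) -> list[EffectSizeResult]:
    """Omega-squared effect sizes from a fixed-effects factorial ANOVA.

    Fits the full factorial model of the given categorical factors with
    Type-I (sequential) sums of squares and returns, per effect,
    ``omega^2 = (SS_effect - df_effect * MS_error) / (SS_total + MS_error)``
    clamped to [0, 1] (``clamp=False`` keeps the raw, approximately
    unbiased estimate, which can go slightly negative for null effects).
    Requires replication (a positive error df) and at least two levels per
    factor.  Unbalanced layouts trigger a warning, as the sequential
    decomposition is then order-dependent.
    """
    if not factors:
        raise ValueError("at least one factor required")
    df = data.dropna(subset=[response] + factors).copy()
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    cell_sizes = df.groupby(factors).size()
    if cell_sizes.nunique() > 1:
        warnings.warn(
            "unbalanced factorial layout: Type-I omega^2 is order-dependent",
            stacklevel=2,
        )
    formula = f"{response} ~ " + "*".join(f"C({f})" for f in factors)
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    if table.loc["Residual", "df"] <= 0:
        raise ValueError("no replication: error mean square undefined")
    mse = table.loc["Residual", "sum_sq"] / table.loc["Residual", "df"]
    ss_total = float(table["sum_sq"].sum())
    results = []
    for name, row in table.iterrows():
        if name == "Residual":
            continue
        w2 = (row["sum_sq"] - row["df"] * mse) / (ss_total + mse)
        if clamp:
            w2 = min(max(w2, 0.0), 1.0)
        results.append(
            EffectSizeResult(
                trait=response,
                effect=name.replace("C(", "").replace(")", ""),
                sum_sq=float(row["sum_sq"]),
                df=float(row["df"]),
                omega_squared=float(w2),
            )
        )
    return results


# ---------------------------------------------------------------------------
# diet surfaces


def metric_surface(metrics: pd.DataFrame, metric: str, genotype=None) -> DietSurface:
    """Mean of a per-vial metric per diet cell, as a yeast x sucrose matrix."""
    df = metrics if genotype is None else metrics[metrics["genotype"] == genotype]
    if len(df) == 0:
        raise ValueError("no rows for the requested genotype")
    pivot = df.pivot_table(
        index="yeast_pct", columns="sucrose_pct", values=metric, aggfunc="mean"
    ).sort_index(axis=0).sort_index(axis=1)
    return DietSurface(
        pivot.index.to_numpy(float), pivot.columns.to_numpy(float), pivot.to_numpy()
    )


def difference_surface(a: DietSurface, b: DietSurface, absolute: bool = False) -> DietSurface:
    """Cell-wise A - B (or |A - B|) between two surfaces on identical axes.

    Missing cells (NaN) propagate as missing.
    """
    if not (
        np.array_equal(a.yeast_levels, b.yeast_levels)
        and np.array_equal(a.sucrose_levels, b.sucrose_levels)
    ):
        raise ValueError("surfaces have mismatched diet axes")
    diff = a.values - b.values
    if absolute:
        diff = np.abs(diff)
    return DietSurface(a.yeast_levels.copy(), a.sucrose_levels.copy(), diff)
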