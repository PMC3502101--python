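"""Correlation and overlay analyses relating volatility, usage, expression,
GC3 and dN/dS — the stage behind the study's headline scatterplots.

Each comparison is quantified with both an ordinary least-squares fit
(slope, intercept, R^2, as regression lines on scatterplots report) and a
Spearman rank correlation, which is robust to the heavy-tailed P-value
scale.  Overlay summaries ask whether a flagged subset (elevated-volatility
or highly expressed genes) sits anywhere unusual within the full codon-usage
distribution.  No multiple-testing correction is applied across the
headline comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_HIGH_EXPRESSION_QUANTILE = 0.167


@dataclass(frozen=True)
class RegressionReport:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs n >= 3")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared out of range: {self.r_squared}")


def fit_linear(x, y) -> RegressionReport:
    """Ordinary least squares of y on x; r_squared is the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in regression input")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if np.isnan(r2):  # constant y: zero explained variance by convention
        r2 = 0.0
    return RegressionReport(
        slope=float(res.slope), intercept=float(res.intercept), r_squared=r2, n=len(x),
    )


@dataclass(frozen=True)
class OverlaySummary:
    subset_mean: float
    subset_sd: float
    complement_mean: float
    complement_sd: float
    full_mean: float
    full_sd: float
    test_statistic: float
    test_pvalue: float
    n_subset: int
    n_total: int


def overlay_summary(values, flags) -> OverlaySummary:
    """Descriptive stats of a flagged subset vs its complement, plus a
    Mann-Whitney rank test for a location difference."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if values.shape != flags.shape:
        raise ValueError("values and flags must align")
    if not flags.any():
        raise ValueError("empty subset")
    sub, comp = values[flags], values[~flags]
    if len(comp) == 0:
        stat, p = float("nan"), float("nan")
    else:
        stat, p = stats.mannwhitneyu(sub, comp, alternative="two-sided")
    return OverlaySummary(
        subset_mean=float(sub.mean()), subset_sd=float(sub.std(ddof=1)) if len(sub) > 1 else 0.0,
        complement_mean=float(comp.mean()) if len(comp) else float("nan"),
        complement_sd=float(comp.std(ddof=1)) if len(comp) > 1 else float("nan"),
        full_mean=float(values.mean()), full_sd=float(values.std(ddof=1)),
        test_statistic=float(stat), test_pvalue=float(p),
        n_subset=int(flags.sum()), n_total=len(values),
    )


def select_high_expression(
    expression: pd.Series, top_n: int | None = None, quantile: float | None = None
) -> pd.Series:
    """Boolean flags for the most highly expressed genes.

    Exactly one of ``top_n`` or ``quantile`` must be given; ``quantile`` q
    flags the top round(n * (1 - q)) genes.  Ties are broken by gene id so
    the selection is deterministic.
    """
    if (top_n is None) == (quantile is None):
        raise ValueError("give exactly one of top_n or quantile")
    n = len(expression)
    if top_n is None:
        if not 0 < quantile < 1:
            raise ValueError("quantile must lie in (0, 1)")
        top_n = int(round(n * (1 - quantile)))
    if top_n > n:
        raise ValueError(f"top_n {top_n} exceeds table size {n}")
    order = expression.reset_index()
    order.columns = ["gene_id", "value"]
    order = order.sort_values(["value", "gene_id"], ascending=[False, True])
    chosen = set(order["gene_id"].head(top_n))
    flags = pd.Series([g in chosen for g in expression.index], index=expression.index,
                      name="high_expression_flag")
    return flags


def build_metric_table(
    volatility: pd.DataFrame | None = None,
    usage: pd.DataFrame | None = None,
    dnds: pd.DataFrame | None = None,
    expression: pd.Series | None = None,
) -> pd.DataFrame:
    """Inner-join per-gene metric tables on gene_id."""
    parts = []
    if volatility is not None:
        v = volatility.set_index("gene_id") if "gene_id" in volatility.columns else volatility
        parts.append(v[[c for c in ("p_value", "v_sum", "v_mean", "elevated_flag") if c in v]])
    if usage is not None:
        u = usage.set_index("gene_id") if "gene_id" in usage.columns else usage
        parts.append(u[[c for c in ("axis1", "axis2", "enc", "gc3") if c in u]])
    if dnds is not None:
        d = dnds.set_index("gene_id") if "gene_id" in dnds.columns else dnds
        parts.append(d[[c for c in ("omega", "dN", "dS") if c in d]])
    if expression is not None:
        parts.append(expression.rename("expression").to_frame())
    if not parts:
        raise ValueError("no metric tables supplied")
    out = parts[0]
    for p in parts[1:]:
        out = out.join(p, how="inner")
    return out


@dataclass
class Comparison:
    name: str
    x: str
    y: str
    regression: RegressionReport
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


@dataclass
class AssociationReport:
    comparisons: list[Comparison]
    overlays: dict[str, OverlaySummary]
    skipped: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comparison": c.name, "x": c.x, "y": c.y, "n": c.n,
                "slope": c.regression.slope, "intercept": c.regression.intercept,
                "r_squared": c.regression.r_squared,
                "pearson_r": c.pearson_r, "pearson_p": c.pearson_p,
                "spearman_rho": c.spearman_rho, "spearman_p": c.spearman_p,
            }
            for c in self.comparisons
        ]
        return pd.DataFrame(rows)

    def overlay_frame(self) -> pd.DataFrame:
        rows = []
        for name, ov in self.overlays.items():
            d = {"overlay": name}
            d.update({k: getattr(ov, k) for k in (
                "subset_mean", "subset_sd", "complement_mean", "complement_sd",
                "full_mean", "full_sd", "test_statistic", "test_pvalue",
                "n_subset", "n_total")})
            rows.append(d)
        return pd.DataFrame(rows)

    def get(self, name: str) -> Comparison:
        for c in self.comparisons:
            if c.name == name:
                return c
        raise KeyError(name)


# (name, x column, y column) of the four headline comparisons
HEADLINE_COMPARISONS: tuple[tuple[str, str, str], ...] = (
    ("volatility_p~omega", "omega", "p_value"),
    ("axis1~expression", "expression", "axis1"),
    ("volatility_p~gc3", "gc3", "p_value"),
    ("v_mean~gc3", "gc3", "v_mean"),
    ("axis1~gc3", "gc3", "axis1"),
)


def association_report(gmt: pd.DataFrame) -> AssociationReport:
    """Regressions and rank correlations for every available headline pair,
    plus overlay summaries of flagged subsets on the usage axes.

    Comparisons whose columns are missing are skipped with a log notice,
    never an error; the report is deterministic for fixed input.
    """
    comparisons: list[Comparison] = []
    skipped: list[str] = []
    for name, xcol, ycol in HEADLINE_COMPARISONS:
        if xcol not in gmt.columns or ycol not in gmt.columns:
            skipped.append(name)
            logger.info("association_report: skipping %s (missing column)", name)
            continue
        sub = gmt[[xcol, ycol]].dropna()
        sub = sub[np.isfinite(sub).all(axis=1)]
        if len(sub) < 3 or np.ptp(sub[xcol].to_numpy()) == 0:
            skipped.append(name)
            logger.info("association_report: skipping %s (too few finite points)", name)
            continue
        x, y = sub[xcol].to_numpy(), sub[ycol].to_numpy()
        reg = fit_linear(x, y)
        pr = stats.pearsonr(x, y)
        sr = stats.spearmanr(x, y)
        comparisons.append(Comparison(
            name=name, x=xcol, y=ycol, regression=reg,
            pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
            spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue), n=len(sub),
        ))
    overlays: dict[str, OverlaySummary] = {}
    for flag in ("elevated_flag", "high_expression_flag"):
        if flag not in gmt.columns or not gmt[flag].any() or gmt[flag].all():
            continue
        for axis in ("axis1", "axis2"):
            if axis not in gmt.columns:
                continue
            sub = gmt[[axis, flag]].dropna()
            if sub[flag].any() and not sub[flag].all():
                overlays[f"{flag}@{axis}"] = overlay_summary(
                    sub[axis].to_numpy(), sub[flag].to_numpy(dtype=bool)
                )
    return AssociationReport(comparisons=comparisons, overlays=overlays, skipped=skipped)
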