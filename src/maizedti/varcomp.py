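"""Balanced ANOVA, expected-mean-squares variance components, broad-sense
heritability and Fisher's LSD.

The model is the classical replicated germplasm-trial one: genotypes
(accessions) random, treatments (osmotic-stress environments) fixed.  For a
balanced two-way layout with g genotypes, t treatments and r replicates the
expected mean squares under that mixing are

    E[MS_e]  = sigma2_e
    E[MS_gt] = sigma2_e + r * sigma2_gt
    E[MS_g]  = sigma2_e + r * sigma2_gt + r * t * sigma2_g

which are solved by method of moments; negative solutions are truncated at
zero and flagged.  Broad-sense heritability on an entry-mean basis is

    within one treatment:   H2 = sigma2_g / (sigma2_g + sigma2_e / r)
    across t treatments:    H2 = sigma2_g / (sigma2_g + sigma2_gt / t
                                              + sigma2_e / (r t))

All sums of squares are computed from first principles on balanced grids;
unbalanced input is rejected rather than silently averaged, because the EMS
algebra above assumes balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError


def significance_stars(p: float) -> str:
    """Tiered star notation: *** p<=0.001, ** p<=0.01, * p<=0.05, ns."""
    if math.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaTable:
    """Per-source df, SS, MS, F against the error MS, and p-values."""

    sources: pd.DataFrame  # index source; columns df, ss, ms, f, p

    def __getitem__(self, source: str) -> pd.Series:
        return self.sources.loc[source]

    def to_frame(self) -> pd.DataFrame:
        out = self.sources.copy()
        out["signif"] = [significance_stars(p) for p in out["p"]]
        return out


def _as_grid(values, ndim: int) -> np.ndarray:
    try:
        arr = np.asarray(values, dtype=float)
    except ValueError as err:  # ragged nested lists
        raise ValidationError(f"unbalanced grid: {err}") from None
    if arr.ndim != ndim:
        raise ValidationError(
            f"expected a balanced {ndim}-d grid, got shape {arr.shape}; "
            "unbalanced designs are not supported"
        )
    if np.isnan(arr).any():
        raise ValidationError(
            "grid contains missing values; balanced complete data required"
        )
    return arr


def _ss_floor(y: np.ndarray, grand: float) -> float:
    # SS below this are float residue of an (effectively) all-equal grid and
    # must collapse to exact zero: otherwise the EMS ratio of ~1e-30 sums of
    # squares fabricates a heritability of 1 on perfectly degenerate data
    return y.size * (1e-12 * max(1.0, abs(grand))) ** 2


def _f_p(ms_num: float, df_num: int, ms_err: float, df_err: int):
    if ms_err <= 0:
        return math.nan, math.nan
    f = ms_num / ms_err
    return f, float(stats.f.sf(f, df_num, df_err))


def anova_oneway(values) -> AnovaTable:
    """One-way genotype ANOVA on a balanced (genotypes x replicates) grid.

    SS_genotype = r * sum_i (mean_i - grand)^2; SS_error by subtraction from
    the total.  With MS_error = 0 (e.g. all values equal) F and p are
    reported as missing rather than infinite.
    """
    y = _as_grid(values, 2)
    g, r = y.shape
    if g < 2 or r < 2:
        raise ValidationError(
            f"one-way ANOVA needs >=2 genotypes and >=2 replicates, got {g}x{r}"
        )
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_g = float(r * ((y.mean(axis=1) - grand) ** 2).sum())
    if ss_total <= _ss_floor(y, grand):
        ss_total = ss_g = 0.0
    ss_e = max(ss_total - ss_g, 0.0)
    df_g, df_e = g - 1, g * (r - 1)
    ms_g, ms_e = ss_g / df_g, ss_e / df_e
    f, p = _f_p(ms_g, df_g, ms_e, df_e)
    table = pd.DataFrame(
        {
            "df": [df_g, df_e, g * r - 1],
            "ss": [ss_g, ss_e, ss_total],
            "ms": [ms_g, ms_e, math.nan],
            "f": [f, math.nan, math.nan],
            "p": [p, math.nan, math.nan],
        },
        index=pd.Index(["genotype", "error", "total"], name="source"),
    )
    return AnovaTable(table)


def anova_twoway(values) -> AnovaTable:
    """Two-way genotype x treatment ANOVA on a balanced (g, t, r) grid.

    Standard balanced-design decomposition into genotype, treatment,
    interaction and error sums of squares; both main-factor F tests and the
    interaction F test use the error MS (treatments fixed, genotypes random;
    under genotypes-random mixing the treatment F against MS_gt is also of
    interest, but the error-MS tests are what the germplasm-trial reports
    tabulate).
    """
    y = _as_grid(values, 3)
    g, t, r = y.shape
    if g < 2 or t < 2:
        raise ValidationError(
            f"two-way ANOVA needs >=2 levels per factor, got {g}x{t}"
        )
    if r < 2:
        raise ValidationError(
            "single replicate per cell leaves zero error degrees of freedom"
        )
    grand = y.mean()
    mean_g = y.mean(axis=(1, 2))
    mean_t = y.mean(axis=(0, 2))
    mean_gt = y.mean(axis=2)
    ss_total = float(((y - grand) ** 2).sum())
    ss_g = float(t * r * ((mean_g - grand) ** 2).sum())
    ss_t = float(g * r * ((mean_t - grand) ** 2).sum())
    ss_gt = float(
        r * ((mean_gt - mean_g[:, None] - mean_t[None, :] + grand) ** 2).sum()
    )
    if ss_total <= _ss_floor(y, grand):
        ss_total = ss_g = ss_t = ss_gt = 0.0
    ss_e = max(ss_total - ss_g - ss_t - ss_gt, 0.0)
    df_g, df_t = g - 1, t - 1
    df_gt, df_e = df_g * df_t, g * t * (r - 1)
    ms = [ss_g / df_g, ss_t / df_t, ss_gt / df_gt, ss_e / df_e]
    f_g, p_g = _f_p(ms[0], df_g, ms[3], df_e)
    f_t, p_t = _f_p(ms[1], df_t, ms[3], df_e)
    f_gt, p_gt = _f_p(ms[2], df_gt, ms[3], df_e)
    table = pd.DataFrame(
        {
            "df": [df_g, df_t, df_gt, df_e, g * t * r - 1],
            "ss": [ss_g, ss_t, ss_gt, ss_e, ss_total],
            "ms": ms + [math.nan],
            "f": [f_g, f_t, f_gt, math.nan, math.nan],
            "p": [p_g, p_t, p_gt, math.nan, math.nan],
        },
        index=pd.Index(
            ["genotype", "treatment", "interaction", "error", "total"],
            name="source",
        ),
    )
    return AnovaTable(table)


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    sigma2_gt: float | None
    r: int
    t: int | None
    truncated: tuple[str, ...] = field(default_factory=tuple)


def variance_components(
    table: AnovaTable, r: int, t: int | None = None
) -> VarianceComponents:
    """Method-of-moments components from a balanced ANOVA table.

    One-way: sigma2_e = MS_e, sigma2_g = (MS_g - MS_e) / r.
    Two-way (genotypes random, treatments fixed): sigma2_e = MS_e,
    sigma2_gt = (MS_gt - MS_e) / r, sigma2_g = (MS_g - MS_gt) / (r t).
    Negative solutions are truncated to zero and recorded in ``truncated``.
    """
    if r < 1 or (t is not None and t < 1):
        raise ValidationError(f"invalid design: r={r}, t={t}")
    src = table.sources
    truncated: list[str] = []

    def _trunc(name: str, value: float) -> float:
        if value < 0:
            truncated.append(name)
            return 0.0
        return value

    ms_e = float(src.loc["error", "ms"])
    if "interaction" in src.index:
        if t is None:
            raise ValidationError("two-way table requires the treatment count t")
        ms_gt = float(src.loc["interaction", "ms"])
        ms_g = float(src.loc["genotype", "ms"])
        s_gt = _trunc("sigma2_gt", (ms_gt - ms_e) / r)
        s_g = _trunc("sigma2_g", (ms_g - ms_gt) / (r * t))
        return VarianceComponents(s_g, ms_e, s_gt, r, t, tuple(truncated))
    ms_g = float(src.loc["genotype", "ms"])
    s_g = _trunc("sigma2_g", (ms_g - ms_e) / r)
    return VarianceComponents(s_g, ms_e, None, r, None, tuple(truncated))


@dataclass
class Heritability:
    h2: float
    scope: str  # "within-treatment" | "across-treatments"


def heritability(vc: VarianceComponents, scope: str = "within-treatment") -> Heritability:
    """Broad-sense heritability on an entry-mean basis, clipped to [0, 1].

    Returns NaN when the phenotypic-variance denominator is zero (no
    variation at all), the undefined marker for degenerate data.
    """
    if scope == "within-treatment":
        denom = vc.sigma2_g + vc.sigma2_e / vc.r
    elif scope == "across-treatments":
        if vc.sigma2_gt is None or vc.t is None:
            raise ValidationError(
                "across-treatments heritability needs two-way components"
            )
        denom = vc.sigma2_g + vc.sigma2_gt / vc.t + vc.sigma2_e / (vc.r * vc.t)
    else:
        raise ValidationError(f"unknown heritability scope {scope!r}")
    if denom <= 0:
        return Heritability(math.nan, scope)
    return Heritability(min(max(vc.sigma2_g / denom, 0.0), 1.0), scope)


@dataclass
class LsdResult:
    lsd: float
    alpha: float
    df_error: int
    mse: float
    n_per_mean: int


def fisher_lsd(
    mse: float, df_error: int, n_per_mean: int, alpha: float = 0.05
) -> LsdResult:
    """Fisher's least significant difference between two equally replicated
    means sharing a pooled error variance:

        LSD = t(1 - alpha/2, df_error) * sqrt(2 * MSE / n)
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if df_error < 1 or n_per_mean < 1:
        raise ValidationError(
            f"invalid df_error={df_error} or n_per_mean={n_per_mean}"
        )
    if mse < 0:
        raise ValidationError(f"MSE must be non-negative, got {mse}")
    t_crit = float(stats.t.ppf(1 - alpha / 2, df_error))
    return LsdResult(t_crit * math.sqrt(2 * mse / n_per_mean),
                     alpha, df_error, mse, n_per_mean)
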