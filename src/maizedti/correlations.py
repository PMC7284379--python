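"""Pearson correlations over accession trait means with tiered significance.

Correlations are computed between trait columns of an accession-mean table
(each column is one trait under one treatment context, so control and stress
variants of the same trait are separate columns, as in the 17- and 27-column
views of the screening trial).  Significance is the usual two-sided t test

    t = r * sqrt((n - 2) / (1 - r^2))   on n - 2 df

reported in tiers (* 0.05, ** 0.01, *** 0.001) without multiple-testing
correction, matching the tiered-star convention of germplasm-trial reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError
from .varcomp import significance_stars

TIER_ALPHAS = {"0.05": 0.05, "0.01": 0.01, "0.001": 0.001}


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with its two-sided t-test p-value on pairwise-complete data.

    Returns (NaN, NaN) for fewer than 3 complete pairs or a zero-variance
    input; |r| = 1 gets p = 0.
    """
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        return math.nan, math.nan
    sx = x - x.mean()
    sy = y - y.mean()
    den = math.sqrt(float(sx @ sx) * float(sy @ sy))
    if den == 0:
        return math.nan, math.nan
    r = float(sx @ sy) / den
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * float(stats.t.sf(abs(t), n - 2))
    return r, p


@dataclass
class CorrelationResult:
    """Symmetric r and p matrices over trait columns, plus significance tiers."""

    r: pd.DataFrame
    p: pd.DataFrame

    @property
    def tiers(self) -> pd.DataFrame:
        return self.p.map(lambda p: tier_of(p))

    def pairs(self) -> pd.DataFrame:
        """Long table of unordered pairs with r, p and tier."""
        cols = list(self.r.columns)
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rows.append(
                    {
                        "trait_a": a,
                        "trait_b": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "tier": tier_of(self.p.loc[a, b]),
                    }
                )
        return pd.DataFrame(rows)

    def lower_triangle_csv(self, path) -> None:
        """Lower-triangle export with star annotations."""
        cols = list(self.r.columns)
        out = pd.DataFrame("", index=cols, columns=cols, dtype=object)
        for i, a in enumerate(cols):
            out.loc[a, a] = "1"
            for b in cols[:i]:
                r, p = self.r.loc[a, b], self.p.loc[a, b]
                if math.isnan(r):
                    out.loc[a, b] = "na"
                else:
                    out.loc[a, b] = f"{r:.2f}{significance_stars(p).replace('ns', '')}"
        out.to_csv(path, index_label="trait")


def tier_of(p: float) -> str:
    """Significance tier of a p-value: ns / 0.05 / 0.01 / 0.001."""
    if isinstance(p, float) and math.isnan(p):
        return "na"
    for tier in ("0.001", "0.01", "0.05"):
        if p <= TIER_ALPHAS[tier]:
            return tier
    return "ns"


def correlation_matrix(means: pd.DataFrame) -> CorrelationResult:
    """All pairwise Pearson correlations of an accession x trait mean table.

    Pairwise-complete observations; self-correlation is 1 by definition;
    zero-variance columns yield missing r for all their pairs.
    """
    if means.shape[0] < 4:
        raise ValidationError(
            f"need >=4 accessions for correlations, got {means.shape[0]}"
        )
    cols = list(means.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    data = means.to_numpy(dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = pearson_r_p(data[:, i], data[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    # a zero-variance column is degenerate even on the diagonal
    for i in range(k):
        if np.nanstd(data[:, i]) == 0:
            r[i, :] = r[:, i] = np.nan
            p[i, :] = p[:, i] = np.nan
    return CorrelationResult(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
    )


def count_significant(
    result: CorrelationResult, r_threshold: float, tier: str = "0.001"
) -> int:
    """Unordered trait pairs with r >= threshold at the given tier or stricter.

    Counts positive correlations only (r >= threshold, not |r|), the
    convention used when tallying "highly significant r >= 0.70" pairs.
    """
    if tier not in TIER_ALPHAS:
        raise ValidationError(f"unknown tier {tier!r}")
    alpha = TIER_ALPHAS[tier]
    pairs = result.pairs()
    if pairs.empty:
        return 0
    ok = (pairs["r"] >= r_threshold) & (pairs["p"] <= alpha)
    return int(ok.sum())
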