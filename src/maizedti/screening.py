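"""Performance-band screening tabulation and DTI-matrix PCA ranking.

Band screening: per trait and condition, the ceil(q*n) best and the
ceil(q*n) worst accessions are flagged (direction-aware: "best" abnormal-
seedling percentage is the smallest).  Counting how often each accession
lands in a top or bottom band across traits, per condition, gives the
screening frequency table used to shortlist candidate tolerant and
susceptible accessions.

PCA: the DTI matrix is standardized column-wise and the correlation matrix
eigendecomposed, because DTI columns live on heterogeneous scales (AS-DTI
can reach 20-30 while trait DTIs sit below 1).  Eigenvector signs are fixed
deterministically (largest-magnitude loading positive) so scores are
reproducible run to run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import TRAITS, ValidationError
from .indices import DTIMatrix

CONDITION_ORDER = ("control", "peg10", "peg15", "peg20")


@dataclass(frozen=True)
class BandAssignment:
    """Top and bottom accession sets for one trait under one condition."""

    condition: str
    trait: str
    top_set: frozenset[str]
    bottom_set: frozenset[str]


def _band(values: pd.Series, size: int, best_is_max: bool) -> tuple[frozenset, frozenset]:
    vals = values.dropna()
    # deterministic direction-aware ranking; ties broken by accession id
    def order(best: bool) -> list[str]:
        ascending = best != best_is_max
        return sorted(
            vals.index,
            key=lambda a: ((vals[a] if ascending else -vals[a]), str(a)),
        )

    return (frozenset(order(True)[:size]), frozenset(order(False)[:size]))


def assign_bands(
    means_by_condition: Mapping[str, pd.DataFrame],
    q: float = 0.05,
    directions: Mapping[str, bool] | None = None,
) -> list[BandAssignment]:
    """Flag the ceil(q*n) best and worst accessions per trait and condition.

    ``means_by_condition`` maps a condition label to an accession x trait
    mean table.  ``directions`` overrides the trait-registry higher-is-better
    flags (useful for DTI columns).  Band size is ceil(q * n_accessions).
    """
    if not 0 < q <= 0.5:
        raise ValidationError(f"band fraction q must be in (0, 0.5], got {q}")
    out: list[BandAssignment] = []
    for cond, means in means_by_condition.items():
        n = means.shape[0]
        size = math.ceil(q * n)
        for trait in means.columns:
            if directions is not None and trait in directions:
                best_is_max = directions[trait]
            elif trait in TRAITS:
                best_is_max = TRAITS[trait].higher_is_better
            else:
                best_is_max = True
            top, bottom = _band(means[trait], size, best_is_max)
            out.append(BandAssignment(cond, trait, top, bottom))
    return out


@dataclass
class ScreeningReport:
    """Per-accession top/bottom band counts per condition, with totals.

    ``counts`` has one row per accession and a column per
    (side, condition) pair plus a total per side; integer additivity
    (row total = sum of its per-condition counts, grand total = sum over
    accessions) holds by construction.
    """

    counts: pd.DataFrame
    conditions: tuple[str, ...]

    @classmethod
    def from_bands(
        cls, bands: Sequence[BandAssignment], accessions: Sequence[str] | None = None
    ) -> "ScreeningReport":
        conds = [c for c in CONDITION_ORDER if any(b.condition == c for b in bands)]
        conds += sorted({b.condition for b in bands} - set(conds))
        if accessions is None:
            acc: set[str] = set()
            for b in bands:
                acc |= b.top_set | b.bottom_set
            accessions = sorted(acc)
        counts = pd.DataFrame(
            0,
            index=pd.Index(accessions, name="accession"),
            columns=[f"{side}_{c}" for side in ("top", "bottom") for c in conds],
            dtype=int,
        )
        for b in bands:
            for a in b.top_set:
                counts.loc[a, f"top_{b.condition}"] += 1
            for a in b.bottom_set:
                counts.loc[a, f"bottom_{b.condition}"] += 1
        return cls._with_totals(counts, tuple(conds))

    @classmethod
    def from_counts(cls, table: pd.DataFrame) -> "ScreeningReport":
        """Fixture mode: ingest a pre-counted per-condition table.

        ``table`` must be indexed by accession with integer columns named
        ``top_<condition>`` / ``bottom_<condition>``; totals are recomputed
        from these counts, never ingested.
        """
        cols = list(table.columns)
        conds = []
        for c in CONDITION_ORDER:
            if f"top_{c}" in cols or f"bottom_{c}" in cols:
                conds.append(c)
        if not conds:
            raise ValidationError(
                "expected columns named top_<condition>/bottom_<condition>"
            )
        counts = table.copy()
        counts.index.name = "accession"
        if (counts.to_numpy() < 0).any():
            raise ValidationError("band counts must be non-negative")
        return cls._with_totals(counts.astype(int), tuple(conds))

    @classmethod
    def _with_totals(cls, counts: pd.DataFrame, conds: tuple[str, ...]):
        for side in ("top", "bottom"):
            cc = [f"{side}_{c}" for c in conds if f"{side}_{c}" in counts.columns]
            counts[f"{side}_total"] = counts[cc].sum(axis=1)
        return cls(counts=counts, conditions=conds)

    def total(self, side: str, accession: str | None = None) -> int:
        """Row total for one accession, or the grand total over all."""
        col = f"{side}_total"
        if accession is not None:
            return int(self.counts.loc[accession, col])
        return int(self.counts[col].sum())

    def condition_totals(self, side: str) -> pd.Series:
        cols = [f"{side}_{c}" for c in self.conditions]
        return self.counts[cols].sum(axis=0)

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


def load_reference_screening_counts() -> pd.DataFrame:
    """Published per-condition screening counts for the 40-accession IPK
    maize drought panel (5% performance bands under control and 10/15/20%
    PEG), for use with :meth:`ScreeningReport.from_counts`."""
    path = resources.files("maizedti.data") / "ipk_maize_screening_counts.csv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, index_col="accession")


def threshold_accessions(
    report: ScreeningReport, k: int, side: str = "top"
) -> pd.Series:
    """Accessions whose ``side`` total is >= k, sorted by total descending.

    Ties break alphabetically; returns a Series accession -> total.
    """
    if side not in ("top", "bottom"):
        raise ValidationError(f"side must be 'top' or 'bottom', got {side!r}")
    totals = report.counts[f"{side}_total"]
    hits = totals[totals >= k]
    order = sorted(hits.index, key=lambda a: (-hits[a], str(a)))
    return hits.loc[order]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """Correlation-matrix PCA of a standardized DTI matrix."""

    standardized: pd.DataFrame
    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # columns PC1..PCk, index = retained DTI columns
    scores: pd.DataFrame  # accessions x PCs
    dropped_columns: list = field(default_factory=list)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def pca_dti(matrix: DTIMatrix | pd.DataFrame, missing: str = "mean") -> PcaResult:
    """PCA of the DTI matrix on its correlation structure.

    Columns are standardized to zero mean and unit variance (so eigenvalues
    sum to the number of retained columns); missing cells are mean-imputed
    (``missing="mean"``, i.e. zero after standardization) or the offending
    accessions dropped (``missing="drop"``).  Constant columns are dropped
    with a warning.  Loading-vector signs are fixed so each component's
    largest-magnitude loading is positive.
    """
    values = matrix.values if isinstance(matrix, DTIMatrix) else matrix
    data = values.copy()
    if missing == "drop":
        data = data.dropna(axis=0)
    elif missing != "mean":
        raise ValidationError(f"unknown missing-cell policy {missing!r}")
    if data.shape[0] < 3 or data.shape[1] < 2:
        raise ValidationError(
            f"PCA needs >=3 accessions and >=2 columns, got {data.shape}"
        )
    sd = data.std(axis=0, ddof=1)
    constant = [c for c in data.columns if not sd[c] > 0]
    if constant:
        warnings.warn(f"dropping constant DTI columns: {constant}", stacklevel=2)
        data = data.drop(columns=constant)
        if data.shape[1] < 2:
            raise ValidationError("fewer than 2 non-constant columns remain")
    z = (data - data.mean(axis=0)) / data.std(axis=0, ddof=1)
    if missing == "mean":
        z = z.fillna(0.0)
    corr = np.asarray(z, dtype=float)
    corr = corr.T @ corr / (z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(eigvec.shape[1]):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    pcs = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=data.columns, columns=pcs)
    scores = pd.DataFrame(z.to_numpy() @ eigvec, index=data.index, columns=pcs)
    return PcaResult(
        standardized=z,
        eigenvalues=eigval,
        loadings=loadings,
        scores=scores,
        dropped_columns=constant,
    )
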