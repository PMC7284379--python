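"""Synthetic replicated phenotype datasets with known variance structure.

The generator emulates a PEG-6000 drought-screening trial: ``n_accessions``
genotypes x 4 treatments (control, 10/15/20% PEG) x ``r`` replicate rolls of
17-20 seeds.  Continuous traits follow

    y_ijk = mu_trait * f_j + g_i + (g tau)_ij + eps_ijk

with multiplicative treatment effects ``f_j`` (so the expected DTI at level
j is exactly ``f_j``: the additive genotype/interaction/residual effects are
zero-mean and cancel in expectation), genotype effects g_i ~ N(0, sigma2_g),
interaction effects ~ N(0, sigma2_gt) and residuals ~ N(0, sigma2_e),
truncated at zero on the physical scale.  Germination and abnormal-seedling
counts are binomial per replicate with logit-linear genotype and treatment
effects, which keeps probabilities in (0, 1) and count invariants
(abnormal <= germinated <= sown) automatic.

Default baseline means and per-level reduction fractions reproduce the
grand means observed in the real 40-accession IPK maize screen (e.g. G%
94.3 -> 90.4 -> 83.9 -> 73.4 and 16-day shoot length 28.7 -> 22.1 -> 13.9);
default variance magnitudes give the medium-to-high entry-mean
heritabilities such trials report.  Every draw is reproducible from the
configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import (
    TRAITS,
    TREATMENTS,
    PhenotypeDataset,
    TreatmentLevel,
    ValidationError,
)


@dataclass(frozen=True)
class TraitSim:
    """Simulation parameters for one continuous trait.

    ``reductions`` maps a stress-treatment label to the multiplicative
    effect f on the baseline mean (f < 1: reduction; the 9-day shoot dry
    weight of the real trial actually rises under 10% PEG, so f > 1 is
    allowed).  Variances are on the trait scale.
    """

    baseline: float
    reductions: dict[str, float]
    sigma2_g: float
    sigma2_gt: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValidationError(f"baseline mean must be positive: {self.baseline}")
        for v in (self.sigma2_g, self.sigma2_gt, self.sigma2_e):
            if v < 0:
                raise ValidationError(f"negative variance component: {v}")
        for lab, f in self.reductions.items():
            if f < 0:
                raise ValidationError(f"negative treatment effect {f} at {lab}")

    @classmethod
    def from_h2(
        cls,
        baseline: float,
        reductions: dict[str, float],
        h2: float,
        r: int = 3,
        cv_g: float = 0.10,
        gt_ratio: float = 0.25,
    ) -> "TraitSim":
        """Build a trait with a target within-treatment entry-mean H².

        Genotype SD is ``cv_g * baseline``; the residual variance is solved
        from H² = sigma2_g / (sigma2_g + sigma2_e / r); the interaction
        variance is ``gt_ratio * sigma2_g``.
        """
        if not 0 < h2 < 1:
            raise ValidationError(f"target H2 must be in (0, 1), got {h2}")
        s_g = (cv_g * baseline) ** 2
        s_e = r * s_g * (1.0 / h2 - 1.0)
        return cls(baseline, dict(reductions), s_g, gt_ratio * s_g, s_e)

    def h2_within(self, r: int) -> float:
        denom = self.sigma2_g + self.sigma2_e / r
        return self.sigma2_g / denom if denom > 0 else math.nan

    def h2_across(self, r: int, t: int) -> float:
        denom = self.sigma2_g + self.sigma2_gt / t + self.sigma2_e / (r * t)
        return self.sigma2_g / denom if denom > 0 else math.nan


@dataclass(frozen=True)
class BinomialSim:
    """Logit-linear simulation parameters for a per-replicate proportion.

    ``level_probs`` are the target marginal probabilities per treatment
    label; genotype and interaction effects are normal on the logit scale.
    """

    level_probs: dict[str, float]
    sigma2_g_logit: float = 0.09
    sigma2_gt_logit: float = 0.02

    def __post_init__(self) -> None:
        for lab, p in self.level_probs.items():
            if not 0 < p < 1:
                raise ValidationError(f"probability at {lab} must be in (0,1): {p}")
        if self.sigma2_g_logit < 0 or self.sigma2_gt_logit < 0:
            raise ValidationError("logit-scale variances must be >= 0")


# Defaults mirror the observed grand means of the real 40-accession screen.
_G_TARGETS = {"control": 0.9428, "peg10": 0.9039, "peg15": 0.8386, "peg20": 0.7341}
_AS_TARGETS = {"control": 0.0741, "peg10": 0.1768, "peg15": 0.3244, "peg20": 0.4868}

_TRAIT_MEANS: dict[str, dict[str, float]] = {
    "ShL1": {"control": 13.09, "peg10": 5.32},
    "ShFW1": {"control": 0.550, "peg10": 0.190},
    "ShDW1": {"control": 0.056, "peg10": 0.189},
    "RL1": {"control": 16.34, "peg10": 13.00},
    "RFW1": {"control": 0.382, "peg10": 0.189},
    "RDW1": {"control": 0.056, "peg10": 0.070},
    "ShL2": {"control": 28.68, "peg10": 22.12, "peg15": 13.86},
    "ShFW2": {"control": 0.925, "peg10": 0.529, "peg15": 0.305},
    "ShDW2": {"control": 0.084, "peg10": 0.062, "peg15": 0.045},
    "RL2": {"control": 27.20, "peg10": 19.87, "peg15": 17.68},
    "RFW2": {"control": 0.742, "peg10": 0.485, "peg15": 0.248},
    "RDW2": {"control": 0.063, "peg10": 0.052, "peg15": 0.038},
    "LL": {"control": 20.63, "peg10": 14.78},
    "LW": {"control": 0.954, "peg10": 0.883},
    "RWC": {"control": 94.22, "peg10": 86.56},
}


def _default_traits() -> dict[str, TraitSim]:
    out = {}
    for code, means in _TRAIT_MEANS.items():
        base = means["control"]
        red = {lab: m / base for lab, m in means.items() if lab != "control"}
        # genotype and residual SD at 10% of baseline, interaction SD at 5%:
        # a within-treatment entry-mean H2 of 0.75 at r = 3.  RWC is bounded
        # at 100% near its baseline, so it gets small absolute SDs (2/1/2
        # percentage points) to keep truncation negligible.
        sd_g, sd_gt, sd_e = 0.10 * base, 0.05 * base, 0.10 * base
        if code == "RWC":
            sd_g, sd_gt, sd_e = 2.0, 1.0, 2.0
        out[code] = TraitSim(
            baseline=base,
            reductions=red,
            sigma2_g=sd_g**2,
            sigma2_gt=sd_gt**2,
            sigma2_e=sd_e**2,
        )
    return out


@dataclass
class SimulationConfig:
    """Full design and variance specification for one synthetic trial."""

    n_accessions: int = 40
    r: int = 3
    seeds_per_replicate: tuple[int, int] = (17, 20)
    treatments: tuple[TreatmentLevel, ...] = TREATMENTS
    traits: dict[str, TraitSim] = field(default_factory=_default_traits)
    germination: BinomialSim = field(
        default_factory=lambda: BinomialSim(dict(_G_TARGETS))
    )
    abnormal: BinomialSim = field(
        default_factory=lambda: BinomialSim(dict(_AS_TARGETS))
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1 or self.r < 1:
            raise ValidationError("need >=1 accession and >=1 replicate")
        lo, hi = self.seeds_per_replicate
        if not 1 <= lo <= hi:
            raise ValidationError(
                f"invalid seeds_per_replicate range {self.seeds_per_replicate}"
            )
        labels = {t.label for t in self.treatments}
        if "control" not in labels:
            raise ValidationError("design must include the control treatment")
        for code, ts in self.traits.items():
            if code not in TRAITS or code in ("G", "AS"):
                raise ValidationError(f"unknown continuous trait code {code!r}")
            unknown = set(ts.reductions) - (labels - {"control"})
            if unknown:
                raise ValidationError(
                    f"trait {code}: reduction levels {sorted(unknown)} not in design"
                )
        for model in (self.germination, self.abnormal):
            missing = labels - set(model.level_probs)
            if missing:
                raise ValidationError(
                    f"count model missing probabilities for {sorted(missing)}"
                )

    def accession_names(self) -> list[str]:
        width = len(str(self.n_accessions))
        return [f"ACC{str(i + 1).zfill(width)}" for i in range(self.n_accessions)]


def noiseless(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of a config with every variance component zeroed (for degenerate
    and identity checks; counts become deterministic rounded expectations)."""
    traits = {
        c: replace(t, sigma2_g=0.0, sigma2_gt=0.0, sigma2_e=0.0)
        for c, t in cfg.traits.items()
    }
    return replace(
        cfg,
        traits=traits,
        germination=replace(cfg.germination, sigma2_g_logit=0.0, sigma2_gt_logit=0.0),
        abnormal=replace(cfg.abnormal, sigma2_g_logit=0.0, sigma2_gt_logit=0.0),
    )


def _is_noiseless(cfg: SimulationConfig) -> bool:
    return (
        all(t.sigma2_g == t.sigma2_gt == t.sigma2_e == 0 for t in cfg.traits.values())
        and cfg.germination.sigma2_g_logit == cfg.germination.sigma2_gt_logit == 0
        and cfg.abnormal.sigma2_g_logit == cfg.abnormal.sigma2_gt_logit == 0
    )


def simulate_dataset(cfg: SimulationConfig) -> PhenotypeDataset:
    """Draw one balanced synthetic trial honoring the trait-availability
    pattern of the assay; bit-reproducible from ``cfg.seed``.

    In the fully noiseless limit counts are deterministic rounded
    expectations (so replicate percentages, hence DTIs, are exact) and every
    continuous replicate equals its expected cell mean.
    """
    rng = np.random.default_rng(cfg.seed)
    acc = cfg.accession_names()
    n, r = cfg.n_accessions, cfg.r
    labels = [t.label for t in cfg.treatments]
    t_count = len(labels)
    deterministic_counts = _is_noiseless(cfg)

    # germination + abnormal counts -------------------------------------
    lo, hi = cfg.seeds_per_replicate
    g_rows = []
    g_eff = rng.normal(0.0, math.sqrt(cfg.germination.sigma2_g_logit), n)
    g_int = rng.normal(0.0, math.sqrt(cfg.germination.sigma2_gt_logit), (n, t_count))
    a_eff = rng.normal(0.0, math.sqrt(cfg.abnormal.sigma2_g_logit), n)
    a_int = rng.normal(0.0, math.sqrt(cfg.abnormal.sigma2_gt_logit), (n, t_count))
    for j, lab in enumerate(labels):
        p_g = expit(logit(cfg.germination.level_probs[lab]) + g_eff + g_int[:, j])
        p_a = expit(logit(cfg.abnormal.level_probs[lab]) + a_eff + a_int[:, j])
        for k in range(r):
            if deterministic_counts:
                sown = np.full(n, hi)
                germ = np.rint(sown * p_g).astype(int)
                abn = np.rint(germ * p_a).astype(int)
            else:
                sown = rng.integers(lo, hi + 1, size=n)
                germ = rng.binomial(sown, p_g)
                abn = rng.binomial(germ, p_a)
            for i, a in enumerate(acc):
                g_rows.append((a, lab, k + 1, int(sown[i]), int(germ[i]), int(abn[i])))
    germination = pd.DataFrame(
        g_rows,
        columns=["accession", "treatment", "replicate",
                 "n_sown", "n_germinated", "n_abnormal"],
    )

    # continuous traits --------------------------------------------------
    t_rows = []
    for code, ts in cfg.traits.items():
        avail = [lab for lab in labels
                 if lab in {t.label for t in TRAITS[code].measured_under}]
        g_i = rng.normal(0.0, math.sqrt(ts.sigma2_g), n)
        gt_ij = rng.normal(0.0, math.sqrt(ts.sigma2_gt), (n, len(avail)))
        for j, lab in enumerate(avail):
            f = 1.0 if lab == "control" else ts.reductions.get(lab)
            if f is None:
                continue
            mu = ts.baseline * f
            eps = rng.normal(0.0, math.sqrt(ts.sigma2_e), (n, r))
            upper = 100.0 if TRAITS[code].units == "%" else None
            y = np.clip(mu + g_i[:, None] + gt_ij[:, j][:, None] + eps, 0.0, upper)
            for i, a in enumerate(acc):
                for k in range(r):
                    t_rows.append((a, lab, k + 1, code, float(y[i, k])))
    traits = pd.DataFrame(
        t_rows, columns=["accession", "treatment", "replicate", "trait", "value"]
    )
    return PhenotypeDataset(germination=germination, traits=traits)


def truth_record(cfg: SimulationConfig) -> pd.DataFrame:
    """Ground-truth table per trait: variance components, entry-mean
    heritabilities at the configured design, and the expected DTI per level
    (the additive effects are zero-mean, so the expected DTI at level j is
    the configured multiplicative effect f_j; count traits report their
    probability-ratio expectations)."""
    stress = [t.label for t in cfg.treatments if not t.is_control]
    rows = []
    for code, ts in cfg.traits.items():
        t_avail = 1 + len(ts.reductions)
        row = {
            "trait": code,
            "sigma2_g": ts.sigma2_g,
            "sigma2_gt": ts.sigma2_gt,
            "sigma2_e": ts.sigma2_e,
            "h2_within": ts.h2_within(cfg.r),
            "h2_across": ts.h2_across(cfg.r, t_avail),
        }
        for lab in stress:
            row[f"dti_{lab}"] = ts.reductions.get(lab, math.nan)
        rows.append(row)
    for code, model in (("G", cfg.germination), ("AS", cfg.abnormal)):
        p0 = model.level_probs["control"]
        row = {
            "trait": code,
            "sigma2_g": math.nan,
            "sigma2_gt": math.nan,
            "sigma2_e": math.nan,
            "h2_within": math.nan,
            "h2_across": math.nan,
        }
        for lab in stress:
            row[f"dti_{lab}"] = model.level_probs[lab] / p0
        rows.append(row)
    return pd.DataFrame(rows).set_index("trait")
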