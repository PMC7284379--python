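"""Phenotype data schema, trait/treatment metadata, validation and CSV IO.

The screening design follows the standard PEG-6000 osmotic-stress germination
assay: each maize accession is germinated under a water control and under
10%, 15% and 20% m/v PEG, in replicated sets of 17-20 seeds.  Germination and
abnormal-seedling calls are replicate-level counts; seedling traits (shoot and
root length and fresh/dry weight at 9 and 16 days, leaf length/width and
relative water content at 21 days) are replicate-level measurements.  Which
traits exist under which treatment follows the assay protocol: severe PEG
levels slow growth so much that late-stage traits cannot be scored there.

Two tidy CSV files are the canonical on-disk form: one germination-count
table and one long trait-measurement table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table violates the phenotype schema."""


# ---------------------------------------------------------------------------
# Treatments
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class TreatmentLevel:
    """One osmotic-stress level: a label and its PEG-6000 m/v fraction."""

    osmoticum_pct: float
    label: str = field(compare=False)

    @property
    def is_control(self) -> bool:
        return self.osmoticum_pct == 0.0

    def __post_init__(self) -> None:
        if (self.label == "control") != (self.osmoticum_pct == 0.0):
            raise ValidationError(
                f"treatment {self.label!r}: control iff osmoticum_pct == 0"
            )


CONTROL = TreatmentLevel(0.0, "control")
PEG10 = TreatmentLevel(0.10, "peg10")
PEG15 = TreatmentLevel(0.15, "peg15")
PEG20 = TreatmentLevel(0.20, "peg20")

TREATMENTS: tuple[TreatmentLevel, ...] = (CONTROL, PEG10, PEG15, PEG20)
TREATMENT_BY_LABEL: Mapping[str, TreatmentLevel] = {t.label: t for t in TREATMENTS}
STRESS_LEVELS: tuple[TreatmentLevel, ...] = (PEG10, PEG15, PEG20)


def treatment(label: str) -> TreatmentLevel:
    """Look up a treatment level by its label."""
    try:
        return TREATMENT_BY_LABEL[label]
    except KeyError:
        raise ValidationError(
            f"unknown treatment {label!r}; expected one of "
            f"{sorted(TREATMENT_BY_LABEL)}"
        ) from None


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitDef:
    """Definition of one measured trait.

    Parameters
    ----------
    code : short field abbreviation (G, ShL1, RWC, ...).
    units : ``"%"``, ``"cm"`` or ``"g"``.
    stage_days : days after sowing at which the trait is scored, or ``None``
        for the germination counts whose scoring day depends on treatment.
    higher_is_better : ranking direction; only the abnormal-seedling
        percentage is reversed (more abnormal seedlings = worse).
    measured_under : treatments under which the trait is scored.
    """

    code: str
    name: str
    units: str
    stage_days: int | None
    higher_is_better: bool
    measured_under: tuple[TreatmentLevel, ...]

    @property
    def stress_levels(self) -> tuple[TreatmentLevel, ...]:
        return tuple(t for t in self.measured_under if not t.is_control)


_ALL = TREATMENTS
_TO_PEG10 = (CONTROL, PEG10)
_TO_PEG15 = (CONTROL, PEG10, PEG15)

#: Trait registry mirroring the assay's availability pattern: germination and
#: abnormal-seedling percentages under all four treatments; 9-day seedling
#: traits under control and 10% PEG; 16-day traits additionally under 15% PEG;
#: 21-day leaf traits under control and 10% PEG only.
TRAITS: dict[str, TraitDef] = {
    t.code: t
    for t in [
        TraitDef("G", "germination percentage", "%", None, True, _ALL),
        TraitDef("AS", "abnormal seedling percentage", "%", None, False, _ALL),
        TraitDef("ShL1", "shoot length, 9 d", "cm", 9, True, _TO_PEG10),
        TraitDef("ShFW1", "shoot fresh weight, 9 d", "g", 9, True, _TO_PEG10),
        TraitDef("ShDW1", "shoot dry weight, 9 d", "g", 9, True, _TO_PEG10),
        TraitDef("RL1", "root length, 9 d", "cm", 9, True, _TO_PEG10),
        TraitDef("RFW1", "root fresh weight, 9 d", "g", 9, True, _TO_PEG10),
        TraitDef("RDW1", "root dry weight, 9 d", "g", 9, True, _TO_PEG10),
        TraitDef("ShL2", "shoot length, 16 d", "cm", 16, True, _TO_PEG15),
        TraitDef("ShFW2", "shoot fresh weight, 16 d", "g", 16, True, _TO_PEG15),
        TraitDef("ShDW2", "shoot dry weight, 16 d", "g", 16, True, _TO_PEG15),
        TraitDef("RL2", "root length, 16 d", "cm", 16, True, _TO_PEG15),
        TraitDef("RFW2", "root fresh weight, 16 d", "g", 16, True, _TO_PEG15),
        TraitDef("RDW2", "root dry weight, 16 d", "g", 16, True, _TO_PEG15),
        TraitDef("LL", "leaf length, 21 d", "cm", 21, True, _TO_PEG10),
        TraitDef("LW", "leaf width, 21 d", "cm", 21, True, _TO_PEG10),
        TraitDef("RWC", "leaf relative water content, 21 d", "%", 21, True, _TO_PEG10),
    ]
}

#: Continuous traits stored in the long measurement table (everything except
#: the two count-derived percentages).
MEASURED_TRAITS: tuple[str, ...] = tuple(c for c in TRAITS if c not in ("G", "AS"))

GERMINATION_COLUMNS = [
    "accession", "treatment", "replicate", "n_sown", "n_germinated", "n_abnormal",
]
TRAIT_COLUMNS = ["accession", "treatment", "replicate", "trait", "value"]


def compute_rwc(fresh_mass: float, turgid_mass: float, dry_mass: float) -> float:
    """Leaf relative water content: ``100 * (FM - DM) / (TM - DM)``.

    FM, TM and DM are the fresh, turgid and dry masses of the same leaf discs.
    """
    if turgid_mass <= dry_mass:
        raise ValidationError(
            f"RWC undefined: turgid mass {turgid_mass} must exceed dry mass {dry_mass}"
        )
    if fresh_mass < dry_mass:
        raise ValidationError(
            f"RWC invalid: fresh mass {fresh_mass} below dry mass {dry_mass}"
        )
    return 100.0 * (fresh_mass - dry_mass) / (turgid_mass - dry_mass)


def leaf_water_to_traits(leaf: pd.DataFrame) -> pd.DataFrame:
    """Convert a leaf fresh/turgid/dry mass table into long RWC trait rows.

    Expects columns accession, treatment, replicate, fresh_mass, turgid_mass,
    dry_mass; returns rows in the canonical trait-table layout with trait
    code ``RWC``.
    """
    required = {"accession", "treatment", "replicate",
                "fresh_mass", "turgid_mass", "dry_mass"}
    missing = required - set(leaf.columns)
    if missing:
        raise ValidationError(f"leaf water table missing columns {sorted(missing)}")
    values = [
        compute_rwc(row.fresh_mass, row.turgid_mass, row.dry_mass)
        for row in leaf.itertuples()
    ]
    return pd.DataFrame(
        {
            "accession": leaf["accession"].to_numpy(),
            "treatment": leaf["treatment"].to_numpy(),
            "replicate": leaf["replicate"].to_numpy(),
            "trait": "RWC",
            "value": values,
        }
    )


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeDataset:
    """Replicated germination counts plus long-format trait measurements.

    ``germination`` holds one row per (accession, treatment, replicate) with
    seed counts; ``traits`` holds one row per (accession, treatment,
    replicate, trait) with a continuous measurement.  ``accession_info`` is
    optional annotation (taxonomy, origin) that no computation depends on.
    """

    germination: pd.DataFrame
    traits: pd.DataFrame
    accession_info: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.germination = self.germination.reset_index(drop=True)
        self.traits = self.traits.reset_index(drop=True)
        validate_dataset(self)

    @property
    def accessions(self) -> list[str]:
        acc = set(self.germination["accession"]) | set(self.traits["accession"])
        return sorted(acc)

    @property
    def treatments(self) -> list[TreatmentLevel]:
        labels = set(self.germination["treatment"]) | set(self.traits["treatment"])
        return [t for t in TREATMENTS if t.label in labels]

    def n_replicates(self, trait: str, level: TreatmentLevel) -> int:
        """Replicate count of the (trait, treatment) cell; requires balance."""
        if trait in ("G", "AS"):
            sub = self.germination[self.germination["treatment"] == level.label]
            counts = sub.groupby("accession").size()
        else:
            sub = self.traits[
                (self.traits["trait"] == trait)
                & (self.traits["treatment"] == level.label)
            ]
            counts = sub.groupby("accession").size()
        if counts.empty:
            raise ValidationError(f"no data for trait {trait} under {level.label}")
        if counts.nunique() != 1:
            raise ValidationError(
                f"unbalanced design for trait {trait} under {level.label}: "
                f"replicate counts {sorted(counts.unique())}"
            )
        return int(counts.iloc[0])


def _check_counts(g: pd.DataFrame) -> None:
    bad = g[
        (g["n_sown"] <= 0)
        | (g["n_germinated"] < 0)
        | (g["n_abnormal"] < 0)
        | (g["n_germinated"] > g["n_sown"])
        | (g["n_abnormal"] > g["n_germinated"])
    ]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValidationError(
            "germination count invariant 0 <= n_abnormal <= n_germinated <= "
            f"n_sown (n_sown > 0) violated at accession={row['accession']!r} "
            f"treatment={row['treatment']!r} replicate={row['replicate']}: "
            f"sown={row['n_sown']} germinated={row['n_germinated']} "
            f"abnormal={row['n_abnormal']}"
        )


def _check_duplicates(df: pd.DataFrame, keys: list[str], what: str) -> None:
    dup = df.duplicated(subset=keys)
    if dup.any():
        row = df[dup].iloc[0]
        key = ", ".join(f"{k}={row[k]!r}" for k in keys)
        raise ValidationError(f"duplicate {what} record for ({key})")


def validate_dataset(ds: PhenotypeDataset) -> None:
    """Check schema, key uniqueness and physical invariants; raise on failure."""
    g, t = ds.germination, ds.traits
    missing = set(GERMINATION_COLUMNS) - set(g.columns)
    if missing:
        raise ValidationError(f"germination table missing columns {sorted(missing)}")
    missing = set(TRAIT_COLUMNS) - set(t.columns)
    if missing:
        raise ValidationError(f"trait table missing columns {sorted(missing)}")

    for df in (g, t):
        unknown = set(df["treatment"]) - set(TREATMENT_BY_LABEL)
        if unknown:
            raise ValidationError(f"unknown treatment labels {sorted(unknown)}")
    unknown = set(t["trait"]) - set(TRAITS)
    if unknown:
        raise ValidationError(f"unknown trait codes {sorted(unknown)}")
    for code in set(t["trait"]):
        allowed = {lvl.label for lvl in TRAITS[code].measured_under}
        seen = set(t.loc[t["trait"] == code, "treatment"])
        extra = seen - allowed
        if extra:
            raise ValidationError(
                f"trait {code} measured under {sorted(extra)} but is only "
                f"defined under {sorted(allowed)}"
            )

    _check_duplicates(g, ["accession", "treatment", "replicate"], "germination")
    _check_duplicates(t, ["accession", "treatment", "replicate", "trait"], "trait")
    _check_counts(g)

    neg = t[t["value"] < 0]
    if not neg.empty:
        row = neg.iloc[0]
        raise ValidationError(
            f"negative trait value at accession={row['accession']!r} "
            f"trait={row['trait']!r}: {row['value']}"
        )
    rwc = t[(t["trait"] == "RWC") & (t["value"] > 100)]
    if not rwc.empty:
        row = rwc.iloc[0]
        raise ValidationError(
            f"RWC above 100% at accession={row['accession']!r} "
            f"replicate={row['replicate']}: {row['value']}"
        )


def read_dataset(
    germination_csv: str | Path,
    traits_csv: str | Path,
    accession_csv: str | Path | None = None,
) -> PhenotypeDataset:
    """Read and validate the canonical CSV pair (plus optional annotation)."""
    g = pd.read_csv(germination_csv)
    t = pd.read_csv(traits_csv)
    info = pd.read_csv(accession_csv) if accession_csv is not None else None
    for df, cols, path in ((g, GERMINATION_COLUMNS, germination_csv),
                           (t, TRAIT_COLUMNS, traits_csv)):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return PhenotypeDataset(germination=g, traits=t, accession_info=info)


def write_dataset(
    ds: PhenotypeDataset, germination_csv: str | Path, traits_csv: str | Path
) -> None:
    """Write the dataset back to the canonical CSV pair."""
    ds.germination[GERMINATION_COLUMNS].to_csv(germination_csv, index=False)
    ds.traits[TRAIT_COLUMNS].to_csv(traits_csv, index=False)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def cell_means(
    ds: PhenotypeDataset,
    trait: str,
    levels: Sequence[TreatmentLevel] | None = None,
) -> pd.DataFrame:
    """Per-accession replicate means of one trait, accessions x treatments.

    For the count traits G and AS the percentage is computed per replicate
    first (G% on sown seeds, AS% on germinated seeds) and then averaged, so a
    replicate with no germinated seeds contributes a missing AS% rather than
    a zero.  A ``grand`` row holds the mean over accessions per treatment.
    """
    if trait not in TRAITS:
        raise ValidationError(f"unknown trait code {trait!r}")
    tdef = TRAITS[trait]
    if levels is None:
        levels = [lvl for lvl in tdef.measured_under if lvl in ds.treatments]
    else:
        bad = [lvl.label for lvl in levels if lvl not in tdef.measured_under]
        if bad:
            raise ValidationError(f"trait {trait} not measured under {bad}")
    labels = [lvl.label for lvl in levels]

    if trait in ("G", "AS"):
        g = ds.germination[ds.germination["treatment"].isin(labels)].copy()
        if trait == "G":
            g["value"] = 100.0 * g["n_germinated"] / g["n_sown"]
        else:
            germ = g["n_germinated"].to_numpy(dtype=float)
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = 100.0 * g["n_abnormal"].to_numpy(dtype=float) / germ
            pct[germ == 0] = np.nan
            g["value"] = pct
        long = g[["accession", "treatment", "value"]]
    else:
        sub = ds.traits[
            (ds.traits["trait"] == trait) & (ds.traits["treatment"].isin(labels))
        ]
        long = sub[["accession", "treatment", "value"]]

    table = long.pivot_table(
        index="accession", columns="treatment", values="value", aggfunc="mean"
    )
    for lab in labels:
        if lab not in table.columns or table[lab].isna().all():
            raise ValidationError(f"empty cell: trait {trait} under {lab}")
    table = table[labels].sort_index()
    table.loc["grand"] = table.mean(axis=0)
    table.columns.name = None
    return table


def replicate_grid(
    ds: PhenotypeDataset, trait: str, level: TreatmentLevel
) -> np.ndarray | None:
    """Accession x replicate value grid for one trait/treatment cell.

    G and AS are converted to per-replicate percentages first.  Returns
    ``None`` when the cell is absent or incomplete (including an AS
    replicate with zero germinated seeds, whose percentage is undefined).
    Accessions are in sorted order, so grids from different levels align.
    """
    if trait in ("G", "AS"):
        sub = ds.germination[ds.germination["treatment"] == level.label].copy()
        if sub.empty:
            return None
        if trait == "G":
            sub["value"] = 100.0 * sub["n_germinated"] / sub["n_sown"]
        else:
            germ = sub["n_germinated"].to_numpy(dtype=float)
            if (germ == 0).any():
                return None
            sub["value"] = 100.0 * sub["n_abnormal"] / germ
    else:
        sub = ds.traits[
            (ds.traits["trait"] == trait) & (ds.traits["treatment"] == level.label)
        ]
        if sub.empty:
            return None
    pivot = sub.pivot_table(
        index="accession", columns="replicate", values="value", aggfunc="first"
    ).sort_index()
    if pivot.isna().any().any():
        return None
    return pivot.to_numpy(dtype=float)


def design_grid(
    ds: PhenotypeDataset, trait: str, levels: Sequence[TreatmentLevel]
) -> np.ndarray:
    """Balanced (genotype, treatment, replicate) grid over several levels."""
    grids = []
    for lvl in levels:
        g = replicate_grid(ds, trait, lvl)
        if g is None:
            raise ValidationError(f"incomplete cell: {trait} under {lvl.label}")
        grids.append(g)
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValidationError(
            f"unbalanced design across treatments for {trait}: {sorted(shapes)}"
        )
    return np.stack(grids, axis=1)


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number summary with Tukey-rule outliers."""

    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    outliers: tuple[float, ...]
    outlier_labels: tuple[str, ...] = ()

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def boxplot_summary(
    values: Sequence[float] | pd.Series,
    quantile_method: str = "linear",
) -> BoxplotSummary:
    """Five-number summary of per-accession means with Tukey outlier flags.

    Quartiles use linear interpolation between order statistics by default
    (numpy's ``linear`` method, the classical type-7 convention); outliers
    are the values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR].  With fewer than
    four values the summary is returned without outlier flagging.
    """
    if isinstance(values, pd.Series):
        labels = [str(i) for i in values.index]
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(list(values), dtype=float)
        labels = [str(i) for i in range(arr.size)]
    if arr.size == 0:
        raise ValidationError("boxplot_summary requires at least one value")
    if np.isnan(arr).any():
        keep = ~np.isnan(arr)
        arr, labels = arr[keep], [l for l, k in zip(labels, keep) if k]
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=quantile_method)
    if arr.size < 4:
        return BoxplotSummary(arr.min(), q1, med, q3, arr.max(), ())
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (arr < lo) | (arr > hi)
    return BoxplotSummary(
        float(arr.min()), float(q1), float(med), float(q3), float(arr.max()),
        tuple(float(v) for v in arr[mask]),
        tuple(l for l, m in zip(labels, mask) if m),
    )
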