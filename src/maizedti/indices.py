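"""Germination metrics and drought-tolerance indices (DTIs).

A DTI is the ratio of a trait's accession mean under an osmotic-stress level
to its mean under the control, stored as a fraction (1.0 = unchanged,
0.5 = halved under stress).  For every trait except the abnormal-seedling
percentage a DTI below one indicates stress damage; AS-DTI is
direction-reversed (values above one mean more abnormal seedlings under
stress, and can run far above one when the control AS% is small).

The grand DTI of an accession is the unweighted mean of its trait DTIs and
serves as its overall drought-tolerance score.  AS-DTI columns are excluded
from the grand DTI by default: they point the other way and their magnitude
(routinely 5-30x) would otherwise dominate the average.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .datamodel import (
    CONTROL,
    TRAITS,
    PhenotypeDataset,
    TreatmentLevel,
    ValidationError,
    cell_means,
)


def germination_pct(n_germinated: int, n_sown: int) -> float:
    """Germination percentage: ``100 * germinated / sown``."""
    if n_sown <= 0:
        raise ValidationError(f"n_sown must be positive, got {n_sown}")
    if not 0 <= n_germinated <= n_sown:
        raise ValidationError(
            f"n_germinated={n_germinated} outside [0, n_sown={n_sown}]"
        )
    return 100.0 * n_germinated / n_sown


def abnormal_pct(n_abnormal: int, n_germinated: int) -> float:
    """Abnormal-seedling percentage on germinated seeds.

    Returns NaN (an undefined marker, not zero) when nothing germinated.
    """
    if n_germinated == 0:
        return math.nan
    if not 0 <= n_abnormal <= n_germinated:
        raise ValidationError(
            f"n_abnormal={n_abnormal} outside [0, n_germinated={n_germinated}]"
        )
    return 100.0 * n_abnormal / n_germinated


def trait_dti(stress_mean: float, control_mean: float) -> float:
    """Stress/control ratio of accession means; NaN when the control is zero.

    Scale-invariant: both means in the same (arbitrary) units.
    """
    if math.isnan(stress_mean) or math.isnan(control_mean) or control_mean <= 0:
        return math.nan
    return stress_mean / control_mean


def dti_column_order() -> list[tuple[str, str]]:
    """The (trait, stress level) column set, derived from trait availability.

    The full assay design yields 27 columns: G and AS at three PEG levels,
    the six 9-day traits at 10%, the six 16-day traits at 10% and 15%, and
    the three leaf traits at 10%.
    """
    return [
        (code, lvl.label)
        for code, tdef in TRAITS.items()
        for lvl in tdef.stress_levels
    ]


@dataclass
class DTIMatrix:
    """Accession x (trait, stress level) matrix of DTI fractions.

    ``values`` has a two-level column index (trait, treatment);
    ``directions`` maps each column to the trait's higher-is-better flag.
    """

    values: pd.DataFrame
    directions: dict[tuple[str, str], bool]

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    def to_csv(self, path) -> None:
        flat = self.values.copy()
        flat.columns = [f"{t}_dti_{lvl}" for t, lvl in flat.columns]
        flat.to_csv(path, index_label="accession")

    def scaled(self) -> pd.DataFrame:
        """Display form with DTIs multiplied by 100."""
        return self.values * 100.0


def build_dti_matrix(ds: PhenotypeDataset) -> DTIMatrix:
    """Compute every available (trait, stress level) DTI per accession.

    Columns are derived mechanically from the trait availability pattern
    restricted to treatments present in the dataset; an accession with a
    missing or zero control cell gets NaN in the affected columns.
    """
    present = {lvl.label for lvl in ds.treatments}
    if "control" not in present:
        raise ValidationError("DTI matrix requires the control treatment")
    cols: dict[tuple[str, str], pd.Series] = {}
    for code, lvl_label in dti_column_order():
        if lvl_label not in present:
            continue
        tdef = TRAITS[code]
        try:
            means = cell_means(ds, code, [CONTROL, _level(lvl_label)])
        except ValidationError:
            continue  # trait absent from this dataset
        means = means.drop(index="grand")
        ctrl = means["control"]
        stress = means[lvl_label]
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = stress / ctrl
        ratio[~(ctrl > 0)] = np.nan
        cols[(code, lvl_label)] = ratio
    if not cols:
        raise ValidationError("no DTI columns computable from this dataset")
    values = pd.DataFrame(cols)
    values.columns = pd.MultiIndex.from_tuples(values.columns,
                                              names=["trait", "treatment"])
    directions = {
        col: TRAITS[col[0]].higher_is_better for col in values.columns
    }
    return DTIMatrix(values=values, directions=directions)


def _level(label: str) -> TreatmentLevel:
    from .datamodel import TREATMENT_BY_LABEL

    return TREATMENT_BY_LABEL[label]


@dataclass
class GrandDTI:
    """Per-accession grand DTI (mean of included columns), ranked."""

    table: pd.DataFrame  # index accession, columns grand_dti, rank
    included_columns: list[tuple[str, str]]

    @property
    def ranking(self) -> list[str]:
        return list(self.table.index)


def grand_dti(
    matrix: DTIMatrix,
    include_reversed: bool = False,
    reciprocal_reversed: bool = False,
) -> GrandDTI:
    """Unweighted mean DTI per accession, sorted best-first.

    Direction-reversed columns (AS-DTI) are excluded by default.  With
    ``include_reversed`` they enter as-is; adding ``reciprocal_reversed``
    enters them as 1/DTI so that larger still means more tolerant.
    Accessions tie-break alphabetically; accessions with no usable column
    are dropped with a warning.
    """
    cols = [
        c for c in matrix.values.columns
        if matrix.directions[c] or include_reversed
    ]
    if not cols:
        raise ValidationError("grand DTI inclusion rule selects no columns")
    sub = matrix.values[cols].copy()
    if include_reversed and reciprocal_reversed:
        for c in cols:
            if not matrix.directions[c]:
                with np.errstate(divide="ignore"):
                    sub[c] = 1.0 / sub[c]
                sub.loc[~np.isfinite(sub[c]), c] = np.nan
    means = sub.mean(axis=1, skipna=True)
    # a row of identical DTIs must average to exactly that value (summing
    # n copies and dividing is not bit-exact)
    row_min, row_max = sub.min(axis=1), sub.max(axis=1)
    identical = (row_min == row_max) & row_min.notna()
    means[identical] = row_min[identical]
    dropped = means[sub.notna().sum(axis=1) == 0].index
    if len(dropped):
        warnings.warn(
            f"accessions with no usable DTI column excluded: {list(dropped)}",
            stacklevel=2,
        )
        means = means.drop(index=dropped)
    order = sorted(means.index, key=lambda a: (-means[a], str(a)))
    table = pd.DataFrame(
        {"grand_dti": [means[a] for a in order],
         "rank": np.arange(1, len(order) + 1)},
        index=pd.Index(order, name="accession"),
    )
    return GrandDTI(table=table, included_columns=list(cols))
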