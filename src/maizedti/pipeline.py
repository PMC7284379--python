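"""End-to-end orchestration: means and heritability tables, control-vs-stress
ANOVA/LSD, DTI matrix, correlations, band screening, grand-DTI ranking and
PCA, bundled into one reproducible report."""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlations import CorrelationResult, correlation_matrix
from .datamodel import (
    CONTROL,
    TRAITS,
    PhenotypeDataset,
    ValidationError,
    cell_means,
    replicate_grid,
)
from .indices import DTIMatrix, GrandDTI, build_dti_matrix, grand_dti
from .screening import PcaResult, ScreeningReport, assign_bands, pca_dti
from .varcomp import (
    anova_oneway,
    anova_twoway,
    fisher_lsd,
    heritability,
    significance_stars,
    variance_components,
)

log = logging.getLogger("maizedti")


@dataclass
class AnalysisConfig:
    band_q: float = 0.05
    lsd_alpha: float = 0.05
    grand_dti_include_reversed: bool = False
    grand_dti_reciprocal_reversed: bool = False
    pca_missing: str = "mean"


@dataclass
class AnalysisReport:
    """All pipeline outputs for one dataset, plus run metadata."""

    trait_summary: pd.DataFrame  # per trait x treatment: mean, F-test stars, H2
    anova_lsd: pd.DataFrame  # control vs each stress level per trait
    dti: DTIMatrix | None
    grand: GrandDTI | None
    correlations: CorrelationResult | None
    screening: ScreeningReport | None
    pca: PcaResult | None
    warnings: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write every section as CSV plus a JSON manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        self.trait_summary.to_csv(out / "trait_summary.csv")
        written.append("trait_summary.csv")
        self.anova_lsd.to_csv(out / "anova_lsd.csv")
        written.append("anova_lsd.csv")
        if self.dti is not None:
            self.dti.to_csv(out / "dti_matrix.csv")
            written.append("dti_matrix.csv")
        if self.grand is not None:
            self.grand.table.to_csv(out / "grand_dti.csv")
            written.append("grand_dti.csv")
        if self.correlations is not None:
            self.correlations.lower_triangle_csv(out / "correlations.csv")
            written.append("correlations.csv")
        if self.screening is not None:
            self.screening.to_csv(out / "screening.csv")
            written.append("screening.csv")
        if self.pca is not None:
            self.pca.scores.to_csv(out / "pca_scores.csv", index_label="accession")
            self.pca.loadings.to_csv(out / "pca_loadings.csv", index_label="column")
            written += ["pca_scores.csv", "pca_loadings.csv"]
        manifest = dict(self.metadata)
        manifest["files"] = written
        manifest["warnings"] = self.warnings
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _dataset_hash(ds: PhenotypeDataset) -> str:
    h = hashlib.sha256()
    h.update(ds.germination.to_csv(index=False).encode())
    h.update(ds.traits.to_csv(index=False).encode())
    return h.hexdigest()[:16]


def run_analysis(
    ds: PhenotypeDataset, cfg: AnalysisConfig | None = None
) -> AnalysisReport:
    """Run the full screening analysis in dependency order.

    Partial designs degrade gracefully: a dataset without stress treatments
    still gets means and ANOVA, but no DTI/correlation/PCA sections.
    """
    cfg = cfg or AnalysisConfig()
    notices: list[str] = []
    present = ds.treatments
    stress = [t for t in present if not t.is_control]
    has_control = any(t.is_control for t in present)
    trait_codes = ["G", "AS"] + sorted(
        set(ds.traits["trait"]), key=list(TRAITS).index
    )
    if ds.germination.empty:
        trait_codes = [c for c in trait_codes if c not in ("G", "AS")]

    # Per-trait/treatment means, one-way genotype ANOVA and heritability ----
    summary_rows = []
    means_by_condition: dict[str, pd.DataFrame] = {}
    for code in trait_codes:
        levels = [l for l in TRAITS[code].measured_under if l in present]
        try:
            means = cell_means(ds, code, levels)
        except ValidationError as err:
            notices.append(f"means[{code}]: {err}")
            continue
        for lvl in levels:
            col = means[lvl.label].drop(index="grand")
            means_by_condition.setdefault(lvl.label, pd.DataFrame(index=col.index))
            means_by_condition[lvl.label][code] = col
            row = {
                "trait": code,
                "treatment": lvl.label,
                "mean": means.loc["grand", lvl.label],
                "f": math.nan,
                "p": math.nan,
                "signif": "",
                "h2": math.nan,
            }
            grid = replicate_grid(ds, code, lvl)
            if grid is not None and grid.shape[0] >= 2 and grid.shape[1] >= 2:
                table = anova_oneway(grid)
                vc = variance_components(table, r=grid.shape[1])
                h2 = heritability(vc, "within-treatment")
                row.update(
                    f=table["genotype"]["f"],
                    p=table["genotype"]["p"],
                    signif=significance_stars(table["genotype"]["p"]),
                    h2=h2.h2,
                )
                if vc.truncated:
                    notices.append(
                        f"{code}/{lvl.label}: truncated {','.join(vc.truncated)}"
                    )
            summary_rows.append(row)
    trait_summary = pd.DataFrame(summary_rows)

    # Control vs each stress level: two-way ANOVA + LSD ---------------------
    lsd_rows = []
    if has_control:
        for code in trait_codes:
            for lvl in stress:
                if lvl not in TRAITS[code].measured_under:
                    continue
                ctrl_grid = replicate_grid(ds, code, CONTROL)
                str_grid = replicate_grid(ds, code, lvl)
                if ctrl_grid is None or str_grid is None:
                    continue
                if ctrl_grid.shape != str_grid.shape or ctrl_grid.shape[1] < 2:
                    notices.append(f"anova_lsd[{code}/{lvl.label}]: unbalanced, skipped")
                    continue
                grid = np.stack([ctrl_grid, str_grid], axis=1)  # (g, 2, r)
                table = anova_twoway(grid)
                n_per_mean = grid.shape[0] * grid.shape[2]
                lsd = fisher_lsd(
                    float(table["error"]["ms"]),
                    int(table["error"]["df"]),
                    n_per_mean,
                    cfg.lsd_alpha,
                )
                lsd_rows.append(
                    {
                        "trait": code,
                        "comparison": f"control_vs_{lvl.label}",
                        "f_treatment": table["treatment"]["f"],
                        "p_treatment": table["treatment"]["p"],
                        "signif": significance_stars(table["treatment"]["p"]),
                        "lsd": lsd.lsd,
                    }
                )
    anova_lsd = pd.DataFrame(lsd_rows)

    # DTI-dependent sections ------------------------------------------------
    dti = grand = corr = pca = None
    if has_control and stress:
        try:
            dti = build_dti_matrix(ds)
        except ValidationError as err:
            notices.append(f"dti: {err}")
    else:
        notices.append("no stress treatments with control: DTI sections skipped")
    if dti is not None:
        grand = grand_dti(
            dti,
            include_reversed=cfg.grand_dti_include_reversed,
            reciprocal_reversed=cfg.grand_dti_reciprocal_reversed,
        )
        flat = dti.values.copy()
        flat.columns = [f"{t}_{lvl}" for t, lvl in flat.columns]
        if flat.shape[0] >= 4:
            corr = correlation_matrix(flat)
        usable = flat.dropna(axis=1, how="all")
        if usable.shape[0] >= 3 and usable.shape[1] >= 2:
            try:
                pca = pca_dti(usable, missing=cfg.pca_missing)
            except ValidationError as err:
                notices.append(f"pca: {err}")

    screening = None
    if means_by_condition:
        n_acc = len(ds.accessions)
        if n_acc >= 1 / cfg.band_q:
            bands = assign_bands(means_by_condition, q=cfg.band_q)
            screening = ScreeningReport.from_bands(bands, accessions=ds.accessions)
        else:
            notices.append("too few accessions for band screening")

    for n in notices:
        log.info(n)
    metadata = {
        "version": __version__,
        "dataset_sha256_16": _dataset_hash(ds),
        "n_accessions": len(ds.accessions),
        "treatments": [t.label for t in present],
        "band_q": cfg.band_q,
    }
    return AnalysisReport(
        trait_summary=trait_summary,
        anova_lsd=anova_lsd,
        dti=dti,
        grand=grand,
        correlations=corr,
        screening=screening,
        pca=pca,
        warnings=notices,
        metadata=metadata,
    )
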