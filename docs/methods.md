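# Methods

This note documents the statistical model behind `maizedti`, the choices
made where the methodology was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Trial design and data model

The package analyses a replicated osmotic-stress germination trial:
`n` accessions × 4 treatments (water control and 10/15/20% m/v PEG-6000) ×
`r` replicate blotting rolls of 17–20 seeds. Germination and
abnormal-seedling calls are replicate-level counts; seedling measurements
are replicate-level continuous values. Trait availability follows the assay
protocol rather than being configurable per dataset: germination (G%) and
abnormal-seedling (AS%) percentages exist under all four treatments, the
six 9-day shoot/root traits only under control and 10% PEG, the six 16-day
traits additionally under 15% PEG, and the three 21-day leaf traits (LL,
LW, RWC) under control and 10% PEG. Expanding every trait over its
non-control levels yields the 27-column DTI matrix of the full design.

Percentages are computed per replicate and then averaged, so a replicate in
which nothing germinated contributes a *missing* AS% (0/0), never a zero.
Undefined ratios (zero control mean) propagate as missing values
throughout; they are never coerced to 0 or infinity.

Balanced designs are required for ANOVA. Unbalanced input raises an
explicit error instead of being silently averaged, because the
expected-mean-squares algebra below assumes equal cell sizes.

## Drought-tolerance indices

A DTI is the ratio of an accession's trait mean under a stress level to its
control mean. Indices are stored as fractions (0.74, not 74): every
downstream use (grand DTI, PCA, ranking) is scale-free, and a display
helper multiplies by 100 where percent-style output is wanted.

The grand DTI of an accession is the unweighted mean of its trait DTIs.
AS-DTI columns are excluded by default: AS% is direction-reversed (larger =
worse) and its ratio routinely reaches 5–30 when the control AS% is small,
so including it as-is would dominate and invert the tolerance score. Two
alternatives are exposed — include the reversed columns unchanged, or enter
them as reciprocals (1/DTI) so that larger still means more tolerant — but
the default is exclusion, which keeps the score interpretable as "average
fraction of control performance retained under stress".

A numerical guarantee worth stating: a row whose included DTIs are all
identical gets exactly that value as its grand DTI (naive summation of n
identical doubles is not bit-exact), and ranking ties break alphabetically
by accession identifier, so rankings are deterministic.

## ANOVA, variance components, heritability

Sums of squares are computed from first principles on balanced grids.
One-way (genotypes within one treatment): `SS_g = r·Σ(ȳ_i − ȳ)²`, error by
subtraction. Two-way (genotype × treatment with replication): the standard
decomposition into genotype, treatment, interaction and error. F tests are
against the error MS, matching germplasm-trial reporting; p-values come
from the F distribution.

With genotypes random and treatments fixed, the expected mean squares are

```
E[MS_e]  = σ²e
E[MS_gt] = σ²e + r·σ²gt
E[MS_g]  = σ²e + r·σ²gt + r·t·σ²g
```

solved by method of moments; negative solutions are truncated to zero and
flagged (`VarianceComponents.truncated`). REML is deliberately not
implemented — for balanced designs the EMS estimator is the conventional
choice and is exactly reproducible.

Broad-sense heritability is on an entry-mean basis:
`H² = σ²g/(σ²g + σ²e/r)` within one treatment and
`H² = σ²g/(σ²g + σ²gt/t + σ²e/(r·t))` across `t` treatments, clipped to
[0, 1]. The across-treatments denominator follows the standard
multi-environment convention (Hallauer), with `t` the number of
treatments/environments. Per-treatment heritability tables use the
within-treatment form; the across-treatments form is reported separately.

Two numerical guards matter for degenerate input. First, an (effectively)
all-equal grid must produce exactly zero sums of squares: float summation
leaves ~1e-30 residues whose EMS ratio would otherwise fabricate H² = 1, so
SS below `n·(1e-12·max(1,|ȳ|))²` collapse to zero. Second, a zero
phenotypic-variance denominator yields an undefined marker (NaN), not 0 or
1. Fisher's LSD is `t(1−α/2, df_e)·√(2·MSE/n)` and is exactly 0 at
MSE = 0.

## Correlations

Pearson r over accession means, with each (trait, treatment) context a
separate column. Significance is the two-sided t test
`t = r·√((n−2)/(1−r²))` on n−2 df, reported in tiers (0.05/0.01/0.001)
with no multiple-testing correction — the tiered-star convention of the
trial reports this pipeline mirrors. Pairwise-complete observations are
used when cells are missing; zero-variance columns give missing r.
Threshold counts (`count_significant`) count positive correlations
(r ≥ threshold) at a tier or stricter, the convention used when tallying
"highly significant r ≥ 0.70" pairs.

## Screening bands and PCA

Per trait and condition the ceil(q·n) best and worst accessions are
flagged, with q = 0.05 by default (q = 0.10 also in common use; both are
exposed). "Best" is direction-aware: minimum for AS%, maximum for
everything else. Ties break alphabetically, making band assignment
deterministic and permutation-invariant. The screening report counts band
appearances per accession and condition; totals are always recomputed from
the per-condition counts, so row/column additivity holds by construction.
The tabulator also ingests pre-counted tables (fixture mode), which is how
the packaged reference table of a published 40-accession IPK maize panel is
handled; recomputation there exposes small arithmetic inconsistencies in
the published totals row, which the package reports as recomputed.

PCA operates on the correlation matrix (columns standardized to zero mean,
unit variance) because DTI columns have heterogeneous scales — AS-DTI can
be 30× larger than trait DTIs, and covariance-matrix PCA would reduce to an
AS axis. Eigenvalues therefore sum to the number of retained columns.
Missing cells are mean-imputed by default (zero after standardization;
`missing="drop"` drops incomplete accessions instead); with imputation the
eigenvalue sum falls slightly below the column count, which is expected.
Constant columns are dropped with a warning. Each eigenvector is oriented
so its largest-magnitude loading is positive — eigendecomposition signs are
otherwise arbitrary, and fixing them makes score plots and regression tests
reproducible. Scores are the standardized data projected on the loadings;
they are centered per component by construction.

PC1 of a DTI matrix dominated by tolerance differences tracks the grand
DTI closely (the test suite checks Spearman > 0.8 on two-cluster synthetic
data), but the two rankings are produced independently and never merged.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular real accession panel. Continuous traits follow

```
y_ijk = μ_trait·f_j + g_i + (gτ)_ij + ε_ijk
```

with multiplicative treatment effects `f_j` on the baseline mean and
zero-mean normal genotype, interaction and residual effects; values are
truncated at zero (and at 100 for percent-scale traits). Because the
additive effects cancel in expectation, the expected DTI at level j is
exactly `f_j` — the property the DTI-semantics tests exploit. Germination
and abnormality are binomial per replicate with logit-linear genotype and
treatment effects, which keeps probabilities in (0, 1) and makes the count
invariants (abnormal ≤ germinated ≤ sown) automatic.

Defaults are fixed to the observed grand means of a real 40-accession IPK
maize screen: G% targets 94.3 → 90.4 → 83.9 → 73.4 and AS% targets
7.4 → 17.7 → 32.4 → 48.7 across the PEG gradient, and per-trait baselines
and reductions such as 16-day shoot length 28.68 → 22.12 → 13.86 cm. (The
9-day shoot dry weight rises under 10% PEG in those data — f > 1 — and the
generator reproduces that as configured.) Default variance magnitudes put
genotype and residual SDs at 10% of the baseline and the interaction SD at
5%, giving a within-treatment entry-mean H² of 0.75 at r = 3 — the
medium-to-high heritability such trials report. RWC, bounded at 100% near
its baseline of 94%, instead uses absolute SDs of 2/1/2 percentage points
to keep truncation negligible. Logit-scale variances for the count models
are 0.09 (genotype) and 0.02 (interaction); at these magnitudes the
logit-normal convexity bias on realized mean percentages is under half a
percentage point. `TraitSim.from_h2` constructs a trait from a target
within-treatment H² instead of explicit variances.

What the generator does **not** emulate: correlations *between* traits
(each trait draws independent genotype effects, so cross-trait correlation
structure in synthetic data is purely incidental), per-accession identity
with any real panel, germination-speed dynamics (the day at which counts
are scored is protocol metadata, not simulated), and spatial or batch
effects. Tests that pass on synthetic data therefore validate the
estimators and bookkeeping — not claims about real maize germplasm, and
not the trait-correlation structure a real trial would show.

One protocol caveat carried as metadata: germination is scored at 9 days
for control/10% PEG but 16 days for 15%/20% PEG, so G-DTIs at the severe
levels compare counts at different ages. The data model records the stage
(`TraitDef.stage_days`) but does not attempt to adjust for it.

## Problem sizes in tests

The test suite and `scripts/acceptance.py` use: 200 random grids (≤ 6×4×3)
for the ANOVA-vs-oracle equivalence; 300 simulated 40-accession × 3-replicate
trials per heritability level (H² ∈ {0.3, 0.6, 0.8}, mean estimate within
±0.05); 40 simulated 200 × 3 × 10 trials for across-treatment
variance-component recovery (mean within 10% relative — a single trial of
that size still carries ~10% sampling noise on the genotype mean square,
so recovery is assessed on the mean); and 30-accession two-cluster DTI
matrices for the PCA separation checks. The full default pipeline run
(40 × 4 × 3, 17 traits) completes in a few seconds.

## Known limitations

* No unbalanced-design ANOVA (Type II/III), no REML, no multiple-comparison
  procedures beyond Fisher's LSD.
* Genotypic vs phenotypic correlation partitioning is not computed.
* Alternative stress indices (DSI, STI, SI) are out of scope; only the
  stress/control ratio DTI is implemented.
* Plotting is limited to data summaries (five-number boxplot statistics
  with Tukey outlier flags); no biplots or dendrograms.
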