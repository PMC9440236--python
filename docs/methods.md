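# Methods

## SCENITH parameter estimation

Protein synthesis is read out as puromycin incorporation per cell; each
analysis group contributes one well per metabolic inhibitor. Wells are
summarised by geometric MFI, `exp(mean(log x))`, matching the
multiplicative error structure of cytometry intensities. Unmixed spectral
intensities can be ≤ 0, so values below a configurable floor (default
1.0 a.u.) are floored before the log; the floored fraction triggers a
warning above 1 %. The dependence/capacity formulas (README) are evaluated
on well gMFIs. They are invariant to any common positive rescaling of the
four core wells — which is why pooling wells across donors is safe even
with donor-to-donor staining-intensity differences: a per-donor
multiplicative factor cancels in every ratio.

Raw parameter values are kept unclamped, so the complement identities
(glycolytic capacity = 100 − mitochondrial dependence, FAAO = 100 − glucose
dependence) hold to machine precision; clamped copies bounded to [0, 100]
are stored for reporting and out-of-range raw values are flagged. Noise can
make the etomoxir/telaglenastat parameters negative; these are reported
clamped with the raw value retained. Adjusted parameters multiply the raw
(not clamped) percentage by the background window `C − DGO`, so the
complement structure survives adjustment. A well set with `C ≤ DGO` has no
usable background window and is rejected as degenerate rather than
producing unstable ratios.

Wells require ≥ 200 cells by default (`min_cells`); the harringtonine well
is a translation-blockade control and enters no formula.

### Oligomycin single-cell classification

Cells translating above background in the oligomycin well are glycolytic;
cells collapsing toward the full-block level are mitochondrially dependent.
Manual gating is replaced by two reproducible rules in arcsinh space:
(default) a threshold at the midpoint between the DGO-well median and the
C-well median of the same group; or a two-component Gaussian mixture whose
higher-mean component is glycolytic. Classified cells additionally receive
equal-frequency puromycin tertiles (low/mid/high; ranks split ties so the
partition is always exact thirds).

## scMEP preprocessing and scores

Intensities are arcsinh-transformed with cofactor 5. Where cell size
changes across states, group intensities are divided by relative cell
volume `(mean radius / reference radius)³` before the transform; the
reference is the monocyte (mono_0h) mean radius. Clustering-scale analyses
subsample 20–25 000 cells per group uniformly without replacement
(deterministic under seed; small groups kept whole with a warning).

Marker benchmarking regresses per-timepoint arcsinh medians on
`log1p(max(adjusted parameter, 0))` by ordinary least squares; `log1p` is
used because adjusted parameters can legitimately be 0. A marker is
selected at slope > 0 and two-sided p < 0.05 (the selection rule "most
significant and positively correlated" has no published threshold; α = 0.05
is the package's choice). Population pathway scores are means of member
arcsinh medians. The single-cell score formula is not published; the
package scales each member marker's arcsinh values to [0, 1] over its
1st–99th percentile window (clipping outside; a degenerate window
contributes a constant 0.5 with a warning) and averages members, which
keeps scores comparable across markers, bounded, and consistent with the
population score's ordering. Score–parameter agreement is quantified by
Spearman correlation with average-rank ties.

## Stratification and differential testing

Quantile stratification supports equal-frequency bins (default; ties broken
by stable input order, bin k = highest expression) and equal-width bins
over the observed arcsinh range — both are exposed because "expression
range" gating is ambiguous between the two readings. Maturation classes are
the k = 3 case on HLA-DR (low/mid/high).

Treatment contrasts are tested per marker on per-donor summaries (one
arcsinh median or gMFI per donor × arm) with OLS containing the treatment
indicator and donor fixed effects. With 3–6 donors, donor fixed effects are
the standard small-sample blocking approximation to a random-intercept
mixed model; this is a deliberate design choice that keeps the test fully
in-package and exactly reproducible. Donors observed in only one arm are
dropped with a warning. A zero-variance marker reports effect 0 and p = 1
by convention. Benjamini–Hochberg adjustment is applied across markers
within each contrast.

## Synthetic-data generator

The generator is the package's study design. Per (archetype, donor,
inhibitor) well it emits n cells with
`intensity = well geometric mean × donor factor × exp(σ_cell · z)`. Because
archetype means are geometric means and all noise is multiplicative
log-normal, gMFI is unbiased for the archetype mean and noiseless
generation reproduces every ground-truth parameter exactly — the
foundation of the recovery tests. Defaults mirror the study conditions:
3 donors with donor σ = 0.1 (N = 3 designs), cell σ = 0.2, 5000 cells/well
for recovery runs; at those settings per-well gMFI has a relative standard
error of ≈ 0.3 %, so recovered parameters sit well inside ±2 percentage
points of truth for any seed.

Built-in archetypes are constructed by inverting the SCENITH formulas
against the reference percentages for each state, with `C = 1000` and
`DGO = 100` a.u. (activated states use `C = 1300` for the transient
protein-synthesis rise). Inhibitor means not pinned by a reference
percentage are plausible fillers and nothing downstream depends on them.
The harringtonine well is generated at 2 % of `C`.

Subpopulations (e.g. CD86-high at 25 % of iDC with an oligomycin-well
override) must satisfy two constraints at once: the whole well's gMFI must
equal the archetype's stated overall mean, and each subpopulation's own
means must reproduce its printed parameters. The generator therefore
back-solves the bulk component's per-inhibitor mean so the
fraction-weighted geometric mean over subpopulations equals the overall
mean. Membership counts are allocated deterministically (largest
remainder) and shuffled, keeping the noiseless limit exact. Subpopulation
marker shifts (CD86 ×4 for CD86-high, CD1c ×4 for CD1c-high) make the
subsets recoverable by quantile stratification.

The scMEP generator assigns each metabolic marker to exactly one
generating pathway group and scales its baseline geometric mean (50 a.u.)
by a per-(stage, condition) activity multiplier. The default coupling sets
multipliers proportional to each archetype's adjusted SCENITH truth
(TCA/ETC and mitochondrial-dynamics markers track adjusted mitochondrial
dependence, glycolysis markers adjusted glycolytic capacity, amino-acid
markers adjusted glutaminolysis dependence, and so on), normalised to the
monocyte state — the structure the benchmarking step assumes. Cell radii
are log-normal (σ = 0.05) around stage means chosen so volume rises 4-fold
from monocyte to mDC in equal geometric steps; an optional volume-scaling
switch additionally multiplies metabolic marker means by relative volume,
modelling the total-protein effect that volume normalisation removes (the
full pipeline enables it; the generator default leaves marker means equal
to baseline × multiplier).

### What the generator does not emulate

No spectral spillover/compensation error, acquisition drift, doublets,
debris, dead-cell contamination, heavy-tailed or zero-inflated intensity
distributions, well-to-well pipetting variation within a donor, or
correlation between markers beyond shared subpopulation membership and the
donor factor. Passing recovery tests therefore demonstrates correctness of
the estimators under the assay's idealised error model, not robustness to
every artefact of real cytometry data.

## Numerical and interface choices

- Canonical on-disk format is CSV (UTF-8, one row per cell, 10 significant
  digits), which keeps tables diffable and round-trips to < 1e-9 relative
  error. Gating is explicit threshold predicates combined by AND, replacing
  manual gates; non-viable events are dropped at load.
- Tolerogenic shifts ("+25 points glycolytic capacity", "+15 points FAAO")
  are interpreted as percentage-point differences of the percentual
  parameters.
- All stage randomness derives from a single run-level seed
  (`numpy.random.default_rng`); identical configuration ⇒ byte-identical
  outputs.
- Problem sizes in the test-suite and acceptance runs: recovery at 5000
  cells/well × 3 donors; noiseless exactness at 200 cells/well;
  differential-test calibration over 200 simulated 3-donor designs per
  property (10 markers, 200 cells per summary).

## Known limitations

- Donor fixed effects estimate the within-donor contrast only; they do not
  generalise variance to a donor population the way REML would.
- The single-cell pathway score and the equal-range stratification are
  documented stand-ins for under-specified upstream procedures; both modes
  are exposed so analyses can state which convention they used.
- FCS ingestion is out of scope; tables must be flattened to the CSV schema
  first.
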