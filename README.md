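# scenmep

Single-cell immunometabolic profiling of dendritic-cell (DC)
differentiation: SCENITH metabolic-dependence analysis, scMEP
metabolic-regulome pathway scoring, population stratification, and
donor-blocked differential testing — driven by a synthetic cytometry
generator with known metabolic ground truth, so every stage of the pipeline
is testable without donor data.

## Who this is for

Cytometrists and computational immunologists analysing
translation-inhibition metabolic assays (SCENITH) and antibody-based
metabolic-regulome panels (scMEP) on myeloid cells: monocytes
differentiating to immature (iDC), activated (actDC) and mature (mDC)
dendritic cells, tolerogenic DC generated with vitamin D3 ± dexamethasone,
and ex-vivo blood monocytes, pDC and cDC1.

## The model

SCENITH reads out protein synthesis (puromycin incorporation) after short
metabolic-inhibitor treatments. With per-well geometric mean fluorescence
intensities (gMFI) of the puromycin stain — `C` (control), `DG`
(2-deoxyglucose), `O` (oligomycin), `DGO` (both), `Eto` (etomoxir), `Tele`
(telaglenastat) — the derived parameters are

```
glucose dependence        = 100 (C − DG)  / (C − DGO)
mitochondrial dependence  = 100 (C − O)   / (C − DGO)
FAO dependence            = 100 (C − Eto) / (C − DGO)
glutaminolysis dependence = 100 (C − Tele)/ (C − DGO)
glycolytic capacity       = 100 − mitochondrial dependence
FAAO capacity             = 100 − glucose dependence
```

Protein-synthesis-adjusted parameters multiply each percentage by the
background window `C − DGO`. scMEP pathway scores are means of member
enzymes' arcsinh (cofactor 5) medians — e.g. TCA/ETC = {CS, ATP5A, IDH2} —
optionally volume-normalised by (radius/reference)³, and are benchmarked
against the adjusted SCENITH parameters by least squares and Spearman
correlation.

The synthetic generator draws per-cell intensities as
`well gMFI × donor factor × exp(σ·z)` (multiplicative log-normal noise), so
the geometric-MFI estimator is unbiased and the pipeline recovers each
archetype's ground truth exactly in the noiseless limit. Built-in
archetypes encode the reference metabolic trajectory (mitochondrial
dependence 18 % → 72 % → 79 % → 86 % from monocyte to mDC, with CD86-high /
CD1c-high subpopulations and tolerogenic shifts).

## Worked example

```python
import scenmep as sm

timeline = [a for a in sm.builtin_archetypes() if a.condition == "ctrl"]
events = sm.generate_scenith_dataset(
    timeline, n_cells_per_well=2000, donor_model=sm.DonorModel(3, 0.1),
    seed=7)
profiles = sm.profiles_from_events(
    events, by=("condition", "stage"),
    required=("C", "DG", "O", "DGO", "Eto", "Tele"))
for p in profiles:
    print(p.group["stage"], round(p.clamped["mitochondrial_dependence"], 1))
```

prints (run `python examples/01_scenith_profiles.py` for the full table):

```
stage      mito dep % glyc cap % gluc dep % FAAO cap %
mono_0h          17.9       82.1       80.0       20.0
mono_24h         71.8       28.2       63.1       36.9
iDC              79.1       20.9       54.9       45.1
actDC            75.1       24.9       60.3       39.7
mDC              86.0       14.0       76.0       24.0
```

i.e. monocytes sustain translation almost entirely through glycolysis
(82 % glycolytic capacity) and fully matured DC almost entirely through
oxidative phosphorylation (86 % mitochondrial dependence), recovered from
noisy single-cell wells to within a fraction of a percentage point of the
generator's ground truth. The other scripts in `examples/` demonstrate
pathway-score benchmarking, subpopulation stratification with oligomycin
classification, and tolerogenic-vs-control differential testing.

A thin CLI mirrors the stages: `scenmep simulate | validate | scenith |
scmep | stratify | diff | run`.

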