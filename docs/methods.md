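# Methods

This note documents the models and procedures implemented in
`crossmodulon`, the choices made where the design was genuinely open,
and what the synthetic benchmark does and does not establish.

## Problem setting

Bacterial transcriptomes can be modularized by independent component
analysis (ICA) into *iModulons*: sparse sets of co-modulated genes
(a column of a weight matrix **M**) with a condition-dependent activity
(a row of an activity matrix **A**), such that **X ≈ M·A** for a
compendium **X** (features × samples). `crossmodulon` applies the same
decomposition to a matched label-free proteomics compendium, matches
the resulting proteome modules (piModulons) to transcriptome modules
(tiModulons), classifies which omics layer dominates each matched
signal, and fits cross-validated regressions that predict the proteome
mass fraction allocated to a module's genes from the module's
transcriptome activity alone.

## Absolute quantification (`quant`)

Protein-level top3 intensities (mean of the three highest peptide
areas) are calibrated against a UPS2 spike-in of proteins at known
amounts by ordinary least squares in log space,
`log10(A) = a + b·log10(top3)`. Calibration is per sample by default —
each sample carries its own spike — with a pooled fit as fallback; a
per-sample fit with r² below 0.9 triggers a warning (heuristic
quality flag, configurable). Calibrated amounts are converted to
mass fractions `A_i / Σ_j A_j` and, for reporting, to concentrations
`C_i = γ·A_i / Σ_j A_j` with γ = 13.94 µmol·gDW⁻¹, the fixed total
protein budget per gram dry weight. "Not observed" is distinct from
zero throughout this stage; nothing is imputed before coverage
filtering.

## Compendium compilation (`compendium`)

Fixed order: (1) drop features observed in fewer than 50% of samples
(strictly-less-than removal, computed on the concatenated multi-batch
table); (2) impute remaining missing cells with the global minimum
observed abundance; (3) renormalise to per-sample fractions and
transform `log2(1e6·fraction + 1)` (log2(PPM+1)); (4) drop replicate
groups whose pairwise squared Pearson correlation falls below 0.9 —
pairs are removed whole, while in groups of three or more the
offending samples are removed greedily until the surviving minimum
pairwise R² clears the threshold; (5) center each batch on the mean
log profile of its common reference condition. Replicate R² is
computed on log-transformed values (an option computes it pre-log).
Centering preserves within-batch contrasts exactly and removes
cross-batch offsets at the reference.

## Robust ICA (`ica`)

`RobustICA(X, k, n_runs, seed).fit()` returns a `Decomposition`:

* FastICA (scikit-learn, logcosh contrast, PCA whitening to exactly k
  components) is run `n_runs` times with sub-seeds drawn from the
  master seed; non-convergent runs are retried up to a cap.
* Run components (unit-norm, largest-magnitude weight positive) are
  pooled and clustered by DBSCAN on the distance `1 − |Pearson r|`
  with neighborhood radius 0.1 and minimum cluster size ⌈n_runs/2⌉;
  each stable cluster contributes its centrotype (the member most
  correlated with the rest of its cluster).
* One alternating-least-squares pass follows: `A = M⁺X_c`,
  `M = X_c A⁺`, renormalise and re-orient, `A = M⁺X_c` (X_c is the
  row-centered compendium). FastICA internally removes the mean over
  the feature axis, so raw centrotypes live in a slightly shifted
  space; the refinement restores the invariants that the
  pseudo-inverse projection reproduces X to the residual reported by
  the explained variance, and that a noiseless rank-k matrix is
  reconstructed exactly. The input to each FastICA run is likewise
  pre-centered on both axes so the runs share one source space.

Per-component explained variance is
`EV_j = 1 − ‖X_c − m_j a_j‖²_F / ‖X_c‖²_F`, one component at a time;
because components are not exactly orthogonal these need not sum to
the cumulative EV `1 − ‖X_c − MA‖²_F / ‖X_c‖²_F`, and both are
reported. Dimensionality selection runs robust ICA over candidate k
values and returns the smallest k whose count of multi-member robust
components comes within one of the maximum (a plateau rule standing in
for the criterion used by external genome-scale workflows, which is not published).

Defaults: `n_runs = 100` is appropriate for real compendia; the test
suite and synthetic studies use 10, which is sufficient at their
signal-to-noise ratios.

## iModulon characterization (`imodulons`)

Membership thresholding removes the largest-magnitude weight
iteratively until the D'Agostino K² normality statistic of the
remaining weights falls below a cutoff; the threshold is placed midway
between the smallest removed and largest kept magnitude, so
`members = {|w| > threshold}` holds exactly. The conventional cutoff
value 550 presumes a genome-scale weight vector (≈4000 features); the
statistic grows roughly linearly in the feature count at a fixed
outlier fraction, so the default `"auto"` cutoff scales that anchor by
n/4000 with a floor of 20 (clean near-normal vectors score below ~10
at any n). Any fixed numeric cutoff can be supplied instead.

Enrichment is a one-sided hypergeometric test of member/regulon
overlap against the compendium background, over single regulons plus
pairwise unions of regulons that overlap the members (combined modules
such as a LeuO/Lrp union are pairwise; deeper combinations are left to
curation), Benjamini–Hochberg adjusted across everything tested.
Categories: *regulatory* when the best adjusted p ≤ 1e-3 (config);
*technical/single-gene* at ≤ 1 member; *biological* and *genomic* only
via a curation table; otherwise *uncharacterized*.

Invariance statistics compute each protein's mean mass fraction and
coefficient of variation (CV = sd/mean on the raw fraction scale,
never log) across samples, split by module membership. A protein is
*invariant* below CV 1. The strict form (CV < 1) is used for
compendium statistics and the inclusive form (CV ≤ 1) for the
allocation treemap; no realistic dataset places a protein exactly at
1.0, but both conventions are explicit.

## Cross-omics matching (`matching`)

Components are matched by the Pearson correlation of their weight
vectors restricted to the shared feature set, compared as |r| against
a threshold of 0.25 (component signs are arbitrary; sign alignment is
applied afterwards). One proteome component may match several
transcriptome components — the lumped case expected when the proteome
compendium is smaller and shallower than the transcriptome one. The
transcriptome decomposition used for matched-pair analyses can be
recomputed on the matched subset (shared features, condition-matched
samples, same reference) via `matched_subset`. A curation override
table is supported; automated and curated outputs are reported
separately.

DiMA (differential iModulon activity) replicate-averages both
activity series per condition, restricts to conditions present in both
compendia, z-standardizes each axis, and flags conditions where
|pi − ti| exceeds a band. The band is **absolute in standardized
units** (default 1.5): a rule relative to the standard deviation of
the difference series is self-normalising — it flags a fixed ~13% tail
even for identical series — which destroys the neutral dominance class;
the relative rule remains available via `relative=True`. Dominance is
classified over the differential conditions: each sides with the layer
whose standardized activity deviates more from its own mean, and a
≥ 2/3 majority (config) names that layer dominant; anything else,
including no differential conditions, is neutral. DiMM tables pair the
(sign-aligned) gene weights of a matched pair with membership flags
for plotting.

## Allocation regression (`allocation`)

For each eligible transcriptome module (uncharacterized, genomic and
technical modules are excluded), the summed proteome mass fraction of
its covered genes, replicate-averaged per condition, is regressed on
its activity. Three families compete:

| family      | model                       | parameters (p) |
|-------------|-----------------------------|----------------|
| linear      | y = m·x + c                 | 2              |
| exponential | y = c + a·exp(b·x)          | 3              |
| broken line | y = β₀ + β₁x + β₂(x − t)₊   | 4              |

The broken line is continuous two-segment piecewise linear; the
breakpoint is found by exhaustive search over interior observed x
values (≥ 2 points strictly on each side), each candidate solved by
least squares on the basis (1, x, (x−t)₊). The exponential is fit by
separable least squares: for fixed rate b the model is linear in
(c, a), so the fit is a 1-D bounded search over b (grid of 81 values
plus the log-linear initial estimates from both orientations, refined
by bounded scalar minimisation); rates are bounded at 50/range(x) so
the exponential stays finite over the data.

Family selection is leave-one-out cross-validation on the mean
absolute error of held-out predictions. The lowest-MAE family wins,
with one refinement: because the exponential and broken-line families
nest the linear one, plain argmin over-selects them on truly linear
data (recovery ≈ 73% in simulation); the default therefore applies the
one-standard-error parsimony rule — the simplest family whose held-out
fold errors are within one standard error of the best family's is
preferred (`se_margin=0` restores plain argmin; exact ties always go
to the simpler family). The winner is refit on all conditions and
scored by `adj R² = 1 − (1−R²)(n−1)/(n−p−1)` with p as tabled;
adj R² ≥ 0.3 labels the module *strong*. Normalized cross-validation
errors are `|y_pred − y_test| / ȳ`.

`holdout_sweep` repeats the selection with 10–30% random holdouts (5%
steps; test size rounds half up; per-(fraction, repeat) seeds derive
deterministically from the master seed) and reports test-set MAE and
adjusted R² distributions. Outlier conditions are never removed by
default; an exclusion option exists but is off.

`summarize_allocation` assigns genes to groups sequentially so no gene
is counted twice: strong modules in descending adjusted R² (ties to
the larger gene count), then weak modules, then the unclaimed genes
split into *invariant* (CV ≤ 1) and *other*. Each group reports its
gene count and the mean and CV across conditions of its summed mass
fraction; group shares partition the covered proteome exactly.

## Synthetic data (`synth`)

The generator plants a fully known ground truth: sparse disjoint
transcriptome modules (1–3% of genes each) with weights uniform in
±[0.5, 1], Laplace(0, 1) activities (heavy tails are what makes the
sources identifiable to ICA), mean-centered per module. Proteome
modules mirror single transcriptome modules or union two of them
(lumping). Per proteome module, a transcript→protein mapping family
shapes its protein activity: linear, exponential (rate 0.1) or broken
line (slopes 0.5/1.0) applied to the summed source activity. The
curvature defaults are deliberately mild: a module planted as
dominance-class *neutral* must genuinely have matched activity shapes,
and matched module activities in real compendia are well correlated;
stronger curvature is available in `SynthConfig`. The
activity→mass-fraction generating laws used in the regression recovery
studies (`generate_allocation_data`) are separate and use rate 0.5 and
slopes 0.002/0.02 in mass-fraction units.

Dominance scenarios act on the protein layer only: one module's
protein signal is multiplied by 0.1 at its five most active conditions
(transcript present, protein suppressed → transcriptome-dominant);
another gains +4 SD at five near-baseline conditions (protein boost →
proteome-dominant); the rest are neutral. Coverage censoring keeps the
top ~1/3 of genes by baseline (log-normal) abundance, emulating
label-free proteomics depth; modules backing proteome components draw
90% of their members from the covered pool. Gaussian replicate noise
(σ = 0.02 in log2 units) is added per sample; condition c000 is the
common reference. Defaults: 2000 genes, 60 conditions × 2 replicates,
k_t = 12, k_p = 8, two lumped modules.

What the generator does **not** emulate: peptide-level
mass-spectrometry noise, missing-not-at-random dropout beyond
top-abundance censoring, batch structure beyond a single batch,
correlated (operon-level) background expression, and regulon databases
with imperfect overlap to modules. Passing tests therefore establish
that the algorithms recover the structures they are designed for at
realistic noise, not that real compendia meet these assumptions.

## Numerical choices and degenerate inputs

* Weight-matrix columns are unit-norm with the largest-magnitude
  weight positive; all results are invariant to component sign flips
  and permutations (tested).
* The membership threshold is the midpoint between the last removed
  and first kept magnitude, so the member-set invariant is exact.
* Conservation: mass fractions sum to 1 and γ-concentrations to 13.94
  per sample to 1e-9 relative; group shares in the allocation summary
  partition the proteome to 1e-9.
* All-missing samples, batches without reference samples, empty
  coverage-filter results, singleton replicate groups, constant
  activity series, zero-mean proteins (CV undefined) and fewer than
  three shared features are rejected or excluded with named messages.
* LOOCV MAE ties go to the simpler family; breakpoint SSE ties to the
  earlier candidate.
* Every source of randomness flows from an explicit seed; reruns are
  byte-identical.

## Study sizes

The test suite and the reproduction script run the synthetic study at
its default scale (2000 genes, 120 samples, 10 ICA restarts), 50
replicates of the dominance study, and 100 replicates per generating
family of the regression study at 57 conditions — sizes chosen so the
full suite completes in a few minutes on one CPU while keeping every
Monte-Carlo margin comfortable.

## Known limitations

* The plateau rule for dimensionality selection is a documented
  stand-in for the selection criterion of external genome-scale workflows.
* The DiMA significance band is a package choice (see above); the
  relative-band variant is provided but not default.
* Real-data mode consumes published decomposition and mass-fraction
  tables; spectral searching, peptide FDR control and regulon-database
  curation are out of scope.
* Enrichment unions stop at pairs; deeper regulator combinations are
  curation territory.
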