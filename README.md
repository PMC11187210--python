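# crossmodulon

Matched transcriptome–proteome iModulon analysis for bacteria:
robust independent component analysis (ICA) of omics compendia,
cross-omics module matching, differential activity classification, and
cross-validated regression of proteome allocation on transcriptome
module activities.

## Who this is for

Systems biologists with condition-matched RNA-seq and label-free
proteomics compendia (or anyone benchmarking module-extraction
methods) who want to ask: do the independently modulated gene sets of
the transcriptome reappear in the proteome, where does
post-transcriptional regulation decouple the two layers, and how much
of the proteome's composition can be inferred from transcriptome
module activities alone?

## The model

A compendium **X** (features × samples, log scale, centered on a
common reference condition) is decomposed as

    X ≈ M · A

where columns of **M** are sparse, independently modulated feature
signatures (iModulons, membership defined by thresholding the weight
distribution's outliers) and rows of **A** are their condition
activities. The decomposition is a consensus over many FastICA
restarts: pooled components are clustered by 1 − |r| distance and only
clusters reproduced in at least half the runs survive.

Downstream of the two decompositions:

* **Matching** — proteome module *p* matches transcriptome module *t*
  when |Pearson r(M_p[:, p], M_t[:, t])| ≥ 0.25 over shared features;
  one proteome module may match several transcriptome modules (a
  "lumped" module).
* **DiMA / dominance** — per condition, the pair of z-standardized
  activities; conditions outside a significance band are
  differentially activated, and a ≥ 2/3 majority of them siding with
  one layer makes the pair transcriptome- or proteome-dominant
  (signatures of attenuation, riboswitches, proteolysis, translational
  activation), otherwise neutral.
* **Allocation** — per transcriptome module, the summed proteome mass
  fraction of its genes is regressed on its activity with three
  competing families (linear, exponential `c + a·e^{bx}`, continuous
  broken line); leave-one-out cross-validation selects the family, and
  adjusted R² ≥ 0.3 labels the relationship strong. Genes are then
  assigned once each — strong modules first — into
  strong / weak / invariant (CV ≤ 1) / other proteome sectors.

Absolute proteomics input is produced by UPS2 spike-in calibration of
top3 intensities (`log10 A = a + b·log10 top3`, per sample) and a
fixed per-sample protein budget γ = 13.94 µmol·gDW⁻¹
(`C_i = γ·A_i/Σ_j A_j`).

A synthetic-data generator plants all of this structure — sparse
modules, Laplace activities, lumping, dominance perturbations,
top-abundance coverage censoring, replicate noise — so every stage has
a recoverable ground truth. See `docs/methods.md` for the full
methodology.

## Worked example

Run the full pipeline on a synthetic study (800 genes, 40 conditions ×
2 replicates, 6 transcriptome / 5 proteome modules, one lumped):

```python
from crossmodulon import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=42, out_dir="demo", n_genes=800, n_conditions=40,
                     k_t=6, k_p=5, n_lumped=1, n_runs=10)
res = run_pipeline(cfg)
print("matches:", len(res.matches), "lumped:", sum(p.is_lumped for p in res.matches))
print(res.scorecard.to_dict())
for s in res.allocation_summary:
    print(f"{s.group:10s} genes={s.gene_count:4d} mean_share={s.mean_mass_share:.3f}")
```

prints

```
matches: 5 lumped: 1
{'min_abs_r': 0.9996050564283494, 'median_jaccard': 1.0,
 'link_recall': 1.0, 'link_precision': 1.0, 'family_recovery': {}}
strong     genes=  40 mean_share=0.140
weak       genes=  60 mean_share=0.227
invariant  genes= 167 mean_share=0.633
other      genes=   0 mean_share=0.000
```

Every planted transcriptome module is recovered essentially exactly
(weight correlation ≥ 0.9996, membership Jaccard 1.0), all five
planted proteome↔transcriptome links are found with no false links
(recall and precision 1.0), including the module that lumps two
transcriptome modules, and the allocation summary partitions the
covered proteome into sectors: here 14.0% of proteome mass follows
strongly predictable modules, 22.7% weakly predictable ones, and
63.3% is invariant background. An individual module's regression
reads:

```python
print(next(iter(res.fits.values())).summary())
```

```
Allocation regression: ic_0
  family          linear
  n conditions    40
  LOOCV MAE       0.00242549
  R^2 / adj R^2   0.1283 / 0.0812
  strength        weak
  parameters      slope=-0.000471584, intercept=0.0776992
  LOOCV MAE by family  linear=0.00242549, exponential=2.16937, broken_line=0.00377333
```

— the linear family wins the cross-validation, but with an adjusted R²
of 0.08 this module's mass fraction is not reliably predictable from
its activity (strength "weak").

The same stages are available from the shell
(`crossmodulon simulate | quantify | compile | decompose |
characterize | match | dima | allocate | run-all`), reading and
writing plain TSV/JSON.

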