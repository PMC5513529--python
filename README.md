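# cnspanel

Cell-type-resolved comparison of bulk brain transcriptomes across
neurodegenerative diseases.

## The problem

Whole-tissue expression profiles of brain (e.g. superior frontal gyrus in
multiple sclerosis, Parkinson's and Alzheimer's disease) are mixtures of
cell types, so a disease signal confined to one cell type — activated
microglia, lost neurons — is diluted and easily missed by whole-tissue
differential expression. `cnspanel` reads the cell-type signal back out of
bulk data by projecting per-gene log2 disease/control ratios onto panels of
cell-type-enriched marker genes (top-500 lists for neuron, microglia,
astrocyte, endothelia, and newly formed / myelinating oligodendrocytes),
and then asks two questions per cell type:

1. **Shift**: is the panel's mean log2 ratio displaced from 0
   (one-sample t-test over the panel's genes)?
2. **Sharing**: do two diseases move the *same* panel genes the same way
   (winsorized Pearson correlation of the two ratio vectors, outliers
   clipped at ±c robust SDs around the median before correlating)?

plus a threshold table: panel genes whose ratio exceeds 0.5 log2 units in
every disease of a required set.

The pipeline per cohort is: sample filtering (e.g. an age floor on controls
for age matching) → quantile normalization → probe-to-gene collapsing
(multi-probe genes averaged) → per-gene ratio
`log2(mean disease / mean control)` on the linear scale.

A synthetic tissue-mixture generator (`cnspanel.simulate`) produces
cohorts with known signatures, mixing proportions, cell-type-specific
effects, multi-probe genes and log-normal noise, together with a ground
truth ledger and a closed-form expected panel ratio

```
ratio(T) = log2( Σ_ct p'_ct e_ct 2^δ_ct / Σ_ct p_ct e_ct ),   e_T = E, e_ct≠T = 1
```

(`p`/`p'` control/disease proportions, `E` marker enrichment, `δ` log2
effects) so every stage is testable with no downloads.

## Worked example

```
python analysis/01_simulate_cohorts.py      # 3 cohorts, shared +1 log2 microglia effect
python analysis/02_run_pipeline.py          # full cross-disease analysis
```

prints (abridged):

```
  microglia                      AD: +0.475 ***
  microglia                      MS: +0.471 ***
  microglia                      PD: +0.480 ***
  neuron                         AD: -0.207 ***
mean cross-cohort winsorized r by cell type:
  microglia                      +0.854
  neuron                         +0.151
most shared cell type: microglia
```

The injected +1.0 log2 microglia effect appears as a panel shift of only
≈ +0.5: tissue with 10% microglia and 10-fold marker enrichment dilutes
the effect to a closed-form +0.61, and quantile normalization compresses
it a bit further (see `docs/methods.md`). Because the three simulated
diseases share their per-gene microglia effects, microglia shows by far
the highest cross-disease correlation — exactly the signature the method
is designed to detect. The other drivers report null calibration
(`03_null_calibration.py`: both tests reject at ≈ 5% under the null),
mixture recovery (`04_mixture_recovery.py`: noise-free error ~1e-15,
noisy panel means within ±0.014), and the replay of a published
shared-gene table (`05_shared_gene_replay.py`: 9 microglia genes common to
all three diseases, 12 astrocyte + 13 endothelia genes common to MS and
PD with AD below threshold).

A `cnspanel` CLI exposes the stages (`simulate`, `normalize`, `collapse`,
`ratios`, `panel-stats`, `correlate`, `shared`, `run-all`,
`export-figures`); real GEO series-matrix files can be fed to `run-all`
with a local probe annotation TSV and a YAML run configuration.

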