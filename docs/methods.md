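# Methods

## Model and procedure

The unit of inference is the **cell-type marker panel**, not the gene.
Bulk brain tissue is modelled as a mixture: the measured value of gene *g*
in sample *s* is `Σ_ct p_ct(s) · x_ct(g)`, the proportion-weighted sum of
the gene's expression across cell types. A panel of genes enriched in one
cell type (each marker expressed E-fold higher in its home type than
elsewhere) concentrates that type's signal; statistics computed over the
panel's disease/control ratios therefore read out, approximately, that
cell type's disease response — diluted by the other types, and confounded
between cell-intrinsic expression change and change in the cell type's
abundance (the generator separates these two levers so the confound can be
studied; the analysis of real data cannot).

Per cohort the pipeline applies, in order:

1. **Sample filtering.** An optional per-cohort age floor on the control
   group (samples strictly under the floor removed; the boundary age is
   kept, matching a reported retained range whose minimum equals the
   floor). Filtering precedes normalization so the normalization target is
   computed only from retained samples; the order is recorded in the run
   summary.
2. **Quantile normalization** within the cohort (never across cohorts —
   only ratios are compared between diseases). Every column is mapped to
   the per-rank means of the sorted columns; tied values receive the mean
   of the rank-means their run spans ("average ties"). On tie-free data
   the transform is exactly idempotent and all columns share one multiset;
   with ties the span-averaging perturbs the column multisets slightly, so
   idempotence is exact only in the tie-free case.
3. **Probe collapsing.** Multi-probe genes are averaged per sample
   (arithmetic mean of normalized linear intensities); probes without a
   gene symbol are carried through normalization but dropped here — they
   can never join a panel. Symbols are upper-cased before any matching.
4. **Ratios.** `ratio(g) = log2( mean_disease(g) / mean_control(g) )` of
   linear-scale values. Groups are unpaired and may be unequal, so the
   ratio of group means (not a mean of per-sample log ratios) is the
   defined quantity. Genes with a nonpositive group mean are excluded and
   counted. Sexes are pooled.

Input intensity scale is auto-detected: a series whose maximum value is
below 30 is assumed to be log2-submitted and is exponentiated to linear
(GEO mixes both conventions); the decision is logged and can be forced
either way per cohort.

## Statistics

**Panel shift.** One-sample t of the panel's ratios against 0:
`t = mean / (sd/√n)`, two-sided p on n−1 df. Panel genes are treated as
independent replicates; they are in fact co-regulated, so p-values are
anti-conservative — the test is reproduced in this conventional form as a
descriptive annotation (tiers * p<0.01, ** p<0.001, *** p<0.0001, the
monotone reading of the customary legend), not as a calibrated gene-set
test.

**Winsorized correlation.** Each margin is centered at its median, scaled
by the normal-consistent MAD (×1.4826), clipped to ±c, and returned to the
original scale; then textbook Pearson r of the clipped vectors, with
two-sided p from `t = r√((n−2)/(1−r²))` on n−2 df. Defaults: c = 2.0
robust SDs (the technique's common default; configurable and logged);
c = ∞ reduces exactly to plain Pearson. Winsorization is marginal (per
vector), not bivariate. A zero MAD (over half the values tied) leaves the
margin unclipped with a warning. No multiple-testing correction is applied
across the 6 panels × 3 pairs; raw p-values are reported.

**Shared genes.** Panel genes whose ratio exceeds a threshold (default
0.5 log2 units) in every cohort of a required set; ratios in all cohorts
are reported either way, rows sorted by gene. The boundary is inclusive
(≥) by default: published ratio tables are printed at two decimals and
treat boundary entries as selected, so a strict comparison applied to
rounded inputs would drop genes whose unrounded value cleared the cutoff.
`inclusive=False` gives the strict reading. Selection is monotone in the
threshold.

## Synthetic cohorts

`SyntheticConfig` defaults describe a plausible bulk-brain study:
4000 genes; six CNS cell types with 500 disjoint markers each;
enrichment E = 10 (marker home-to-away fold); neuron-dominant mixing
fractions (neuron 0.40, astrocyte 0.20, myelinating oligodendrocyte 0.15,
microglia 0.10, endothelia 0.10, newly formed oligodendrocyte 0.05);
10 disease + 10 control samples; multiplicative log-normal noise with
SD 0.3 log2 units; 1–3 probes per gene (50/30/20%), the first probe
reporting the tissue value and extra probes carrying fixed offsets hashed
from (seed, gene, index); ages uniform in 70–95 (disease) and 70–99
(control). Gene base levels are log-normal (log2 mean 7, SD 1). Disease
samples multiply affected cell types' intrinsic expression by
`2^(δ_ct + N(0, effect_gene_sd))` — the per-gene deviations can be shared
between simulated diseases (what makes cross-disease panel correlation
positive) or drawn independently — and may additionally shift mixing
proportions. Mixing fractions are fixed per group (no per-sample jitter),
which keeps the closed-form expected panel ratio exact in the noise-free
case:

```
ratio(T) = log2( Σ_ct p'_ct e_ct 2^δ_ct / Σ_ct p_ct e_ct ),  e_T = E, else 1.
```

What the generator does **not** emulate: platform-specific noise models,
array spatial artifacts, batch effects, per-sample composition
variability, and realistic marker-enrichment heterogeneity (all markers
share one E). Passing tests therefore demonstrate correctness of the
computations and recoverability under the stated mixture model, not
robustness to everything real arrays do.

## Validation studies (what the suite and acceptance script compute)

* Quantile normalization equals an independent sort/average/unsort oracle
  elementwise on random 50×8 tie-free matrices and is idempotent to 1e-9.
* Winsorized correlation equals the two-step oracle (marginal winsorize,
  then `scipy.stats.pearsonr`) to 1e-12, and plain Pearson at c = ∞.
* Under i.i.d. normal nulls (500 genes, 2000 replicates) both tests reject
  at ≈ 5% at α = 0.05.
* A noise-free default cohort recovers the closed-form panel ratio to
  machine precision via simulate → collapse → ratio → project; with the
  default noise the 20-seed panel means stay within ±0.1 (observed ≈ ±0.014).
* Disease pairs sharing per-gene microglia effects (gene SD 0.5) give
  winsorized panel r with 20-seed median > 0.6 (observed ≈ 0.89);
  independent pairs give median |r| < 0.2 (observed ≈ 0.02).
* Feeding a published two-decimal ratio table through the shared-gene
  selection reproduces its printed memberships exactly.

Problem sizes above (matrix dimensions, replicate and seed counts) are the
package's standard validation settings; all run in seconds to a couple of
minutes.

## Numerical and design notes

* **Recovery route bypasses quantile normalization.** QN is a
  between-array correction; the generator's arrays are already on a common
  scale. More importantly QN forces identical column distributions, so
  when a sizeable fraction of genes genuinely shifts in one direction
  (500/4000 markers here) it compresses the shift — measured ≈ −0.15 bias
  on a +0.61 expected panel ratio — and induces small opposite shifts in
  unaffected panels. The full pipeline keeps QN (real series need it and
  real platforms measure 20–50k probes, where the distortion is smaller);
  the bias is demonstrated in a dedicated test and visible in the worked
  example.
* Panel genes absent from a platform are dropped silently with an
  `n_matched` count; a panel with zero overlap raises, since that
  indicates a symbol-vintage or annotation mismatch. Annotation is an
  explicit input — no fixed platform vintage is assumed.
* Cross-disease correlations use the intersection of the panel with genes
  measured in both cohorts.
* Degenerate inputs: single-sample matrices, zero-variance panels,
  constant-after-winsorization margins, and empty groups raise informative
  errors rather than returning NaN; an empty shared-gene table is a valid
  result.
* Determinism: every simulation is reproducible from its seed; result
  tables are written sorted by declared keys with floats at 6 significant
  digits, so reruns are byte-identical.

## Limitations

The panel t-test's pseudo-replication (genes as replicates) and the
mixture confound (expression change vs abundance change) are inherent to
the marker-panel readout and are reproduced as published conventions;
conclusions from the shift tiers should lean on effect sizes, and the
generator's two effect levers exist precisely to probe the confound.
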