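# assocmod

Inference of **association modules** — sets of passenger mRNA/microRNA
expressions explained by driver molecular aberrations — from multi-omic
cell-line panels.

Cancer cell lines carry many molecular aberrations: chromosomal segment
copy-number variations (CNVs), point mutations, promoter DNA methylation,
and expression changes of regulators such as transcription factors (TFs)
and microRNAs. Only some of these *drive* downstream expression changes.
`assocmod` reconstructs driver–passenger structure as modules: a small
driver set, optional mediating regulators, a fixed association sign, and a
passenger list. It is aimed at computational biologists integrating
heterogeneous omics matrices over a modest sample panel (tens of samples,
e.g. a 60-line, 9-tissue cell-line panel).

## The model

All continuous data are rank-transformed per feature to CDF values and
softly quantized into probability triples over three ordered states
(low/mid/high). A passenger state y ∈ {−1, 0, +1} given driver values
x = (x₁, …, x_k) follows the log-linear conditional

    P(y | x) = (1/Z(x)) · exp( Σᵢ λᵢ fᵢ(xᵢ) · y ),   λᵢ ≥ 0,

with scalar feature functions fᵢ(xᵢ) = xᵢ for an activating aberration and
fᵢ(xᵢ) = −xᵢ for a repressive one, and Z(x) the three-state partition
function. Weights are fitted by constrained maximum likelihood; nested
models are compared by likelihood-ratio tests (LRT). Modules are built in
layers:

1. **Screen** every (driver, passenger) pair per driver type under the
   type's sign convention (cis-CNV +, methylation −, microRNA −,
   mutation ±, TF ±).
2. **Mediators**: a trans-acting segment CNV candidate is kept only if a TF
   on that segment is cis-associated with the segment and associated with
   the passenger.
3. **TF exclusion**: TFs explained by any observed aberration cannot seed
   expression-driver modules.
4. **Replaceability filter**: for driver pair (A, B), fit the joint model
   M_AB; if it significantly beats M_A but not M_B, remove A. Cis effects
   have priority over trans effects.
5. **Assemble**: group passengers by driver; report modules with ≥ 10
   passengers.

Validation layers: permutation false discovery rates (null counts of
significant pairwise calls from label-permuted driver data; FDR = null mean
or null 99th percentile over the observed positive count), exact
hypergeometric enrichment of marked gene sets in passenger lists, and
tissue-pattern extraction (decomposition onto ideal tissue indicator
profiles intersected with a GSEA-style driver test).

Chromosome segmentation, a synthetic benchmark generator with planted
ground truth, and a CLI tie the stages into a reproducible pipeline.

## Worked example

Generate a synthetic 60-sample, 9-tissue panel with one planted module of
each of the six types and run the whole pipeline:

```bash
assocmod --seed 3 --outdir out all
cat out/modules.tsv
```

```
index  driver_type  drivers    reg        sign  N
1      cis_cnv      seg_1      NA         +     20
2      trans_cnv    seg_2      trans1_TF  +     16
3      mutation     mut1       NA         +     14
4      methylation  meth1      NA         -     15
5      mirna        mir1       NA         -     17
6      tf           tfexo1_TF  NA         +     21
```

All six planted modules are recovered: module 1 is a cis effect of
segment 1's CNV on 20 of its local genes; module 2 is a trans effect of
segment 2 mediated by the TF located on it (column `reg`); modules 3–6 are
mutation (+), methylation (−), microRNA (−) and exogenous-TF (+) modules.
`N` is the passenger count (the ≥ 10 size rule applies).
`out/tissue_patterns.tsv` shows the melanoma-style cis module called `up`
in the ME tissue while the tissue-independent mutation module stays
incoherent everywhere, and `out/fdr.tsv` reports permutation FDRs per
driver type (constrained cis associations have far smaller FDR, e.g.
0.0079 versus 0.26 for methylation in this run).

The same stages are available as library functions
(`assocmod.build_modules`, `assocmod.permutation_null`,
`assocmod.hypergeom_tail`, ...) for programmatic use.

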