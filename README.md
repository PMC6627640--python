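# polysig

Discovery of a polycomb/H3K27me3-target expression signature from replicated
parental-vs-resistant RNA-seq designs, and stratification of patient cohorts
by that signature.

## The problem

Embryonal carcinoma cell lines that acquire cisplatin resistance derepress
genes normally silenced by the polycomb repressive complexes (PRC1/PRC2,
via H3K27me3).  Given count matrices for several resistant clones and their
parental lines — each in biological triplicate — the analysis asks three
questions:

1. Which genes are recurrently upregulated, and which curated gene sets are
   enriched, in the resistant clones?  (moderated-t differential
   expression; weighted running-sum GSEA with a gene-set permutation null)
2. Can a *consensus signature* be distilled from the enrichment results?
   (leading-edge genes of the top-NES polycomb-related sets per line,
   keeping genes that recur in ≥ 4 resistant lines)
3. Does that signature stratify tumor patients by disease-free survival?
   (per-gene Z-scores, per-patient sum-Z score, median split,
   Kaplan–Meier / log-rank / Pike hazard ratio)

The package implements each stage as a library module with a thin CLI, plus
ground-truthed synthetic-data generators for all three inputs, so the whole
path can be validated end to end against planted truth.

## The statistics in brief

* **Moderated t** — per gene, a two-group linear model on
  `log2(count/libsize·1e6 + 0.5)`; residual variances `s²_g` are shrunk
  toward a prior `s²_0` fitted by matching the moments of `log s²_g` to a
  scaled-F distribution (trigamma inversion):
  `s̃²_g = (d₀s²₀ + d_g s²_g)/(d₀ + d_g)`, `t = Δ/(s̃_g·√(1/n₁+1/n₂))`
  with `d₀ + d_g` degrees of freedom; Benjamini–Hochberg FDR.
* **GSEA** — genes ranked by signal-to-noise `(μ_t−μ_r)/(σ_t+σ_r)` with a
  floored σ; the enrichment score is the extreme deviation of a running sum
  in which set members add `|metric|^w / Σ|metric|^w` and non-members
  subtract `1/(N−N_hits)`.  NES = ES divided by the mean of same-sign
  permutation-null ES; p-values carry a pseudocount; FDR is the
  ratio-of-tails on the pooled null NES distribution.
* **Signature scoring** — each gene standardized to mean 0, SD 1 across
  samples; a sample's score is the sum of Z-scores over the signature genes
  present; cohorts are split at the score median.
* **Survival** — Kaplan–Meier product-limit curves, the two-sample log-rank
  test `(O−E)²/V` with the hypergeometric variance, and the Pike hazard
  ratio `(O₁/E₁)/(O₂/E₂)` with a log-normal 95% CI.

## Worked example

Run the full synthetic analysis at the default study conditions
(3 parental lines; 8, 4 and 2 resistant clones of which 10 are profiled,
in triplicate; 5000 genes with a planted 400-gene polycomb-target pool;
a 210-set collection with 10 planted polycomb sets; a 132-patient cohort
with a generative hazard ratio of 2.1):

```bash
polysig run --seed 1 --out runs/demo
```

prints

```
run complete: 273 signature genes, cell-line purity 1.000, log-rank p=0.01577, HR=2.5 -> runs/demo
```

meaning: the consensus signature holds 273 genes (occurrence ≥ 4 of the 10
profiled resistant lines); clustering the 13 line-averaged Z-score profiles
on those genes separates parental from resistant lines perfectly (purity
1.0 at the two-cluster cut); and in the synthetic cohort the high-score
half recurs significantly faster than the low-score half.  The run
directory holds every intermediate table; `runs/demo/survival.json`
contains

```
chi2 = 5.828, p = 0.0158, hazard_ratio = 2.50 (95% CI 1.25-4.99),
observed events: 23 high vs 9 low of 32 total
```

— the Pike estimate straddles the generative hazard ratio of 2.1.  Each
stage can also be run on its own files: `polysig de`, `polysig gsea`,
`polysig signature`, `polysig score`, `polysig survive`, and
`polysig simulate celllines|collection|cohort` write and read the plain
TSV/GMT formats, so real count matrices, MSigDB collections and clinical
tables can be substituted for the synthetic ones at any stage.

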