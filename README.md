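# genestage

Scores arbitrary gene lists against Alzheimer's disease (AD) severity, and
explains the resulting drug rankings through drug–target binding statistics.

The package is aimed at computational biologists doing transcriptomics-driven
drug repurposing: given (i) postmortem brain expression cohorts annotated with
Braak stage and (ii) gene lists — typically genes differentially expressed
after drugging neural cell cultures, but any named list works — it quantifies
how well each list predicts disease stage relative to random lists of the same
length, ranks drugs by the combined evidence, and then asks which protein
targets and target pairs the top-ranking drugs have in common.

## Method

**Stage prediction.** Braak scores 0–6 are grouped into severity categories
A (0–2), B (3–4), C (5–6), defining binary tasks (default A-vs-C). For a gene
list *G*, a ridge-regularized logistic regression restricted to *G* is
evaluated by age-matched leave-pair-out cross-validation (LPOCV): each sample
is paired with its closest age match from the opposite class, the model is
refit with each pair withheld, and

AUC = (# pairs where the later-stage member scores higher) / (# pairs),

the fraction of correctly ranked pairs, which estimates the area under the
ROC curve while controlling for age.

**Significance.** The list's AUC is compared with *n* random lists of equal
length drawn uniformly from the protein-coding universe: the empirical
p-value is the fraction of random lists that outperform it (clamped below at
1/(n+1)). P-values for the same list across datasets and brain regions are
combined with the harmonic mean p-value (HMP), per-experiment HMPs are merged
by geometric mean, and drugs are ranked by merged HMP (ascending).

**Target affinity spectrum (TAS).** Heterogeneous binding evidence is reduced
to TAS ∈ {1, 2, 3, 10} (1 = strongest binder, 10 = confirmed non-binder,
absent = unknown). Dose–response affinities map by banded thresholds
(<100 nM → 1, 100–999 nM → 2, 1–10 µM → 3, >10 µM → 10); single-dose percent
measurements use concentration-specific cutoffs; literature assertions map
confirming → 2, negative → 10. Repeated measurements aggregate by first
quartile; dose–response takes precedence over single-dose over literature.

**Target statistics.** For each target, per-TAS ECDF areas locate its binders
in the drug ranking, and a one-sided Kendall statistic (fraction of
concordant pairs among orderable pairs, permutation p-value) tests whether
stronger binding tracks better rank. For target pairs, Wilcoxon rank-sum
tests compare joint binders against single binders; per-target aggregation
uses Brown's method with Jaccard similarity of compound sets as the
dependence proxy, followed by Benjamini–Hochberg adjustment.

All inputs can be emulated by the built-in synthetic generators (staged
cohorts, drug-vs-DMSO count matrices, binding-record tables), each emitting a
machine-readable ground-truth file.

## Worked example

A complete screen on synthetic data, via the `genestage` command:

```sh
cat > config.yaml <<'YAML'
simulate:
  n_drugs: 8
  n_targets: 4
  density: 1.0
  cohort: {n_per_stage: [15, 8, 15], n_genes: 400, n_informative: 20, effect_size: 0.6}
  perturbation: {n_genes: 500, n_responsive: 40}
YAML
genestage simulate --config config.yaml --outdir data --seed 1
genestage derive-signatures --counts data/counts.tsv --manifest data/manifest.tsv --out out/lists.gmt
genestage evaluate-lists --expr data/expression.tsv --meta data/metadata.tsv \
    --universe data/universe.txt --lists out/lists.gmt \
    --out out/evaluations.tsv --n-background 100 --seed 1
genestage rank-drugs --evaluations out/evaluations.tsv --out out/ranking.tsv
genestage tas --binding data/binding.csv --out out/tas.csv
genestage target-tests --ranking out/ranking.tsv --tas-table out/tas.csv \
    --out out/targets.tsv --n-perm 1000 --seed 1
genestage polypharm --ranking out/ranking.tsv --tas-table out/tas.csv \
    --out-pairs out/pairs.tsv --out-targets out/pp_targets.tsv --min-compounds 3
```

`out/ranking.tsv` then holds the drug ranking:

```
gene_list  experiment  hmp   merged_hmp  rank
drug04     EXP1:10uM   0.2   0.2         1
drug06     EXP1:10uM   0.21  0.21        2
drug01     EXP1:10uM   0.24  0.24        3
...
drug00     EXP1:10uM   0.72  0.72        8
```

Each drug's gene list beat (1 − p) of 100 random equal-length lists at
predicting early-vs-late stage; drug04's list outperformed 80 of them
(empirical p = 0.2, a single cohort, so HMP equals that p). The head of
`out/targets.tsv` reads:

```
target  n_drugs  n_binders  tau   tau_classical  p      ecdf_auc_tas1  ...
T02     8        6          0.8   0.6            0.068  0.75
```

For target T02, 80% of orderable drug pairs are concordant (stronger binders
rank better); the permutation p-value 0.068 is suggestive at this toy scale,
and the TAS-1 ECDF area 0.75 says its strongest binders concentrate near the
top of the ranking. `out/pairs.tsv` and `out/pp_targets.tsv` hold the
pairwise polypharmacology tests and their Brown/BH aggregation — neutral
here, as this small example plants no polypharmacology signal.

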