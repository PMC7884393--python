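# Methods

This note documents the statistical procedures implemented in `genestage`,
the choices made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about behavior on real data.

## Stage prediction and the LPOCV estimator

Samples are labeled by grouping Braak neurofibrillary-tangle stages into
ordered severity categories A (Braak 0–2), B (3–4), C (5–6); a binary task
selects two categories (default A-vs-C, the maximally separated contrast) and
requires at least two samples per class. Expression values are consumed as
provided — the loader assumes log-scale normalized abundance and offers an
optional log2(CPM+1) transform for raw counts, but never silently
re-normalizes. Censored ages ("90+") parse to their numeric prefix.

The predictor is an L2-penalized logistic regression (scikit-learn, lbfgs).
Ridge rather than lasso is deliberate: the gene list *is* the feature
selection, and no listed gene may be dropped by the fit. The regularization
weight (default 1.0 on standardized features) is fixed, not tuned per fold,
to keep evaluations deterministic and comparable across lists. Features are
z-scored with training-fold statistics only; zero-variance training columns
map to zero in both fold and held-out data.

Leave-pair-out cross-validation pairs every sample with its nearest-age
opposite-class sample. Age ties are broken uniformly at random with an RNG
keyed on (seed, CRC32 of the anchor's sample id) over candidates sorted by
sample id — this makes pairing, and hence the AUC, invariant to the order in
which samples appear in the input files, while remaining reproducible under
the seed. Mutual selections are deduplicated. For each pair, the model is
refit on all task samples except the two withheld members (members appearing
in other pairs stay in the fold), and the pair counts as correct when the
later-stage member receives the strictly higher score; exact score ties count
1/2, the unbiased AUC convention. The fraction of correct pairs estimates the
area under the ROC curve.

A consequence worth knowing: because the model is refit per fold and the
penalized logistic objective is exactly sign-symmetric, the LPOCV AUC is
invariant under negating features or swapping class labels — an
anti-correlated gene is as informative as a correlated one. The familiar
`auc -> 1 - auc` complement applies only to a fixed, non-refit scorer.

## Empirical significance, HMP, and the drug ranking

The null for a list of length L on a given (dataset, region, task) is the
AUC distribution of `n_background` lists (default 1000) of exactly L distinct
genes drawn uniformly without replacement from the cohort's gene universe.
Nulls are cached per (cohort, task, L) and shared across drugs with
equal-length lists. The empirical p-value is the fraction of null lists with
strictly greater AUC ("outperformed" read strictly, so AUC ties favor the
target), clamped below at 1/(n_background+1): the resolution of a finite null
is bounded, and the downstream harmonic mean is undefined at zero.

P-values for one list across datasets/regions pool into an unweighted
harmonic mean p-value, k/Σ(1/p); all evaluations pool into a single HMP per
(list, experiment) rather than first aggregating within dataset. Derived
lists are named by drug with the (experiment, dose) contrast carried
separately, so a drug profiled at several doses or in repeat experiments has
its per-contrast HMPs merged by geometric mean. Drugs sort ascending by
merged HMP, ties broken lexicographically.

## Drug-associated gene lists

The differential-expression step is a deliberately simple, self-contained
stand-in behind a stable contract (per-gene logFC, p, BH-adjusted FDR): a
Welch t-test on log2(CPM + 0.5), with per-column library sizes taken from the
full experiment so that subsetting columns to one contrast does not change
normalization. Genes with zero counts everywhere are reported with p = 1 and
logFC = 0 rather than dropped. Any external DE engine can replace it by
supplying precomputed lists; a test cross-checks the logFC contract against
edgeR on a synthetic contrast. A derived list keeps genes at FDR < 0.05,
ranked by ascending FDR, then descending |logFC|, then symbol, truncated to
300 — the tie-break makes the cap reproducible. A contrast with no
significant genes yields an empty sentinel list that downstream evaluation
skips, so one inert drug cannot abort a screen.

## TAS resolution

Binding evidence resolves per drug–target pair in three steps: (1) aggregate
repeated measurements of the same kind by the first quartile (linear
interpolation between order statistics — the common statistical default; the
quartile favors the strongest measurements); (2) convert via the banded
rules — dose–response <100 nM → 1, [100, 1000) → 2, [1000, 10000] → 3,
>10 µM → 10; single-dose thresholds per assay concentration (100 nM: <25% → 2,
≥75% → 10; 1 µM: <1% → 2, ≥90% → 10; 10 µM: <0.1% → 2, ≥75% → 10), values in
the unassigned middle band staying undecided; literature confirming → 2,
negative → 10; (3) pick the highest-precedence kind with a decided outcome:
dose–response, then single-dose, then literature. Single-dose conflicts
across concentrations resolve at the lowest concentration with a decided
outcome (the most stringent binding evidence). For literature, where a
quartile of categorical assertions is not meaningful, any confirming
assertion outweighs negatives (the first quartile of mapped {2, 10} values
reduces to the same rule). A pair with no decided evidence stays unknown —
a missing entry, never a score. The single-dose measured quantity behaves as
a percent-of-control readout (low values indicate binding), which is the
polarity consistent with the thresholds as stated; the thresholds are
implemented verbatim either way.

## Ranking-association and polypharmacology statistics

Per-TAS ECDF areas use the closed form 1 − mean(rank)/n over member drugs'
1-based positions; values near 1 mean saturation at the top. The Kendall
statistic is the fraction of concordant pairs (lower TAS ↔ better rank)
among orderable pairs (unequal TAS); the classical tau-a on orderable pairs
is 2·tau − 1 and both are reported. Its one-sided p-value shuffles TAS labels
across drugs: Monte Carlo with plus-one smoothing, (b+1)/(n_perm+1), at the
default 10,000 permutations, or exhaustive enumeration on request for small
instances. Targets with fewer than three confirmed binders are not evaluated,
and drugs with unknown TAS for the target are excluded.

Target pairs are eligible with ≥6 compounds of known TAS for both targets
and nonempty "binds both" and "binds exactly one" sets. Each comparison
(joint binders vs A-only, vs B-only, vs the XOR union) runs as two one-sided
Wilcoxon rank-sum tests on ranking positions — exact enumeration when both
sides have ≤10 members (positions are distinct, so no tie correction is
needed there), normal approximation with tie correction otherwise. The
reported p is the smaller side; the pair's direction is the consensus of
comparisons whose two-sided equivalent clears α = 0.05 (voting on the raw
one-sided minimum would double the null rate of non-neutral calls). The
three p-values combine by harmonic mean into `pair_hmp`.

Per target, its pairs' `pair_hmp` values combine with Brown's scaled-χ²
extension of Fisher's method. The covariance of the −2·ln p terms between
two pair tests is approximated by the standard cubic polynomial
3.263·r + 0.710·r² + 0.027·r³, with the Jaccard similarity of the two pairs'
joint-binder compound sets standing in for the correlation r; at Jaccard 0
the combination reduces exactly to Fisher's method, and a single-pair target
keeps its own p. BH adjustment runs across targets; a target's direction is
the majority among its nominally significant pairs.

## Synthetic fixtures

The cohort generator emulates the statistical skeleton of a staged brain
cohort: per-gene baseline means N(6, 1) on the log scale, a chosen set of
informative genes shifted by `effect_size` (default 1.0, i.e. one noise SD)
per category step A → B → C, N(0, 1) noise, Braak scores drawn within the
category, and ages uniform on overlapping category ranges (A 60–85, B 65–90,
C 70–95) so age matching is informative and exercises tie-breaking. The
perturbation generator produces negative-binomial (gamma-Poisson) counts,
overdispersion 0.005 (biological CV ≈ 7%, representative of technical
replicates of a clonal culture) around a library of 10⁷ expected counts,
with each drug's responsive genes split half up-, half down-regulated by the
fold change (default 4) so the perturbation is approximately
composition-neutral and unperturbed genes remain null on the CPM scale. The
binding-table generator draws a truth TAS per sampled pair and constructs
evidence that provably resolves back to it, including deliberately
conflicting lower-precedence records.

What these fixtures do not model: gene–gene correlation structure,
brain-region heterogeneity, donor-level covariates beyond age, batch
effects, realistic kinome binding densities, or dose–response shapes.
Passing tests therefore demonstrate correctness of the estimators and their
calibration under the generators' assumptions, not performance on real
cohorts.

## Problem sizes and numerical checks

The test suite runs everything at desk scale: the LPOCV oracle comparison
refits 8–12-sample tasks against an explicit-gradient solver (BFGS, gtol
1e-10) and requires exact AUC equality; null calibration uses a 100-sample ×
2000-gene effect-free cohort with 50 probe lists against a 200-list
background, averaging the Kolmogorov–Smirnov distance over three fixed seeds
(a single 50-probe draw sharing one background is dominated by the
background's own sampling noise — the two-sample KS critical value at these
sizes is ≈0.21 — so the three-seed mean is both less noisy and a stricter
check against the same 0.15 bound); planted-signal recovery uses
(20, 10, 20)-sample, 500-gene cohorts over 20 seeds with 50-list
backgrounds. Logistic fits use tolerance 1e-6 by default (1e-10 where exact
equality is asserted). All randomness flows from explicit integer seeds;
pipeline outputs are written with a fixed float format so reruns are
byte-identical.

## Known limitations

- The DE stand-in has lower power than count-model engines at n = 2–3
  replicates; supplying externally derived lists is the expected path for
  real perturbation data.
- Specimens are treated as independent samples; repeated specimens per donor
  are not modeled.
- The empirical null resolution is bounded by `n_background`; p-values below
  1/(n_background+1) are not distinguishable.
- Brown's method with a Jaccard dependence proxy is an approximation; the
  mapping is isolated in one function so alternatives can be swapped.
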