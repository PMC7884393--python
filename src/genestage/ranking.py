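"""Empirical significance of gene lists and the drug ranking.

A gene list's LPOCV AUC means little on its own: in brain expression data
many random gene lists predict disease stage weakly but reliably.  A list is
therefore compared against a background of random lists of the same length
drawn uniformly from the protein-coding space, yielding a one-sided
empirical p-value — the fraction of random lists that outperform it.
Per-(dataset, region) p-values for the same list are combined with the
harmonic mean p-value (HMP), which tolerates dependence between the
component tests; drugs profiled in several experiments have their HMPs
merged by geometric mean, and the final screen output is the ascending
ranking by merged HMP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .cohort import BinaryTask, StagedCohort, build_binary_task
from .lpocv import AucEstimate, PredictorSpec, build_age_matched_pairs, lpocv_auc
from .signatures import GeneList

log = logging.getLogger(__name__)

DEFAULT_N_BACKGROUND = 1000


@dataclass
class BackgroundDistribution:
    """Null AUCs of ``n_lists`` random gene lists of one fixed length."""

    list_length: int
    aucs: np.ndarray
    seed: int

    @property
    def n_lists(self) -> int:
        return len(self.aucs)


@dataclass
class ListEvaluation:
    """One (gene list, dataset/region, task) evaluation with its empirical p."""

    gene_list_name: str
    experiment_id: str | None
    dataset_id: str
    region_id: str
    task: str
    auc: AucEstimate
    empirical_p: float


def sample_background(
    length: int,
    universe: list[str],
    n_lists: int = DEFAULT_N_BACKGROUND,
    seed: int = 0,
) -> list[GeneList]:
    """Draw ``n_lists`` random lists of ``length`` distinct genes from ``universe``.

    Sampling is uniform without replacement and reproducible under ``seed``
    (the universe is sorted internally so the draw ignores input order).
    """
    uni = sorted(set(universe))
    if length > len(uni):
        raise ValueError(f"list length {length} exceeds universe size {len(uni)}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_lists):
        genes = list(rng.choice(uni, size=length, replace=False))
        out.append(GeneList(f"null_{length}_{i}", genes, source="supplied"))
    return out


def empirical_p(target_auc: float, background: BackgroundDistribution) -> float:
    """Fraction of background lists strictly outperforming the target AUC.

    An exact zero is clamped to 1/(n_lists + 1): the resolution of the null
    is bounded by its size, and downstream HMP is undefined at 0.
    """
    n = background.n_lists
    if n == 0:
        raise ValueError("background distribution is empty")
    p = float(np.sum(background.aucs > target_auc)) / n
    return max(p, 1.0 / (n + 1))


def combine_hmp(ps) -> float:
    """Unweighted harmonic mean p-value: k / sum(1/p_i)."""
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(len(ps) / np.sum(1.0 / ps))


# ---------------------------------------------------------------------------
# Evaluation driver
# ---------------------------------------------------------------------------

def evaluate_lists(
    cohorts: list[StagedCohort],
    gene_lists: list[GeneList],
    *,
    lo: str = "A",
    hi: str = "C",
    n_background: int = DEFAULT_N_BACKGROUND,
    seed: int = 0,
    spec: PredictorSpec = PredictorSpec(),
) -> list[ListEvaluation]:
    """Score every gene list on every cohort against length-matched nulls.

    Background null AUC vectors are computed per (cohort, task, list length)
    and cached, so drugs whose lists share a length reuse one null.  Empty
    lists and lists with no genes present in a cohort are skipped.
    """
    evaluations: list[ListEvaluation] = []
    for cohort in cohorts:
        task = build_binary_task(cohort, lo, hi)
        pairs = build_age_matched_pairs(task, seed)
        universe = list(cohort.genes)
        cache: dict[int, BackgroundDistribution] = {}
        for gl in gene_lists:
            if gl.is_empty:
                log.warning("list %r is empty; skipped on %s", gl.name, cohort.label())
                continue
            est = lpocv_auc(task, gl, spec=spec, seed=seed, pairs=pairs)
            if est is None:
                continue
            length = len([g for g in gl.genes if g in cohort.expr.index])
            bg = cache.get(length)
            if bg is None:
                bg = _background_aucs(task, pairs, universe, length, n_background, seed, spec)
                cache[length] = bg
                log.info(
                    "background cache: %s task %s length %d -> %d null AUCs",
                    cohort.label(),
                    task.name,
                    length,
                    bg.n_lists,
                )
            p = empirical_p(est.auc, bg)
            evaluations.append(
                ListEvaluation(
                    gene_list_name=gl.name,
                    experiment_id=gl.experiment_id,
                    dataset_id=cohort.dataset_id,
                    region_id=cohort.region_id,
                    task=task.name,
                    auc=est,
                    empirical_p=p,
                )
            )
    return evaluations


def _background_aucs(
    task: BinaryTask,
    pairs,
    universe: list[str],
    length: int,
    n_lists: int,
    seed: int,
    spec: PredictorSpec,
) -> BackgroundDistribution:
    nulls = sample_background(length, universe, n_lists=n_lists, seed=seed)
    aucs = np.array([lpocv_auc(task, gl, spec=spec, seed=seed, pairs=pairs).auc for gl in nulls])
    return BackgroundDistribution(list_length=length, aucs=aucs, seed=seed)


def evaluations_to_frame(evaluations: list[ListEvaluation]) -> pd.DataFrame:
    """Flatten evaluations into a tidy table (one row per list x cohort x task)."""
    rows = [
        {
            "gene_list": e.gene_list_name,
            "experiment": e.experiment_id if e.experiment_id is not None else "",
            "dataset": e.dataset_id,
            "region": e.region_id,
            "task": e.task,
            "auc": e.auc.auc,
            "n_pairs": e.auc.n_pairs,
            "empirical_p": e.empirical_p,
        }
        for e in evaluations
    ]
    return pd.DataFrame(rows)


def rank_drugs(evaluations: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-evaluation p-values into the final drug ranking.

    Per (gene_list, experiment): HMP over its evaluations across datasets
    and regions.  Per gene_list: geometric mean of the per-experiment HMPs
    (a drug profiled once keeps its single HMP).  Output sorted ascending by
    merged HMP, ties broken lexicographically; rank is 1-based.
    """
    if evaluations.empty:
        raise ValueError("no evaluations to rank")
    per_exp = (
        evaluations.groupby(["gene_list", "experiment"], sort=True)["empirical_p"]
        .apply(lambda ps: combine_hmp(ps.to_numpy()))
        .rename("hmp")
        .reset_index()
    )
    merged = (
        per_exp.groupby("gene_list", sort=True)["hmp"]
        .apply(lambda h: float(gmean(h)))
        .rename("merged_hmp")
        .reset_index()
    )
    merged = merged.sort_values(["merged_hmp", "gene_list"], kind="mergesort").reset_index(drop=True)
    merged["rank"] = np.arange(1, len(merged) + 1)
    return merged.merge(per_exp, on="gene_list", how="left")[
        ["gene_list", "experiment", "hmp", "merged_hmp", "rank"]
    ]
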