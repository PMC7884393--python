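"""Age-matched leave-pair-out cross-validation (LPOCV) of stage predictors.

Given a binary stage task and a gene list, a ridge-regularized logistic
regression is restricted to the listed genes and evaluated by LPOCV: every
sample is paired with its closest age match from the opposite class, and for
each pair the model is re-fit on all remaining samples and asked whether it
assigns the later-stage member a higher score.  The fraction of correctly
ranked pairs estimates the area under the ROC curve, and is the quantity
that gene lists are scored on.

Age matching controls for the strong confounding between age and Braak
stage in postmortem cohorts; ridge (L2) rather than lasso regularization is
used because the gene list is a deliberate feature pre-selection and no
feature may be dropped.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .cohort import BinaryTask
from .signatures import GeneList

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictorSpec:
    """Ridge-logistic model settings.

    ``regularization_strength`` is the L2 penalty weight on standardized
    features (sklearn's ``C`` is its reciprocal).  ``standardize`` z-scores
    features with training-fold statistics only; constant columns map to 0.
    """

    regularization_strength: float = 1.0
    standardize: bool = True
    max_iter: int = 1000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.regularization_strength > 0:
            raise ValueError("regularization_strength must be > 0")


@dataclass
class AgeMatchedPairs:
    """Deduplicated (lo_sample, hi_sample) index pairs from nearest-age matching."""

    pairs: list[tuple[int, int]]
    seed: int

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AucEstimate:
    """LPOCV pair-ranking AUC: ``auc = correctly_ranked / n_pairs`` (ties = 1/2)."""

    auc: float
    n_pairs: int
    correctly_ranked: float


def _anchor_rng(seed: int, sample_id: str) -> np.random.Generator:
    # keyed per anchor sample so tie resolution ignores sample order
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode())])


def build_age_matched_pairs(task: BinaryTask, seed: int = 0) -> AgeMatchedPairs:
    """Pair every task sample with its nearest-age opposite-class sample.

    Ties are resolved uniformly at random, deterministically under ``seed``
    (and independent of sample ordering).  A pair discovered from both of
    its members is kept once.
    """
    ages = task.ages.to_numpy(dtype=float)
    ids = np.asarray(task.sample_ids, dtype=object)
    labels = task.labels
    lo_idx = np.flatnonzero(labels == 0)
    hi_idx = np.flatnonzero(labels == 1)

    pairs: set[tuple[int, int]] = set()
    for anchor in range(len(labels)):
        candidates = hi_idx if labels[anchor] == 0 else lo_idx
        gaps = np.abs(ages[candidates] - ages[anchor])
        best = candidates[gaps == gaps.min()]
        if len(best) > 1:
            # sort candidates by sample id so the draw is order-invariant
            best = best[np.argsort(ids[best].astype(str))]
            partner = int(_anchor_rng(seed, str(ids[anchor])).choice(best))
        else:
            partner = int(best[0])
        pair = (anchor, partner) if labels[anchor] == 0 else (partner, anchor)
        pairs.add(pair)
    ordered = sorted(pairs)
    log.debug("age matching: %d samples -> %d unique pairs", len(labels), len(ordered))
    return AgeMatchedPairs(ordered, seed)


def _standardize(train: np.ndarray, other: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    zt = (train - mu) / sd_safe
    zo = (other - mu) / sd_safe
    # constant training columns carry no information: force them to zero
    const = sd == 0
    if const.any():
        zt[:, const] = 0.0
        zo[:, const] = 0.0
    return zt, zo


def fit_predictor(X: np.ndarray, y: np.ndarray, spec: PredictorSpec = PredictorSpec()):
    """Fit the ridge-logistic model; returns ``scorer(Xnew) -> scores``.

    Scores are monotone in the predicted probability of the later-stage
    class.  All supplied features enter the model (no sparsity).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with >= 1 feature")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")

    if spec.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        const = sd == 0
        Xz = (X - mu) / sd_safe
        if const.any():
            Xz[:, const] = 0.0
    else:
        mu = np.zeros(X.shape[1])
        sd_safe = np.ones(X.shape[1])
        const = np.zeros(X.shape[1], dtype=bool)
        Xz = X

    model = LogisticRegression(
        C=1.0 / spec.regularization_strength,
        solver="lbfgs",
        max_iter=spec.max_iter,
        tol=spec.tol,
    )
    model.fit(Xz, y)

    def scorer(Xnew: np.ndarray) -> np.ndarray:
        Z = (np.asarray(Xnew, dtype=float) - mu) / sd_safe
        if const.any():
            Z[:, const] = 0.0
        return model.decision_function(Z)

    return scorer


def lpocv_auc(
    task: BinaryTask,
    gene_list: GeneList,
    spec: PredictorSpec = PredictorSpec(),
    seed: int = 0,
    pairs: AgeMatchedPairs | None = None,
) -> AucEstimate | None:
    """Leave-pair-out AUC of the gene list's stage predictor on ``task``.

    For each age-matched pair, the model is trained on every task sample
    except the two withheld members (even if those members appear in other
    pairs) and the pair counts as correct iff the later-stage member scores
    strictly higher; ties contribute 1/2.  Genes absent from the cohort are
    dropped with a warning; a list with no genes left returns ``None``
    (evaluation skipped).

    ``pairs`` allows reusing a precomputed pairing across many lists.
    """
    present = [g for g in gene_list.genes if g in task.cohort.expr.index]
    if len(present) < len(gene_list.genes):
        log.warning(
            "gene list %r: %d of %d genes absent from cohort",
            gene_list.name,
            len(gene_list.genes) - len(present),
            len(gene_list.genes),
        )
    if not present:
        log.warning("gene list %r has no genes in the cohort; evaluation skipped", gene_list.name)
        return None

    if pairs is None:
        pairs = build_age_matched_pairs(task, seed)
    X = task.expression(present)
    y = task.labels
    n = X.shape[0]

    correct = 0.0
    for lo, hi in pairs.pairs:
        mask = np.ones(n, dtype=bool)
        mask[[lo, hi]] = False
        if len(np.unique(y[mask])) < 2:  # degenerate fold; should not occur with >=2 per class
            correct += 0.5
            continue
        if spec.standardize:
            Xtr, Xte = _standardize(X[mask], X[[lo, hi]])
        else:
            Xtr, Xte = X[mask], X[[lo, hi]]
        model = LogisticRegression(
            C=1.0 / spec.regularization_strength,
            solver="lbfgs",
            max_iter=spec.max_iter,
            tol=spec.tol,
        )
        model.fit(Xtr, y[mask])
        s_lo, s_hi = model.decision_function(Xte)
        if s_hi > s_lo:
            correct += 1.0
        elif s_hi == s_lo:
            correct += 0.5
    n_pairs = len(pairs)
    return AucEstimate(auc=correct / n_pairs, n_pairs=n_pairs, correctly_ranked=correct)
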