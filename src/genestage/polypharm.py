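"""Polypharmacology pair tests and per-target aggregation.

For a pair of targets (A, B), compounds with known TAS for both are split
into three base categories — binds both ("A AND B"), binds A but not B,
binds B but not A — plus the union "A XOR B" of the latter two ("binds"
means TAS 1/2/3, "not" means TAS 10).  One-sided Wilcoxon rank-sum tests
ask whether the joint binders sit closer to the top of the drug ranking
than each comparison set; the three p-values are averaged with the harmonic
mean.  Per target, the pair-level harmonic means are combined with Brown's
method (a covariance-aware extension of Fisher's method), where dependence
between two pair tests is proxied by the Jaccard similarity of their joint
binder compound sets, followed by Benjamini-Hochberg adjustment across
targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ranking import combine_hmp
from .tas import TAS_BINDER, TAS_NONBINDER, tas_lookup

log = logging.getLogger(__name__)

DEFAULT_MIN_COMPOUNDS = 6
DEFAULT_ALPHA = 0.05
#: Kost-McDermott cubic mapping from inter-test correlation to the
#: covariance of the -2 ln p Fisher terms; Jaccard similarity stands in for
#: the correlation.
_BROWN_COV_COEF = (3.263, 0.710, 0.027)


def jaccard(set_x, set_y) -> float:
    """|x n y| / |x u y|; requires at least one nonempty set."""
    x, y = set(set_x), set(set_y)
    union = x | y
    if not union:
        raise ValueError("Jaccard similarity of two empty sets is undefined")
    return len(x & y) / len(union)


@dataclass
class PairCategories:
    """Compound categories for one target pair (disjoint base sets)."""

    target_a: str
    target_b: str
    set_ab: frozenset[str]
    set_a_not_b: frozenset[str]
    set_b_not_a: frozenset[str]

    @property
    def set_xor(self) -> frozenset[str]:
        return self.set_a_not_b | self.set_b_not_a


@dataclass
class TargetPairResult:
    """Rank-test outcome for one target pair.

    ``p_values`` maps comparison name (vs_a_not_b / vs_b_not_a / vs_xor) to
    the smaller of the two one-sided rank-sum p-values; ``sides`` records
    which side won (+1: joint binders closer to the top, -1: further down).
    """

    target_a: str
    target_b: str
    categories: PairCategories
    p_values: dict[str, float]
    sides: dict[str, int]
    pair_hmp: float
    direction: str


def build_pair_categories(
    tas_table: pd.DataFrame,
    target_a: str,
    target_b: str,
    min_compounds: int = DEFAULT_MIN_COMPOUNDS,
) -> PairCategories | None:
    """Categorize compounds for a target pair; ``None`` if the pair is ineligible.

    Eligibility requires at least ``min_compounds`` compounds with known TAS
    for both targets, a nonempty joint-binder set, and a nonempty XOR set.
    Compounds with unknown TAS for either target are excluded throughout.
    """
    lut_a = tas_lookup(tas_table, target_a)
    lut_b = tas_lookup(tas_table, target_b)
    both_known = sorted(set(lut_a) & set(lut_b))
    if len(both_known) < min_compounds:
        return None

    def binds(t: int) -> bool:
        return t in TAS_BINDER

    ab, a_not_b, b_not_a = set(), set(), set()
    for d in both_known:
        ba, bb = binds(lut_a[d]), binds(lut_b[d])
        if ba and bb:
            ab.add(d)
        elif ba and lut_b[d] == TAS_NONBINDER:
            a_not_b.add(d)
        elif bb and lut_a[d] == TAS_NONBINDER:
            b_not_a.add(d)
    cats = PairCategories(target_a, target_b, frozenset(ab), frozenset(a_not_b), frozenset(b_not_a))
    if not cats.set_ab or not cats.set_xor:
        return None
    return cats


def _one_sided_ranksum(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Smaller one-sided rank-sum p for positions x vs y, with winning side.

    Side +1 means x stochastically smaller (closer to the top of a
    best-first ranking).  Exact enumeration when both sets have <= 10
    members, normal approximation with tie correction otherwise.
    """
    method = "exact" if (len(x) <= 10 and len(y) <= 10) else "asymptotic"
    p_less = stats.mannwhitneyu(x, y, alternative="less", method=method).pvalue
    p_greater = stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    if p_less <= p_greater:
        return float(p_less), +1
    return float(p_greater), -1


def pair_rank_tests(
    ranking: list[str],
    categories: PairCategories,
    alpha: float = DEFAULT_ALPHA,
) -> TargetPairResult:
    """Compare joint binders' ranking positions against each comparison set.

    Direction is the consensus of the significant comparisons: since the
    reported p is the smaller of two one-sided tests, a comparison votes
    when its two-sided equivalent clears alpha (2 * p <= alpha), keeping
    the null rate of non-neutral calls at ~alpha.  Positive means joint
    binders sit significantly closer to the top, negative the opposite,
    neutral otherwise or on a tie.  ``pair_hmp`` is the harmonic mean of
    the per-comparison p-values over the comparisons that could be run.
    """
    position = {d: i + 1 for i, d in enumerate(ranking)}
    missing = categories.set_ab - position.keys()
    if missing:
        raise ValueError(f"joint binders absent from ranking: {sorted(missing)}")

    pos_ab = np.array([position[d] for d in sorted(categories.set_ab)], dtype=float)
    comparisons = {
        "vs_a_not_b": categories.set_a_not_b,
        "vs_b_not_a": categories.set_b_not_a,
        "vs_xor": categories.set_xor,
    }
    p_values: dict[str, float] = {}
    sides: dict[str, int] = {}
    for name, members in comparisons.items():
        members = [d for d in sorted(members) if d in position]
        if not members:
            continue
        pos_other = np.array([position[d] for d in members], dtype=float)
        p, side = _one_sided_ranksum(pos_ab, pos_other)
        p_values[name] = p
        sides[name] = side
    if not p_values:
        raise ValueError("no comparison set available for this pair")

    votes = [sides[k] for k, p in p_values.items() if 2 * p <= alpha]
    score = sum(votes)
    direction = "positive" if score > 0 else "negative" if score < 0 else "neutral"
    return TargetPairResult(
        target_a=categories.target_a,
        target_b=categories.target_b,
        categories=categories,
        p_values=p_values,
        sides=sides,
        pair_hmp=combine_hmp(list(p_values.values())),
        direction=direction,
    )


def evaluate_all_pairs(
    ranking: list[str],
    tas_table: pd.DataFrame,
    min_compounds: int = DEFAULT_MIN_COMPOUNDS,
    alpha: float = DEFAULT_ALPHA,
) -> list[TargetPairResult]:
    """Run the pair test for every eligible target pair in the TAS table.

    TAS entries for drugs absent from the ranking (e.g. never profiled, or
    with no scoreable gene list) are ignored.
    """
    ranked = set(ranking)
    dropped = set(tas_table["drug"]) - ranked
    if dropped:
        log.info("ignoring TAS entries for %d unranked drug(s)", len(dropped))
        tas_table = tas_table[tas_table["drug"].isin(ranked)]
    targets = sorted(tas_table["target"].unique())
    results = []
    for a, b in combinations(targets, 2):
        cats = build_pair_categories(tas_table, a, b, min_compounds=min_compounds)
        if cats is None:
            continue
        results.append(pair_rank_tests(ranking, cats, alpha=alpha))
    log.info("polypharmacology: %d eligible pairs among %d targets", len(results), len(targets))
    return results


# ---------------------------------------------------------------------------
# Brown's method with Jaccard dependence
# ---------------------------------------------------------------------------

def _fisher_term_cov(j: float) -> float:
    a, b, c = _BROWN_COV_COEF
    return a * j + b * j * j + c * j ** 3


def brown_combine(ps, jaccard_matrix: np.ndarray) -> float:
    """Combine dependent p-values with Brown's scaled-chi-square method.

    ``jaccard_matrix[i, j]`` is the dependence proxy between tests i and j
    (0 = independent, 1 = identical).  With all zeros this reduces exactly
    to Fisher's method; a single p-value is returned unchanged.
    """
    ps = np.asarray(ps, dtype=float)
    if np.any(ps <= 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    k = len(ps)
    psi = -2.0 * np.sum(np.log(ps))
    expected = 2.0 * k
    var = 4.0 * k
    for i in range(k):
        for j in range(i + 1, k):
            var += 2.0 * _fisher_term_cov(float(jaccard_matrix[i, j]))
    c = var / (2.0 * expected)
    df = 2.0 * expected ** 2 / var
    return float(stats.chi2.sf(psi / c, df))


def aggregate_by_target(
    pair_results: list[TargetPairResult],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-target Brown aggregation of pair p-values, BH-adjusted across targets.

    Each pair is represented by its joint-binder compound set for the
    Jaccard dependence proxy.  Direction is the majority direction among
    the target's nominally significant pairs (pair_hmp < alpha), neutral
    when there are none or on a tie.
    """
    if not pair_results:
        return pd.DataFrame(columns=["target", "direction", "n_pairs", "p", "p_adj"])
    by_target: dict[str, list[TargetPairResult]] = {}
    for res in pair_results:
        by_target.setdefault(res.target_a, []).append(res)
        by_target.setdefault(res.target_b, []).append(res)

    rows = []
    for target in sorted(by_target):
        results = by_target[target]
        ps = [r.pair_hmp for r in results]
        sets = [r.categories.set_ab for r in results]
        k = len(ps)
        jac = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                jac[i, j] = jac[j, i] = jaccard(sets[i], sets[j])
        brown_p = brown_combine(ps, jac)
        sig = [r.direction for r in results if r.pair_hmp < alpha and r.direction != "neutral"]
        pos, neg = sig.count("positive"), sig.count("negative")
        direction = "positive" if pos > neg else "negative" if neg > pos else "neutral"
        rows.append({"target": target, "direction": direction, "n_pairs": k, "p": brown_p})

    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df.sort_values(["p", "target"], kind="mergesort").reset_index(drop=True)


def pair_results_to_frame(pair_results: list[TargetPairResult]) -> pd.DataFrame:
    """Tidy per-pair table (category sizes, three p-values, HMP, direction)."""
    rows = []
    for r in pair_results:
        rows.append(
            {
                "target_a": r.target_a,
                "target_b": r.target_b,
                "n_ab": len(r.categories.set_ab),
                "n_a_not_b": len(r.categories.set_a_not_b),
                "n_b_not_a": len(r.categories.set_b_not_a),
                "p_vs_a_not_b": r.p_values.get("vs_a_not_b", float("nan")),
                "p_vs_b_not_a": r.p_values.get("vs_b_not_a", float("nan")),
                "p_vs_xor": r.p_values.get("vs_xor", float("nan")),
                "pair_hmp": r.pair_hmp,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "target_a",
            "target_b",
            "n_ab",
            "n_a_not_b",
            "n_b_not_a",
            "p_vs_a_not_b",
            "p_vs_b_not_a",
            "p_vs_xor",
            "pair_hmp",
            "direction",
        ],
    )
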