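"""Target Affinity Spectrum (TAS) scores and target-ranking association tests.

A TAS score summarizes heterogeneous drug-target binding evidence as a
single integer: 1, 2, or 3 for confirmed binders (lower = stronger binding)
and 10 for confirmed non-binders.  Absent evidence stays "unknown" — a
missing entry, not a score.  Three evidence kinds are supported, in strict
precedence order:

1. dose-response affinities (Kd/Ki-style values in nM),
2. single-dose percent measurements at fixed assay concentrations,
3. literature assertions (confirming / negative statements).

Within one drug-target pair, repeated measurements of the same kind are
aggregated by the first quartile before conversion.  The conversion bands:

===============  ==========================================
dose-response    <100 nM -> 1; 100-999 nM -> 2;
                 1-10 uM -> 3; >10 uM -> 10
single dose      100 nM: <25% -> 2, >=75% -> 10
                 1 uM:   <1%  -> 2, >=90% -> 10
                 10 uM:  <0.1% -> 2, >=75% -> 10
literature       confirming -> 2; negative -> 10
===============  ==========================================

Single-dose values falling between a concentration's two cutoffs are
undecided (unknown).  The module also tests whether binding affinity to a
target tracks a drug ranking, via per-TAS ECDF areas and a one-sided
fraction-of-concordant-pairs Kendall statistic with a permutation p-value.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TAS_BINDER = (1, 2, 3)
TAS_NONBINDER = 10
VALID_TAS = (1, 2, 3, 10)

#: Single-dose cutoffs per assay concentration (nM):
#: value < lo -> TAS 2, value >= hi -> TAS 10, otherwise undecided.
SINGLE_DOSE_CUTOFFS: dict[float, tuple[float, float]] = {
    100.0: (25.0, 75.0),
    1000.0: (1.0, 90.0),
    10000.0: (0.1, 75.0),
}

EVIDENCE_PRECEDENCE = ("dose_response", "single_dose", "literature")

BINDING_COLUMNS = ("drug", "target", "evidence_kind", "affinity_nM", "assay_conc_nM", "percent", "assertion")


def aggregate_first_quartile(values) -> float:
    """First quartile with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty measurement vector")
    return float(np.quantile(values, 0.25))


def tas_from_dose_response(affinity_nM: float) -> int:
    """Banded conversion of a dose-response affinity (nM) to a TAS score."""
    if not affinity_nM > 0:
        raise ValueError(f"affinity must be positive, got {affinity_nM!r}")
    if affinity_nM < 100:
        return 1
    if affinity_nM < 1000:
        return 2
    if affinity_nM <= 10000:
        return 3
    return 10


def tas_from_single_dose(conc_nM: float, percent: float) -> int | None:
    """Threshold lookup for a single-dose measurement; ``None`` if undecided.

    The measured quantity is a percent-of-control-style readout: values
    below the low cutoff indicate binding (TAS 2), values at or above the
    high cutoff indicate a non-binder (TAS 10).
    """
    cutoffs = SINGLE_DOSE_CUTOFFS.get(float(conc_nM))
    if cutoffs is None:
        raise ValueError(
            f"unsupported assay concentration {conc_nM!r} nM; expected one of {sorted(SINGLE_DOSE_CUTOFFS)}"
        )
    if not 0 <= percent <= 100:
        raise ValueError(f"percent must be in [0, 100], got {percent!r}")
    lo, hi = cutoffs
    if percent < lo:
        return 2
    if percent >= hi:
        return TAS_NONBINDER
    return None


def tas_from_literature(assertion: str) -> int:
    """Literature assertion to TAS: confirming -> 2, negative -> 10."""
    if assertion == "confirming":
        return 2
    if assertion == "negative":
        return TAS_NONBINDER
    raise ValueError(f"assertion must be 'confirming' or 'negative', got {assertion!r}")


def resolve_tas(records: pd.DataFrame) -> tuple[int, str] | None:
    """Resolve all binding records of one drug-target pair to (tas, evidence_kind).

    Per-kind aggregation first (first quartile of affinities; first quartile
    of percents within each assay concentration; any confirming assertion
    beats negatives), then the highest-precedence kind with a decided
    outcome wins: dose-response > single-dose > literature.  Returns
    ``None`` when no kind decides (unknown affinity).
    """
    by_kind = {k: g for k, g in records.groupby("evidence_kind")}
    unknown_kinds = set(by_kind) - set(EVIDENCE_PRECEDENCE)
    if unknown_kinds:
        raise ValueError(f"unknown evidence kind(s): {sorted(unknown_kinds)}")

    if "dose_response" in by_kind:
        q = aggregate_first_quartile(by_kind["dose_response"]["affinity_nM"])
        return tas_from_dose_response(q), "dose_response"

    if "single_dose" in by_kind:
        sd = by_kind["single_dose"]
        # lowest assay concentration with a decided outcome wins
        for conc, grp in sorted(sd.groupby("assay_conc_nM")):
            q = aggregate_first_quartile(grp["percent"])
            tas = tas_from_single_dose(conc, q)
            if tas is not None:
                return tas, "single_dose"

    if "literature" in by_kind:
        assertions = set(by_kind["literature"]["assertion"])
        for a in assertions:
            tas_from_literature(a)  # validate
        return (2, "literature") if "confirming" in assertions else (TAS_NONBINDER, "literature")

    return None


def build_tas_table(records: pd.DataFrame) -> pd.DataFrame:
    """Resolve a full binding-record table into a TAS table.

    Input columns: drug, target, evidence_kind, affinity_nM, assay_conc_nM,
    percent, assertion (unused fields empty/NaN).  Output: one row per
    drug-target pair with a decided TAS (drug, target, tas, evidence_kind);
    undecided pairs are omitted (unknown affinity).
    """
    missing = [c for c in ("drug", "target", "evidence_kind") if c not in records.columns]
    if missing:
        raise ValueError(f"binding records missing column(s): {missing}")
    rows = []
    for (drug, target), grp in records.groupby(["drug", "target"], sort=True):
        resolved = resolve_tas(grp)
        if resolved is None:
            continue
        tas, kind = resolved
        rows.append({"drug": drug, "target": target, "tas": tas, "evidence_kind": kind})
    return pd.DataFrame(rows, columns=["drug", "target", "tas", "evidence_kind"])


def read_binding_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def tas_lookup(tas_table: pd.DataFrame, target: str) -> dict[str, int]:
    """drug -> TAS mapping for one target (drugs with unknown TAS absent)."""
    sub = tas_table[tas_table["target"] == target]
    return dict(zip(sub["drug"], sub["tas"].astype(int)))


def combined_family_affinity(tas_values) -> int | None:
    """Strongest binding (minimum TAS) across a target family; None if all unknown."""
    known = [int(t) for t in tas_values if t is not None and not (isinstance(t, float) and math.isnan(t))]
    if not known:
        return None
    return min(known)


# ---------------------------------------------------------------------------
# Ranking association statistics
# ---------------------------------------------------------------------------

@dataclass
class TargetRankingTest:
    """Association between a drug ranking and one target's TAS values.

    ``tau`` is the fraction of concordant pairs among orderable pairs
    (drugs with unequal TAS); ``tau_classical = 2*tau - 1`` is the familiar
    Kendall tau-a restricted to orderable pairs.  ``p`` is a one-sided
    permutation p-value for enrichment of strong binders at the top.
    """

    target: str
    n_drugs: int
    n_binders: int
    tau: float
    tau_classical: float
    p: float
    ecdf_auc: dict[int, float]


def ecdf_auc(ranking: list[str], tas_table: pd.DataFrame, target: str, tas_value: int) -> float | None:
    """Area under the ECDF of member drugs' normalized positions in ``ranking``.

    ``ranking`` is best-first.  With member positions r_i (1-based) among n
    ranked drugs, the step-function area over [0, 1] is 1 - mean(r_i)/n:
    near 1 when members saturate the top of the ranking, near 0 when they
    sit at the bottom, 0.5 - 1/(2n) for uniform occupancy.
    """
    lookup = tas_lookup(tas_table, target)
    positions = [i + 1 for i, d in enumerate(ranking) if lookup.get(d) == tas_value]
    if not positions:
        return None
    n = len(ranking)
    return 1.0 - float(np.mean(positions)) / n


def _fraction_concordant(positions: np.ndarray, tas: np.ndarray) -> float | None:
    """Fraction of concordant pairs among orderable (unequal-TAS) pairs."""
    concordant = 0
    orderable = 0
    n = len(positions)
    for i in range(n):
        for j in range(i + 1, n):
            if tas[i] == tas[j]:
                continue
            orderable += 1
            # concordant: stronger binder (lower TAS) ranked closer to the top
            if (tas[i] < tas[j]) == (positions[i] < positions[j]):
                concordant += 1
    if orderable == 0:
        return None
    return concordant / orderable


def kendall_ranking_test(
    ranking: list[str],
    tas_table: pd.DataFrame,
    target: str,
    n_perm: int = 10_000,
    seed: int = 0,
    exact: bool = False,
    min_binders: int = 3,
) -> TargetRankingTest | None:
    """One-sided Kendall test of affinity-vs-ranking concordance for a target.

    Drugs with unknown TAS for the target are excluded; targets with fewer
    than ``min_binders`` confirmed binders (TAS 1/2/3) are not evaluated
    (returns ``None``), as are targets with no orderable pairs.  The
    p-value is the fraction of TAS-label permutations with tau >= observed;
    Monte Carlo sampling uses plus-one smoothing, ``exact=True`` enumerates
    all label permutations (small instances only).
    """
    lookup = tas_lookup(tas_table, target)
    positions, tas = [], []
    for i, d in enumerate(ranking):
        if d in lookup:
            positions.append(i + 1)
            tas.append(lookup[d])
    positions = np.asarray(positions)
    tas = np.asarray(tas)
    n_binders = int(np.isin(tas, TAS_BINDER).sum())
    if n_binders < min_binders:
        log.info("target %s has %d confirmed binders (<%d); not evaluated", target, n_binders, min_binders)
        return None

    observed = _fraction_concordant(positions, tas)
    if observed is None:
        return None

    if exact:
        taus = [
            _fraction_concordant(positions, np.asarray(perm))
            for perm in itertools.permutations(tas)
        ]
        p = float(np.mean([t >= observed for t in taus]))
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            t = _fraction_concordant(positions, rng.permutation(tas))
            if t >= observed:
                hits += 1
        p = (hits + 1) / (n_perm + 1)

    aucs = {
        v: a
        for v in VALID_TAS
        if (a := ecdf_auc(ranking, tas_table, target, v)) is not None
    }
    return TargetRankingTest(
        target=target,
        n_drugs=len(positions),
        n_binders=n_binders,
        tau=observed,
        tau_classical=2 * observed - 1,
        p=p,
        ecdf_auc=aucs,
    )


def evaluate_all_targets(
    ranking: list[str],
    tas_table: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the Kendall ranking test for every eligible target; tidy table out."""
    rows = []
    for target in sorted(tas_table["target"].unique()):
        res = kendall_ranking_test(ranking, tas_table, target, n_perm=n_perm, seed=seed)
        if res is None:
            continue
        row = {
            "target": res.target,
            "n_drugs": res.n_drugs,
            "n_binders": res.n_binders,
            "tau": res.tau,
            "tau_classical": res.tau_classical,
            "p": res.p,
        }
        for v in VALID_TAS:
            row[f"ecdf_auc_tas{v}"] = res.ecdf_auc.get(v, float("nan"))
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["p", "target"], kind="mergesort").reset_index(drop=True)
    return df
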