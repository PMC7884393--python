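"""TAS conversion rules, evidence precedence, ECDF areas, Kendall tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from genestage import (
    aggregate_first_quartile,
    build_tas_table,
    combined_family_affinity,
    ecdf_auc,
    kendall_ranking_test,
    resolve_tas,
    tas_from_dose_response,
    tas_from_literature,
    tas_from_single_dose,
)
from genestage.synth import generate_binding_table


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["drug", "target", "evidence_kind", "affinity_nM", "assay_conc_nM", "percent", "assertion"],
    )


def _dr(drug, target, affinity):
    return (drug, target, "dose_response", affinity, None, None, None)


def _sd(drug, target, conc, percent):
    return (drug, target, "single_dose", None, conc, percent, None)


def _lit(drug, target, assertion):
    return (drug, target, "literature", None, None, None, assertion)


class TestConversionRules:
    @pytest.mark.parametrize(
        "affinity,tas",
        [(50, 1), (99.9, 1), (100, 2), (500, 2), (999, 2), (1000, 3), (5000, 3), (10000, 3), (10001, 10), (20000, 10)],
    )
    def test_dose_response_bands(self, affinity, tas):
        assert tas_from_dose_response(affinity) == tas

    def test_dose_response_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tas_from_dose_response(0)

    @given(st.floats(0.1, 1e6), st.floats(0.1, 1e6))
    @settings(deadline=None)
    def test_dose_response_monotone(self, a, b):
        """Weaker binding (higher affinity value) never lowers the TAS score."""
        if a <= b:
            assert tas_from_dose_response(a) <= tas_from_dose_response(b)

    @pytest.mark.parametrize(
        "conc,percent,tas",
        [
            (100, 20, 2), (100, 24.9, 2), (100, 75, 10), (100, 90, 10), (100, 50, None),
            (1000, 0.5, 2), (1000, 90, 10), (1000, 95, 10), (1000, 50, None),
            (10000, 0.05, 2), (10000, 75, 10), (10000, 1, None),
        ],
    )
    def test_single_dose_thresholds(self, conc, percent, tas):
        assert tas_from_single_dose(conc, percent) == tas

    def test_single_dose_rejects_unknown_concentration(self):
        with pytest.raises(ValueError, match="concentration"):
            tas_from_single_dose(500, 50)

    def test_literature_assertions(self):
        assert tas_from_literature("confirming") == 2
        assert tas_from_literature("negative") == 10
        with pytest.raises(ValueError):
            tas_from_literature("maybe")


class TestAggregationAndPrecedence:
    def test_first_quartile_convention(self):
        assert aggregate_first_quartile([10, 10, 10]) == 10
        assert aggregate_first_quartile([250]) == 250
        assert aggregate_first_quartile([1, 2, 3, 4]) == pytest.approx(1.75)

    def test_dose_response_beats_literature(self):
        recs = _records([_dr("d", "t", 50), _lit("d", "t", "negative")])
        assert resolve_tas(recs) == (1, "dose_response")

    def test_single_dose_beats_literature(self):
        recs = _records([_sd("d", "t", 100, 10), _lit("d", "t", "negative")])
        assert resolve_tas(recs) == (2, "single_dose")

    def test_literature_alone(self):
        assert resolve_tas(_records([_lit("d", "t", "confirming")])) == (2, "literature")

    def test_undecided_single_dose_falls_through(self):
        """An unassigned-band single-dose value propagates unknown or defers."""
        assert resolve_tas(_records([_sd("d", "t", 1000, 50)])) is None
        recs = _records([_sd("d", "t", 1000, 50), _lit("d", "t", "negative")])
        assert resolve_tas(recs) == (10, "literature")

    def test_lowest_decided_concentration_wins(self):
        recs = _records([_sd("d", "t", 100, 50), _sd("d", "t", 1000, 95)])
        assert resolve_tas(recs) == (10, "single_dose")  # 100 nM undecided, 1 uM decides

    def test_quartile_aggregation_before_conversion(self):
        # affinities {50, 200, 200, 200}: Q1 = 162.5 -> TAS 2 even though one value is < 100
        recs = _records([_dr("d", "t", a) for a in (50, 200, 200, 200)])
        assert resolve_tas(recs) == (2, "dose_response")

    def test_resolution_order_invariant(self):
        rows = [_dr("d", "t", 5000), _sd("d", "t", 100, 10), _lit("d", "t", "confirming")]
        for perm in itertools.permutations(rows):
            assert resolve_tas(_records(list(perm))) == (3, "dose_response")

    def test_build_tas_table_omits_unknown(self):
        recs = _records([_dr("a", "t1", 50), _sd("b", "t1", 1000, 50)])
        table = build_tas_table(recs)
        assert len(table) == 1
        assert table.iloc[0].tolist() == ["a", "t1", 1, "dose_response"]


def test_combined_family_affinity():
    assert combined_family_affinity([2, 3, 10]) == 2
    assert combined_family_affinity([10, 10]) == 10
    assert combined_family_affinity([None, None]) is None
    assert combined_family_affinity([None, 3]) == 3


class TestEcdfAuc:
    def _table(self, members, tas=1, target="T"):
        return pd.DataFrame({"drug": members, "target": target, "tas": tas, "evidence_kind": "x"})

    def test_top_k_members(self):
        n, k = 40, 4
        ranking = [f"d{i}" for i in range(n)]
        auc = ecdf_auc(ranking, self._table(ranking[:k]), "T", 1)
        assert auc == pytest.approx(1 - (k + 1) / (2 * n))

    def test_bottom_k_members_symmetric(self):
        n, k = 40, 4
        ranking = [f"d{i}" for i in range(n)]
        auc_top = ecdf_auc(ranking, self._table(ranking[:k]), "T", 1)
        auc_bot = ecdf_auc(ranking, self._table(ranking[-k:]), "T", 1)
        # reversal symmetry holds up to the step-grid asymmetry of 1/n
        assert abs(auc_top + auc_bot - 1.0) <= 1 / n + 1e-12
        assert auc_bot == pytest.approx((k - 1) / (2 * n))

    def test_all_drugs_near_half(self):
        n = 25
        ranking = [f"d{i}" for i in range(n)]
        auc = ecdf_auc(ranking, self._table(ranking), "T", 1)
        assert abs(auc - 0.5) <= 1 / (2 * n) + 1e-12

    def test_invariant_to_nonmember_relabeling(self):
        ranking = [f"d{i}" for i in range(10)]
        table = self._table(["d2", "d5"])
        base = ecdf_auc(ranking, table, "T", 1)
        relabeled = ["x" + d if d not in ("d2", "d5") else d for d in ranking]
        assert ecdf_auc(relabeled, table, "T", 1) == base

    def test_empty_member_set(self):
        assert ecdf_auc(["d1"], self._table(["d1"]), "T", 3) is None


class TestKendall:
    def _table(self, mapping, target="T"):
        return pd.DataFrame(
            {"drug": list(mapping), "target": target, "tas": list(mapping.values()), "evidence_kind": "x"}
        )

    def test_perfectly_ordered_tau_one(self):
        """All TAS-1 drugs ranked before all TAS-3 drugs: every orderable pair concordant."""
        table = self._table({"a": 1, "b": 1, "c": 1, "d": 3, "e": 3})
        res = kendall_ranking_test(["a", "b", "c", "d", "e"], table, "T", n_perm=200, seed=0)
        assert res.tau == 1.0 and res.tau_classical == 1.0

    def test_anti_ordered_tau_zero(self):
        table = self._table({"a": 3, "b": 3, "c": 1, "d": 1, "e": 1})
        res = kendall_ranking_test(["a", "b", "c", "d", "e"], table, "T", n_perm=200, seed=0)
        assert res.tau == 0.0 and res.tau_classical == -1.0

    def test_transform_identity(self):
        table = self._table({"a": 1, "b": 2, "c": 3, "d": 10, "e": 2})
        res = kendall_ranking_test(["a", "b", "c", "d", "e"], table, "T", n_perm=100, seed=1)
        assert res.tau_classical == pytest.approx(2 * res.tau - 1)

    def test_fewer_than_three_binders_ineligible(self):
        table = self._table({"a": 1, "b": 2, "c": 10, "d": 10})
        assert kendall_ranking_test(["a", "b", "c", "d"], table, "T") is None

    def test_exact_matches_enumeration_oracle(self):
        """Exact permutation p equals brute-force enumeration over all 5! labelings."""
        ranking = ["a", "b", "c", "d", "e"]
        tas = {"a": 1, "b": 3, "c": 1, "d": 10, "e": 2}
        table = self._table(tas)
        res = kendall_ranking_test(ranking, table, "T", exact=True)

        # independent oracle: enumerate permutations, count fraction concordant
        positions = np.arange(1, 6)
        labels = np.array([tas[d] for d in ranking])

        def frac_concordant(lab):
            conc = order = 0
            for i in range(5):
                for j in range(i + 1, 5):
                    if lab[i] == lab[j]:
                        continue
                    order += 1
                    conc += (lab[i] < lab[j]) == (positions[i] < positions[j])
            return conc / order

        obs = frac_concordant(labels)
        taus = [frac_concordant(np.asarray(p)) for p in itertools.permutations(labels)]
        expect = np.mean([t >= obs for t in taus])
        assert res.p == pytest.approx(expect)

    def test_permutation_p_uniform_under_null(self):
        """Monte-Carlo p-values are ~uniform when TAS labels carry no signal."""
        from scipy.stats import kstest

        rng = np.random.default_rng(4)
        ranking = [f"d{i}" for i in range(12)]
        ps = []
        for _ in range(50):
            tas_vals = rng.choice([1, 2, 3, 10], size=12, p=[0.3, 0.3, 0.2, 0.2])
            table = self._table(dict(zip(ranking, tas_vals)))
            res = kendall_ranking_test(ranking, table, "T", n_perm=500, seed=int(rng.integers(1 << 30)))
            if res is not None:
                ps.append(res.p)
        assert len(ps) >= 40
        assert kstest(ps, "uniform").statistic < 0.2


def test_generated_binding_table_resolves_to_truth():
    """TAS resolution on generated records reproduces the generator's truth table."""
    drugs = [f"d{i}" for i in range(12)]
    targets = [f"t{i}" for i in range(6)]
    records, truth = generate_binding_table(drugs, targets, density=0.8, seed=5)
    table = build_tas_table(records).sort_values(["drug", "target"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(
        table[["drug", "target", "tas"]], truth, check_dtype=False
    )


def test_generated_binding_table_density_one_saturates():
    records, truth = generate_binding_table(["a", "b"], ["x", "y"], density=1.0, seed=0)
    assert len(truth) == 4
    r2, t2 = generate_binding_table(["a", "b"], ["x", "y"], density=1.0, seed=0)
    pd.testing.assert_frame_equal(records, r2)
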