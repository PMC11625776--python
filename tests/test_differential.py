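"""Pair enumeration, BH adjustment, pairwise screening and selection rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urbanmicro.data import SampleMetadata
from urbanmicro.differential import (
    DifferentialResult,
    PairKey,
    bh_adjust,
    enumerate_pairs,
    most_differential,
    pair_mask,
    run_pairwise,
    select_top_k,
)
from urbanmicro.simulate import SimConfig, simulate_abundance

from conftest import make_table


def brute_force_bh(p):
    """Direct double-loop evaluation of the printed step-up formula."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(pos, m + 1)
        ]
        out[idx] = min(1.0, min(candidates))
    return out


class TestBhAdjust:
    def test_hand_evaluated_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.1, 0.9]), [0.015, 0.15, 0.9], atol=1e-12
        )

    def test_linear_ladder_collapses(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05]), [0.05] * 5, atol=1e-12
        )

    def test_single_p_identity(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2, abs=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(18)
        for _ in range(50):
            p = rng.random(int(rng.integers(2, 60)))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_rank_preserving_and_dominating(self, p):
        adj = bh_adjust(p)
        p = np.asarray(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        # order preserved up to ties
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)


def metadata_from_groups(groups):
    rows = []
    for (city, year), n in groups.items():
        for i in range(n):
            rows.append((f"{city}_{year}_{i}", city, year, 100))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "city", "year", "total_reads"]
    ).set_index("sample_id")
    return SampleMetadata(frame)


class TestEnumeratePairs:
    def test_three_groups(self):
        meta = metadata_from_groups({("A", "2016"): 2, ("B", "2016"): 2, ("B", "2017"): 3})
        assert len(enumerate_pairs(meta)) == 3

    def test_twenty_two_groups_give_231_pairs(self):
        """16 cities, six sampled in both years -> C(22, 2) comparisons."""
        groups = {(f"c{i}", "2016"): 2 for i in range(16)}
        groups.update({(f"c{i}", "2017"): 2 for i in range(6)})
        meta = metadata_from_groups(groups)
        assert len(enumerate_pairs(meta)) == 231

    def test_singleton_group_excluded(self):
        meta = metadata_from_groups({("A", "2016"): 3, ("B", "2016"): 1})
        assert enumerate_pairs(meta) == []

    def test_canonical_ordering(self):
        k1 = PairKey.make(("B", "2017"), ("A", "2016"))
        k2 = PairKey.make(("A", "2016"), ("B", "2017"))
        assert k1 == k2
        with pytest.raises(ValueError):
            PairKey.make(("A", "2016"), ("A", "2016"))


class TestPairMask:
    @pytest.fixture
    def setup(self):
        meta = metadata_from_groups({("A", "2016"): 2, ("B", "2016"): 2})
        table = make_table(np.array([[5, 0, 3, 0], [5, 0, 0, 0], [0, 0, 0, 0]]))
        table.sample_ids[:] = list(meta.frame.index)
        pair = PairKey.make(("A", "2016"), ("B", "2016"))
        return table, meta, pair

    def test_positive_in_both_included(self, setup):
        table, meta, pair = setup
        assert pair_mask(table, pair, "otu0", meta) is True

    def test_zero_in_one_group_excluded(self, setup):
        table, meta, pair = setup
        assert pair_mask(table, pair, "otu1", meta) is False

    def test_zero_in_both_excluded(self, setup):
        table, meta, pair = setup
        assert pair_mask(table, pair, "otu2", meta) is False


class TestRunPairwise:
    def test_planted_otus_recovered(self):
        planted = {j: ((("city01", "2016"),), np.log(4)) for j in range(5)}
        cfg = SimConfig(
            n_cities=2, samples_per_group=20, n_otus=50, model="NB",
            dispersion=0.5, planted=planted, seed=29,
        )
        table, meta, truth = simulate_abundance(cfg)
        result = run_pairwise(table, meta, models=("NB",))
        chosen = result.chosen_records()
        hits = set(chosen[chosen["adj_p"] <= 0.05]["unit"])
        assert set(truth.differential) <= hits

    def test_fdr_controlled_with_calibrated_pvalues(self):
        """With Poisson-calibrated p-values, BH keeps the FDR of calls at
        the nominal level (isolates the adjustment from small-sample Wald
        liberality of the NB fits)."""
        fdps = []
        for seed in range(100):
            planted = {j: ((("city01", "2016"),), np.log(4)) for j in range(5)}
            cfg = SimConfig(n_cities=2, samples_per_group=20, n_otus=50,
                            model="P", planted=planted, seed=50_000 + seed)
            table, meta, truth = simulate_abundance(cfg)
            result = run_pairwise(table, meta, models=("P",))
            chosen = result.chosen_records()
            calls = set(chosen[chosen["adj_p"] <= 0.05]["unit"])
            fdps.append(len(calls - set(truth.differential)) / max(len(calls), 1))
        fdps = np.asarray(fdps)
        assert fdps.mean() <= 0.05 + 3 * fdps.std(ddof=1) / np.sqrt(len(fdps))

    def test_effect_size_monotonicity(self):
        """A larger planted fold change never loses differential pairs."""
        prev_hits = -1
        for lfc in (0.0, np.log(2), np.log(4), np.log(16)):
            hits = 0
            for seed in range(3):
                planted = {0: ((("city01", "2016"),), lfc)} if lfc else {}
                cfg = SimConfig(n_cities=3, samples_per_group=12, n_otus=8,
                                model="NB", dispersion=0.3, planted=planted,
                                seed=60_000 + seed)
                table, meta, _ = simulate_abundance(cfg)
                result = run_pairwise(table, meta, models=("NB",))
                hits += result.differential_pair_count(alpha=0.05).get("otu0000", 0)
            assert hits >= prev_hits
            prev_hits = hits

    def test_pair_exclusion_rule(self):
        meta = metadata_from_groups({("A", "2016"): 3, ("B", "2016"): 3})
        counts = np.array([[4, 6, 3, 0, 0, 0], [4, 6, 3, 5, 2, 7]])
        table = make_table(counts)
        table.sample_ids[:] = list(meta.frame.index)
        result = run_pairwise(table, meta, models=("P",))
        assert set(result.records["unit"]) == {"otu1"}

    def test_adj_p_dominates_raw(self):
        cfg = SimConfig(n_cities=3, samples_per_group=6, n_otus=12, model="P", seed=31)
        table, meta, _ = simulate_abundance(cfg)
        result = run_pairwise(table, meta, models=("P", "NB"))
        ok = result.records["adj_p"].notna()
        assert (result.records.loc[ok, "adj_p"] >= result.records.loc[ok, "raw_p"] - 1e-12).all()
        assert result.records.loc[ok, "adj_p"].between(0, 1).all()

    def test_chosen_model_references_converged_record(self):
        cfg = SimConfig(n_cities=2, samples_per_group=8, n_otus=10, model="NB",
                        dispersion=0.4, seed=37)
        table, meta, _ = simulate_abundance(cfg)
        result = run_pairwise(table, meta, models=("P", "NB"))
        recs = result.records
        for (unit, pair), model in result.chosen_model.items():
            match = recs[
                (recs["unit"] == unit) & (recs["pair"] == pair) & (recs["model"] == model)
            ]
            assert len(match) == 1 and bool(match["converged"].iloc[0])


def result_from_table(rows):
    """Build a DifferentialResult from (unit, pair, model, adj_p, aic) rows."""
    records = pd.DataFrame(
        rows, columns=["unit", "pair", "model", "adj_p", "aic"]
    )
    records["raw_p"] = records["adj_p"]
    records["converged"] = True
    records["level"] = "otu"
    records["n_params"] = 3
    chosen = {
        (r["unit"], r["pair"]): r["model"]
        for _, r in records.sort_values("aic").drop_duplicates(["unit", "pair"]).iterrows()
    }
    return DifferentialResult(records=records, chosen_model=chosen)


PAIR1 = PairKey.make(("A", "2016"), ("B", "2016"))
PAIR2 = PairKey.make(("A", "2016"), ("C", "2016"))


class TestSelectTopK:
    def test_truncates_to_available(self):
        res = result_from_table(
            [("u1", PAIR1, "NB", 0.01, 10), ("u2", PAIR1, "NB", 0.2, 11),
             ("u3", PAIR1, "NB", 0.5, 9)]
        )
        per_pair, summary = select_top_k(res, "NB", k=5)
        assert per_pair[PAIR1] == ["u1", "u2", "u3"]
        assert summary["fraction_never_selected"] == 0.0

    def test_tie_broken_by_aic(self):
        res = result_from_table(
            [("u1", PAIR1, "NB", 0.05, 20), ("u2", PAIR1, "NB", 0.05, 10)]
        )
        per_pair, _ = select_top_k(res, "NB", k=1)
        assert per_pair[PAIR1] == ["u2"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(41)
        rows = [
            (f"u{i}", PAIR1, "NB", float(rng.random()), float(rng.random()))
            for i in range(20)
        ]
        res = result_from_table(rows)
        per_pair, _ = select_top_k(res, "NB", k=5)
        expected = [r[0] for r in sorted(rows, key=lambda r: (r[3], r[4], r[0]))[:5]]
        assert per_pair[PAIR1] == expected

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(43)
        rows = [
            (f"u{i}", PAIR1, "NB", float(rng.random()), float(rng.random()))
            for i in range(15)
        ]
        res1 = result_from_table(rows)
        res2 = result_from_table(rows[::-1])
        assert select_top_k(res1, "NB", k=4)[0] == select_top_k(res2, "NB", k=4)[0]


class TestMostDifferential:
    def _result_with_pair_counts(self, n_pairs, adj_p=0.01):
        rows = []
        for i in range(n_pairs):
            pair = PairKey.make(("A", "2016"), (f"B{i}", "2016"))
            rows.append(("u1", pair, "NB", adj_p, 10.0))
        return result_from_table(rows)

    def test_eleven_pairs_included(self):
        res = self._result_with_pair_counts(11)
        assert most_differential(res, min_pairs=11) == ["u1"]

    def test_ten_pairs_excluded(self):
        res = self._result_with_pair_counts(10)
        assert most_differential(res, min_pairs=11) == []

    def test_alpha_zero_empty(self):
        res = self._result_with_pair_counts(12, adj_p=0.01)
        assert most_differential(res, alpha=0.0, min_pairs=1) == []
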