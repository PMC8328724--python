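"""Paired fold changes and the 4-of-6 deregulation rule, against a brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from secretodep import (
    ConfigurationError,
    SimulationConfig,
    call_dep,
    classify_vector,
    exclude_control_dep,
    generate_dataset,
    paired_log2fc,
    partition_sets,
    summarize_dep,
)
from secretodep.dep_calling import DepPartition
from secretodep.errors import DesignError
from secretodep.preprocess import collapse_tech_reps, normalize_to_spike, run_funnel

from conftest import toy_design, toy_matrix


def oracle_call(values, threshold=1.0, min_qualifying=4):
    """Independent reimplementation: plain loops, no shared code path."""
    n_up = 0
    n_down = 0
    for v in values:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        if v >= threshold:
            n_up += 1
        if v <= -threshold:
            n_down += 1
    if n_up >= min_qualifying:
        return "up", n_up
    if n_down >= min_qualifying:
        return "down", n_down
    return "none", 0


class TestPairedLog2FC:
    def make(self, t0, tend):
        d = toy_design(n_animals=1, groups=(("LPS", "T50"),))
        q = toy_matrix([[t0, tend]], d.sample_ids, protein_ids=["P1"])
        return q, d

    def test_exact_ratio(self):
        q, d = self.make(10.0, 40.0)
        fc = paired_log2fc(q, d)
        assert fc.loc[0, "log2fc"] == pytest.approx(2.0)

    def test_missing_propagates(self):
        q, d = self.make(np.nan, 40.0)
        fc = paired_log2fc(q, d)
        assert np.isnan(fc.loc[0, "log2fc"])

    def test_pairing_invariance_under_per_animal_scaling(self):
        q1, d = self.make(10.0, 40.0)
        q2, _ = self.make(30.0, 120.0)
        fc1, fc2 = paired_log2fc(q1, d), paired_log2fc(q2, d)
        assert fc1.loc[0, "log2fc"] == pytest.approx(fc2.loc[0, "log2fc"])

    def test_zero_intensity_in_pair_rejected(self):
        q, d = self.make(0.0, 40.0)
        with pytest.raises(DesignError, match="zero intensity"):
            paired_log2fc(q, d)


class TestCallDep:
    def test_published_style_vector(self):
        # 5 of 6 above threshold; min over qualifying is the value nearest 1
        call = classify_vector([3.31, 1.02, 5.20, 2.5, 4.0, 0.5])
        assert call.direction == "up"
        assert call.n_qualifying == 5
        assert call.n_animals == 6
        assert call.log2fc_min == pytest.approx(1.02)
        assert call.log2fc_max == pytest.approx(5.20)
        assert call.log2fc_median == pytest.approx(3.31)

    def test_flat_vector_is_none(self):
        call = classify_vector([0.0] * 6)
        assert call.direction == "none"

    def test_nan_does_not_count_toward_quorum(self):
        call = classify_vector([1.5, 1.2, -1.3, 1.1, np.nan, 1.4])
        assert (call.direction, call.n_qualifying) == ("up", 4)

    def test_boundary_values_qualify(self):
        assert classify_vector([1.0] * 4 + [0.0] * 2).direction == "up"
        assert classify_vector([-1.0] * 4 + [0.0] * 2).direction == "down"
        assert classify_vector([0.999] * 6).direction == "none"

    def test_min_qualifying_above_group_size_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_vector([1.0] * 6, min_qualifying=7)
        fc = pd.DataFrame(
            {
                "protein_id": ["P1"] * 6,
                "group": ["LPS50"] * 6,
                "animal_id": [f"a{i}" for i in range(6)],
                "log2fc": [1.0] * 6,
            }
        )
        with pytest.raises(ConfigurationError):
            call_dep(fc, min_qualifying=7)

    def test_agrees_with_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(123)
        n_vectors = 10_000
        values = rng.normal(0.0, 1.5, size=(n_vectors, 6))
        values[rng.uniform(size=values.shape) < 0.15] = np.nan
        mismatches = 0
        for row in values:
            call = classify_vector(row)
            direction, n = oracle_call(list(row))
            if (call.direction, call.n_qualifying if call.direction != "none" else 0) != (
                direction,
                n,
            ):
                mismatches += 1
        assert mismatches == 0

    def test_oracle_agreement_on_all_sign_patterns(self):
        # exhaustive over {-1.5, 0, +1.5}^6: every up/down/none boundary
        from itertools import product

        for pattern in product([-1.5, 0.0, 1.5], repeat=6):
            call = classify_vector(list(pattern))
            direction, _ = oracle_call(list(pattern))
            assert call.direction == direction


class TestControlExclusion:
    @staticmethod
    def calls(rows, group):
        return pd.DataFrame(
            [
                {
                    "protein_id": p,
                    "group": group,
                    "direction": direction,
                    "n_qualifying": 4 if direction != "none" else 0,
                    "n_animals": 6,
                    "log2fc_median": np.nan,
                    "log2fc_min": np.nan,
                    "log2fc_max": np.nan,
                }
                for p, direction in rows
            ]
        )

    def test_control_dep_excluded_same_endpoint(self):
        lps = self.calls([("A", "up"), ("B", "up"), ("C", "none")], "LPS50")
        ct = self.calls([("A", "up"), ("C", "none")], "CT50")
        retained, excluded = exclude_control_dep(lps, ct)
        assert excluded == frozenset({"A"})
        assert set(retained["protein_id"]) == {"B", "C"}

    def test_control_down_also_excludes(self):
        lps = self.calls([("A", "up")], "LPS90")
        ct = self.calls([("A", "down")], "CT90")
        retained, excluded = exclude_control_dep(lps, ct)
        assert excluded == frozenset({"A"})
        assert len(retained) == 0

    def test_none_in_control_is_retained(self):
        lps = self.calls([("A", "up")], "LPS50")
        ct = self.calls([("A", "none")], "CT50")
        retained, excluded = exclude_control_dep(lps, ct)
        assert excluded == frozenset()
        assert list(retained["protein_id"]) == ["A"]

    def test_endpoint_mismatch_rejected(self):
        lps = self.calls([("A", "up")], "LPS50")
        ct = self.calls([("A", "up")], "CT90")
        with pytest.raises(DesignError):
            exclude_control_dep(lps, ct)


class TestPartition:
    def test_set_algebra(self):
        part = partition_sets({"A", "B", "C"}, {"B", "C", "D"})
        assert part.common_ids == frozenset({"B", "C"})
        assert part.t50_specific_ids == frozenset({"A"})
        assert part.t90_specific_ids == frozenset({"D"})

    def test_identical_lists_have_empty_specific_sets(self):
        part = partition_sets({"A", "B"}, {"A", "B"})
        assert part.t50_specific_ids == frozenset()
        assert part.t90_specific_ids == frozenset()

    def test_sizes_for_published_scale_lists(self):
        shared = [f"S{i}" for i in range(79)]
        t50 = shared + [f"A{i}" for i in range(140 - 79)]
        t90 = shared + [f"B{i}" for i in range(132 - 79)]
        part = partition_sets(t50, t90)
        assert len(part.common_ids) == 79
        assert len(part.t50_specific_ids) == 61
        assert len(part.t90_specific_ids) == 53

    def test_sets_are_disjoint_and_cover_union(self):
        part = partition_sets({"A", "B", "C"}, {"B", "D"})
        sets = [part.common_ids, part.t50_specific_ids, part.t90_specific_ids]
        assert sets[0] | sets[1] | sets[2] == frozenset("ABCD")
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])


class TestSummaries:
    def test_excluded_protein_never_reported(self):
        calls = TestControlExclusion.calls([("A", "up"), ("B", "up")], "LPS50")
        part = DepPartition(
            common_ids=frozenset({"A", "B"}),
            t50_specific_ids=frozenset(),
            t90_specific_ids=frozenset(),
            control_excluded_ids=frozenset({"A"}),
        )
        tables = summarize_dep(calls, part)
        assert set(tables["common_t50"]["protein_id"]) == {"B"}

    def test_empty_calls_give_empty_tables_with_header(self):
        calls = TestControlExclusion.calls([], "LPS50")
        calls = pd.DataFrame(columns=calls.columns if len(calls.columns) else [
            "protein_id", "group", "direction", "n_qualifying", "n_animals",
            "log2fc_median", "log2fc_min", "log2fc_max"])
        part = partition_sets([], [])
        tables = summarize_dep(calls, part)
        for tab in tables.values():
            assert len(tab) == 0
            assert "protein_id" in tab.columns

    def test_reported_rows_meet_quorum(self, small_dataset, small_config):
        q, d, _ = small_dataset
        qf, df, _ = run_funnel(q, d, spike_id=small_config.spike_protein_id)
        calls = call_dep(paired_log2fc(qf, df))
        part = partition_sets(qf.protein_ids, qf.protein_ids)
        tables = summarize_dep(calls, part)
        for tab in tables.values():
            if len(tab):
                assert (tab["n_qualifying"] >= 4).all()


class TestRecoveryAndInvariance:
    def test_planted_effects_recovered_without_missingness(self):
        cfg = SimulationConfig(
            n_proteins=200,
            effect_log2fc=2.0,
            missing_rate=0.0,
            seed=21,
        )
        q, d, truth = generate_dataset(cfg)
        qf, df, _ = run_funnel(q, d, spike_id=cfg.spike_protein_id)
        calls = call_dep(paired_log2fc(qf, df))
        lps = calls[calls["group"].str.startswith("LPS")]
        truth_map = truth.set_index("protein_id")["planted_class"]
        surviving = [p for p in qf.protein_ids if p != cfg.spike_protein_id]
        planted = [p for p in surviving if truth_map[p] in ("up", "down")]
        assert planted
        # sensitivity 1: every surviving planted protein called in its direction
        for p in planted:
            sub = lps[lps["protein_id"] == p]
            assert (sub["direction"] == truth_map[p]).all(), p
        # nulls whose per-animal noise stayed below the threshold in >= 3
        # animals cannot reach the 4-of-6 quorum: no false positives there
        fc = paired_log2fc(qf, df)
        for p in surviving:
            if truth_map[p] != "null":
                continue
            for group in ("LPS50", "LPS90"):
                vec = fc[(fc["protein_id"] == p) & (fc["group"] == group)]["log2fc"]
                if (vec.abs() < 1).sum() >= 3:
                    sub = lps[(lps["protein_id"] == p) & (lps["group"] == group)]
                    assert (sub["direction"] == "none").all(), p

    def test_calls_invariant_under_per_sample_rescaling(self, small_dataset, small_config):
        q, d, _ = small_dataset
        spike = small_config.spike_protein_id

        def pipeline(mat):
            qf, df, _ = run_funnel(mat, d, spike_id=spike)
            return call_dep(paired_log2fc(qf, df))

        base = pipeline(q)
        rng = np.random.default_rng(0)
        scaled = q.intensities * rng.uniform(0.2, 5.0, size=len(q.sample_ids))
        from secretodep import QuantMatrix

        rescaled = pipeline(QuantMatrix(scaled, q.metadata.copy()))
        pd.testing.assert_frame_equal(base, rescaled)
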