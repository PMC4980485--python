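"""The synthetic-data generator and its planted truth sets."""

import numpy as np
import pandas as pd
import pytest

from clonaldrift.purity import correct_vaf
from clonaldrift.simdata import (
    SimulationConfig,
    read_truth,
    simulate_case,
    simulate_phylogeny,
    simulate_reads,
    write_fixture,
)


class TestSimulationConfig:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            SimulationConfig(scenario="wild")

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            SimulationConfig(depth_mean=0)

    def test_monoclonal_forces_single_clone(self):
        assert SimulationConfig(n_clones=5, scenario="monoclonal").n_clones == 1


class TestSimulatePhylogeny:
    def test_monoclonal_truth(self):
        truth = simulate_phylogeny(1, "monoclonal", seed=7, purity=0.8)
        assert truth.tree_parent == {0: None}
        for s in truth.samples:
            assert truth.exclusive_fraction.loc[0, s] == pytest.approx(1.0)

    def test_dynamic_swaps_a_dominant_subclone(self):
        """At least one clone shifts by >= 0.5 between time points."""
        truth = simulate_phylogeny(5, "dynamic", seed=1, purity=0.9)
        pre = truth.exclusive_fraction["B1"]
        post = truth.exclusive_fraction["S1"]
        assert (pre - post).abs().max() >= 0.5

    def test_collision_splits_clones_across_time_points(self):
        truth = simulate_phylogeny(4, "collision", seed=3, purity=0.8)
        roots = [c for c, p in truth.tree_parent.items() if p is None]
        assert len(roots) == 2
        pre = truth.exclusive_fraction["B1"]
        post = truth.exclusive_fraction["S1"]
        assert set(pre[pre > 0].index).isdisjoint(set(post[post > 0].index))

    @pytest.mark.parametrize("scenario, n", [("stable", 3), ("dynamic", 4), ("emergent", 3)])
    def test_fractions_sum_to_one_per_sample(self, scenario, n):
        truth = simulate_phylogeny(n, scenario, seed=5, purity=0.7,
                                   n_cores_per_timepoint=2, core_jitter=200.0)
        totals = truth.exclusive_fraction.sum(axis=0)
        assert np.allclose(totals, 1.0)

    def test_parent_prevalence_dominates_children(self):
        truth = simulate_phylogeny(5, "dynamic", seed=2, purity=0.9)
        for s in truth.samples:
            for clone, parent in truth.tree_parent.items():
                if parent is None:
                    continue
                kids = [c for c, p in truth.tree_parent.items() if p == parent]
                assert truth.prevalence(parent, s) >= sum(
                    truth.prevalence(c, s) for c in kids
                ) - 1e-9

    def test_default_purity_within_study_range(self):
        truth = simulate_phylogeny(2, "stable", seed=9)
        for p in truth.true_purity.values():
            assert 0.12 <= p <= 1.0


class TestSimulateReads:
    def test_expected_vaf_at_half_purity(self):
        """Founder VAF concentrates at purity/2; corrected mean near 0.5."""
        config = SimulationConfig(scenario="monoclonal", purity_by_sample=0.5,
                                  depth_mean=1000, n_variants_per_clone=200, seed=0)
        truth, reads = simulate_case(config)
        sub = reads[reads["sample"] == "B1"]
        vaf = sub["dna_var_reads"] / (sub["dna_var_reads"] + sub["dna_ref_reads"])
        assert vaf.mean() == pytest.approx(0.25, abs=0.01)

    def test_corrected_founder_vaf_converges_at_high_depth(self):
        config = SimulationConfig(scenario="monoclonal", purity_by_sample=0.6,
                                  depth_mean=10_000, n_variants_per_clone=200, seed=1)
        truth, reads = simulate_case(config)
        sub = reads[reads["sample"] == "S1"]
        vaf = sub["dna_var_reads"] / (sub["dna_var_reads"] + sub["dna_ref_reads"])
        assert np.mean(correct_vaf(vaf, 0.6)) == pytest.approx(0.5, abs=0.005)

    def test_emergent_clone_is_below_detection_at_baseline(self):
        """At depth 50 most variants of a 1%-prevalence clone see 0 reads."""
        config = SimulationConfig(n_clones=2, scenario="emergent",
                                  purity_by_sample=1.0, depth_mean=50,
                                  n_variants_per_clone=100, seed=2)
        truth, reads = simulate_case(config)
        emergent_clone = 1
        keys = [v for v, c in truth.variant_assignment.items() if c == emergent_clone]
        pos = {int(k.split(":")[1]) for k in keys}
        sub = reads[(reads["sample"] == "B1") & reads["pos"].isin(pos)]
        assert (sub["dna_var_reads"] == 0).mean() > 0.5

    def test_matched_normal_carries_only_error_reads(self):
        config = SimulationConfig(scenario="monoclonal", purity_by_sample=1.0,
                                  depth_mean=100, n_variants_per_clone=100, seed=3)
        _, reads = simulate_case(config)
        norm_vaf = reads["normal_var_reads"] / (
            reads["normal_var_reads"] + reads["normal_ref_reads"]
        )
        assert norm_vaf.mean() < 0.01


class TestFixtures:
    def test_fixed_seed_gives_byte_identical_fixtures(self, tmp_path):
        config = SimulationConfig(n_clones=3, scenario="dynamic", seed=13,
                                  purity_by_sample=0.8, depth_mean=60,
                                  n_variants_per_clone=20)
        for d in ("one", "two"):
            truth, reads = simulate_case(config)
            write_fixture(reads, truth, tmp_path / d)
        for name in ("variants.tsv", "segments.bed", "clinical.csv", "truth.json"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()

    def test_truth_json_round_trip(self, stable_case, tmp_path):
        truth, reads = stable_case
        paths = write_fixture(reads, truth, tmp_path)
        back = read_truth(paths["truth"])
        assert back.tree_parent == truth.tree_parent
        pd.testing.assert_frame_equal(back.exclusive_fraction, truth.exclusive_fraction)
        assert back.variant_assignment == truth.variant_assignment

    def test_truth_fractions_sum_to_one(self, collision_case, tmp_path):
        truth, reads = collision_case
        paths = write_fixture(reads, truth, tmp_path)
        import json

        d = json.loads(paths["truth"].read_text())
        for s, frac in d["exclusive_fraction"].items():
            assert sum(frac.values()) == pytest.approx(1.0)

    def test_collision_fixture_shares_no_variants(self, collision_case):
        truth, reads = collision_case
        roots = [c for c, p in truth.tree_parent.items() if p is None]
        tumour_a = {
            v for v, c in truth.variant_assignment.items()
            if truth.prevalence(c, "B1") > 0
        }
        tumour_b = {
            v for v, c in truth.variant_assignment.items()
            if truth.prevalence(c, "S1") > 0
        }
        assert len(roots) == 2
        assert tumour_a and tumour_b
        assert tumour_a.isdisjoint(tumour_b)

    def test_empty_records_rejected(self, tmp_path, stable_case):
        truth, _ = stable_case
        with pytest.raises(ValueError):
            write_fixture(pd.DataFrame(), truth, tmp_path)
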