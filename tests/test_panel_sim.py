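"""Panel construction, HWE genotype simulation and the read-count generator."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import forensnp as f
from forensnp.panel import PairLabels


class TestBuildPanel:
    def test_counts_by_construction(self):
        panel = f.build_panel(5000, 379, ("uniform", 0.05, 0.95), seed=1)
        assert len(panel) == 5379
        assert panel.n_y == 379
        assert panel.targetable_count("female") == 5000
        assert panel.targetable_count("male") == 5379

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            f.build_panel(0, 0, seed=1)

    def test_beta_frequencies_match_analytic_mean(self):
        # Beta(2,2) has mean 0.5 and sd 1/sqrt(20); compare at 3 SE
        n = 10_000
        panel = f.build_panel(n, 0, ("beta", 2, 2), seed=7)
        se = np.sqrt(stats.beta(2, 2).var() / n)
        assert abs(panel.alt_freq.mean() - 0.5) < 3 * se

    def test_deterministic_per_seed(self):
        a = f.build_panel(300, 30, seed=5)
        b = f.build_panel(300, 30, seed=5)
        assert a.frame.equals(b.frame)
        c = f.build_panel(300, 30, seed=6)
        assert not a.frame["alt_freq"].equals(c.frame["alt_freq"])

    def test_marker_validation(self):
        with pytest.raises(ValueError, match="ref and alt"):
            f.SNPMarker("m1", "1", 100, "A", "A", 0.5)
        with pytest.raises(ValueError, match="alt_freq"):
            f.SNPMarker("m1", "1", 100, "A", "G", 1.5)


class TestSimulateIndividuals:
    def test_monomorphic_marker_gives_zero_dosage(self):
        panel = f.Panel(pd.DataFrame({
            "marker_id": ["m1"], "chrom": ["1"], "pos": [100],
            "ref": ["A"], "alt": ["G"], "alt_freq": [0.0]}))
        truth = f.simulate_individuals(panel, 50, seed=3)
        assert all(ind.dosage[0] == 0 for ind in truth.individuals)

    def test_het_fraction_near_hwe_expectation(self):
        panel = f.Panel(pd.DataFrame({
            "marker_id": ["m1"], "chrom": ["1"], "pos": [100],
            "ref": ["A"], "alt": ["G"], "alt_freq": [0.5]}))
        n = 10_000
        truth = f.simulate_individuals(panel, n, seed=4)
        het = np.mean([ind.dosage[0] == 1 for ind in truth.individuals])
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(het - 0.5) < 3 * se

    def test_single_individual_has_no_pairs(self, small_panel):
        truth = f.simulate_individuals(small_panel, 1, seed=5)
        assert len(truth.pair_labels) == 0

    def test_all_pairs_unrelated(self, small_panel):
        truth = f.simulate_individuals(small_panel, 4, seed=5)
        labels = {lab for _, lab in truth.pair_labels.items()}
        assert labels == {"unrelated"}

    def test_females_carry_no_y(self, small_panel):
        truth = f.simulate_individuals(small_panel, 20, sex_ratio=0.0, seed=6)
        for ind in truth.individuals:
            assert ind.sex == "female"
            assert (ind.dosage[small_panel.is_y] == -1).all()

    def test_male_y_is_haploid(self, small_panel):
        truth = f.simulate_individuals(small_panel, 20, sex_ratio=1.0, seed=6)
        for ind in truth.individuals:
            assert set(np.unique(ind.dosage[small_panel.is_y])) <= {0, 1}

    def test_hwe_recovery_per_marker(self):
        """Genotype frequencies match HWE proportions within 4 SE at n=5000."""
        panel = f.build_panel(20, 0, ("uniform", 0.2, 0.8), seed=9)
        n = 5000
        truth = f.simulate_individuals(panel, n, seed=10)
        dosages = np.stack([ind.dosage for ind in truth.individuals])
        for j, p in enumerate(panel.alt_freq):
            for g, expected in [(0, (1 - p) ** 2), (1, 2 * p * (1 - p)),
                                (2, p ** 2)]:
                obs = (dosages[:, j] == g).mean()
                se = np.sqrt(expected * (1 - expected) / n)
                assert abs(obs - expected) < 4 * se + 1e-12


class TestAddReplicates:
    def test_replicate_shares_genotypes_and_label(self, small_panel):
        truth = f.simulate_individuals(small_panel, 3, seed=7)
        out = f.add_replicates(truth, "ind000", 1)
        rep = out.get("ind000-rep1")
        assert np.array_equal(rep.dosage, out.get("ind000").dosage)
        assert out.pair_labels.label("ind000", "ind000-rep1") == "same_donor"
        assert out.pair_labels.label("ind001", "ind000-rep1") == "unrelated"

    def test_unknown_sample_rejected(self, small_panel):
        truth = f.simulate_individuals(small_panel, 3, seed=7)
        with pytest.raises(KeyError):
            f.add_replicates(truth, "nope", 1)

    def test_two_replicates_make_three_mutual_pairs(self, small_panel):
        truth = f.simulate_individuals(small_panel, 3, seed=7)
        out = f.add_replicates(truth, "ind000", 2)
        group = ["ind000", "ind000-rep1", "ind000-rep2"]
        # enumeration oracle: all C(3,2) pairs within the group
        pairs = list(itertools.combinations(group, 2))
        assert len(pairs) == 3
        for a, b in pairs:
            assert out.pair_labels.label(a, b) == "same_donor"
        assert len(out.pair_labels.same_donor_pairs()) == 3


class TestPairLabels:
    def test_self_pair_rejected(self):
        labels = PairLabels(["a", "b"])
        with pytest.raises(ValueError):
            labels.label("a", "a")

    def test_symmetric_lookup(self):
        labels = PairLabels(["a", "b"], {frozenset({"a", "b"})})
        assert labels[("a", "b")] == labels[("b", "a")] == "same_donor"


class TestSimulateReads:
    def test_deterministic(self, small_panel, truth_small):
        cfg = f.preset("wgs_like", seed=21)
        a = f.simulate_reads(truth_small, small_panel, cfg)
        b = f.simulate_reads(truth_small, small_panel, cfg)
        pd.testing.assert_frame_equal(a.reads, b.reads)
        pd.testing.assert_frame_equal(a.bookkeeping, b.bookkeeping)

    def test_count_conservation(self, small_panel, truth_small):
        sim = f.simulate_reads(truth_small, small_panel,
                               f.preset("capture_like", seed=22))
        r = sim.reads
        total = r["n_ref"] + r["n_alt"] + r["n_other"]
        assert (total == r["n_fwd"] + r["n_rev"]).all()
        assert (r[["n_ref", "n_alt", "n_other"]] >= 0).all().all()

    def test_near_zero_depth_limit(self, small_panel, truth_small):
        cfg = f.SimulationConfig(mean_depth=1e-9, seed=23)
        sim = f.simulate_reads(truth_small, small_panel, cfg)
        assert (sim.reads[["n_ref", "n_alt", "n_other"]] == 0).all().all()

    def test_noiseless_limit_matches_dosage(self, small_panel, truth_small,
                                            deep_noiseless):
        """With eps=delta=c=0 homozygous sites carry zero discordant reads
        and het alt fractions concentrate at 1/2."""
        ind = truth_small.individuals[0]
        tab = deep_noiseless.per_sample(ind.sample_id)
        d = tab["n_ref"] + tab["n_alt"]
        covered = (d > 0).to_numpy() & (ind.dosage >= 0)
        dos = ind.dosage
        hap = small_panel.is_y  # all-male markers are diploid except Y
        assert (tab["n_other"] == 0).all()
        hom0 = covered & (dos == 0)
        assert (tab.loc[hom0, "n_alt"] == 0).all()
        hom2 = covered & (dos == 2) & ~hap
        assert (tab.loc[hom2, "n_ref"] == 0).all()

    def test_mean_depth_within_3_se(self):
        panel = f.build_panel(100_000, 0, seed=31)
        truth = f.simulate_individuals(panel, 1, seed=32)
        cfg = f.SimulationConfig(mean_depth=0.3, depth_dispersion=1.0,
                                 site_efficiency_sd=0.0, seed=33)
        sim = f.simulate_reads(truth, panel, cfg)
        depth = (sim.reads["n_ref"] + sim.reads["n_alt"]
                 + sim.reads["n_other"]).to_numpy()
        # NB variance m + m^2/r
        var = 0.3 + 0.3 ** 2 / 1.0
        se = np.sqrt(var / depth.size)
        assert abs(depth.mean() - 0.3) < 3 * se

    def test_contamination_shifts_hom_sites(self, small_panel):
        truth = f.simulate_individuals(small_panel, 2, seed=41)
        clean = f.simulate_reads(truth, small_panel, f.SimulationConfig(
            mean_depth=80, error_rate=0.0, contamination=0.0, seed=42))
        dirty = f.simulate_reads(truth, small_panel, f.SimulationConfig(
            mean_depth=80, error_rate=0.0, contamination=0.3, seed=42))
        ind = truth.individuals[0]
        hom0 = (ind.dosage == 0) & small_panel.is_autosomal
        mids = small_panel.marker_ids.to_numpy()[hom0]
        c_tab = clean.per_sample(ind.sample_id).set_index("marker_id")
        d_tab = dirty.per_sample(ind.sample_id).set_index("marker_id")
        assert d_tab.loc[mids, "n_alt"].sum() > c_tab.loc[mids, "n_alt"].sum()

    def test_damage_only_hits_transition_markers(self):
        frame = pd.DataFrame({
            "marker_id": ["ct", "ag"], "chrom": ["1", "1"], "pos": [1, 2],
            "ref": ["C", "A"], "alt": ["T", "C"], "alt_freq": [0.5, 0.5]})
        panel = f.Panel(frame)
        assert panel.damage_prone.tolist() == [True, False]

    def test_bookkeeping_fractions(self, small_panel, truth_small):
        cfg = f.SimulationConfig(mean_depth=30, nonhuman_fraction=0.8,
                                 duplicate_fraction=0.2, seed=51)
        sim = f.simulate_reads(truth_small, small_panel, cfg)
        row = sim.bookkeeping.iloc[0]
        assert row["human_reads"] / row["total_reads"] == pytest.approx(0.2, rel=1e-3)
        assert row["duplicate_reads"] / row["human_reads"] == pytest.approx(
            0.2, rel=1e-2)
        assert row["on_target_reads"] == row["human_reads"] - row["duplicate_reads"]

    def test_preset_names(self):
        assert f.preset("wgs_like").mean_depth == pytest.approx(0.3)
        assert f.preset("capture_like").mean_depth == pytest.approx(30.0)
        assert f.preset("control_like").nonhuman_fraction == 0.0
        with pytest.raises(ValueError):
            f.preset("nope")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            f.SimulationConfig(mean_depth=0.0)
        with pytest.raises(ValueError):
            f.SimulationConfig(error_rate=0.6)
        with pytest.raises(ValueError):
            f.SimulationConfig(contamination=1.0)
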