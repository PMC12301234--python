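"""Generator tests: assembly, affinity assignment, selection model, FASTQ."""

import numpy as np
import pytest
from scipy import stats

from panscreen import synthetic
from panscreen.synthetic import (DegenerateRoundError, PanningConfig,
                                 assign_affinities, emit_fastq,
                                 generate_library, selection_weights,
                                 simulate_campaign, simulate_round)


class TestGenerateLibrary:
    def test_deterministic_assembly_of_singleton_pools(self, singleton_design):
        camp = generate_library(singleton_design, 1)
        (clone,) = camp.clones
        d = singleton_design
        expected = (d.anchor + d.framework_regions[0] + d.cdr_pools[0][0]
                    + d.framework_regions[1] + d.cdr_pools[1][0]
                    + d.framework_regions[2] + d.cdr_pools[2][0]
                    + d.framework_regions[3])
        assert clone.nt_sequence == expected

    def test_zero_liability_fraction_plants_nothing(self, small_design):
        camp = generate_library(small_design, 200)
        assert all(not c.planted_liabilities for c in camp.clones)

    def test_liability_fraction_plants_one_motif_each(self):
        design = synthetic.default_library_design(seed=4, liability_fraction=0.3)
        camp = generate_library(design, 200)
        carriers = [c for c in camp.clones if c.planted_liabilities]
        assert all(len(c.planted_liabilities) == 1 for c in carriers)
        # binomial 99.9% sanity band around 0.3 * 200
        assert 30 <= len(carriers) <= 90

    def test_clones_unique(self, small_design):
        camp = generate_library(small_design, 500)
        seqs = {c.nt_sequence for c in camp.clones}
        assert len(seqs) == 500

    def test_empty_pool_rejected(self, small_design):
        bad = synthetic.LibraryDesign(
            framework_regions=small_design.framework_regions,
            cdr_pools=([], small_design.cdr_pools[1], small_design.cdr_pools[2]))
        with pytest.raises(ValueError, match="non-empty"):
            generate_library(bad, 1)

    def test_seeded_reproducibility_byte_identical(self):
        out = []
        for _ in range(2):
            camp = simulate_campaign(n_clones=100, seed=42,
                                     config=PanningConfig(reads_per_round=1000,
                                                          seed=42))
            out.append(camp.truth_json())
        assert out[0] == out[1]


class TestAssignAffinities:
    def test_all_binders_at_fraction_one(self, small_design):
        camp = generate_library(small_design, 50)
        assign_affinities(camp, binder_fraction=1.0, by_motif=False, seed=1)
        assert all(c.is_binder for c in camp.clones)

    def test_disjoint_ranges_separate_classes(self, small_design):
        camp = generate_library(small_design, 200)
        assign_affinities(camp, binder_fraction=0.5, by_motif=False, seed=1,
                          kd_binder_range=(1e-10, 1e-9),
                          kd_nonbinder_range=(1e-7, 1e-5))
        binder_kds = [c.kd for c in camp.clones if c.is_binder]
        nonbinder_kds = [c.kd for c in camp.clones if not c.is_binder]
        assert max(binder_kds) < min(nonbinder_kds)

    def test_overlapping_ranges_rejected(self, small_design):
        camp = generate_library(small_design, 5)
        with pytest.raises(ValueError, match="strictly below"):
            assign_affinities(camp, kd_binder_range=(1e-9, 1e-7),
                              kd_nonbinder_range=(1e-8, 1e-5))

    def test_binder_count_within_binomial_interval(self):
        design = synthetic.default_library_design(seed=9, n_cdr3=240)
        camp = generate_library(design, 1000)
        assign_affinities(camp, binder_fraction=0.1, by_motif=False, seed=7)
        n_binders = sum(c.is_binder for c in camp.clones)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.1)
        assert lo <= n_binders <= hi


class TestSimulateRound:
    def test_langmuir_weight_closed_form(self):
        # one binder (1 nM) vs one non-binder (10 uM), equal counts,
        # C = 100 nM, wash retention 1e-3
        counts = np.array([1.0, 1.0])
        kds = np.array([1e-9, 1e-5])
        w = selection_weights(counts, kds, 100e-9, 1e-3)
        w_binder = 100 / 101 + 1e-3
        w_non = 100e-9 / (100e-9 + 1e-5) + 1e-3
        assert w[0] == pytest.approx(w_binder, abs=1e-12)
        assert w[1] == pytest.approx(w_non, abs=1e-12)
        expected_freq = w_binder / (w_binder + w_non)
        assert expected_freq == pytest.approx(0.989, abs=5e-4)

    def test_expected_frequency_matches_multinomial_mean(self, small_design):
        camp = generate_library(small_design, 2)
        camp.clones[0].kd, camp.clones[1].kd = 1e-9, 1e-5
        ids = [c.clone_id for c in camp.clones]
        counts = {ids[0]: 100, ids[1]: 100}
        rng = np.random.default_rng(0)
        total = np.zeros(2)
        n_rep, reads = 200, 10_000
        for _ in range(n_rep):
            out = simulate_round(counts, camp.clone_map, 100e-9, 1e-3,
                                 reads, rng)
            total += [out[i] for i in sorted(out)]
        w = selection_weights(np.array([100.0, 100.0]),
                              np.array([1e-9, 1e-5]), 100e-9, 1e-3)
        expected = w / w.sum()
        observed = total / (n_rep * reads)
        assert observed == pytest.approx(expected, abs=0.005)

    def test_identical_kd_is_symmetric(self):
        w = selection_weights(np.array([5.0, 5.0, 5.0]),
                              np.full(3, 1e-8), 50e-9, 1e-3)
        assert np.allclose(w, w[0])

    def test_saturation_limit_weights_proportional_to_counts(self):
        counts = np.array([3.0, 7.0, 1.0])
        kds = np.array([1e-9, 1e-6, 1e-4])
        w = selection_weights(counts, kds, 1.0, 1e-3)  # C >> all K_D
        assert np.allclose(w / w.sum(), counts / counts.sum(), atol=1e-3)

    def test_all_zero_counts_degenerate(self, small_design):
        camp = generate_library(small_design, 3)
        for c in camp.clones:
            c.kd = 1e-9
        counts = {c.clone_id: 0 for c in camp.clones}
        with pytest.raises(DegenerateRoundError):
            simulate_round(counts, camp.clone_map, 100e-9, 1e-3, 100,
                           np.random.default_rng(0))


class TestEmitFastq:
    def test_error_free_reads_equal_clone_sequences(self, small_campaign, tmp_path):
        path = tmp_path / "r1.fastq"
        n = emit_fastq(small_campaign, 1, path, error_rate=0.0, seed=0)
        assert n == sum(small_campaign.round_counts[1].values())
        clone_map = small_campaign.clone_map
        lines = path.read_text().splitlines()
        assert len(lines) == 4 * n
        for i in range(0, len(lines), 4):
            clone_id = lines[i][1:].split("|")[0]
            assert lines[i + 1] == clone_map[clone_id].nt_sequence

    def test_substitution_error_rate(self, small_campaign, tmp_path):
        path = tmp_path / "r0.fastq"
        emit_fastq(small_campaign, 0, path, error_rate=0.01, seed=1)
        clone_map = small_campaign.clone_map
        lines = path.read_text().splitlines()
        mismatches, n_reads, read_len = 0, 0, None
        for i in range(0, len(lines), 4):
            clone_id = lines[i][1:].split("|")[0]
            ref = clone_map[clone_id].nt_sequence
            read = lines[i + 1]
            read_len = len(ref)
            mismatches += sum(a != b for a, b in zip(read, ref))
            n_reads += 1
        expected = 0.01 * read_len
        assert mismatches / n_reads == pytest.approx(expected, rel=0.1)

    def test_byte_identical_given_seed(self, small_campaign, tmp_path):
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        emit_fastq(small_campaign, 2, p1, error_rate=0.01, seed=5)
        emit_fastq(small_campaign, 2, p2, error_rate=0.01, seed=5)
        assert p1.read_bytes() == p2.read_bytes()


class TestCampaignProperties:
    def test_round_totals_conserved(self, small_campaign):
        for counts in small_campaign.round_counts:
            assert sum(counts.values()) == 3000
            freqs = np.array(list(counts.values())) / 3000
            assert freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mean_frequency_of_best_clone_non_decreasing(self):
        """Across 20 seeds, the lowest-K_D clone's mean per-round frequency
        rises monotonically under decreasing antigen concentration."""
        n_rounds = 5  # including the input round
        traj = np.zeros(n_rounds)
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = PanningConfig(reads_per_round=3000, seed=seed)
            camp = simulate_campaign(n_clones=300, seed=seed, config=cfg)
            best = min(camp.clones, key=lambda c: c.kd)
            for r in range(n_rounds):
                counts = camp.round_counts[r]
                traj[r] += counts[best.clone_id] / sum(counts.values())
        traj /= n_seeds
        assert np.all(np.diff(traj) >= 0), traj
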