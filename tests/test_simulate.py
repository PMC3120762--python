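"""Structured-coalescent simulator and finite-sites mutation."""

import numpy as np
import pytest

from phylodeme.haplotypes import collapse_haplotypes, classify_segregating_sites
from phylodeme.scenarios import get_scenario
from phylodeme.simulate import (SimulationConfig, GrowthSpec, simulate_genealogy,
                                mutate_on_genealogy, mutate_encoded, generate_dataset,
                                check_coalescible)
from phylodeme.substitution import jc69, gtr


def _single_deme_config(n, theta=0.01, seed=0, **kw):
    return SimulationConfig(deme_labels=("F", "S", "A"), sample_sizes=(0, n, 0),
                            theta=theta, migration_rates=0.0,
                            scenario=get_scenario("S>A, S>F"), growth=None,
                            locus_length=kw.pop("locus_length", 100), seed=seed, **kw)


class TestGenealogy:
    def test_single_sample_degenerate(self):
        g = simulate_genealogy(_single_deme_config(1))
        assert g.n_tips == 1
        assert g.times.max() == 0.0

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            simulate_genealogy(SimulationConfig(sample_sizes=(0, 0, 0)))

    def test_pairwise_coalescence_time_matches_closed_form(self):
        """Two lineages, one deme: E[T2] = theta/2 under the documented
        j(j-1)/theta rate scaling."""
        theta = 0.01
        rng = np.random.default_rng(1)
        cfg = _single_deme_config(2, theta=theta)
        times = []
        for _ in range(10_000):
            g = simulate_genealogy(cfg, rng=rng)
            times.append(g.times[g.root])
        mean = np.mean(times)
        se = np.std(times) / np.sqrt(len(times))
        assert abs(mean - theta / 2) < 3 * se

    def test_zero_rate_produces_no_migration(self):
        cfg = SimulationConfig(sample_sizes=(0, 12, 0), migration_rates=0.0,
                               scenario=get_scenario("S>A, S>F"), growth=None, seed=3)
        g = simulate_genealogy(cfg)
        assert len(g.mig_times) == 0

    def test_absorbing_scenario_paths_end_in_origin(self):
        """All samples in A under a lone backward A->S rate: every deme
        path must end in S (the origin) at the root."""
        cfg = SimulationConfig(sample_sizes=(0, 0, 10), theta=0.01,
                               scenario=get_scenario("S>A, S>F"),
                               migration_rates={("A", "S"): 50.0},
                               growth=None, seed=4)
        g = simulate_genealogy(cfg)
        g.validate()
        assert g.deme_labels[g.root_deme()] == "S"

    def test_disconnected_multi_deme_configuration_rejected(self):
        cfg = SimulationConfig(sample_sizes=(10, 10, 10), migration_rates=0.0,
                               growth=None, seed=0)
        with pytest.raises(ValueError, match="non-coalescible"):
            simulate_genealogy(cfg)

    def test_split_absorption_rejected(self):
        # deme 0 can be absorbed into closed classes {1} and {2}
        M = np.zeros((3, 3))
        M[0, 1] = M[0, 2] = 1.0
        with pytest.raises(ValueError, match="non-coalescible"):
            check_coalescible(np.array([True, False, False]), M)

    def test_histories_validate_and_are_ultrametric(self):
        cfg = SimulationConfig(sample_sizes=(5, 6, 7), seed=9)
        g = simulate_genealogy(cfg)
        g.validate()
        par = g.parents()
        assert (g.times[par[par >= 0]] >= g.times[np.where(par >= 0)[0]]).all()

    def test_masked_rates_produce_no_events_across_replicates(self):
        """Scenario compliance: migration counts on masked entries are 0."""
        cfg = SimulationConfig(sample_sizes=(6, 6, 6), theta=0.05,
                               migration_rates=20.0, growth=None, seed=0)
        mask = cfg.scenario.backward_mask(cfg.deme_labels)
        rng = np.random.default_rng(0)
        for _ in range(100):
            g = simulate_genealogy(cfg, rng=rng)
            _, _, nmat, _ = g.sufficient_stats(3)
            assert (nmat[~mask] == 0).all()


class TestMutation:
    def test_zero_length_rejected(self):
        g = simulate_genealogy(_single_deme_config(3, seed=2))
        with pytest.raises(ValueError):
            mutate_on_genealogy(g, jc69(), 0, 1)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            gtr(freqs=(0.5, 0.5, 0.1, -0.1))

    def test_zero_branch_lengths_give_identical_sequences(self):
        cfg = _single_deme_config(5, theta=1e-12, seed=5, locus_length=200)
        g = simulate_genealogy(cfg)
        seqs = list(mutate_on_genealogy(g, jc69(), 200, 1).values())
        assert len(set(seqs)) == 1

    def test_jc_divergence_matches_closed_form(self):
        """Two tips at divergence 2t: P(diff) = 3/4 (1 - e^{-8t/3})."""
        from phylodeme.genealogy import Genealogy
        t = 0.05
        g = Genealogy(["a", "b"], np.zeros(2, dtype=np.int64), ("D",),
                      np.array([0.0, 0.0, t]), np.array([[-1, -1], [-1, -1], [0, 1]]),
                      np.array([0]))
        rng = np.random.default_rng(7)
        L = 10_000
        mat = mutate_encoded(g, jc69(), L, rng)
        p_hat = (mat[0] != mat[1]).mean()
        p_true = 0.75 * (1 - np.exp(-8 * t / 3))
        se = np.sqrt(p_true * (1 - p_true) / L)
        assert abs(p_hat - p_true) < 3 * se

    def test_stationary_composition_reached_from_skewed_root(self):
        """Long branches drive composition to the model's frequencies."""
        from phylodeme.genealogy import Genealogy
        g = Genealogy(["a", "b"], np.zeros(2, dtype=np.int64), ("D",),
                      np.array([0.0, 0.0, 30.0]), np.array([[-1, -1], [-1, -1], [0, 1]]),
                      np.array([0]))
        L = 100_000
        mat = mutate_encoded(g, gtr(freqs=(0.25,) * 4), L, np.random.default_rng(3))
        freqs = np.bincount(mat[0], minlength=4) / L
        se = np.sqrt(0.25 * 0.75 / L)
        assert np.all(np.abs(freqs - 0.25) < 4 * se)


class TestDatasets:
    def test_byte_identical_under_fixed_seed(self, tmp_path):
        cfg = SimulationConfig(sample_sizes=(5, 5, 5), seed=11)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(cfg, d1)
        generate_dataset(cfg, d2)
        for name in ("alignment.fasta", "deme_map.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_coi_shape(self, coi_like_dataset):
        aln, dm, truth = coi_like_dataset
        assert len(aln) == 138 and len(dm) == 138
        assert all(len(s) == 604 for s in aln.values())
        assert sorted(set(dm.values())) == ["A", "F", "S"]
        assert truth["scenario"] == "S>A>F"

    def test_coi_defaults_emulate_published_diversity_shape(self):
        """Across seeds, the default condition yields shallow
        singleton-dominated diversity near 13 haplotypes / 17 variable
        sites in 138 sequences."""
        haps, svar = [], []
        for seed in range(5):
            aln, dm, _ = generate_dataset(SimulationConfig.coi_like(seed=seed))
            t = collapse_haplotypes(aln, dm)
            s, pi = classify_segregating_sites(aln)
            haps.append(len(t.haplotype_ids))
            svar.append(s + pi)
        assert 8 <= np.mean(haps) <= 20
        assert 9 <= np.mean(svar) <= 26

    def test_diploid_mode_doubles_records_with_allele_suffix(self):
        aln, dm, truth = generate_dataset(SimulationConfig.hsp70_like(seed=1))
        assert len(aln) == 76
        assert truth["sample_sizes"] == [10, 14, 14]
        assert all(r.split("|")[2] in ("1", "2") for r in aln)

    def test_watterson_recovery_single_deme(self):
        """Mean S/(a_n L) across replicates within 15% of theta."""
        theta, n, L = 0.01, 20, 600
        a_n = sum(1.0 / i for i in range(1, n))
        est = []
        for seed in range(50):
            cfg = _single_deme_config(n, theta=theta, seed=seed, locus_length=L)
            aln, dm, _ = generate_dataset(cfg)
            s, pi = classify_segregating_sites(aln)
            est.append((s + pi) / (a_n * L))
        assert abs(np.mean(est) - theta) < 0.15 * theta
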