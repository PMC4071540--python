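import numpy as np
import pytest

from mimiclocus.core_io import DataError
from mimiclocus.molevol import harmonic_numbers
from mimiclocus.simulate import (
    DEFAULT_COUNTS,
    SimConfig,
    freqs_from_counts,
    null_population,
    simulate_brood,
    simulate_locus_coalescent,
    simulate_outgroup_coding,
    simulate_population,
    simulate_reads,
)


class TestPopulation:
    def test_sample_sizes_and_ranks(self, default_population):
        g, morphs, truth = default_population
        assert g.n_individuals == 97
        counts = [len(morphs.individuals_of(m)) for m in morphs.hierarchy]
        assert tuple(counts) == DEFAULT_COUNTS
        assert sorted(morphs.rank_of.values()) == [0, 1, 2, 3, 4]

    def test_phenotype_is_max_rank_allele(self, default_population):
        g, morphs, truth = default_population
        for ind, (lo, hi) in truth.h_alleles.items():
            assert lo <= hi
            assert morphs.morph_of[ind] == truth.hierarchy[hi]

    def test_diagnostic_alleles_respect_dominance(self, default_population):
        """Diagnostics of a morph appear in >= 1 copy in every individual of
        that morph and in 0 copies in every lower-ranked individual."""
        g, morphs, truth = default_population
        idx = g.site_index()
        ranks = morphs.ranks_for(g.individuals)
        for key, morph in truth.diagnostic_sites.items():
            c = morphs.rank_of[morph]
            col = g.dosage[:, idx[key]]
            assert (col[ranks == c] >= 1).all()
            assert (col[ranks < c] == 0).all()

    def test_reproducible_and_seed_sensitive(self):
        g1, _, t1 = simulate_population(SimConfig(seed=7))
        g2, _, t2 = simulate_population(SimConfig(seed=7))
        g3, _, _ = simulate_population(SimConfig(seed=8))
        assert np.array_equal(g1.dosage, g2.dosage)
        assert t1.h_alleles == t2.h_alleles
        assert not np.array_equal(g1.dosage, g3.dosage)

    def test_zero_frequency_positive_count_rejected(self):
        cfg = SimConfig(causal_allele_freqs=(0.5, 0.5, 0.0, 0.0, 0.0))
        with pytest.raises(DataError, match="frequency 0"):
            simulate_population(cfg)

    def test_planted_carriage_realized(self, default_population):
        g, morphs, truth = default_population
        top = morphs.hierarchy[-1]
        pairs = [truth.h_alleles[i] for i in morphs.individuals_of(top)]
        lows = [lo for lo, hi in pairs]
        assert lows.count(3) >= 1  # planemoides allele hidden in poultoni
        assert lows.count(2) >= 2  # lamborni alleles hidden in poultoni

    def test_large_decay_background_independent_of_morph(self):
        """With copying switched off, background dosages are uncorrelated
        with morph rank (|r| < 0.1 at n = 10^4)."""
        counts = (2888, 2165, 2062, 515, 2370)  # Table-1 proportions x ~100
        g, morphs, truth = null_population(
            n_sites=60, seed=3, n_per_morph=counts
        )
        ranks = morphs.ranks_for(g.individuals).astype(float)
        ranks -= ranks.mean()
        for j in range(g.n_sites):
            col = g.dosage[:, j].astype(float)
            if col.std() == 0:
                continue
            r = np.corrcoef(col, ranks)[0, 1]
            assert abs(r) < 0.1

    def test_back_computed_frequencies_reproduce_counts(self):
        p = freqs_from_counts(DEFAULT_COUNTS)
        assert p.sum() == pytest.approx(1.0)
        cum = np.cumsum(p)
        expected = np.diff(np.concatenate([[0.0], cum**2]))
        observed = np.asarray(DEFAULT_COUNTS) / sum(DEFAULT_COUNTS)
        assert np.allclose(expected, observed, atol=1e-12)


class TestCoalescent:
    def test_moments_match_watterson(self):
        """Mean and variance of S match theta*a_n and theta*a_n + theta^2*b_n;
        mean divergence matches theta*(T+1)."""
        theta, n, T = 2.0, 5, 5.0
        reps = 30000
        rng = np.random.default_rng(5)
        S = np.empty(reps)
        D = np.empty(reps)
        for i in range(reps):
            c = simulate_locus_coalescent(theta, n, T, rng)
            S[i] = c.S
            D[i] = c.D
        a_n, b_n = harmonic_numbers(n)
        se_S = S.std() / np.sqrt(reps)
        assert abs(S.mean() - theta * a_n) < 4 * se_S
        var_target = theta * a_n + theta**2 * b_n
        assert abs(S.var() - var_target) < 0.1 * var_target
        se_D = D.std() / np.sqrt(reps)
        assert abs(D.mean() - theta * (T + 1)) < 4 * se_D

    def test_zero_theta(self):
        c = simulate_locus_coalescent(0.0, 4, 5.0, 1)
        assert c.S == 0 and c.D == 0

    def test_haplotypes_segregate(self):
        c = simulate_locus_coalescent(10.0, 8, 1.0, 2)
        assert c.haplotypes.shape == (8, c.S)
        if c.S:
            counts = c.haplotypes.sum(axis=0)
            assert ((counts >= 1) & (counts <= 7)).all()

    def test_sample_size_contract(self):
        with pytest.raises(DataError):
            simulate_locus_coalescent(1.0, 1, 1.0, 0)


class TestOutgroupCoding:
    def test_zero_divergence_zero_theta_identical(self):
        aln = simulate_outgroup_coding("x", 300, 6, 0.0, 0.0, rng=0)
        seqs = set(aln.in_species.values()) | set(aln.outgroup.values())
        assert len(seqs) == 1

    def test_length_contract(self):
        with pytest.raises(DataError, match="codons"):
            simulate_outgroup_coding("x", 100, 6, 1.0, 1.0, rng=0)

    def test_no_stop_codons_emitted(self):
        from mimiclocus.simulate import _STOPS

        aln = simulate_outgroup_coding("x", 300, 10, 20.0, 5.0, 3.0, rng=1)
        for seq in list(aln.in_species.values()) + list(aln.outgroup.values()):
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & _STOPS)


class TestReads:
    def test_carrier_three_distinct_inside_span_no_error(self, default_population):
        from mimiclocus.structvar import window_haplotypes

        g, morphs, truth = default_population
        cfg = SimConfig(seed=0, read_error=0.0)
        ind = truth.dup_carriers[0]
        rws = simulate_reads(truth, cfg, individuals=[ind])[ind]
        lo, hi = cfg.dup_span
        window = (lo + 150, lo + 300)
        assert len(window_haplotypes(rws, window, min_reads=1, min_fraction=0.0)) == 3

    def test_carrier_at_most_two_outside_span(self, default_population):
        from mimiclocus.structvar import window_haplotypes

        g, morphs, truth = default_population
        cfg = SimConfig(seed=0, read_error=0.0)
        ind = truth.dup_carriers[0]
        rws = simulate_reads(truth, cfg, individuals=[ind])[ind]
        assert len(window_haplotypes(rws, (0, 150), min_reads=1, min_fraction=0.0)) <= 2

    def test_homozygote_single_string(self, default_population):
        from mimiclocus.structvar import window_haplotypes

        g, morphs, truth = default_population
        cfg = SimConfig(seed=0, read_error=0.0, het_spacing=None)
        ind = next(i for i in truth.h_alleles if i not in set(truth.dup_carriers))
        rws = simulate_reads(truth, cfg, individuals=[ind])[ind]
        assert len(window_haplotypes(rws, (300, 450), min_reads=1, min_fraction=0.0)) == 1

    def test_read_length_contract(self, default_population):
        g, morphs, truth = default_population
        cfg = SimConfig(seed=0, read_length=4000)
        with pytest.raises(DataError, match="read_length"):
            simulate_reads(truth, cfg, individuals=[])


class TestBrood:
    def test_planted_recombinants_discordant_distal(self):
        from mimiclocus.mapping import score_cosegregation

        brood, truth = simulate_brood(
            n_offspring=50, crossover_between=(3, 4), n_recombinants=2, seed=0
        )
        table = score_cosegregation(brood)
        for mk in brood.markers[:4]:
            assert table.discordant[mk] == []
        for mk in brood.markers[4:]:
            assert sorted(table.discordant[mk]) == truth.recombinant_ids

    def test_zero_recombinants_cosegregate(self):
        from mimiclocus.mapping import score_cosegregation

        brood, _ = simulate_brood(n_offspring=30, n_recombinants=0, seed=1)
        table = score_cosegregation(brood)
        assert all(not v for v in table.discordant.values())

    def test_uninformative_marker_flagged(self):
        from mimiclocus.mapping import score_cosegregation

        brood, _ = simulate_brood(
            n_offspring=10, n_recombinants=0, uninformative_markers=("M2",), seed=2
        )
        table = score_cosegregation(brood)
        assert table.uninformative == ["M2"]
        assert "M2" not in table.markers

    def test_non_adjacent_crossover_rejected(self):
        with pytest.raises(DataError, match="adjacent"):
            simulate_brood(crossover_between=(2, 4))


def test_config_validation():
    with pytest.raises(DataError):
        SimConfig(dup_span=(2500, 3500))
    with pytest.raises(DataError):
        SimConfig(causal_nonsyn_excess=0.5)
    with pytest.raises(DataError):
        SimConfig(causal_allele_freqs=(0.5, 0.5))
    with pytest.raises(DataError):
        SimConfig(causal_locus="nope")
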