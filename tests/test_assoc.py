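import numpy as np
import pytest

from mimiclocus.assoc import (
    DegenerateTableError,
    ScanConfig,
    build_response,
    full_association,
    genotype_table,
    lrt_statistic,
    permutation_pvalue,
    results_to_frame,
    scan,
)
from mimiclocus.core_io import MISSING, DataError, make_morph_table

from conftest import HIERARCHY, make_matrix


def table1_morphs():
    counts = dict(zip(HIERARCHY, (28, 21, 20, 5, 23)))
    morph_of = {}
    k = 0
    for m, n in counts.items():
        for _ in range(n):
            morph_of[f"i{k}"] = m
            k += 1
    return make_morph_table(morph_of, HIERARCHY)


class TestBuildResponse:
    def test_top_morph_controls_are_all_lower(self):
        m = table1_morphs()
        r = build_response(m, "poultoni")
        assert len(r.case_ids) == 23
        assert len(r.control_ids) == 74

    def test_rank1_controls_are_bottom_only(self):
        m = table1_morphs()
        r = build_response(m, "cenea")
        assert len(r.control_ids) == 28
        assert {m.morph_of[i] for i in r.control_ids} == {"hippocoonides"}

    def test_bottom_morph_rejected(self):
        with pytest.raises(DataError, match="no lower"):
            build_response(table1_morphs(), "hippocoonides")


class TestGenotypeTable:
    CASES = [1, 1, 1]
    CONTROLS = [0, 0, 0]

    def setup_method(self):
        self.d = np.array(self.CASES + self.CONTROLS)
        self.mask = np.array([True] * 3 + [False] * 3)

    def test_recessive_groups_het_with_hom_major(self):
        t = genotype_table(self.d, self.mask, coding="recessive")
        assert t.tolist() == [[3, 3], [0, 0]]

    def test_dominant_groups_het_with_hom_minor(self):
        t = genotype_table(self.d, self.mask, coding="dominant")
        assert t.tolist() == [[0, 3], [3, 0]]

    def test_allelic_counts_chromosomes(self):
        t = genotype_table(self.d, self.mask, coding="allelic")
        assert t.tolist() == [[3, 6], [3, 0]]

    def test_phenotype_group_all_missing(self):
        d = np.array([MISSING, MISSING, 0, 1])
        mask = np.array([True, True, False, False])
        with pytest.raises(DegenerateTableError):
            genotype_table(d, mask)

    def test_unknown_coding(self):
        with pytest.raises(DataError, match="coding"):
            genotype_table(self.d, self.mask, coding="additive")


class TestLRT:
    def test_perfect_separation(self):
        assert lrt_statistic([[10, 0], [0, 10]]) == pytest.approx(40 * np.log(2))

    def test_independence_gives_zero(self):
        assert lrt_statistic([[5, 5], [5, 5]]) == 0.0

    def test_label_symmetry(self):
        g = lrt_statistic([[10, 0], [0, 10]])
        assert lrt_statistic([[0, 10], [10, 0]]) == pytest.approx(g)
        assert lrt_statistic([[7, 3], [2, 8]]) == pytest.approx(
            lrt_statistic([[2, 8], [7, 3]])
        )
        assert lrt_statistic([[7, 3], [2, 8]]) == pytest.approx(
            lrt_statistic([[3, 7], [8, 2]])
        )

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            lrt_statistic([[0, 0], [5, 5]])


class TestPermutationPvalue:
    def test_perfect_association_attains_floor(self):
        d = np.array([2] * 20 + [0] * 20)
        mask = np.array([True] * 20 + [False] * 20)
        p, g, _ = permutation_pvalue(d, mask, coding="dominant", n_perm=999, rng=0)
        assert p == pytest.approx(1 / 1000)

    def test_constant_dosage_flagged(self):
        d = np.zeros(10, dtype=int)
        mask = np.array([True] * 5 + [False] * 5)
        with pytest.raises(DegenerateTableError):
            permutation_pvalue(d, mask)

    @pytest.mark.parametrize("coding", ["recessive", "dominant", "allelic"])
    def test_matches_explicit_label_shuffling(self, coding):
        """The hypergeometric sampler must agree with literally permuting
        phenotype labels (independent oracle, same tie convention)."""
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=40)
        mask = np.zeros(40, dtype=bool)
        mask[:15] = True
        n_perm = 4000
        p_fast, g_obs, table = permutation_pvalue(
            d, mask, coding=coding, n_perm=n_perm, rng=1
        )
        count = 0
        for _ in range(n_perm):
            pm = rng.permutation(mask)
            t = genotype_table(d, pm, coding=coding)
            if lrt_statistic(t) >= g_obs - 1e-12:
                count += 1
        p_slow = (1 + count) / (n_perm + 1)
        # both are MC estimates of the same exact p; compare within 4 SE
        se = np.sqrt(p_slow * (1 - p_slow) / n_perm)
        assert abs(p_fast - p_slow) < 4 * se + 2 / n_perm

    def test_null_pvalues_super_uniform(self):
        """Validity: on null data the rejection rate at alpha never exceeds
        alpha by more than Monte-Carlo error (the test may be conservative
        because 2x2 permutation distributions are discrete)."""
        rng = np.random.default_rng(8)
        n, alpha = 400, 0.05
        rej = 0
        tested = 0
        for _ in range(n):
            f = 0.05 + 0.45 * rng.random()
            d = rng.binomial(2, f, size=80)
            mask = np.zeros(80, dtype=bool)
            mask[:30] = True
            try:
                p, _, _ = permutation_pvalue(d, mask, coding="dominant",
                                             n_perm=399, rng=rng)
            except DegenerateTableError:
                continue
            tested += 1
            rej += p <= alpha
        rate = rej / tested
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / tested)


class TestScan:
    def test_bookkeeping(self, default_population):
        g, morphs, truth = default_population
        from mimiclocus.core_io import filter_by_major_allele

        gf = filter_by_major_allele(g)
        results = scan(gf, morphs, ScanConfig(coding="dominant", n_perm=99, seed=0))
        per_morph = results_to_frame(results).groupby("morph").size()
        assert set(per_morph.index) == set(HIERARCHY[1:])  # rank 0 absent
        assert (per_morph == gf.n_sites).all()
        frame = results_to_frame(results)
        tested = frame[frame.tested]
        # Bonferroni multiplier is the per-morph tested-site count
        for morph, grp in tested.groupby("morph"):
            mult = len(grp)
            assert np.allclose(
                grp.p_bonf, np.minimum(1.0, grp.p_perm * mult)
            )

    def test_deterministic_fields_invariant_to_individual_order(self):
        rng = np.random.default_rng(4)
        morphs = table1_morphs()
        inds = list(morphs.morph_of)
        dosage = rng.integers(0, 3, size=(97, 6))
        g1 = make_matrix(dosage, individuals=inds)
        perm = rng.permutation(97)
        g2 = make_matrix(dosage[perm], individuals=[inds[i] for i in perm])
        r1 = scan(g1, morphs, ScanConfig(n_perm=9, seed=0))
        r2 = scan(g2, morphs, ScanConfig(n_perm=9, seed=0))
        for a, b in zip(r1, r2):
            assert a.focal_morph == b.focal_morph and a.site.key == b.site.key
            assert a.tested == b.tested
            if a.tested:
                assert a.G == pytest.approx(b.G)
                assert np.array_equal(a.table, b.table)


class TestFullAssociation:
    def test_reported_with_carriage_above(self):
        morphs = make_morph_table(
            {"a0": "low", "a1": "low", "b0": "mid", "b1": "mid", "c0": "top"},
            ("low", "mid", "top"),
        )
        # site 0: mid-diagnostic allele, carried recessively by the top ind
        dosage = np.array([[0], [0], [1], [2], [1]])
        g = make_matrix(dosage, individuals=["a0", "a1", "b0", "b1", "c0"])
        out = full_association(g, morphs)
        mid = [f for f in out if f.morph == "mid" and f.allele == "G"]
        assert len(mid) == 1
        assert mid[0].carriage_above == ["c0"]

    def test_incomplete_focal_presence_not_reported(self):
        morphs = make_morph_table(
            {"a0": "low", "b0": "mid", "b1": "mid"}, ("low", "mid")
        )
        dosage = np.array([[0], [1], [0]])  # allele absent from one mid ind
        g = make_matrix(dosage, individuals=["a0", "b0", "b1"])
        assert [f for f in full_association(g, morphs) if f.allele == "G"] == []

    def test_lower_rank_carrier_disqualifies(self):
        morphs = make_morph_table(
            {"a0": "low", "a1": "low", "b0": "mid", "b1": "mid"}, ("low", "mid")
        )
        dosage = np.array([[0], [1], [1], [1]])
        g = make_matrix(dosage, individuals=["a0", "a1", "b0", "b1"])
        assert [f for f in full_association(g, morphs) if f.allele == "G"] == []

    def test_planted_diagnostics_recovered(self, default_population):
        from mimiclocus.core_io import filter_by_major_allele

        g, morphs, truth = default_population
        gf = filter_by_major_allele(g)
        found = {
            morph: sorted(
                (f.site.key, f.allele)
                for f in full_association(gf, morphs)
                if f.morph == morph
            )
            for morph in morphs.hierarchy[1:]
        }
        want = {m: sorted(truth.full_assoc[m]) for m in morphs.hierarchy[1:]}
        assert found == want
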