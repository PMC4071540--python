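import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact

from mimiclocus.core_io import DataError, HaplotypeAlignment
from mimiclocus.molevol import (
    HKAInput,
    HKALocus,
    PathwayError,
    apply_jc_correction,
    classify_variation,
    count_sites,
    exclude_duplication_carriers,
    fisher_exact_two_sided,
    harmonic_numbers,
    hka_fit,
    jc_correct,
    mk_test,
    pathway_counts,
    watterson_moments,
    MKCounts,
)

BASES = "ACGT"


def aln(in_seqs, og, locus="L", frame=0):
    return HaplotypeAlignment(
        locus_id=locus,
        in_species={f"h{i}": s for i, s in enumerate(in_seqs)},
        outgroup={"og": og},
        frame=frame,
    )


class TestCountSites:
    def test_tryptophan_fully_nonsynonymous(self):
        assert count_sites("TGG") == (0.0, 3.0)

    def test_glycine_third_position_synonymous(self):
        assert count_sites("GGG") == (1.0, 2.0)

    def test_sites_sum_to_three_for_all_sense_codons(self):
        from Bio.Seq import Seq

        for codon in ("".join(t) for t in itertools.product(BASES, repeat=3)):
            if str(Seq(codon).translate()) == "*":
                continue
            s, n = count_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert 0 <= s <= 3

    @pytest.mark.parametrize("bad", ["TAA", "NGG", "AG", "AGGT"])
    def test_contracts(self, bad):
        with pytest.raises(DataError):
            count_sites(bad)


class TestPathways:
    def test_two_step_average(self):
        # GGG->AGG->AGA and GGG->GGA->AGA: (0s,2n) and (1s,1n)... both legal
        assert pathway_counts("GGG", "AGA") == (1.0, 1.0)

    def test_identity(self):
        assert pathway_counts("ACT", "ACT") == (0.0, 0.0)

    def test_brute_force_enumeration_all_sense_pairs(self):
        """Agree with a brute-force path enumerator on every sense-codon
        pair; pairs whose every pathway crosses a stop must raise."""
        from Bio.Seq import Seq

        table = {
            "".join(t): str(Seq("".join(t)).translate())
            for t in itertools.product(BASES, repeat=3)
        }
        sense = [c for c, a in table.items() if a != "*"]
        n_blocked = 0
        for c1, c2 in itertools.combinations(sense, 2):
            diff = [i for i in range(3) if c1[i] != c2[i]]
            paths = []
            for order in itertools.permutations(diff):
                cur, syn, nonsyn, ok = c1, 0, 0, True
                for pos in order:
                    nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                    if table[nxt] == "*":
                        ok = False
                        break
                    syn += table[nxt] == table[cur]
                    nonsyn += table[nxt] != table[cur]
                    cur = nxt
                if ok:
                    paths.append((syn, nonsyn))
            if not paths:
                n_blocked += 1
                with pytest.raises(PathwayError):
                    pathway_counts(c1, c2)
            else:
                want = (
                    sum(p[0] for p in paths) / len(paths),
                    sum(p[1] for p in paths) / len(paths),
                )
                assert pathway_counts(c1, c2) == pytest.approx(want)
        # every sense-sense pair has at least one stop-free pathway; full
        # blockage only arises against stop-containing hybrid codons
        assert n_blocked == 0

    def test_stop_target_blocks_all_pathways(self):
        with pytest.raises(PathwayError):
            pathway_counts("TAC", "TAA")


class TestClassifyVariation:
    def test_fourfold_fixed_difference(self):
        counts = classify_variation(aln(["GGT", "GGT"], "GGC"))
        assert (counts.Ds, counts.Dn) == (1.0, 0.0)

    def test_identical_alignment_zero(self):
        counts = classify_variation(aln(["ATGAAA"] * 3, "ATGAAA"))
        assert (counts.Pn, counts.Ps, counts.Dn, counts.Ds) == (0, 0, 0, 0)

    def test_polymorphic_site_not_double_counted_as_divergent(self):
        # site segregating in-species AND differing from outgroup counts
        # as polymorphism only
        counts = classify_variation(aln(["GGT", "GGC"], "GGG"))
        assert counts.Ps == 1.0
        assert counts.Ds == 0.0 and counts.Dn == 0.0

    def test_nonsynonymous_polymorphism(self):
        counts = classify_variation(aln(["ATG", "AGG"], "ATG"))
        assert counts.Pn == 1.0 and counts.Ps == 0.0

    def test_order_invariance(self):
        seqs = ["GGTATG", "GGCATG", "GGTAGG"]
        a = classify_variation(aln(seqs, "GGGATG"))
        b = classify_variation(aln(seqs[::-1], "GGGATG"))
        assert (a.Pn, a.Ps, a.Dn, a.Ds) == (b.Pn, b.Ps, b.Dn, b.Ds)

    def test_gap_codons_excluded_and_tallied(self):
        counts = classify_variation(aln(["GGT---", "GGT---"], "GGCAAA"))
        assert counts.excluded_codons == 1
        assert counts.Ds == 1.0
        assert counts.sites_syn + counts.sites_nonsyn == pytest.approx(3.0)

    def test_site_totals_cover_stop_free_cds(self):
        seq = "ATGGCTAAAGGTTGC"
        counts = classify_variation(aln([seq, seq], seq))
        assert counts.sites_syn + counts.sites_nonsyn == pytest.approx(len(seq))


class TestJukesCantor:
    def test_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_closed_form(self):
        assert jc_correct(0.10) == pytest.approx(0.10733, abs=1e-4)

    def test_saturation_domain(self):
        with pytest.raises(DataError):
            jc_correct(0.75)

    def test_monotone_and_above_identity(self):
        grid = np.linspace(0.0, 0.74, 100)
        vals = [jc_correct(d) for d in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(v >= d for v, d in zip(vals, grid))

    def test_corrected_counts_not_below_raw(self):
        c = MKCounts("L", Pn=3, Ps=4, Dn=10, Ds=6, sites_syn=50, sites_nonsyn=150)
        cc = apply_jc_correction(c)
        assert cc.Dn_corrected >= c.Dn and cc.Ds_corrected >= c.Ds


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact_two_sided([[1, 1], [1, 1]]) == 1.0

    def test_matches_exact_fraction_enumeration(self):
        """Independent oracle: exact rational hypergeometric enumeration."""
        def oracle(a, b, c, d):
            r1, r2, c1 = a + b, c + d, a + c
            n = r1 + r2
            den = math.comb(n, c1)
            obs = math.comb(r1, a) * math.comb(r2, c1 - a)
            tot = sum(
                num
                for k in range(max(0, c1 - r2), min(c1, r1) + 1)
                if (num := math.comb(r1, k) * math.comb(r2, c1 - k)) <= obs
            )
            return float(Fraction(tot, den))

        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 20, 4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            assert fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
                oracle(a, b, c, d), abs=1e-12
            )

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            t = rng.integers(0, 25, size=(2, 2))
            if min(t.sum(0).min(), t.sum(1).min()) == 0:
                continue
            assert fisher_exact_two_sided(t) == pytest.approx(
                fisher_exact(t)[1], abs=1e-9
            )

    def test_zero_margin_rejected(self):
        with pytest.raises(DataError):
            fisher_exact_two_sided([[0, 0], [3, 4]])


class TestMKTest:
    def test_excess_nonsynonymous_divergence_detected(self):
        c = MKCounts("en", Pn=2, Ps=10, Dn=30, Ds=5, sites_syn=120, sites_nonsyn=390)
        res = mk_test(c)
        assert res.odds_ratio > 1
        assert res.p_value < 0.001

    def test_corrected_rounding(self):
        c = MKCounts("L", Pn=3, Ps=4, Dn=10, Ds=6, sites_syn=50, sites_nonsyn=150)
        res = mk_test(c, use_corrected=True)
        assert res.table[0, 0] >= 10  # corrected Dn rounded, never below raw

    def test_zero_margin_rejected(self):
        c = MKCounts("L", Pn=0, Ps=0, Dn=3, Ds=4, sites_syn=10, sites_nonsyn=30)
        with pytest.raises(DataError, match="MK undefined"):
            mk_test(c)


class TestWatterson:
    @pytest.mark.parametrize(
        "n, theta, mean, var",
        [(2, 1.0, 1.0, 2.0), (5, 2.0, 4.16667, None), (5, 0.0, 0.0, 0.0)],
    )
    def test_moments(self, n, theta, mean, var):
        m, v = watterson_moments(n, theta)
        assert m == pytest.approx(mean, abs=1e-4)
        if var is not None:
            assert v == pytest.approx(var)

    def test_sample_size_contract(self):
        with pytest.raises(DataError):
            watterson_moments(1, 1.0)


class TestHKA:
    def exact_input(self, thetas, T, n=20):
        a_n, _ = harmonic_numbers(n)
        return HKAInput(
            {
                k: HKALocus(S=t * a_n, D=t * (T + 1), n=n)
                for k, t in thetas.items()
            }
        )

    def test_exact_expectation_recovery(self):
        thetas = {"focal": 4.0, "r1": 7.0, "r2": 2.5}
        res = hka_fit(self.exact_input(thetas, 5.0), "focal", ["r1", "r2"])
        assert res.X2 == pytest.approx(0.0, abs=1e-12)
        assert res.T_hat == pytest.approx(5.0, abs=1e-6)
        for k, t in thetas.items():
            assert res.theta_hat[k] == pytest.approx(t, abs=1e-6)
        assert res.df == 2

    def test_minimize_method_agrees_on_exact_input(self):
        thetas = {"focal": 4.0, "r1": 7.0}
        res = hka_fit(self.exact_input(thetas, 3.0), "focal", ["r1"], method="minimize")
        assert res.X2 == pytest.approx(0.0, abs=1e-10)

    def test_single_locus_rejected(self):
        with pytest.raises(DataError, match="2 loci"):
            hka_fit(self.exact_input({"focal": 4.0}, 5.0), "focal", [])

    def test_excess_focal_polymorphism_inflates_x2(self):
        inp = self.exact_input({"focal": 4.0, "r1": 4.0, "r2": 4.0}, 5.0)
        inflated = HKAInput(dict(inp.loci))
        l = inflated.loci["focal"]
        inflated.loci["focal"] = HKALocus(S=l.S * 4, D=l.D, n=l.n)
        base = hka_fit(inp, "focal", ["r1", "r2"]).X2
        high = hka_fit(inflated, "focal", ["r1", "r2"]).X2
        assert high > base + 1


class TestCarrierExclusion:
    def make(self, n):
        seqs = {f"ind{i:03d}/{k}": "ATGGGT" for i in range(n) for k in (0, 1)}
        return HaplotypeAlignment("L", seqs, {"og": "ATGGGT"})

    def test_prefix_matching_removal(self):
        a = exclude_duplication_carriers(self.make(5), ["ind001", "ind003"])
        assert len(a.in_species) == 6
        assert all(not k.startswith(("ind001", "ind003")) for k in a.in_species)

    def test_empty_set_identity(self):
        a = exclude_duplication_carriers(self.make(3), [])
        assert len(a.in_species) == 6

    def test_removal_below_two_rejected(self):
        with pytest.raises(DataError):
            exclude_duplication_carriers(self.make(2), ["ind000", "ind001"])
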