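"""Simulation-based validation experiments for the analysis stack.

Each function runs a self-contained, seeded experiment — calibration of the
permutation association test on null data, recovery of planted causal
signal, oracle agreement for the composite-LD and Fisher-exact primitives,
neutrality-test calibration, duplication-window sensitivity/specificity,
pedigree crossover recovery, synteny oracle agreement, and pipeline
determinism — and returns plain numbers.  The test suite asserts bands on
these numbers; the acceptance script reports them.
"""

from __future__ import annotations

import itertools
import json
import math
import tempfile
from pathlib import Path

import numpy as np

from mimiclocus import assoc as assoc_mod
from mimiclocus import ld as ld_mod
from mimiclocus import mapping as mapping_mod
from mimiclocus import molevol as M
from mimiclocus import structvar as SV
from mimiclocus.core_io import filter_by_major_allele
from mimiclocus.simulate import (
    SimConfig,
    null_population,
    simulate_brood,
    simulate_locus_coalescent,
    simulate_outgroup_coding,
    simulate_population,
    simulate_reads,
)


def assoc_null_calibration(
    n_sites: int = 500,
    n_perm: int = 999,
    alpha: float = 0.05,
    coding: str = "allelic",
    seed: int = 0,
) -> dict:
    """Per-test rejection rate of the permutation scan on null data.

    Null population: study morph counts, background sites statistically
    independent of morph.  The allelic coding is the default here because
    its permutation distribution has the finest support, so the attainable
    significance levels sit closest to nominal.
    """
    g, morphs, _ = null_population(n_sites=n_sites, seed=seed)
    gf = filter_by_major_allele(g)
    results = assoc_mod.scan(
        gf, morphs, assoc_mod.ScanConfig(coding=coding, n_perm=n_perm, seed=seed)
    )
    tested = [r for r in results if r.tested]
    rate = sum(r.p_perm <= alpha for r in tested) / len(tested)
    return {"rate": rate, "n_tests": len(tested)}


def assoc_recovery(n_reps: int = 50, n_perm: int = 999, seed: int = 0) -> dict:
    """Fraction of replicates in which the strongest-associated site for
    each planted morph (minimum permutation p, ties broken by larger G)
    falls inside the causal locus."""
    hits: dict[str, int] = {}
    morph_list: list[str] = []
    for rep in range(n_reps):
        cfg = SimConfig(seed=seed * 100003 + rep)
        g, morphs, truth = simulate_population(cfg)
        gf = filter_by_major_allele(g)
        results = assoc_mod.scan(
            gf, morphs, assoc_mod.ScanConfig(coding="dominant", n_perm=n_perm, seed=rep)
        )
        top = assoc_mod.top_site_per_morph(results)
        morph_list = morphs.hierarchy[1:]
        for morph in morph_list:
            hits[morph] = hits.get(morph, 0) + (
                top[morph].site.locus_id == truth.causal_locus
            )
    rates = {m: hits[m] / n_reps for m in morph_list}
    return {"min_rate": min(rates.values()), "per_morph": rates, "n_reps": n_reps}


def full_association_exactness(n_seeds: int = 20, seed: int = 0) -> dict:
    """Fraction of seeds on which the full-association detector returns
    exactly the planted diagnostic alleles: no false positives, no misses."""
    exact = 0
    for k in range(n_seeds):
        g, morphs, truth = simulate_population(SimConfig(seed=seed * 100003 + k))
        gf = filter_by_major_allele(g)
        found = {
            morph: sorted(
                (f.site.key, f.allele)
                for f in assoc_mod.full_association(gf, morphs)
                if f.morph == morph
            )
            for morph in morphs.hierarchy[1:]
        }
        want = {m: sorted(truth.full_assoc[m]) for m in morphs.hierarchy[1:]}
        exact += found == want
    return {"exact_fraction": exact / n_seeds, "n_seeds": n_seeds}


def ld_formula_equivalence(n_matrices: int = 1000, seed: int = 0) -> dict:
    """Max |dosage-formula delta - genotype-class count formula| over random
    dosage matrices."""
    rng = np.random.default_rng([seed, 0xA])
    worst = 0.0
    n_defined = 0
    for _ in range(n_matrices):
        n = int(rng.integers(4, 80))
        x = rng.integers(0, 3, n)
        y = rng.integers(0, 3, n)
        d = ld_mod.composite_delta(x, y)
        if np.isnan(d):
            continue
        n_defined += 1
        n_AABB = np.sum((x == 2) & (y == 2))
        n_AABb = np.sum((x == 2) & (y == 1))
        n_AaBB = np.sum((x == 1) & (y == 2))
        n_AaBb = np.sum((x == 1) & (y == 1))
        alt = (2 * n_AABB + n_AABb + n_AaBB + 0.5 * n_AaBb) / n - 2 * (
            x.mean() / 2
        ) * (y.mean() / 2)
        worst = max(worst, abs(d - alt))
    return {"max_abs_diff": worst, "n_defined": n_defined}


def ld_gametic_agreement(n: int = 10000, n_reps: int = 5, seed: int = 0) -> dict:
    """Max |composite r^2 - gametic r^2| on phased-known random-mating
    simulations."""
    rng = np.random.default_rng([seed, 0xB])
    worst = 0.0
    for _ in range(n_reps):
        f = 0.2 + 0.3 * rng.random()
        c = 0.4 + 0.5 * rng.random()
        h1a = (rng.random(n) < f).astype(int)
        h1b = np.where(rng.random(n) < c, h1a, (rng.random(n) < f).astype(int))
        h2a = (rng.random(n) < f).astype(int)
        h2b = np.where(rng.random(n) < c, h2a, (rng.random(n) < f).astype(int))
        r2c = ld_mod.composite_r2(h1a + h2a, h1b + h2b)
        ha = np.concatenate([h1a, h2a]).astype(float)
        hb = np.concatenate([h1b, h2b]).astype(float)
        pa, pb = ha.mean(), hb.mean()
        d = (ha * hb).mean() - pa * pb
        r2g = d * d / (pa * (1 - pa) * pb * (1 - pb))
        worst = max(worst, abs(r2c - r2g))
    return {"max_abs_diff": worst, "n": n, "n_reps": n_reps}


def mk_enumeration_check(max_total: int = 60) -> dict:
    """Max |Fisher two-sided p - exact hypergeometric enumeration| over all
    2x2 tables with positive margins and grand total <= max_total.

    The oracle shares only the tie convention (point probability <= the
    observed one, compared on exact integer numerators) and is computed per
    margin set with prefix sums.
    """
    worst = 0.0
    n_tables = 0
    comb = math.comb
    for n in range(2, max_total + 1):
        for r1 in range(1, n):
            r2 = n - r1
            for c1 in range(1, n):
                k_lo, k_hi = max(0, c1 - r2), min(c1, r1)
                if k_lo > k_hi:
                    continue
                nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)]
                den = comb(n, c1)
                order = sorted(range(len(nums)), key=nums.__getitem__)
                prefix = 0
                p_of = [0.0] * len(nums)
                i = 0
                while i < len(order):
                    j = i
                    tie = 0
                    while j < len(order) and nums[order[j]] == nums[order[i]]:
                        tie += nums[order[j]]
                        j += 1
                    prefix += tie
                    for t in range(i, j):
                        p_of[order[t]] = prefix / den
                    i = j
                for k in range(k_lo, k_hi + 1):
                    a = k
                    b = r1 - k
                    c = c1 - k
                    d = r2 - (c1 - k)
                    impl = M.fisher_exact_two_sided([[a, b], [c, d]])
                    worst = max(worst, abs(impl - p_of[k - k_lo]))
                    n_tables += 1
    return {"max_abs_diff": worst, "n_tables": n_tables}


def mk_neutral_calibration(
    n_loci: int = 1000, length: int = 999, n_haplotypes: int = 20,
    theta: float = 20.0, T: float = 5.0, alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Rejection rate of the MK Fisher test on neutrally simulated loci
    (no excess nonsynonymous fixation)."""
    rng = np.random.default_rng([seed, 0xC])
    rej = 0
    tested = 0
    for _ in range(n_loci):
        aln = simulate_outgroup_coding(
            "L", length, n_haplotypes, theta, T, nonsyn_excess=1.0, rng=rng
        )
        counts = M.classify_variation(aln)
        try:
            res = M.mk_test(counts)
        except Exception:
            continue
        tested += 1
        rej += res.p_value <= alpha
    return {"rate": rej / tested, "n_tested": tested}


def jc_recovery(
    true_d: float = 0.2, n_sites: int = 10000, n_reps: int = 200, seed: int = 0
) -> dict:
    """Recovery of a known evolutionary distance from simulated multiple-hit
    substitution data via the Jukes-Cantor correction."""
    rng = np.random.default_rng([seed, 0xD])
    p_obs_expected = 0.75 * (1.0 - math.exp(-4.0 * true_d / 3.0))
    est = np.empty(n_reps)
    for i in range(n_reps):
        hits = rng.binomial(n_sites, p_obs_expected)
        est[i] = M.jc_correct(hits / n_sites)
    se = est.std(ddof=1) / math.sqrt(n_reps)
    return {
        "mean": float(est.mean()),
        "se": float(se),
        "z": float((est.mean() - true_d) / se),
        "true_d": true_d,
    }


def hka_exact_recovery() -> dict:
    """Parameter recovery on exact-expectation inputs (X^2 must vanish)."""
    thetas = {"focal": 4.0, "r1": 7.0, "r2": 2.5}
    T = 5.0
    a_n, _ = M.harmonic_numbers(20)
    inp = M.HKAInput(
        {k: M.HKALocus(S=t * a_n, D=t * (T + 1), n=20) for k, t in thetas.items()}
    )
    res = M.hka_fit(inp, "focal", ["r1", "r2"])
    max_err = max(
        max(abs(res.theta_hat[k] - t) for k, t in thetas.items()),
        abs(res.T_hat - T),
    )
    return {"X2": res.X2, "max_param_err": max_err}


def hka_null_calibration(
    n_reps: int = 1000, L: int = 5, n: int = 20, theta: float = 5.0,
    T: float = 5.0, alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Rejection rate of the multilocus HKA test on neutral coalescent
    simulations (chi^2 reference is approximate; some conservatism is
    expected)."""
    rng = np.random.default_rng([seed, 0xE])
    rej = 0
    tested = 0
    for _ in range(n_reps):
        loci = {}
        for i in range(L):
            c = simulate_locus_coalescent(theta, n, T, rng)
            loci[f"L{i}"] = M.HKALocus(S=c.S, D=c.D, n=n)
        if any(l.S + l.D <= 0 for l in loci.values()):
            continue
        res = M.hka_fit(M.HKAInput(loci), "L0", [f"L{i}" for i in range(1, L)])
        tested += 1
        rej += res.p_chi2 <= alpha
    return {"rate": rej / tested, "n_tested": tested}


def duplication_metrics(
    n_seeds: int = 3, n_carriers: int = 3, n_noncarriers: int = 3, seed: int = 0
) -> dict:
    """Window sensitivity inside the planted span, fraction of outside /
    diploid windows reaching 3 alleles, and worst per-side segment boundary
    error, at the study's window parameters (150/75), 30x coverage and
    0.5% read error."""
    sens_n = sens_hit = out_n = out_hit = 0
    max_err = 0
    n_segments_expected = 0
    for k in range(n_seeds):
        cfg = SimConfig(seed=seed * 100003 + k)
        g, morphs, truth = simulate_population(cfg)
        carriers = truth.dup_carriers[:n_carriers]
        others = [i for i in g.individuals if i not in set(truth.dup_carriers)]
        assay = carriers + others[:n_noncarriers]
        read_sets = simulate_reads(truth, cfg, individuals=assay)
        lo, hi = cfg.dup_span
        for ind in carriers:
            prof = SV.allele_count_profile(read_sets[ind])
            for w in prof.windows:
                if w.start >= lo and w.end <= hi:
                    sens_n += 1
                    sens_hit += w.count >= 3
                elif w.end <= lo or w.start >= hi:
                    out_n += 1
                    out_hit += w.count >= 3
            segs = SV.call_duplication_segments(prof)
            n_segments_expected += len(segs) == 1
            s = max(segs, key=lambda s: s.n_windows)
            max_err = max(max_err, abs(s.start - lo), abs(s.end - hi))
        for ind in assay[len(carriers):]:
            prof = SV.allele_count_profile(read_sets[ind])
            for w in prof.windows:
                out_n += 1
                out_hit += w.count >= 3
            if SV.call_duplication_segments(prof):
                n_segments_expected -= 1  # false positive call
    return {
        "sensitivity": sens_hit / sens_n,
        "outside_rate": out_hit / out_n,
        "max_boundary_error_bp": max_err,
        "single_segment_calls": n_segments_expected,
        "n_carrier_assays": n_seeds * n_carriers,
    }


def pedigree_recovery(n_broods: int = 20, seed: int = 0) -> dict:
    """Fraction of seeded broods whose planted crossover gap and recombinant
    offspring are recovered exactly."""
    exact = 0
    for k in range(n_broods):
        brood, truth = simulate_brood(
            n_offspring=50, crossover_between=(3, 4), n_recombinants=2,
            seed=seed * 100003 + k,
        )
        iv = mapping_mod.crossover_interval(brood)
        recs = sorted({o for offs in iv.recombinants.values() for o in offs})
        gaps = [tuple(gp) for gp in iv.crossover_gaps]
        exact += truth.crossover_gap in gaps and recs == truth.recombinant_ids
    return {"exact_fraction": exact / n_broods, "n_broods": n_broods}


def synteny_oracle_check(max_n: int = 6) -> dict:
    """Block counts vs the breakpoint-count oracle over all permutations of
    up to max_n genes, plus the identical 24-gene map check."""
    mismatches = 0
    total = 0
    for n in range(2, max_n + 1):
        genes = [chr(65 + i) for i in range(n)]
        a = mapping_mod.GeneOrder("a", [(g, "+") for g in genes])
        for perm in itertools.permutations(genes):
            b = mapping_mod.GeneOrder("b", [(g, "+") for g in perm])
            rank = {g: i for i, g in enumerate(perm)}
            oracle = 1 + sum(
                1 for x, y in zip(genes, genes[1:]) if abs(rank[y] - rank[x]) != 1
            )
            got = mapping_mod.collinear_blocks(a, b).n_blocks
            total += 1
            mismatches += got != oracle
    genes24 = [f"g{i}" for i in range(24)]
    o = mapping_mod.GeneOrder("x", [(g, "+") for g in genes24])
    blocks24 = mapping_mod.collinear_blocks(o, o).n_blocks
    return {
        "oracle_agreement": 1.0 - mismatches / total,
        "n_permutations": total,
        "identical_24_gene_blocks": blocks24,
    }


def pipeline_determinism(seed: int = 0, workdir: str | Path | None = None) -> dict:
    """Run the full pipeline twice with one seed; reports must be
    byte-identical."""
    from mimiclocus.pipeline import RunConfig, run_pipeline

    def run_once(outdir: Path) -> bytes:
        cfg = RunConfig(seed=seed, outdir=str(outdir))
        run_pipeline(cfg)
        return (outdir / "report.json").read_bytes()

    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            a = run_once(Path(tmp) / "a")
            b = run_once(Path(tmp) / "b")
    else:
        workdir = Path(workdir)
        a = run_once(workdir / "a")
        b = run_once(workdir / "b")
    return {"identical": a == b, "report_bytes": len(a)}
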