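"""McDonald-Kreitman and multilocus HKA neutrality tests.

The MK test contrasts nonsynonymous vs synonymous counts between
within-species polymorphism and between-species fixed differences in a 2x2
Fisher exact test.  Synonymous/nonsynonymous site and change counting
follows the Nei-Gojobori convention: per-position fractional site counts
from the nine single-base neighbours of each codon, multi-hit codons
resolved by averaging over minimal mutational pathways with stop-traversing
pathways excluded.  Fixed-difference counts can be corrected for multiple
hits with the Jukes-Cantor distance, applied separately per site class.

The multilocus HKA test compares each locus's synonymous polymorphism (S)
and divergence (D) against shared parameters (a per-locus theta and one
divergence time T) by minimizing the HKA goodness-of-fit statistic

    X^2 = sum_i (S_i - theta_i a_i)^2 / (theta_i a_i + theta_i^2 b_i)
        + sum_i (D_i - theta_i (T+1))^2 / (theta_i (T+1) + theta_i^2)

with a_n = sum_{j<n} 1/j, b_n = sum_{j<n} 1/j^2, referred to chi^2 with
L - 1 degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from mimiclocus.core_io import DataError, HaplotypeAlignment

logger = logging.getLogger(__name__)

BASES = "ACGT"

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Seq import Seq

        for c in ("".join(t) for t in itertools.product(BASES, repeat=3)):
            _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE


def is_stop(codon: str) -> bool:
    return _codon_table()[codon] == "*"


class PathwayError(DataError):
    """All mutational pathways between two codons traverse a stop codon."""


def count_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of a codon.

    Per position the synonymous fraction is the share of single-base
    neighbours encoding the same amino acid; neighbours that create stop
    codons are excluded from both numerator and denominator of that
    position.  The two fractions sum to 3 for any stop-free codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise DataError(f"invalid codon {codon!r}")
    table = _codon_table()
    aa = table[codon]
    if aa == "*":
        raise DataError(f"stop codon {codon!r}")
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if table[alt] == "*":
                continue
            n_valid += 1
            n_syn += table[alt] == aa
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) changes between two codons, averaged over
    all minimal mutational pathways that avoid stop codons.

    Raises :class:`PathwayError` when every pathway traverses a stop.
    """
    c1, c2 = c1.upper(), c2.upper()
    table = _codon_table()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if table[nxt] == "*":
                ok = False
                break
            if table[nxt] == table[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            paths.append((syn, nonsyn))
    if not paths:
        raise PathwayError(f"all pathways {c1}->{c2} traverse stop codons")
    syn = sum(p[0] for p in paths) / len(paths)
    nonsyn = sum(p[1] for p in paths) / len(paths)
    return syn, nonsyn


# ---------------------------------------------------------------------------
# Counting polymorphism and divergence


@dataclass
class MKCounts:
    locus_id: str
    Pn: float
    Ps: float
    Dn: float
    Ds: float
    sites_syn: float
    sites_nonsyn: float
    Dn_corrected: float | None = None
    Ds_corrected: float | None = None
    excluded_codons: int = 0


def _consensus(codons: Sequence[str]) -> str:
    """Majority codon, position-wise; ties broken alphabetically."""
    out = []
    for pos in range(3):
        counts: dict[str, int] = {}
        for c in codons:
            counts[c[pos]] = counts.get(c[pos], 0) + 1
        out.append(max(sorted(counts), key=counts.__getitem__))
    return "".join(out)


def classify_variation(
    a: HaplotypeAlignment, outgroup_mode: str = "first"
) -> MKCounts:
    """Raw MK counts from an aligned set of in-species haplotypes + outgroup.

    Per codon: positions segregating within the in-species set are counted
    as polymorphic; positions monomorphic in-species but differing from the
    outgroup are fixed differences, resolved by pathway averaging within the
    codon.  Sites both polymorphic and divergent count as polymorphic only.
    Codons overlapping gaps or ambiguity codes in any considered sequence
    are excluded entirely and tallied.
    """
    if outgroup_mode not in ("first", "consensus"):
        raise DataError("outgroup_mode must be 'first' or 'consensus'")
    seqs = list(a.in_species.values())
    if outgroup_mode == "first":
        og_seq = next(iter(a.outgroup.values()))
    else:
        ogs = list(a.outgroup.values())
        og_seq = "".join(
            max(sorted({s[i] for s in ogs}), key=lambda b: sum(s[i] == b for s in ogs))
            for i in range(a.length)
        )
    Pn = Ps = Dn = Ds = 0.0
    sites_syn = sites_nonsyn = 0.0
    excluded = 0
    for ci in range(a.n_codons):
        lo = a.frame + 3 * ci
        in_codons = [s[lo : lo + 3] for s in seqs]
        og_codon = og_seq[lo : lo + 3]
        allc = in_codons + [og_codon]
        if any(b not in BASES for c in allc for b in c):
            excluded += 1
            continue
        cons = _consensus(in_codons)
        if is_stop(cons):
            excluded += 1
            logger.warning("%s: consensus stop codon at codon %d excluded", a.locus_id, ci)
            continue
        s_sites, n_sites = count_sites(cons)
        sites_syn += s_sites
        sites_nonsyn += n_sites
        poly_pos = [p for p in range(3) if len({c[p] for c in in_codons}) > 1]
        # polymorphic changes: per segregating position, each non-major state
        # classified in the consensus context
        try:
            for p in poly_pos:
                states = sorted({c[p] for c in in_codons})
                for b in states:
                    if b == cons[p]:
                        continue
                    alt = cons[:p] + b + cons[p + 1 :]
                    syn, nonsyn = pathway_counts(cons, alt)
                    Ps += syn
                    Pn += nonsyn
            # fixed differences: only positions monomorphic in-species
            og_masked = "".join(
                cons[p] if p in poly_pos else og_codon[p] for p in range(3)
            )
            syn, nonsyn = pathway_counts(cons, og_masked)
            Ds += syn
            Dn += nonsyn
        except PathwayError:
            excluded += 1
            sites_syn -= s_sites
            sites_nonsyn -= n_sites
            logger.warning(
                "%s: codon %d excluded (all pathways traverse stops)", a.locus_id, ci
            )
            continue
    return MKCounts(
        locus_id=a.locus_id,
        Pn=Pn,
        Ps=Ps,
        Dn=Dn,
        Ds=Ds,
        sites_syn=sites_syn,
        sites_nonsyn=sites_nonsyn,
        excluded_codons=excluded,
    )


def jc_correct(d_obs: float) -> float:
    """Jukes-Cantor multiple-hit correction -(3/4) ln(1 - 4 d / 3).

    Defined for observed proportions in [0, 0.75); monotone increasing and
    never below the identity on its domain.
    """
    if not (0.0 <= d_obs < 0.75):
        raise DataError(f"JC undefined (saturation) for d = {d_obs}")
    return -0.75 * math.log1p(-4.0 * d_obs / 3.0)


def apply_jc_correction(c: MKCounts) -> MKCounts:
    """JC-correct fixed-difference counts, separately per site class.

    Each class's observed divergence proportion (count over its own site
    total) is corrected and rescaled to a count; corrected counts are never
    below the raw counts.
    """
    if c.sites_nonsyn <= 0 or c.sites_syn <= 0:
        raise DataError(f"{c.locus_id}: no sites to correct")
    dn = jc_correct(c.Dn / c.sites_nonsyn) * c.sites_nonsyn
    ds = jc_correct(c.Ds / c.sites_syn) * c.sites_syn
    return replace(c, Dn_corrected=dn, Ds_corrected=ds)


# ---------------------------------------------------------------------------
# Fisher's exact test (probability-mass two-sided definition)


def fisher_exact_two_sided(table: Sequence[Sequence[float]]) -> float:
    """Two-sided Fisher exact p by the probability-mass method.

    Sums hypergeometric probabilities, at the observed margins, of all
    tables whose point probability does not exceed the observed one.  The
    comparison is done on exact integer numerators (the shared denominator
    C(n, c1) cancels), so ties are handled exactly.
    """
    (a, b), (c, d) = table
    cells = [a, b, c, d]
    if any(x < 0 or x != int(x) for x in cells):
        raise DataError(f"table cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise DataError("degenerate table (zero margin)")
    k_lo, k_hi = max(0, c1 - r2), min(c1, r1)
    nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(k_lo, k_hi + 1)]
    obs = nums[a - k_lo]
    total = sum(num for num in nums if num <= obs)
    return float(Fraction(total, math.comb(n, c1)))


@dataclass
class MKResult:
    locus_id: str
    table: np.ndarray  # [[Dn, Ds], [Pn, Ps]]
    odds_ratio: float
    p_value: float
    corrected: bool


def mk_test(c: MKCounts, use_corrected: bool = False) -> MKResult:
    """McDonald-Kreitman Fisher exact test on [[Dn, Ds], [Pn, Ps]].

    With ``use_corrected`` the JC-corrected fixed-difference counts are
    rounded half-up to integers for the exact test.
    """
    if use_corrected:
        if c.Dn_corrected is None or c.Ds_corrected is None:
            c = apply_jc_correction(c)
        dn = math.floor(c.Dn_corrected + 0.5)
        ds = math.floor(c.Ds_corrected + 0.5)
    else:
        dn, ds = round(c.Dn), round(c.Ds)
    pn, ps = round(c.Pn), round(c.Ps)
    table = np.array([[dn, ds], [pn, ps]], dtype=float)
    if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
        raise DataError(f"{c.locus_id}: MK undefined (zero margin)")
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (dn * ps) / (ds * pn) if ds * pn > 0 else math.inf
    p = fisher_exact_two_sided(table.astype(int))
    return MKResult(c.locus_id, table, float(odds), p, use_corrected)


# ---------------------------------------------------------------------------
# Watterson moments and the multilocus HKA test


def harmonic_numbers(n: int) -> tuple[float, float]:
    """(a_n, b_n) = (sum_{j=1}^{n-1} 1/j, sum_{j=1}^{n-1} 1/j^2)."""
    if n < 2:
        raise DataError(f"sample size {n} < 2")
    j = np.arange(1, n)
    return float((1.0 / j).sum()), float((1.0 / j**2).sum())


def watterson_moments(n: int, theta: float) -> tuple[float, float]:
    """Mean and variance of the segregating-site count S under the neutral
    coalescent: E[S] = theta a_n, Var[S] = theta a_n + theta^2 b_n."""
    if theta < 0:
        raise DataError("theta must be >= 0")
    a_n, b_n = harmonic_numbers(n)
    return theta * a_n, theta * a_n + theta**2 * b_n


@dataclass(frozen=True)
class HKALocus:
    S: float  # synonymous segregating sites
    D: float  # synonymous divergence
    n: int  # in-species sample size (sequences)
    sites: float | None = None  # synonymous site count (informational)

    def __post_init__(self) -> None:
        if self.S < 0 or self.D < 0:
            raise DataError("S and D must be >= 0")
        if self.n < 2:
            raise DataError("sample size < 2")


@dataclass
class HKAInput:
    loci: dict[str, HKALocus]


@dataclass
class HKAResult:
    loci: list[str]
    theta_hat: dict[str, float]
    T_hat: float
    X2: float
    df: int
    p_chi2: float
    a_n: dict[str, float]
    b_n: dict[str, float]


def _hka_x2(theta: np.ndarray, T: float, S, D, a, b) -> float:
    eS = theta * a
    vS = theta * a + theta**2 * b
    eD = theta * (T + 1.0)
    vD = theta * (T + 1.0) + theta**2
    return float(((S - eS) ** 2 / vS).sum() + ((D - eD) ** 2 / vD).sum())


def hka_fit(
    inp: HKAInput,
    focal: str,
    reference: Iterable[str],
    max_iter: int = 500,
    method: str = "moment",
) -> HKAResult:
    """Fit the multilocus HKA system over the focal plus reference loci.

    With ``method="moment"`` (the classic estimator) the parameters solve
    the moment system theta_i = (S_i + D_i)/(a_i + T + 1),
    T = sum(D)/sum(theta) - 1, iterated to convergence, and X^2 is
    evaluated at that solution.  ``method="minimize"`` additionally
    polishes the estimates by numerically minimizing X^2; this shrinks the
    statistic below its chi^2 reference and makes the test conservative,
    so it is not the default.  The p-value refers X^2 to chi^2 with L - 1
    degrees of freedom.
    """
    if method not in ("moment", "minimize"):
        raise DataError("method must be 'moment' or 'minimize'")
    names = [focal] + [r for r in reference if r != focal]
    if len(names) < 2:
        raise DataError("HKA needs at least 2 loci (df = 0 otherwise)")
    missing = [x for x in names if x not in inp.loci]
    if missing:
        raise DataError(f"loci not in HKA input: {missing}")
    loci = [inp.loci[x] for x in names]
    if any(l.S + l.D <= 0 for l in loci):
        raise DataError("every locus must have S + D > 0")
    S = np.array([l.S for l in loci], dtype=float)
    D = np.array([l.D for l in loci], dtype=float)
    ab = [harmonic_numbers(l.n) for l in loci]
    a = np.array([x[0] for x in ab])
    b = np.array([x[1] for x in ab])

    T = max(D.mean() / max(S.mean() / a.mean(), 1e-9) - 1.0, 0.0)
    theta = np.maximum((S + D) / (a + T + 1.0), 1e-9)
    for _ in range(max_iter):
        T_new = max(D.sum() / theta.sum() - 1.0, 0.0)
        theta_new = np.maximum((S + D) / (a + T_new + 1.0), 1e-12)
        if abs(T_new - T) < 1e-12 and np.abs(theta_new - theta).max() < 1e-12:
            theta, T = theta_new, T_new
            break
        theta, T = theta_new, T_new

    theta_hat, T_hat = theta, float(T)
    if method == "minimize":

        def objective(z: np.ndarray) -> float:
            th = np.exp(z[:-1])
            return _hka_x2(th, max(z[-1], 0.0), S, D, a, b)

        z0 = np.concatenate([np.log(theta), [T]])
        res = optimize.minimize(
            objective, z0, method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-12, "fatol": 1e-14},
        )
        if not res.success and res.fun > objective(z0) + 1e-9:
            raise DataError(f"HKA fit did not converge: {res.message}")
        if res.fun <= objective(z0):
            theta_hat = np.exp(res.x[:-1])
            T_hat = max(float(res.x[-1]), 0.0)
    x2 = _hka_x2(theta_hat, T_hat, S, D, a, b)
    df = len(names) - 1
    p = float(stats.chi2.sf(x2, df))
    return HKAResult(
        loci=names,
        theta_hat=dict(zip(names, theta_hat.tolist())),
        T_hat=T_hat,
        X2=x2,
        df=df,
        p_chi2=p,
        a_n=dict(zip(names, a.tolist())),
        b_n=dict(zip(names, b.tolist())),
    )


# ---------------------------------------------------------------------------
# Carrier exclusion


def exclude_duplication_carriers(
    a: HaplotypeAlignment, carriers: Iterable[str]
) -> HaplotypeAlignment:
    """Remove in-species haplotypes belonging to duplication carriers.

    A haplotype is removed when its id, or its id up to a ``/`` separator
    (``ind042/1`` style haplotype naming), is in ``carriers``.  Removal must
    leave at least 2 in-species haplotypes.
    """
    carriers = set(carriers)
    kept = {
        k: v
        for k, v in a.in_species.items()
        if k not in carriers and k.split("/")[0] not in carriers
    }
    if len(kept) < 2:
        raise DataError(
            f"{a.locus_id}: carrier exclusion leaves {len(kept)} haplotype(s)"
        )
    return HaplotypeAlignment(
        locus_id=a.locus_id, in_species=kept, outgroup=dict(a.outgroup), frame=a.frame
    )


def hka_input_from_alignments(
    alignments: Mapping[str, HaplotypeAlignment], outgroup_mode: str = "first"
) -> HKAInput:
    """Synonymous S/D per locus from coding alignments (HKA on synonymous
    sites only): S = synonymous polymorphic changes, D = raw synonymous
    fixed differences."""
    loci = {}
    for locus_id, aln in alignments.items():
        c = classify_variation(aln, outgroup_mode=outgroup_mode)
        loci[locus_id] = HKALocus(
            S=c.Ps, D=c.Ds, n=len(aln.in_species), sites=c.sites_syn
        )
    return HKAInput(loci=loci)
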