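"""Synthetic mimicry-population generator with known ground truth.

Emulates the data structure of a supergene association study in a
polymorphic Batesian mimic: five female morphs in a strict dominance
hierarchy determined by a single polyallelic locus, diagnostic causal SNPs
inside one gene fragment of a multi-locus candidate region, background SNPs
whose association with the causal haplotypes decays with physical distance,
a duplication haplotype linked to one morph and carrying an 8-bp deletion,
coding alignments with outgroup divergence (optionally with excess
nonsynonymous fixation at the causal gene), error-bearing amplicon reads
over the duplicated span, and a pedigree brood with planted crossovers.

All randomness derives from one root seed via fixed-offset substreams, so
identical configurations reproduce byte-identical outputs and toggling one
stage does not shift another's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from mimiclocus.core_io import (
    DataError,
    GenotypeMatrix,
    HaplotypeAlignment,
    MorphTable,
    VariantSite,
    make_morph_table,
)
from mimiclocus.mapping import Offspring, PedigreeBrood
from mimiclocus.structvar import ReadWindowSet

# fixed substream offsets
_POP, _COAL, _ALN, _READS, _BROOD = 11, 23, 37, 47, 59

BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

DEFAULT_HIERARCHY = ("hippocoonides", "cenea", "lamborni", "planemoides", "poultoni")
#: specimen counts per morph, bottom-recessive first
DEFAULT_COUNTS = (28, 21, 20, 5, 23)


@dataclass(frozen=True)
class LocusDef:
    locus_id: str
    length: int
    position: int | None  # position on the candidate-region map; None = unlinked


def default_loci() -> list[LocusDef]:
    """Gene fragments of the candidate region plus four unlinked loci,
    with fragment lengths and map positions modelled on the study design."""
    return [
        LocusDef("MAD", 145, 1000),
        LocusDef("CBP", 162, 46589),
        LocusDef("orange", 129, 133078),
        LocusDef("en_exon1", 513, 192833),
        LocusDef("SCF", 82, 194342),
        LocusDef("en_exon3", 177, 208074),
        LocusDef("inv_exon5", 191, 243505),
        LocusDef("inv_exon1", 335, 286121),
        LocusDef("AR", 192, 311476),
        LocusDef("CbpA", 140, 319618),
        LocusDef("CTD", 119, 337000),
        LocusDef("hyp_protein", 202, 360000),
        LocusDef("dpp", 189, None),
        LocusDef("RpS19", 151, None),
        LocusDef("cdp", 214, None),
        LocusDef("wg", 314, None),
    ]


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic generator.

    ``causal_allele_freqs`` are the population frequencies of the
    morph-determining alleles; when ``None`` they are back-computed from
    the morph sample counts assuming Hardy-Weinberg pairing under the
    dominance hierarchy.  ``planted_carriage`` forces specific higher-morph
    individuals to carry lower-morph alleles recessively (the study-like
    default plants one planemoides and two lamborni alleles in poultoni).
    """

    n_per_morph: tuple[int, ...] = DEFAULT_COUNTS
    hierarchy: tuple[str, ...] = DEFAULT_HIERARCHY
    loci: list[LocusDef] = field(default_factory=default_loci)
    causal_locus: str = "en_exon1"
    causal_allele_freqs: tuple[float, ...] | None = None
    n_diagnostic_per_allele: int = 3
    dup_morph: str = "lamborni"
    dup_linked_loci: tuple[str, ...] = ("inv_exon5", "AR", "CbpA")
    planted_carriage: tuple[tuple[str, str, int], ...] = (
        ("poultoni", "planemoides", 1),
        ("poultoni", "lamborni", 2),
    )
    snp_density: float = 0.06  # background SNPs per bp
    maf_min: float = 0.03  # background derived-frequency spectrum truncation
    ld_decay: float = 0.004  # per-bp decay of haplotype copying probability
    copy_max: float = 0.8  # copying probability at zero distance
    background_theta: float = 5.0  # per-locus scaled mutation rate
    outgroup_T: float = 5.0  # divergence time, coalescent units of 2N
    causal_nonsyn_excess: float = 5.0
    region_length: int = 3000  # amplicon region for read simulation
    dup_span: tuple[int, int] = (900, 2100)
    dup_marker: int = 1500  # start of the 8-bp deletion on the third copy
    het_spacing: int | None = 50  # spacing of haplotype-distinguishing variants
    read_coverage: float = 30.0
    read_length: int = 500
    read_error: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_morph) != len(self.hierarchy):
            raise DataError("n_per_morph and hierarchy lengths differ")
        if any(n < 0 for n in self.n_per_morph):
            raise DataError("morph counts must be >= 0")
        if self.causal_allele_freqs is not None:
            f = self.causal_allele_freqs
            if len(f) != len(self.hierarchy):
                raise DataError("causal_allele_freqs length mismatch")
            if abs(sum(f) - 1.0) > 1e-9 or any(x < 0 for x in f):
                raise DataError("causal_allele_freqs must be >= 0 and sum to 1")
        if not (0 <= self.dup_span[0] < self.dup_span[1] <= self.region_length):
            raise DataError("dup_span outside the read-simulation region")
        if not (self.dup_span[0] <= self.dup_marker <= self.dup_span[1] - 8):
            raise DataError("dup_marker (8-bp deletion) outside dup_span")
        if self.causal_nonsyn_excess < 1:
            raise DataError("causal_nonsyn_excess must be >= 1")
        if self.causal_locus not in {l.locus_id for l in self.loci}:
            raise DataError(f"causal locus {self.causal_locus!r} not in loci")

    def allele_freqs(self) -> np.ndarray:
        if self.causal_allele_freqs is not None:
            return np.asarray(self.causal_allele_freqs, dtype=float)
        return freqs_from_counts(self.n_per_morph)


def freqs_from_counts(n_per_morph: Sequence[int]) -> np.ndarray:
    """Back-compute allele frequencies from morph counts.

    Under random pairing, the probability that an individual's top-ranked
    allele is rank r is C_r^2 - C_{r-1}^2 with C_r the cumulative allele
    frequency; inverting the observed morph proportions gives
    C_r = sqrt(cumulative proportion).
    """
    n = np.asarray(n_per_morph, dtype=float)
    if n.sum() <= 0:
        raise DataError("total sample size must be positive")
    cum = np.sqrt(np.cumsum(n) / n.sum())
    return np.diff(np.concatenate([[0.0], cum]))


@dataclass
class SimTruth:
    """Ground truth of one simulated population."""

    hierarchy: list[str]
    h_alleles: dict[str, tuple[int, int]]  # individual -> (low, high) allele ranks
    diagnostic_sites: dict[tuple[str, int], str]  # site key -> morph
    full_assoc: dict[str, list[tuple[tuple[str, int], str]]]  # morph -> [(key, allele)]
    dup_carriers: list[str]
    causal_locus: str
    dup_span: tuple[int, int]
    dup_marker: int

    def morph_of(self, individual: str) -> str:
        return self.hierarchy[self.h_alleles[individual][1]]


# ---------------------------------------------------------------------------
# Population


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, MorphTable, SimTruth]:
    """Simulate genotypes, morphs and ground truth for one population.

    Each individual draws two alleles of the morph locus conditioned on its
    morph (so realized morph counts match the configuration exactly); each
    allele class deterministically carries its diagnostic causal-site
    alleles; background SNPs copy the causal-haplotype state with
    probability ``copy_max * exp(-ld_decay * distance)`` and otherwise draw
    independently from their background frequency.
    """
    rng = np.random.default_rng([cfg.seed, _POP])
    K = len(cfg.hierarchy)
    p = cfg.allele_freqs()
    for r, (morph, n_m) in enumerate(zip(cfg.hierarchy, cfg.n_per_morph)):
        if n_m > 0 and p[r] <= 0:
            raise DataError(
                f"morph {morph!r} has count {n_m} but allele frequency 0"
            )

    individuals: list[str] = []
    morph_of: dict[str, str] = {}
    pairs: list[tuple[int, int]] = []
    idx = 0
    for r, (morph, n_m) in enumerate(zip(cfg.hierarchy, cfg.n_per_morph)):
        # pair distribution conditioned on the top-ranked allele being r
        lower = np.arange(r)
        w = np.concatenate([2.0 * p[lower] * p[r], [p[r] ** 2]])
        w = w / w.sum()
        for _ in range(n_m):
            ind = f"ind{idx:03d}"
            idx += 1
            individuals.append(ind)
            morph_of[ind] = morph
            other = int(rng.choice(len(w), p=w))
            low = other if other < r else r
            pairs.append((low, r))

    # planted recessive carriage in higher morphs; carriers of different
    # planted alleles are disjoint individuals
    planted: set[int] = set()
    for carrier_morph, allele_morph, count in cfg.planted_carriage:
        cr = cfg.hierarchy.index(carrier_morph)
        ar = cfg.hierarchy.index(allele_morph)
        if ar >= cr:
            raise DataError("planted carriage must be of a lower-ranked allele")
        pool = [
            i
            for i, ind in enumerate(individuals)
            if morph_of[ind] == carrier_morph and i not in planted
        ]
        if count > len(pool):
            raise DataError(f"cannot plant {count} carriers in {carrier_morph}")
        chosen = rng.choice(len(pool), size=count, replace=False)
        for c in sorted(int(x) for x in chosen):
            pairs[pool[c]] = (ar, cr)
            planted.add(pool[c])

    n_ind = len(individuals)
    # chromosome allele classes: shape (n_ind, 2); which copy holds the
    # top-ranked allele is randomized
    chrom_class = np.empty((n_ind, 2), dtype=int)
    for i, (lo, hi) in enumerate(pairs):
        if rng.random() < 0.5:
            chrom_class[i] = (lo, hi)
        else:
            chrom_class[i] = (hi, lo)
    flat_class = chrom_class.reshape(-1)  # 2 * n_ind chromosomes

    loci = {l.locus_id: l for l in cfg.loci}
    causal = loci[cfg.causal_locus]
    if causal.position is None:
        raise DataError("causal locus must have a map position")

    sites: list[VariantSite] = []
    site_class: list[int | None] = []  # diagnostic allele class or None
    site_bg: list[tuple[float, float] | None] = []  # (freq, copy prob) for background
    used: dict[str, set[int]] = {l.locus_id: set() for l in cfg.loci}

    def chrom_of(l: LocusDef) -> str:
        return "Hregion" if l.position is not None else f"unl_{l.locus_id}"

    def locus_pos(l: LocusDef, offset: int) -> int:
        return (l.position if l.position is not None else 0) + offset

    # diagnostic sites for allele classes 1..K-1 inside the causal locus;
    # the bottom-recessive allele is the ancestral haplotype and carries no
    # derived diagnostics
    nd = cfg.n_diagnostic_per_allele
    n_slots = (K - 1) * max(nd, 1) + 2
    slot = 0
    dup_rank = cfg.hierarchy.index(cfg.dup_morph)
    for c in range(1, K):
        for t in range(nd):
            slot += 1
            off = slot * causal.length // n_slots
            used[causal.locus_id].add(off)
            ref = BASES[(slot + 1) % 4]
            alt = BASES[slot % 4] if BASES[slot % 4] != ref else BASES[(slot + 2) % 4]
            sites.append(
                VariantSite(chrom_of(causal), locus_pos(causal, off),
                            causal.locus_id, ref, alt)
            )
            site_class.append(c)
            site_bg.append(None)
    if nd > 0:
        # the 8-bp deletion, diagnostic for the duplication-bearing morph
        slot += 1
        off = slot * causal.length // n_slots
        used[causal.locus_id].add(off)
        sites.append(
            VariantSite(chrom_of(causal), locus_pos(causal, off),
                        causal.locus_id, "ATGCATGCA", "A")
        )
        site_class.append(dup_rank)
        site_bg.append(None)
    # duplication-linked diagnostics outside the causal gene
    for lid in cfg.dup_linked_loci:
        l = loci[lid]
        off = l.length // 2
        used[lid].add(off)
        sites.append(VariantSite(chrom_of(l), locus_pos(l, off), lid, "C", "T"))
        site_class.append(dup_rank)
        site_bg.append(None)

    # background SNPs
    causal_span = (causal.position, causal.position + causal.length)
    for l in cfg.loci:
        n_bg = int(round(l.length * cfg.snp_density)) - len(used[l.locus_id])
        if n_bg <= 0:
            continue
        avail = [o for o in range(l.length) if o not in used[l.locus_id]]
        offs = rng.choice(len(avail), size=n_bg, replace=False)
        for o in sorted(int(avail[i]) for i in offs):
            pos = locus_pos(l, o)
            if l.position is None:
                c_copy = 0.0
            else:
                d = max(causal_span[0] - pos, pos - (causal_span[1] - 1), 0)
                c_copy = cfg.copy_max * math.exp(-cfg.ld_decay * d)
            f = cfg.maf_min * (0.97 / cfg.maf_min) ** rng.random()
            ref = BASES[o % 4]
            alt = BASES[(o + 1 + (pos % 3)) % 4]
            if alt == ref:
                alt = BASES[(o + 2) % 4]
            sites.append(VariantSite(chrom_of(l), pos, l.locus_id, ref, alt))
            site_class.append(None)
            site_bg.append((f, c_copy))

    n_chrom = 2 * n_ind
    alleles = np.zeros((n_chrom, len(sites)), dtype=np.int8)
    for j in range(len(sites)):
        if site_class[j] is not None:
            alleles[:, j] = (flat_class == site_class[j]).astype(np.int8)
        else:
            f, c_copy = site_bg[j]
            profile = (rng.random(K) < f).astype(np.int8)  # per-class state
            # Background variants model polymorphism older than the morph
            # allele radiation: when the derived state rides on any class
            # it also segregates on the ancestral (lowest) classes, so no
            # background variant is morph-private -- morph-private variation
            # is exactly what the planted diagnostics represent.
            if profile.any():
                profile[: min(2, K)] = 1
            copied = rng.random(n_chrom) < c_copy
            background = (rng.random(n_chrom) < f).astype(np.int8)
            alleles[:, j] = np.where(copied, profile[flat_class], background)
    dosage = alleles.reshape(n_ind, 2, -1).sum(axis=1).astype(np.int8)

    g = GenotypeMatrix(sites=sites, individuals=individuals, dosage=dosage)
    m = make_morph_table(morph_of, cfg.hierarchy)

    site_by_key = {s.key: (s, site_class[j]) for j, s in enumerate(sites)}
    diag = {s.key: cfg.hierarchy[c] for j, s in enumerate(sites)
            if (c := site_class[j]) is not None}
    full_assoc: dict[str, list[tuple[tuple[str, int], str]]] = {
        morph: [] for morph in cfg.hierarchy[1:]
    }
    for key, (s, c) in sorted(site_by_key.items()):
        if c is not None and c >= 1:
            full_assoc[cfg.hierarchy[c]].append((key, s.alt_allele))
    truth = SimTruth(
        hierarchy=list(cfg.hierarchy),
        h_alleles={ind: pairs[i] for i, ind in enumerate(individuals)},
        diagnostic_sites=diag,
        full_assoc=full_assoc,
        dup_carriers=[ind for i, ind in enumerate(individuals)
                      if dup_rank in pairs[i]],
        causal_locus=cfg.causal_locus,
        dup_span=cfg.dup_span,
        dup_marker=cfg.dup_marker,
    )
    return g, m, truth


def null_population(
    n_sites: int = 500, seed: int = 0, **overrides
) -> tuple[GenotypeMatrix, MorphTable, SimTruth]:
    """A population with no causal SNPs: background sites are statistically
    independent of morph (zero copying probability, no diagnostics)."""
    total_len = sum(l.length for l in default_loci())
    cfg = SimConfig(
        seed=seed,
        n_diagnostic_per_allele=0,
        dup_linked_loci=(),
        planted_carriage=(),
        copy_max=0.0,
        snp_density=n_sites / total_len,
        **overrides,
    )
    return simulate_population(cfg)


# ---------------------------------------------------------------------------
# Coalescent machinery


def _coalescent_segments(
    n: int, rng: np.random.Generator
) -> tuple[list[frozenset[int]], np.ndarray, float]:
    """Kingman coalescent of n lineages.

    Returns (segment leaf-sets, segment lengths, total tree length); each
    active lineage during the interval with k lineages contributes one
    segment of that interval's duration.
    """
    active: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    seg_sets: list[frozenset[int]] = []
    seg_len: list[float] = []
    total = 0.0
    for k in range(n, 1, -1):
        t = rng.exponential(2.0 / (k * (k - 1)))
        total += k * t
        for lin in active:
            seg_sets.append(lin)
            seg_len.append(t)
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        merged = active[i] | active[j]
        active = [l for a, l in enumerate(active) if a not in (i, j)] + [merged]
    return seg_sets, np.asarray(seg_len), total


@dataclass
class CoalescentLocus:
    S: int
    D: int
    haplotypes: np.ndarray  # (n, S) 0/1 derived-allele matrix
    tree_length: float


def simulate_locus_coalescent(
    theta: float, n: int, T: float, rng: np.random.Generator | int | None = None
) -> CoalescentLocus:
    """Neutral-coalescent segregating sites and outgroup divergence.

    Inter-coalescent times are Exponential(i(i-1)/2) for i = n..2 (units of
    2N generations); S ~ Poisson(theta * L / 2) with L the total tree
    length; divergence D ~ Poisson(theta * (T + W)), W ~ Exponential(1), so
    E[D] = theta (T + 1).  Mutations are placed uniformly on branches to
    emit infinite-sites haplotypes.
    """
    if n < 2:
        raise DataError("coalescent sample size must be >= 2")
    if theta < 0 or T < 0:
        raise DataError("theta and T must be >= 0")
    rng = np.random.default_rng(rng)
    seg_sets, seg_len, total = _coalescent_segments(n, rng)
    S = int(rng.poisson(theta * total / 2.0))
    haps = np.zeros((n, S), dtype=np.int8)
    if S:
        probs = seg_len / seg_len.sum()
        segs = rng.choice(len(seg_sets), size=S, p=probs)
        for s, gi in enumerate(segs):
            haps[list(seg_sets[gi]), s] = 1
    W = rng.exponential(1.0)
    D = int(rng.poisson(theta * (T + W)))
    return CoalescentLocus(S=S, D=D, haplotypes=haps, tree_length=total)


# ---------------------------------------------------------------------------
# Coding alignments with outgroup divergence


def _random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    codons = [c for c in
              ("".join((a, b, c)) for a in BASES for b in BASES for c in BASES)
              if c not in _STOPS]
    # exclude codons one step from a stop being overrepresented is not
    # needed; any stop-free codon is acceptable
    picks = rng.choice(len(codons), size=n_codons)
    return "".join(codons[i] for i in picks)


def _mutation_candidates(seq: str, pos: int, want_syn: bool) -> list[str]:
    """Target bases at ``pos`` that are (non)synonymous in the current codon
    context and do not create a stop codon."""
    from mimiclocus.molevol import _codon_table

    table = _codon_table()
    ci = pos // 3
    codon = seq[3 * ci : 3 * ci + 3]
    if codon in _STOPS or any(b not in BASES for b in codon):
        return []
    off = pos % 3
    out = []
    for b in BASES:
        if b == codon[off]:
            continue
        alt = codon[:off] + b + codon[off + 1 :]
        if table[alt] == "*":
            continue
        if (table[alt] == table[codon]) == want_syn:
            out.append(b)
    return out


def simulate_outgroup_coding(
    locus_id: str,
    length: int,
    n_haplotypes: int,
    theta: float,
    T: float,
    nonsyn_excess: float = 1.0,
    rng: np.random.Generator | int | None = None,
    haplotype_ids: Sequence[str] | None = None,
) -> HaplotypeAlignment:
    """Simulate a coding alignment of in-species haplotypes plus outgroup.

    Synonymous and nonsynonymous mutation supplies are split according to
    the base sequence's fractional site counts; fixed differences are
    placed at a nonsynonymous:synonymous rate ratio scaled by
    ``nonsyn_excess`` (1 = neutral), polymorphic sites follow neutral
    coalescent haplotypes.  Infinite sites: each position mutates at most
    once.
    """
    from mimiclocus.molevol import count_sites

    if length % 3:
        raise DataError(f"locus length {length} not divisible into codons")
    if nonsyn_excess < 1:
        raise DataError("nonsyn_excess must be >= 1")
    rng = np.random.default_rng(rng)
    n_codons = length // 3
    base = _random_coding_sequence(n_codons, rng)

    syn_sites = nonsyn_sites = 0.0
    for ci in range(n_codons):
        s, ns = count_sites(base[3 * ci : 3 * ci + 3])
        syn_sites += s
        nonsyn_sites += ns
    theta_syn = theta * syn_sites / (syn_sites + nonsyn_sites)
    theta_nonsyn = theta * nonsyn_sites / (syn_sites + nonsyn_sites)

    seg_sets, seg_len, total = _coalescent_segments(n_haplotypes, rng)
    W = rng.exponential(1.0)
    n_fix_syn = int(rng.poisson(theta_syn * (T + W)))
    n_fix_nonsyn = int(rng.poisson(nonsyn_excess * theta_nonsyn * (T + W)))
    n_poly_syn = int(rng.poisson(theta_syn * total / 2.0))
    n_poly_nonsyn = int(rng.poisson(theta_nonsyn * total / 2.0))

    in_seqs = [list(base) for _ in range(n_haplotypes)]
    og_seq = list(base)
    used: set[int] = set()

    def place(count: int, want_syn: bool, fixed: bool) -> None:
        placed = 0
        attempts = 0
        while placed < count and attempts < 200 * (count + 1):
            attempts += 1
            pos = int(rng.integers(length))
            if pos in used:
                continue
            context = "".join(og_seq) if fixed else base
            targets = _mutation_candidates(context, pos, want_syn)
            if not targets:
                continue
            b = targets[int(rng.integers(len(targets)))]
            used.add(pos)
            if fixed:
                og_seq[pos] = b
            else:
                probs = seg_len / seg_len.sum()
                gi = int(rng.choice(len(seg_sets), p=probs))
                for leaf in seg_sets[gi]:
                    in_seqs[leaf][pos] = b
            placed += 1

    place(n_fix_syn, want_syn=True, fixed=True)
    place(n_fix_nonsyn, want_syn=False, fixed=True)
    place(n_poly_syn, want_syn=True, fixed=False)
    place(n_poly_nonsyn, want_syn=False, fixed=False)

    if haplotype_ids is None:
        haplotype_ids = [f"hap{i:03d}" for i in range(n_haplotypes)]
    elif len(haplotype_ids) != n_haplotypes:
        raise DataError("haplotype_ids length mismatch")
    return HaplotypeAlignment(
        locus_id=locus_id,
        in_species={hid: "".join(s) for hid, s in zip(haplotype_ids, in_seqs)},
        outgroup={"outgroup": "".join(og_seq)},
        frame=0,
    )


# ---------------------------------------------------------------------------
# Amplicon reads over the duplicated span


def simulate_reads(
    truth: SimTruth,
    cfg: SimConfig,
    individuals: Iterable[str] | None = None,
) -> dict[str, ReadWindowSet]:
    """Simulate aligned amplicon reads per individual.

    Every individual carries two region haplotypes (differing at regularly
    spaced variant positions when ``het_spacing`` is set); duplication
    carriers have a third (tandem-duplicate) copy inside ``dup_span`` with
    private variants and the 8-bp deletion (rendered as ``-`` so coordinates
    stay in the reference frame).  Reads of fixed length start uniformly on
    each template copy and suffer independent per-base substitution errors.
    ``read_coverage`` is the per-base diploid depth: each template copy is
    sequenced at ``coverage / 2``, so the duplicated span shows ~1.5x depth
    in carriers, as real copy-number gains do.
    """
    rng = np.random.default_rng([cfg.seed, _READS])
    L = cfg.region_length
    if cfg.read_length > L:
        raise DataError("read_length exceeds region length")
    if cfg.read_coverage <= 0:
        raise DataError("coverage must be > 0")
    base = "".join(BASES[i] for i in rng.integers(0, 4, size=L))
    hap_a = list(base)
    hap_b = list(base)
    het_positions: list[int] = []
    if cfg.het_spacing:
        for pos in range(cfg.het_spacing // 2, L, cfg.het_spacing):
            hap_b[pos] = _other_base(base[pos])
            het_positions.append(pos)
    span_lo, span_hi = cfg.dup_span
    hap_c = list(hap_a)
    private_positions: list[int] = []
    spacing = cfg.het_spacing or 50
    del_range = range(cfg.dup_marker, cfg.dup_marker + 8)
    for pos in range(span_lo + spacing // 5, span_hi, spacing):
        if pos in del_range or pos in het_positions:
            continue
        hap_c[pos] = _other_base(hap_a[pos])
        private_positions.append(pos)
    for pos in del_range:
        hap_c[pos] = "-"
    variant_positions = sorted(set(het_positions) | set(private_positions) | set(del_range))

    hap_a, hap_b, hap_c = "".join(hap_a), "".join(hap_b), "".join(hap_c)
    if individuals is None:
        individuals = list(truth.h_alleles)
    carriers = set(truth.dup_carriers)
    per_copy = cfg.read_coverage / 2.0 * L / cfg.read_length
    out: dict[str, ReadWindowSet] = {}
    for ind in individuals:
        copies = [hap_a, hap_b] + ([hap_c] if ind in carriers else [])
        n_reads = int(round(per_copy * len(copies)))
        starts = rng.integers(0, L - cfg.read_length + 1, size=n_reads)
        picks = rng.integers(0, len(copies), size=n_reads)
        reads = []
        for s, ci in zip(starts.tolist(), picks.tolist()):
            seq = list(copies[ci][s : s + cfg.read_length])
            if cfg.read_error > 0:
                err = np.flatnonzero(rng.random(cfg.read_length) < cfg.read_error)
                for e in err.tolist():
                    if seq[e] != "-":
                        seq[e] = _other_base(seq[e], rng)
            reads.append((s, s + cfg.read_length, "".join(seq)))
        out[ind] = ReadWindowSet(
            individual=ind,
            reads=reads,
            region_length=L,
            variant_positions=variant_positions,
        )
    return out


def _other_base(b: str, rng: np.random.Generator | None = None) -> str:
    others = [x for x in BASES if x != b]
    if rng is None:
        return others[0]
    return others[int(rng.integers(3))]


# ---------------------------------------------------------------------------
# Pedigree brood


@dataclass
class BroodTruth:
    crossover_gap: tuple[str, str]
    recombinant_ids: list[str]


def simulate_brood(
    n_offspring: int = 50,
    markers: Sequence[str] | None = None,
    crossover_between: tuple[int, int] = (3, 4),
    n_recombinants: int = 2,
    uninformative_markers: Sequence[str] = (),
    seed: int = 0,
) -> tuple[PedigreeBrood, BroodTruth]:
    """Simulate a brood with planted single crossovers.

    The mother (the H-carrying parent) is heterozygous 1/0 at every
    informative marker with allele 1 phased to the H-bearing haplotype; the
    father is homozygous 0/0.  Recombinant offspring carry a single
    crossover between the named adjacent markers on the maternal
    chromosome; H is transmitted with the left block.
    """
    if markers is None:
        markers = [f"M{i + 1}" for i in range(8)]
    markers = list(markers)
    i, j = crossover_between
    if j != i + 1 or not (0 <= i < len(markers) - 1):
        raise DataError("crossover_between must name adjacent marker indices")
    if n_recombinants > n_offspring:
        raise DataError("more recombinants than offspring")
    rng = np.random.default_rng([seed, _BROOD])
    uninformative = set(uninformative_markers)
    mother = {mk: ("0", "0") if mk in uninformative else ("1", "0") for mk in markers}
    father = {mk: ("0", "0") for mk in markers}
    phase = {mk: "0" if mk in uninformative else "1" for mk in markers}

    rec_idx = set(rng.choice(n_offspring, size=n_recombinants, replace=False).tolist())
    offspring = []
    for o in range(n_offspring):
        oid = f"off{o:02d}"
        if o in rec_idx:
            h_carrier = bool(rng.integers(2))
            left = "1" if h_carrier else "0"
            right = "0" if h_carrier else "1"
            maternal = {
                mk: left if k <= i else right for k, mk in enumerate(markers)
            }
        else:
            h_carrier = bool(rng.integers(2))
            maternal = {mk: "1" if h_carrier else "0" for mk in markers}
        for mk in uninformative:
            maternal[mk] = "0"
        offspring.append(
            Offspring(
                id=oid,
                genotypes={mk: (maternal[mk], "0") for mk in markers},
                h_carrier=h_carrier,
            )
        )
    brood = PedigreeBrood(
        markers=markers, mother=mother, father=father,
        offspring=offspring, mother_phase=phase,
    )
    truth = BroodTruth(
        crossover_gap=(markers[i], markers[j]),
        recombinant_ids=sorted(f"off{o:02d}" for o in rec_idx),
    )
    return brood, truth
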