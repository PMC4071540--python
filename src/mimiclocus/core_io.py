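"""Data model, file I/O, allele frequencies and the major-allele SNP filter.

Coordinates are 0-based half-open internally; VCF's 1-based positions are
converted at the boundary.  Genotypes are stored as alt-allele dosages
(0, 1, 2) with ``-1`` marking a missing diploid call.  Missing genotypes are
excluded pairwise per computation, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing diploid genotype.
MISSING = -1


class DataError(ValueError):
    """Raised for malformed or contract-violating input data."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic variant site.

    ``alt_allele`` may be multi-base relative to ``ref_allele`` so that small
    indels (for example an 8-bp deletion segregating with a morph) can be
    carried as ordinary biallelic sites; no left-alignment or normalization
    is performed beyond what the input states.
    """

    chrom: str
    pos: int  # 0-based
    locus_id: str
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise DataError(f"negative position {self.pos} on {self.chrom}")
        if self.ref_allele == self.alt_allele:
            raise DataError(f"ref == alt at {self.chrom}:{self.pos}")
        if not self.locus_id:
            raise DataError(f"empty locus_id at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class GenotypeMatrix:
    """Individuals x sites diploid dosage matrix.

    ``dosage[i, j]`` is the alt-allele count of individual ``i`` at site
    ``j`` (0, 1 or 2), or :data:`MISSING`.  Sites are kept sorted by
    ``(chrom, pos)``.
    """

    sites: list[VariantSite]
    individuals: list[str]
    dosage: np.ndarray  # (n_individuals, n_sites) int8

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n_ind, n_sites = len(self.individuals), len(self.sites)
        if self.dosage.shape != (n_ind, n_sites):
            raise DataError(
                f"dosage shape {self.dosage.shape} != ({n_ind}, {n_sites})"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise DataError(f"invalid dosage values: {np.unique(self.dosage[bad])}")
        # sort by coordinate; split multi-allelic records may share a
        # position and are tie-broken by alt allele
        keys = [(s.chrom, s.pos, s.alt_allele) for s in self.sites]
        if len(set(keys)) != len(keys):
            raise DataError("duplicate site records")
        if any(keys[i] >= keys[i + 1] for i in range(len(keys) - 1)):
            order = sorted(range(len(keys)), key=keys.__getitem__)
            self.sites = [self.sites[i] for i in order]
            self.dosage = self.dosage[:, order]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self) -> dict[tuple[str, int], int]:
        return {s.key: j for j, s in enumerate(self.sites)}

    def subset_sites(self, indices: Sequence[int]) -> "GenotypeMatrix":
        indices = list(indices)
        return GenotypeMatrix(
            sites=[self.sites[j] for j in indices],
            individuals=list(self.individuals),
            dosage=self.dosage[:, indices].copy(),
        )

    def subset_individuals(self, ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = set(ids)
        rows = [i for i, ind in enumerate(self.individuals) if ind in wanted]
        return GenotypeMatrix(
            sites=list(self.sites),
            individuals=[self.individuals[i] for i in rows],
            dosage=self.dosage[rows, :].copy(),
        )


@dataclass
class MorphTable:
    """Individual -> morph mapping plus the morph dominance hierarchy.

    ``rank_of`` assigns each morph a dominance rank, 0 being the bottom
    recessive morph; ranks form a total order with no ties, and an
    individual's phenotype is that of its highest-ranked locus allele.
    """

    morph_of: dict[str, str]
    rank_of: dict[str, int]

    def __post_init__(self) -> None:
        ranks = sorted(self.rank_of.values())
        if ranks != list(range(len(ranks))):
            raise DataError(f"morph ranks must be 0..K-1 without ties, got {ranks}")
        missing = {m for m in self.morph_of.values() if m not in self.rank_of}
        if missing:
            raise DataError(f"morphs not in hierarchy: {sorted(missing)}")

    @property
    def hierarchy(self) -> list[str]:
        """Morph labels in order of increasing dominance."""
        return sorted(self.rank_of, key=self.rank_of.__getitem__)

    def individuals_of(self, morph: str) -> list[str]:
        return [i for i, m in self.morph_of.items() if m == morph]

    def ranks_for(self, individuals: Sequence[str]) -> np.ndarray:
        return np.array([self.rank_of[self.morph_of[i]] for i in individuals])


@dataclass(frozen=True)
class SiteFrequency:
    site: VariantSite
    n_called: int
    p_major: float
    major_is_ref: bool

    def __post_init__(self) -> None:
        if not (0.5 <= self.p_major <= 1.0):
            raise DataError(f"p_major {self.p_major} outside [0.5, 1]")


@dataclass
class HaplotypeAlignment:
    """Per-locus aligned in-species coding haplotypes plus outgroup sequence(s).

    Sequences are phased haplotypes (one sequence per chromosome), aligned to
    equal length; ``frame`` is the codon offset of the first complete codon.
    """

    locus_id: str
    in_species: dict[str, str]
    outgroup: dict[str, str]
    frame: int = 0

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.in_species.values()} | {
            len(s) for s in self.outgroup.values()
        }
        if len(lengths) > 1:
            raise DataError(f"{self.locus_id}: unequal alignment lengths {lengths}")
        if not self.in_species:
            raise DataError(f"{self.locus_id}: no in-species sequences")
        if not self.outgroup:
            raise DataError(f"{self.locus_id}: no outgroup sequences")
        if self.frame not in (0, 1, 2):
            raise DataError(f"{self.locus_id}: frame must be 0, 1 or 2")
        if self.length - self.frame < 3:
            raise DataError(f"{self.locus_id}: fewer than one complete codon")

    @property
    def length(self) -> int:
        return len(next(iter(self.in_species.values())))

    @property
    def n_codons(self) -> int:
        return (self.length - self.frame) // 3


# ---------------------------------------------------------------------------
# VCF I/O


def read_genotypes(path: str | Path, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF into a :class:`GenotypeMatrix`.

    The ``LOCUS`` INFO field, when present, supplies the gene-fragment label;
    otherwise the contig name is used.  Multi-allelic records are rejected
    unless ``split_multiallelic`` is set, in which case each alt allele
    becomes its own biallelic site.

    Raises
    ------
    DataError
        On non-diploid genotypes or multi-allelic records (by default).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise DataError(f"cannot parse VCF {path}: {exc}") from exc

    individuals = list(vcf.samples)
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 and not split_multiallelic:
            raise DataError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                "(use split_multiallelic=True to split)"
            )
        locus = rec.INFO.get("LOCUS") or rec.CHROM
        gts = rec.genotypes  # [[a1, a2, phased], ...]
        for g in gts:
            if len(g) != 3:  # alleles + phase flag
                raise DataError(
                    f"non-diploid genotype at {rec.CHROM}:{rec.POS}"
                )
        for alt_idx, alt in enumerate(alts, start=1):
            dos = np.full(len(individuals), MISSING, dtype=np.int8)
            for i, g in enumerate(gts):
                a1, a2 = g[0], g[1]
                if a1 < 0 or a2 < 0:
                    continue
                dos[i] = int(a1 == alt_idx) + int(a2 == alt_idx)
            sites.append(
                VariantSite(
                    chrom=rec.CHROM,
                    pos=rec.POS - 1,  # to 0-based
                    locus_id=str(locus),
                    ref_allele=rec.REF,
                    alt_allele=alt,
                )
            )
            columns.append(dos)
    dosage = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(individuals), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(sites=sites, individuals=individuals, dosage=dosage)
    logger.info("read %d sites x %d individuals from %s", gm.n_sites, gm.n_individuals, path)
    return gm


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` as a plain-text VCF 4.2 file."""
    path = Path(path)
    contigs = []
    for s in g.sites:
        if s.chrom not in contigs:
            contigs.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=LOCUS,Number=1,Type=String,Description="Gene fragment">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individuals)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, s in enumerate(g.sites):
            gts = "\t".join(gt_map[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\t.\t"
                f"LOCUS={s.locus_id}\tGT\t{gts}\n"
            )
    logger.info("wrote %d sites to %s", g.n_sites, path)


# ---------------------------------------------------------------------------
# Phenotypes


def read_phenotypes(path: str | Path, hierarchy: Sequence[str]) -> MorphTable:
    """Read an (individual, morph) TSV and attach a dominance hierarchy.

    ``hierarchy`` lists morphs in order of increasing dominance; ranks are
    assigned 0..K-1 in that order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "individual" not in cols or "morph" not in cols:
        raise DataError(f"{path}: need columns 'individual' and 'morph'")
    inds = df[cols["individual"]].tolist()
    morphs = df[cols["morph"]].tolist()
    if len(set(inds)) != len(inds):
        dupes = sorted({i for i in inds if inds.count(i) > 1})
        raise DataError(f"duplicate individuals in phenotype table: {dupes}")
    return make_morph_table(dict(zip(inds, morphs)), hierarchy)


def make_morph_table(morph_of: Mapping[str, str], hierarchy: Sequence[str]) -> MorphTable:
    unknown = sorted(set(morph_of.values()) - set(hierarchy))
    if unknown:
        raise DataError(f"morphs not in hierarchy: {unknown}")
    if len(set(hierarchy)) != len(hierarchy):
        raise DataError("hierarchy contains duplicate morphs")
    rank_of = {m: r for r, m in enumerate(hierarchy)}
    return MorphTable(morph_of=dict(morph_of), rank_of=rank_of)


# ---------------------------------------------------------------------------
# Allele frequencies and the SNP inclusion filter


def allele_frequencies(g: GenotypeMatrix) -> list[SiteFrequency]:
    """Per-site major-allele frequencies over called chromosomes.

    The frequency denominator is twice the number of individuals with a
    non-missing call (chromosome counting).  When p_ref = p_alt = 0.5 the
    reference allele is deemed major (deterministic tie-break).
    """
    out: list[SiteFrequency] = []
    for j, site in enumerate(g.sites):
        col = g.dosage[:, j]
        called = col != MISSING
        n_called = int(called.sum())
        if n_called == 0:
            raise DataError(f"all genotypes missing at {site.chrom}:{site.pos}")
        p_alt = float(col[called].sum()) / (2 * n_called)
        major_is_ref = p_alt <= 0.5
        out.append(
            SiteFrequency(
                site=site,
                n_called=n_called,
                p_major=max(p_alt, 1.0 - p_alt),
                major_is_ref=major_is_ref,
            )
        )
    return out


def filter_by_major_allele(g: GenotypeMatrix, threshold: float = 0.97) -> GenotypeMatrix:
    """Retain exactly the sites whose major-allele frequency is < ``threshold``.

    The comparison is strict: a site at exactly the threshold is removed, so
    the default keeps sites with major-allele relative frequency below 0.97.
    """
    if not (0.5 < threshold <= 1.0):
        raise DataError(f"threshold {threshold} outside (0.5, 1]")
    freqs = allele_frequencies(g)
    keep = [j for j, f in enumerate(freqs) if f.p_major < threshold]
    out = g.subset_sites(keep)
    logger.info(
        "major-allele filter (<%g): kept %d / %d sites", threshold, out.n_sites, g.n_sites
    )
    return out


# ---------------------------------------------------------------------------
# Alignments


def read_alignment(
    path: str | Path,
    locus_id: str,
    outgroup_ids: Iterable[str],
    frame: int = 0,
) -> HaplotypeAlignment:
    """Read an aligned FASTA and partition into in-species and outgroup sets."""
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    outgroup_ids = set(outgroup_ids)
    missing = outgroup_ids - set(records)
    if missing:
        raise DataError(f"outgroup ids not found in {path}: {sorted(missing)}")
    outgroup = {k: v for k, v in records.items() if k in outgroup_ids}
    in_species = {k: v for k, v in records.items() if k not in outgroup_ids}
    return HaplotypeAlignment(
        locus_id=locus_id, in_species=in_species, outgroup=outgroup, frame=frame
    )
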