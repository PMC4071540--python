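"""Pedigree co-segregation mapping and gene-order collinearity.

Co-segregation scoring tracks, for every marker informative in the
H-carrying parent, whether the marker allele each offspring received is the
one phased with the major-locus (H) allele that its phenotype implies it
inherited.  Discordant offspring mark crossovers; the locus is localized to
the maximal block of markers concordant in all offspring, bounded by the
nearest flanking discordant markers.

Collinearity compares two species' gene orders restricted to their shared
genes: maximal runs in which the relative order (and optionally relative
orientation) is preserved form synteny blocks; breakpoints separate blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from mimiclocus.core_io import DataError


@dataclass
class Offspring:
    id: str
    genotypes: dict[str, tuple[str, str]]
    h_carrier: bool  # phenotype-implied: inherited the maternal H allele


@dataclass
class PedigreeBrood:
    """A single brood with the H-carrying parent labelled 'mother'.

    ``mother_phase`` gives, per marker, the allele on the mother's
    H-bearing haplotype; when ``None`` the phase is inferred from the
    non-recombinant majority during scoring.
    """

    markers: list[str]  # ordered by map position
    mother: dict[str, tuple[str, str]]
    father: dict[str, tuple[str, str]]
    offspring: list[Offspring]
    mother_phase: dict[str, str] | None = None


@dataclass
class CosegregationTable:
    markers: list[str]  # informative markers, map order
    discordant: dict[str, list[str]]  # marker -> discordant offspring ids
    uninformative: list[str]
    ambiguous: dict[str, list[str]]  # marker -> offspring with ambiguous transmission
    phase: dict[str, str]


@dataclass
class CrossoverInterval:
    """Localization of the phenotype-determining locus.

    ``left_marker``/``right_marker`` bound the maximal all-concordant block;
    an open flag marks a map end reached without observing discordance.
    ``crossover_gaps`` lists the adjacent-marker pairs (last concordant,
    first discordant) in which crossovers were localized.
    """

    left_marker: str
    right_marker: str
    left_open: bool
    right_open: bool
    crossover_gaps: list[tuple[str, str]]
    recombinants: dict[str, list[str]]
    resolved: bool


def _transmitted_maternal(
    mother: tuple[str, str], father: tuple[str, str], child: tuple[str, str]
) -> set[str]:
    """Maternal alleles consistent with the trio at one marker."""
    out = set()
    child_ms = sorted(child)
    for m in set(mother):
        for f in set(father):
            if sorted((m, f)) == child_ms:
                out.add(m)
    return out


def score_cosegregation(b: PedigreeBrood) -> CosegregationTable:
    """Per-marker concordance of transmitted maternal alleles with the
    phenotype-implied H transmission.

    Markers at which the mother is homozygous are uninformative and are
    flagged and excluded.  Offspring genotypes inconsistent with the
    parents raise an error naming offspring and marker.
    """
    informative = []
    uninformative = []
    for mk in b.markers:
        if b.mother[mk][0] == b.mother[mk][1]:
            uninformative.append(mk)
        else:
            informative.append(mk)

    transmitted: dict[str, dict[str, str]] = {mk: {} for mk in informative}
    ambiguous: dict[str, list[str]] = {mk: [] for mk in informative}
    for off in b.offspring:
        for mk in informative:
            alleles = _transmitted_maternal(b.mother[mk], b.father[mk], off.genotypes[mk])
            if not alleles:
                raise DataError(
                    f"offspring {off.id} genotype at {mk} is not Mendel-consistent"
                )
            if len(alleles) > 1:
                ambiguous[mk].append(off.id)
            else:
                transmitted[mk][off.id] = next(iter(alleles))

    if b.mother_phase is not None:
        phase = {mk: b.mother_phase[mk] for mk in informative}
    else:
        # infer from the non-recombinant majority among H-carriers
        phase = {}
        for mk in informative:
            votes: dict[str, int] = {}
            for off in b.offspring:
                al = transmitted[mk].get(off.id)
                if al is None:
                    continue
                want = al if off.h_carrier else _other(b.mother[mk], al)
                votes[want] = votes.get(want, 0) + 1
            phase[mk] = max(sorted(votes), key=votes.__getitem__)

    discordant: dict[str, list[str]] = {mk: [] for mk in informative}
    for off in b.offspring:
        for mk in informative:
            al = transmitted[mk].get(off.id)
            if al is None:
                continue
            expected = phase[mk] if off.h_carrier else _other(b.mother[mk], phase[mk])
            if al != expected:
                discordant[mk].append(off.id)
    return CosegregationTable(
        markers=informative,
        discordant=discordant,
        uninformative=uninformative,
        ambiguous=ambiguous,
        phase=phase,
    )


def _other(genotype: tuple[str, str], allele: str) -> str:
    a, b = genotype
    return b if allele == a else a


def crossover_interval(b: PedigreeBrood, table: CosegregationTable | None = None) -> CrossoverInterval:
    """Localize the locus to the maximal all-concordant marker block.

    Every offspring's discordance pattern must be consistent with a single
    crossover: its discordant markers must form a contiguous run touching
    one end of the informative-marker map.  Boundaries of the returned
    interval are the nearest flanking markers showing any discordance, or
    the map ends (flagged open).
    """
    table = table or score_cosegregation(b)
    mks = table.markers
    if not mks:
        raise DataError("no informative markers")
    index = {mk: i for i, mk in enumerate(mks)}

    by_off: dict[str, list[int]] = {}
    for mk, offs in table.discordant.items():
        for o in offs:
            by_off.setdefault(o, []).append(index[mk])
    for off, idxs in by_off.items():
        idxs = sorted(idxs)
        contiguous = idxs == list(range(idxs[0], idxs[-1] + 1))
        touches_end = idxs[0] == 0 or idxs[-1] == len(mks) - 1
        if not (contiguous and touches_end):
            raise DataError(
                f"offspring {off}: non-single-crossover discordance pattern "
                f"at marker indices {idxs}"
            )

    concordant = [i for i, mk in enumerate(mks) if not table.discordant[mk]]
    if len(concordant) == len(mks):
        return CrossoverInterval(
            left_marker=mks[0], right_marker=mks[-1],
            left_open=True, right_open=True,
            crossover_gaps=[], recombinants={}, resolved=False,
        )
    if not concordant:
        raise DataError("no marker concordant in all offspring")
    if concordant != list(range(concordant[0], concordant[-1] + 1)):
        raise DataError("all-concordant markers are not contiguous")
    lo, hi = concordant[0], concordant[-1]
    gaps = []
    if lo > 0:
        gaps.append((mks[lo], mks[lo - 1]))
    if hi < len(mks) - 1:
        gaps.append((mks[hi], mks[hi + 1]))
    recombinants = {mk: list(v) for mk, v in table.discordant.items() if v}
    return CrossoverInterval(
        left_marker=mks[lo - 1] if lo > 0 else mks[0],
        right_marker=mks[hi + 1] if hi < len(mks) - 1 else mks[-1],
        left_open=lo == 0,
        right_open=hi == len(mks) - 1,
        crossover_gaps=gaps,
        recombinants=recombinants,
        resolved=True,
    )


# ---------------------------------------------------------------------------
# Gene-order collinearity


@dataclass
class GeneOrder:
    species: str
    genes: list[tuple[str, str]]  # (gene id, strand '+'/'-'/'')

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.genes]
        if len(set(ids)) != len(ids):
            raise DataError(f"{self.species}: duplicate gene ids")

    @property
    def ids(self) -> list[str]:
        return [g for g, _ in self.genes]


@dataclass
class SyntenyBlocks:
    blocks: list[list[str]]
    shared_genes: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_breakpoints(self) -> int:
        return max(0, len(self.blocks) - 1)


def collinear_blocks(a: GeneOrder, b: GeneOrder, use_strand: bool = False) -> SyntenyBlocks:
    """Maximal order-preserved runs of the shared genes of two gene maps.

    Both orders are restricted to their shared genes.  A block extends while
    consecutive genes in ``a`` are also consecutive in ``b``, in the same
    order (step +1) or reversed (step -1, an inverted segment); with
    ``use_strand`` a same-order step additionally requires both genes to
    keep their orientation and a reversed step requires both to flip.
    Within a block the run direction can never conflict: a permutation
    cannot produce a +1 step followed by a -1 step without revisiting a
    rank.
    """
    shared = [g for g in a.ids if g in set(b.ids)]
    if not shared:
        raise DataError("no shared genes between gene orders")
    shared_set = set(shared)
    b_rank = {g: i for i, g in enumerate(g for g in b.ids if g in shared_set)}
    strand_a = {g: s for g, s in a.genes}
    strand_b = {g: s for g, s in b.genes}

    def flipped(g: str) -> bool:
        return strand_a[g] != strand_b[g]

    blocks: list[list[str]] = [[shared[0]]]
    for prev, cur in zip(shared, shared[1:]):
        step = b_rank[cur] - b_rank[prev]
        if step == 1:
            ok = not use_strand or (not flipped(prev) and not flipped(cur))
        elif step == -1:
            ok = not use_strand or (flipped(prev) and flipped(cur))
        else:
            ok = False
        if ok:
            blocks[-1].append(cur)
        else:
            blocks.append([cur])
    return SyntenyBlocks(blocks=blocks, shared_genes=len(shared))


# ---------------------------------------------------------------------------
# I/O


def read_gene_order(path: str | Path, species: str | None = None) -> GeneOrder:
    """Read a gene order from BED (chrom start end name [score strand]) or a
    TSV with columns gene[, strand] in map order."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first and first.split("\t")[1].strip().isdigit():
        cols = ["chrom", "start", "end", "name", "score", "strand"]
        df = pd.read_csv(path, sep="\t", header=None, names=cols[: len(first.split('\t'))])
        df = df.sort_values(["chrom", "start"], kind="stable")
        genes = [
            (str(r.name_), str(getattr(r, "strand", "")))
            for r in df.rename(columns={"name": "name_"}).itertuples()
        ]
    else:
        df = pd.read_csv(path, sep="\t")
        strand_col = "strand" if "strand" in df.columns else None
        genes = [
            (str(g), str(df[strand_col][i]) if strand_col else "")
            for i, g in enumerate(df["gene"])
        ]
    return GeneOrder(species=species or path.stem, genes=genes)


def read_brood_tsv(
    path: str | Path,
    markers: Sequence[str],
    mother: dict[str, tuple[str, str]],
    father: dict[str, tuple[str, str]],
    mother_phase: dict[str, str] | None = None,
) -> PedigreeBrood:
    """Read offspring rows (id, h_carrier, one 'a/b' genotype column per
    marker) and assemble a brood."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    offspring = []
    for row in df.itertuples():
        genos = {}
        for mk in markers:
            a, b = str(getattr(row, mk)).split("/")
            genos[mk] = (a, b)
        offspring.append(
            Offspring(
                id=str(row.id),
                genotypes=genos,
                h_carrier=str(row.h_carrier).lower() in ("1", "true", "h"),
            )
        )
    return PedigreeBrood(
        markers=list(markers), mother=mother, father=father,
        offspring=offspring, mother_phase=mother_phase,
    )
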