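"""Sliding-window distinct-allele counting and duplication-segment calling.

A tandem duplication carried on one chromosome puts three haplotype copies
of the duplicated span into a diploid individual, so deep amplicon reads
show three distinct local haplotypes inside the span and at most two
outside it.  Windows (150 bp, shifted by 75 bp by default) tile the region;
within each window, reads that fully span it are reduced to their bases at
the window's variant positions (or the full window sequence when none are
provided), identical strings are clustered, and clusters passing a
read-support threshold count as alleles.

This is a deliberately simple support-threshold cluster counter standing in
for full probabilistic read-error correction; its error tolerance comes
from requiring both a minimum read count and a minimum read fraction per
cluster, and is validated by sensitivity/specificity properties on
simulated reads.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from mimiclocus.core_io import DataError

logger = logging.getLogger(__name__)


@dataclass
class ReadWindowSet:
    """Reads aligned to a region for one individual.

    Reads are (start, end, sequence) in 0-based half-open region
    coordinates; aligned deletions may be represented with ``-`` characters
    so that coordinates stay in the reference frame.
    """

    individual: str
    reads: list[tuple[int, int, str]]
    region_length: int
    variant_positions: list[int] | None = None

    def __post_init__(self) -> None:
        for start, end, seq in self.reads:
            if not (0 <= start < end <= self.region_length):
                raise DataError(
                    f"{self.individual}: read [{start}, {end}) outside region "
                    f"[0, {self.region_length})"
                )
            if end - start != len(seq):
                raise DataError(
                    f"{self.individual}: read span {end - start} != sequence "
                    f"length {len(seq)}"
                )


@dataclass
class WindowCount:
    start: int
    end: int
    count: int
    n_spanning: int
    supported: list[str] = field(default_factory=list)
    flag: str = ""


@dataclass
class AlleleCountProfile:
    individual: str
    windows: list[WindowCount]
    size: int
    shift: int


@dataclass
class DuplicationSegment:
    individual: str
    start: int
    end: int
    max_alleles: int
    n_windows: int


def window_haplotypes(
    rws: ReadWindowSet,
    window: tuple[int, int],
    min_reads: int = 3,
    min_fraction: float = 0.05,
) -> list[str]:
    """Supported haplotype strings within one window.

    Only reads fully spanning the window are used.  Each read is reduced to
    its bases at the window's variant positions when ``variant_positions``
    is set, otherwise to its full window subsequence.  Identical strings are
    clustered; a cluster is supported when it holds at least ``min_reads``
    reads and at least ``min_fraction`` of the spanning reads.
    """
    w_start, w_end = window
    if not (0 <= w_start < w_end <= rws.region_length):
        raise DataError(f"window [{w_start}, {w_end}) outside region")
    if rws.variant_positions is not None:
        positions = [p for p in rws.variant_positions if w_start <= p < w_end]
    else:
        positions = None
    strings: list[str] = []
    for start, end, seq in rws.reads:
        if start > w_start or end < w_end:
            continue
        if positions is None:
            strings.append(seq[w_start - start : w_end - start])
        else:
            strings.append("".join(seq[p - start] for p in positions))
    if not strings:
        return []
    counts = Counter(strings)
    n = len(strings)
    supported = [
        s
        for s, c in counts.items()
        if c >= min_reads and c / n >= min_fraction
    ]
    return sorted(supported)


def allele_count_profile(
    rws: ReadWindowSet,
    size: int = 150,
    shift: int = 75,
    min_reads: int = 3,
    min_fraction: float = 0.05,
) -> AlleleCountProfile:
    """Distinct supported-allele counts over a sliding window grid.

    Windows are anchored at the region start and advance by ``shift``; a
    final partial window is dropped.  Windows with no spanning reads get
    count 0 and a "no coverage" flag.
    """
    if rws.region_length < size:
        raise DataError(
            f"region length {rws.region_length} shorter than window size {size}"
        )
    if size < shift:
        logger.info("window size %d < shift %d: windows leave gaps", size, shift)
    windows: list[WindowCount] = []
    start = 0
    while start + size <= rws.region_length:
        w = (start, start + size)
        n_spanning = sum(1 for s, e, _ in rws.reads if s <= start and e >= start + size)
        supported = window_haplotypes(rws, w, min_reads=min_reads, min_fraction=min_fraction)
        windows.append(
            WindowCount(
                start=start,
                end=start + size,
                count=len(supported),
                n_spanning=n_spanning,
                supported=supported,
                flag="" if n_spanning else "no coverage",
            )
        )
        start += shift
    return AlleleCountProfile(individual=rws.individual, windows=windows, size=size, shift=shift)


def call_duplication_segments(
    profile: AlleleCountProfile,
    min_alleles: int = 3,
    min_windows: int = 2,
    max_gap: int = 2,
) -> list[DuplicationSegment]:
    """Merge runs of windows with at least ``min_alleles`` supported alleles
    into duplication segments.

    Runs separated by at most ``max_gap`` non-qualifying windows are bridged:
    read-support dropouts inside a real duplication are expected at finite
    coverage, and because consecutive windows share reads a local coverage
    trough knocks out up to size/shift (= 2 by default) adjacent windows.
    A segment must contain at least ``min_windows`` qualifying windows and
    always starts and ends on a qualifying window.
    """
    qual = [i for i, w in enumerate(profile.windows) if w.count >= min_alleles]
    segments: list[DuplicationSegment] = []
    group: list[int] = []

    def close_group() -> None:
        if len(group) >= min_windows:
            ws = [profile.windows[i] for i in range(group[0], group[-1] + 1)]
            segments.append(
                DuplicationSegment(
                    individual=profile.individual,
                    start=profile.windows[group[0]].start,
                    end=profile.windows[group[-1]].end,
                    max_alleles=max(w.count for w in ws),
                    n_windows=len(group),
                )
            )

    for i in qual:
        if group and i - group[-1] > max_gap + 1:
            close_group()
            group = []
        group.append(i)
    close_group()
    return segments


# ---------------------------------------------------------------------------
# I/O


def read_aligned_tsv(path: str | Path, individual: str, region_length: int,
                     variant_positions: Sequence[int] | None = None) -> ReadWindowSet:
    """Read aligned reads from a TSV with columns start, end, sequence."""
    df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int, "sequence": str})
    reads = [(int(r.start), int(r.end), str(r.sequence)) for r in df.itertuples()]
    return ReadWindowSet(
        individual=individual,
        reads=reads,
        region_length=region_length,
        variant_positions=list(variant_positions) if variant_positions is not None else None,
    )


def read_aligned_sam(path: str | Path, individual: str,
                     variant_positions: Sequence[int] | None = None) -> ReadWindowSet:
    """Read aligned reads for a single-reference SAM file.

    Deletions in the CIGAR are rendered as ``-`` runs so read strings stay
    in reference coordinates; insertions and clipped bases are dropped.
    """
    import pysam

    with pysam.AlignmentFile(str(path), "r") as sam:
        if sam.nreferences != 1:
            raise DataError(f"{path}: expected a single reference sequence")
        region_length = sam.lengths[0]
        reads: list[tuple[int, int, str]] = []
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            seq = []
            qpos = 0
            for op, length in rec.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    seq.append(rec.query_sequence[qpos : qpos + length])
                    qpos += length
                elif op == 1:  # I: insertion to reference, drop
                    qpos += length
                elif op == 2:  # D: deletion, pad in reference frame
                    seq.append("-" * length)
                elif op == 4:  # soft clip
                    qpos += length
            s = "".join(seq)
            reads.append((rec.reference_start, rec.reference_start + len(s), s))
    return ReadWindowSet(
        individual=individual,
        reads=reads,
        region_length=region_length,
        variant_positions=list(variant_positions) if variant_positions is not None else None,
    )


def write_profile_tsv(profile: AlleleCountProfile, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"start": w.start, "end": w.end, "count": w.count,
             "n_spanning": w.n_spanning, "flag": w.flag}
            for w in profile.windows
        ]
    ).to_csv(path, sep="\t", index=False)


def write_segments_bed(segments: Sequence[DuplicationSegment], path: str | Path,
                       region_name: str = "region") -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(
                f"{region_name}\t{seg.start}\t{seg.end}\t"
                f"{seg.individual}\t{seg.max_alleles}\n"
            )
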