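"""Reduce alignments to 5' ends and count them per gene locus and super-exon union.

Each aligned record is collapsed to the genomic position of its 5' end —
the leftmost aligned base for plus-strand (or unstranded) alignments, the
rightmost for minus-strand ones.  For every gene locus we count the ends
falling anywhere in the locus span and those falling inside the super-exon
union; their difference is the intronic count.  A 5' end inside several
overlapping loci contributes to each of them, since every gene is counted
independently.

Alignments may come from BED6 files (one record per aligned mate, taken at
face value) or SAM/BAM (secondary, supplementary and unmapped records are
skipped; optionally only first mates are counted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .gene_models import GeneLocus, GenomicInterval

__all__ = [
    "ReadEnd",
    "EndCount",
    "five_prime_end",
    "count_ends_for_gene",
    "count_all",
    "read_bed_ends",
    "read_sam_ends",
    "write_counts",
]

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["gene_id", "sample_id", "locus_count", "exonic_count", "intronic_count"]


@dataclass(frozen=True)
class ReadEnd:
    """The 5'-end position of one aligned record."""

    chrom: str
    pos: int
    strand: str = "."
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"5' end position must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class EndCount:
    """Per gene x sample 5'-end counts over the locus and its super-exons."""

    gene_id: str
    sample_id: str
    locus_count: int
    exonic_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.exonic_count <= self.locus_count):
            raise ValueError(
                f"{self.gene_id}/{self.sample_id}: exonic_count "
                f"{self.exonic_count} outside [0, locus_count={self.locus_count}]"
            )

    @property
    def intronic_count(self) -> int:
        return self.locus_count - self.exonic_count


def five_prime_end(
    chrom: str, start: int, end: int, strand: str = ".", sample_id: str = ""
) -> ReadEnd:
    """5' end of an alignment spanning [start, end) on the given strand.

    Plus-strand or unstranded alignments start transcription at the
    leftmost base (``start``); minus-strand alignments at the rightmost
    covered base (``end - 1``, 0-based).
    """
    if end <= start:
        raise ValueError(f"alignment [{start}, {end}) is empty or inverted")
    if start < 0:
        raise ValueError(f"alignment start must be >= 0, got {start}")
    pos = end - 1 if strand == "-" else start
    return ReadEnd(chrom=chrom, pos=pos, strand=strand, sample_id=sample_id)


def _count_in_intervals(pos_sorted: np.ndarray, intervals: Sequence[GenomicInterval]) -> int:
    total = 0
    for iv in intervals:
        lo = np.searchsorted(pos_sorted, iv.start, side="left")
        hi = np.searchsorted(pos_sorted, iv.end, side="left")
        total += int(hi - lo)
    return total


def count_ends_for_gene(
    ends: Iterable[ReadEnd],
    locus: GeneLocus,
    strand_mode: str = "ignore",
    sample_id: str = "",
) -> EndCount:
    """Count 5' ends over one gene locus and its super-exon union.

    Parameters
    ----------
    ends : iterable of ReadEnd
        5' ends on the locus chromosome (ends on other chromosomes are
        ignored).
    locus : GeneLocus
    strand_mode : {'ignore', 'match'}
        ``'ignore'`` (default) counts ends regardless of orientation;
        ``'match'`` counts only ends whose strand equals the gene strand.
    """
    if strand_mode not in ("ignore", "match"):
        raise ValueError(f"strand_mode must be 'ignore' or 'match', got {strand_mode!r}")
    positions = [
        e.pos
        for e in ends
        if e.chrom == locus.chrom
        and (strand_mode == "ignore" or e.strand == locus.strand)
    ]
    pos_sorted = np.sort(np.asarray(positions, dtype=np.int64))
    locus_count = _count_in_intervals(pos_sorted, [locus.span])
    exonic_count = _count_in_intervals(pos_sorted, locus.super_exons)
    return EndCount(
        gene_id=locus.gene_id,
        sample_id=sample_id,
        locus_count=locus_count,
        exonic_count=exonic_count,
    )


# ---------------------------------------------------------------------------
# alignment sources


def read_bed_ends(path: str | Path, sample_id: str = "") -> List[ReadEnd]:
    """Load 5' ends from a BED6 file (one record per aligned mate)."""
    ends: List[ReadEnd] = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path} line {lineno}: expected >= 6 BED columns")
            chrom, start, end, strand = fields[0], int(fields[1]), int(fields[2]), fields[5]
            ends.append(five_prime_end(chrom, start, end, strand, sample_id))
    return ends


def read_sam_ends(
    path: str | Path, sample_id: str = "", first_mate_only: bool = False
) -> List[ReadEnd]:
    """Load 5' ends from SAM/BAM, skipping secondary/supplementary/unmapped.

    With ``first_mate_only`` paired records contribute only their first
    mate, approximating fragment-level counting.
    """
    import pysam

    ends: List[ReadEnd] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if first_mate_only and rec.is_paired and not rec.is_read1:
                continue
            strand = "-" if rec.is_reverse else "+"
            ends.append(
                five_prime_end(
                    rec.reference_name, rec.reference_start, rec.reference_end, strand, sample_id
                )
            )
    return ends


def _load_ends(path: str | Path, sample_id: str, first_mate_only: bool) -> List[ReadEnd]:
    suffix = Path(path).suffix.lower()
    if suffix in (".sam", ".bam", ".cram"):
        return read_sam_ends(path, sample_id, first_mate_only=first_mate_only)
    return read_bed_ends(path, sample_id)


def _ends_by_chrom(
    ends: Sequence[ReadEnd], strand_mode: str
) -> Dict[str, np.ndarray] | Dict[Tuple[str, str], np.ndarray]:
    """Index positions by chromosome (or chromosome+strand) as sorted arrays."""
    buckets: Dict = {}
    for e in ends:
        key = (e.chrom, e.strand) if strand_mode == "match" else e.chrom
        buckets.setdefault(key, []).append(e.pos)
    return {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in buckets.items()}


def count_all(
    alignments: Mapping[str, str | Path] | Mapping[str, Sequence[ReadEnd]],
    loci: Sequence[GeneLocus],
    design: pd.DataFrame | None = None,
    first_mate_only: bool = False,
    strand_mode: str = "ignore",
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Count 5' ends per (gene, sample) over a whole design.

    Parameters
    ----------
    alignments : mapping sample_id -> BED6/SAM/BAM path or ReadEnd list
    loci : the gene loci to count against
    design : optional sample table with a ``sample_id`` column; every design
        sample must have an alignment source.
    first_mate_only, strand_mode : see :func:`read_sam_ends` and
        :func:`count_ends_for_gene`.

    Returns
    -------
    (counts, unassigned)
        ``counts`` is a DataFrame with one row per (gene, sample) —
        explicit zeros included — and columns ``gene_id, sample_id,
        locus_count, exonic_count, intronic_count``.  ``unassigned`` maps
        each sample to its number of ends on chromosomes absent from the
        annotation.
    """
    if design is not None:
        missing = set(design["sample_id"]) - set(alignments)
        if missing:
            raise ValueError(f"design samples without alignment source: {sorted(missing)}")
        sample_ids = list(design["sample_id"])
    else:
        sample_ids = list(alignments)

    known_chroms = {l.chrom for l in loci}
    rows: List[tuple] = []
    unassigned: Dict[str, int] = {}
    for sample_id in sample_ids:
        source = alignments[sample_id]
        if isinstance(source, (str, Path)):
            ends = _load_ends(source, sample_id, first_mate_only)
        else:
            ends = list(source)
        unassigned[sample_id] = sum(1 for e in ends if e.chrom not in known_chroms)
        if unassigned[sample_id]:
            logger.warning(
                "sample %s: %d 5' ends on chromosomes absent from the annotation",
                sample_id,
                unassigned[sample_id],
            )
        index = _ends_by_chrom(ends, strand_mode)
        empty = np.empty(0, dtype=np.int64)
        for locus in loci:
            key = (locus.chrom, locus.strand) if strand_mode == "match" else locus.chrom
            pos_sorted = index.get(key, empty)
            locus_count = _count_in_intervals(pos_sorted, [locus.span])
            exonic_count = _count_in_intervals(pos_sorted, locus.super_exons)
            rows.append(
                (locus.gene_id, sample_id, locus_count, exonic_count, locus_count - exonic_count)
            )
    counts = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return counts, unassigned


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write the per-(gene, sample) count table as TSV with header."""
    counts.to_csv(path, sep="\t", index=False)
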