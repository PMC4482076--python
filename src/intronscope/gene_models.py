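"""Gene models: merged super-exons and derived introns per gene locus.

A gene locus is the genomic span from the first to the last exonic base of
a gene, over all of its annotated transcripts.  Within that span, all
overlapping (or abutting) exons are merged into disjoint *super-exons*;
the complementary gaps are the locus *introns*.  Super-exons and introns
partition the locus exactly, which is the coordinate basis for classifying
read 5' ends as exonic or intronic downstream.

Coordinates are 0-based half-open throughout (BED convention); GTF input
(1-based inclusive) is converted at the parsing boundary.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneLocus",
    "GtfParseError",
    "parse_gtf",
    "merge_intervals",
    "build_gene_locus",
    "write_locus_beds",
]


class GtfParseError(ValueError):
    """Raised when a GTF line violates the format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open coordinate span [start, end) on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome name; must be non-empty.
    start, end : int
        0-based half-open bounds, ``0 <= start < end``.
    strand : str
        One of ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval bounds [{self.start}, {self.end}) "
                f"on {self.chrom}: require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """Whether a 0-based position lies inside the half-open span."""
        return self.start <= pos < self.end


@dataclass
class Transcript:
    """One annotated isoform: an exon chain on a single chromosome/strand."""

    transcript_id: str
    gene_id: str
    biotype: str
    exons: List[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple "
                f"chromosomes/strands ({chroms}, {strands})"
            )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass
class GeneLocus:
    """A gene's span with its merged super-exons and complementary introns.

    Invariant: super-exons and introns are sorted, pairwise disjoint, and
    tile the span exactly; the first super-exon starts at ``span.start``
    and the last ends at ``span.end``.
    """

    gene_id: str
    chrom: str
    strand: str
    span: GenomicInterval
    super_exons: List[GenomicInterval]
    introns: List[GenomicInterval] = field(default_factory=list)

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.super_exons)

    @property
    def intronic_length(self) -> int:
        return sum(i.length for i in self.introns)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Merge intervals that overlap or abut into a sorted disjoint list.

    Abutting intervals (end of one equals start of the next under half-open
    coordinates) are merged, matching bedtools-merge's default distance-0
    behaviour.  The output covers exactly the same base set as the input.

    Raises
    ------
    ValueError
        If the intervals are not all on the same chromosome.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"merge_intervals requires a single chromosome, got {sorted(chroms)}")
    chrom = intervals[0].chrom
    strand = intervals[0].strand
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: List[List[int]] = [[ordered[0].start, ordered[0].end]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start <= last[1]:  # overlap or abut
            last[1] = max(last[1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    return [GenomicInterval(chrom, s, e, strand) for s, e in merged]


def build_gene_locus(
    transcripts: Sequence[Transcript],
    on_multi: str = "error",
) -> GeneLocus:
    """Build a :class:`GeneLocus` from all transcripts of one gene.

    The span runs from the minimum exon start to the maximum exon end;
    super-exons are the merged union of every exon of every transcript,
    and introns are the gaps between consecutive super-exons.

    Parameters
    ----------
    transcripts : sequence of Transcript
        All transcripts sharing one gene_id.
    on_multi : {'error', 'largest'}
        What to do when one gene_id spans multiple chromosomes or strands:
        reject (default), or keep the chromosome/strand group with the
        largest total exonic length.
    """
    if not transcripts:
        raise ValueError("build_gene_locus requires at least one transcript")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) > 1:
        raise ValueError(f"transcripts belong to multiple genes: {sorted(gene_ids)}")
    gene_id = transcripts[0].gene_id

    groups: Dict[tuple, List[Transcript]] = defaultdict(list)
    for t in transcripts:
        groups[(t.chrom, t.strand)].append(t)
    if len(groups) > 1:
        if on_multi == "largest":
            key = max(
                groups,
                key=lambda k: sum(e.length for t in groups[k] for e in t.exons),
            )
            transcripts = groups[key]
        else:
            raise ValueError(
                f"gene {gene_id} spans multiple chromosome/strand groups "
                f"{sorted(groups)}; pass on_multi='largest' to keep the biggest"
            )

    chrom = transcripts[0].chrom
    strand = transcripts[0].strand
    exons = [e for t in transcripts for e in t.exons]
    super_exons = merge_intervals(exons)
    span = GenomicInterval(chrom, super_exons[0].start, super_exons[-1].end, strand)
    introns = [
        GenomicInterval(chrom, a.end, b.start, strand)
        for a, b in zip(super_exons, super_exons[1:])
    ]
    return GeneLocus(gene_id, chrom, strand, span, super_exons, introns)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_BIOTYPE_KEYS = ("transcript_biotype", "transcript_type", "gene_biotype", "biotype")


def parse_gtf(path: str | Path) -> Dict[str, List[Transcript]]:
    """Parse exon features from a GTF file into transcripts grouped by gene.

    GTF 1-based inclusive coordinates are converted to internal 0-based
    half-open ones.  Records without a recognisable biotype attribute get
    biotype ``"unknown"``.  Non-exon features (including gene lines) are
    ignored; the locus is defined purely by its exons.

    Returns
    -------
    dict mapping gene_id to its list of :class:`Transcript`.

    Raises
    ------
    GtfParseError
        On a malformed exon line (too few columns, non-numeric or inverted
        coordinates, missing gene_id/transcript_id), naming the line number.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    # (gene_id, transcript_id) -> (biotype, exon list)
    tx: Dict[tuple, List[GenomicInterval]] = defaultdict(list)
    biotypes: Dict[tuple, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(f"{path} line {lineno}: expected 9 tab-delimited columns")
            if fields[2] != "exon":
                continue
            try:
                start1 = int(fields[3])
                end1 = int(fields[4])
            except ValueError as exc:
                raise GtfParseError(f"{path} line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GtfParseError(f"{path} line {lineno}: end {end1} < start {start1}")
            strand = fields[6] if fields[6] in ("+", "-") else "."
            attrs = dict(_ATTR_RE.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            transcript_id = attrs.get("transcript_id")
            if not gene_id or not transcript_id:
                raise GtfParseError(
                    f"{path} line {lineno}: exon lacks gene_id or transcript_id attribute"
                )
            key = (gene_id, transcript_id)
            tx[key].append(GenomicInterval(fields[0], start1 - 1, end1, strand))
            for bk in _BIOTYPE_KEYS:
                if bk in attrs:
                    biotypes[key] = attrs[bk]
                    break
    genes: Dict[str, List[Transcript]] = defaultdict(list)
    for (gene_id, transcript_id), exons in tx.items():
        genes[gene_id].append(
            Transcript(
                transcript_id=transcript_id,
                gene_id=gene_id,
                biotype=biotypes.get((gene_id, transcript_id), "unknown"),
                exons=exons,
            )
        )
    return dict(genes)


def build_all_loci(
    genes: Dict[str, List[Transcript]], on_multi: str = "error"
) -> List[GeneLocus]:
    """Build a locus for every gene, sorted by (chrom, start)."""
    loci = [build_gene_locus(ts, on_multi=on_multi) for ts in genes.values()]
    loci.sort(key=lambda l: (l.chrom, l.span.start, l.gene_id))
    return loci


def write_locus_beds(
    loci: Iterable[GeneLocus], exon_path: str | Path, intron_path: str | Path
) -> None:
    """Write super-exons and introns as BED6 (name column = gene_id)."""
    with open(exon_path, "wt") as fe, open(intron_path, "wt") as fi:
        for locus in loci:
            for iv in locus.super_exons:
                fe.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{locus.gene_id}\t0\t{locus.strand}\n"
                )
            for iv in locus.introns:
                fi.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{locus.gene_id}\t0\t{locus.strand}\n"
                )
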