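"""Shared fixtures and brute-force oracles for the test suite.

The oracles here deliberately work per base: an interval is expanded into
its explicit set of covered positions, so merging, complement and
membership can be checked by plain set arithmetic, independently of the
searchsorted-based implementation.
"""

from __future__ import annotations

from typing import List, Sequence, Set

import numpy as np
import pytest

from intronscope.gene_models import GeneLocus, GenomicInterval
from intronscope.synthetic_data import SimDesign


def base_set(intervals: Sequence[GenomicInterval]) -> Set[int]:
    """All positions covered by the intervals (half-open expansion)."""
    covered: Set[int] = set()
    for iv in intervals:
        covered.update(range(iv.start, iv.end))
    return covered


def runs_from_base_set(chrom: str, covered: Set[int], strand: str = ".") -> List[GenomicInterval]:
    """Maximal contiguous runs of a position set, as sorted intervals."""
    out: List[GenomicInterval] = []
    for pos in sorted(covered):
        if out and pos == out[-1].end:
            out[-1] = GenomicInterval(chrom, out[-1].start, pos + 1, strand)
        else:
            out.append(GenomicInterval(chrom, pos, pos + 1, strand))
    return out


def random_exon_set(rng: np.random.Generator, max_coord: int = 10_000) -> List[GenomicInterval]:
    """A random pile of possibly overlapping exons on one chromosome."""
    n = int(rng.integers(1, 12))
    exons = []
    for _ in range(n):
        start = int(rng.integers(0, max_coord - 2))
        end = int(rng.integers(start + 1, min(start + 500, max_coord)))
        exons.append(GenomicInterval("chr1", start, end, "+"))
    return exons


def random_locus(rng: np.random.Generator, gene_id: str = "G") -> GeneLocus:
    """A random well-formed locus with up to 5 super-exons."""
    n_exons = int(rng.integers(1, 6))
    cursor = int(rng.integers(0, 100))
    exons = []
    for _ in range(n_exons):
        elen = int(rng.integers(1, 200))
        exons.append(GenomicInterval("chr1", cursor, cursor + elen, "+"))
        cursor += elen + int(rng.integers(1, 300))
    span = GenomicInterval("chr1", exons[0].start, exons[-1].end, "+")
    introns = [
        GenomicInterval("chr1", a.end, b.start, "+") for a, b in zip(exons, exons[1:])
    ]
    return GeneLocus(gene_id, "chr1", "+", span, exons, introns)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250930)


@pytest.fixture
def default_design() -> SimDesign:
    return SimDesign.default(seed=7)
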