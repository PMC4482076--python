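"""Synthetic annotations, read 5'-end alignments and abundance tables with truth.

Emulates the statistical structure of a splicing-factor knockdown
experiment: six samples (two biological replicates each of a CWC22
knockdown, an eIF4A3 knockdown and a luciferase control) in which only
the CWC22 knockdown shows elevated per-gene intron retention.  The
generative model is intentionally minimal and matches exactly what the
5'-end counting statistic consumes: per gene and sample the number of
locus reads is Poisson, each read is intronic with the condition's
retention probability ``r`` and lands uniformly on the intron base set,
otherwise uniformly on the super-exon base set.  No fragment-length or
positional-bias modelling — neither affects the statistic's inputs.

All randomness flows from one integer seed; per-sample streams are
derived by stable hashing of the sample id, so any sample can be
regenerated independently and runs are byte-identical per seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .gene_models import GeneLocus, GenomicInterval, Transcript, build_gene_locus
from .read_counting import COUNT_COLUMNS

__all__ = [
    "CWC22_KD",
    "EIF4A3_KD",
    "CONTROL",
    "SimDesign",
    "AnnotationSim",
    "SimReads",
    "simulate_annotation",
    "simulate_truth",
    "simulate_read_ends",
    "simulate_abundances",
]

logger = logging.getLogger(__name__)

CWC22_KD = "cwc22_kd"
EIF4A3_KD = "eif4a3_kd"
CONTROL = "control"
CONDITIONS = (CWC22_KD, EIF4A3_KD, CONTROL)

#: default per-condition retention fractions: elevated only under CWC22 depletion
DEFAULT_RETENTION = {CWC22_KD: 0.30, EIF4A3_KD: 0.05, CONTROL: 0.05}

#: default per-condition, per-biotype abundance fold changes versus control:
#: CWC22 depletion boosts retained_intron isoforms and downregulates
#: protein-coding (gene-expression machinery) transcripts.
DEFAULT_FOLD_CHANGES: Dict[str, Dict[str, float]] = {
    CWC22_KD: {"retained_intron": 2.0, "protein_coding": 0.7},
    EIF4A3_KD: {},
}

_BIOTYPES = ("protein_coding", "retained_intron", "lincRNA")
_BIOTYPE_PROBS = (0.8, 0.1, 0.1)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample generator derived from the master seed by stable hashing."""
    h = int.from_bytes(hashlib.blake2b(sample_id.encode(), digest_size=4).digest(), "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


@dataclass(frozen=True)
class SimDesign:
    """The experimental design: samples with condition and replicate labels."""

    samples: Tuple[Tuple[str, str, int], ...]
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "SimDesign":
        """Two biological replicates per condition, six samples in total."""
        samples = tuple(
            (f"{cond}_rep{rep}", cond, rep) for cond in CONDITIONS for rep in (1, 2)
        )
        return cls(samples=samples, seed=seed)

    @property
    def sample_ids(self) -> List[str]:
        return [s[0] for s in self.samples]

    @property
    def conditions(self) -> List[str]:
        return list(dict.fromkeys(s[1] for s in self.samples))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=["sample_id", "condition", "replicate"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class AnnotationSim:
    """A simulated annotation: transcripts, loci and per-gene biotypes."""

    transcripts: Dict[str, List[Transcript]]
    loci: List[GeneLocus]
    biotypes: Dict[str, str]
    chrom: str

    def gtf_text(self) -> str:
        lines = []
        for gene_id in sorted(self.transcripts):
            for t in self.transcripts[gene_id]:
                for iv in t.exons:
                    attrs = (
                        f'gene_id "{gene_id}"; transcript_id "{t.transcript_id}"; '
                        f'transcript_biotype "{t.biotype}";'
                    )
                    lines.append(
                        "\t".join(
                            [
                                iv.chrom,
                                "sim",
                                "exon",
                                str(iv.start + 1),
                                str(iv.end),
                                ".",
                                t.strand,
                                ".",
                                attrs,
                            ]
                        )
                    )
        return "\n".join(lines) + "\n"

    def write_gtf(self, path: str | Path) -> None:
        Path(path).write_text(self.gtf_text())


def simulate_annotation(
    n_genes: int = 500,
    exons_per_gene: Tuple[int, int] = (2, 8),
    exon_length: Tuple[int, int] = (80, 300),
    intron_length: Tuple[int, int] = (200, 1500),
    intergenic: Tuple[int, int] = (500, 2000),
    chrom: str = "chrS",
    chrom_length: int = 50_000_000,
    overlapping_pairs: int = 0,
    seed: int = 0,
) -> AnnotationSim:
    """Place ``n_genes`` synthetic single-transcript genes on one chromosome.

    Genes are laid out left to right with random intergenic gaps and are
    non-overlapping by default; ``overlapping_pairs`` makes the first so
    many gene pairs overlap (the second gene of a pair starts inside the
    first's span) to exercise multi-locus counting edge cases.
    Deterministic for a fixed seed, including the GTF text.

    Ranges are inclusive on both ends.  Raises a ``ValueError`` suggesting
    a longer chromosome if the genes do not fit within ``chrom_length``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for name, (lo, hi) in (
        ("exons_per_gene", exons_per_gene),
        ("exon_length", exon_length),
        ("intron_length", intron_length),
        ("intergenic", intergenic),
    ):
        if lo < 1 or hi < lo:
            raise ValueError(f"{name} range must satisfy 1 <= lo <= hi, got ({lo}, {hi})")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x616E6E]))
    width = len(str(n_genes))
    transcripts: Dict[str, List[Transcript]] = {}
    loci: List[GeneLocus] = []
    biotypes: Dict[str, str] = {}
    cursor = int(rng.integers(intergenic[0], intergenic[1] + 1))
    prev_span: GenomicInterval | None = None
    overlaps_left = overlapping_pairs

    for i in range(n_genes):
        gene_id = f"G{i + 1:0{width}d}"
        if overlaps_left > 0 and i % 2 == 1 and prev_span is not None:
            start = prev_span.start + prev_span.length // 2
            overlaps_left -= 1
        else:
            start = cursor
        n_exons = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exons: List[GenomicInterval] = []
        strand = "+" if rng.random() < 0.5 else "-"
        pos = start
        for k in range(n_exons):
            elen = int(rng.integers(exon_length[0], exon_length[1] + 1))
            exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
            pos += elen
            if k < n_exons - 1:
                pos += int(rng.integers(intron_length[0], intron_length[1] + 1))
        if pos > chrom_length:
            raise ValueError(
                f"gene {gene_id} ends at {pos}, beyond chrom_length={chrom_length}; "
                "use a longer synthetic chromosome"
            )
        biotype = str(rng.choice(_BIOTYPES, p=_BIOTYPE_PROBS))
        t = Transcript(
            transcript_id=f"{gene_id}.1", gene_id=gene_id, biotype=biotype, exons=exons
        )
        transcripts[gene_id] = [t]
        locus = build_gene_locus([t])
        loci.append(locus)
        biotypes[gene_id] = biotype
        prev_span = locus.span
        cursor = max(cursor, pos) + int(rng.integers(intergenic[0], intergenic[1] + 1))
    return AnnotationSim(transcripts=transcripts, loci=loci, biotypes=biotypes, chrom=chrom)


def simulate_truth(
    annotation: AnnotationSim,
    design: SimDesign,
    retention: Mapping[str, float] | None = None,
    weight_sigma: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ground-truth retention fraction and expression weight per gene x condition.

    Retention ``r`` is the condition's value for every gene (defaults:
    0.30 under CWC22 knockdown, 0.05 elsewhere); the expression weight
    ``w`` is log-normal across genes (sigma ``weight_sigma``) and shared
    across conditions — condition-specific abundance fold changes are
    applied by :func:`simulate_abundances`.
    """
    retention = dict(DEFAULT_RETENTION if retention is None else retention)
    for cond in design.conditions:
        if cond not in retention:
            raise ValueError(f"no retention fraction for condition {cond!r}")
        if not (0.0 <= retention[cond] <= 1.0):
            raise ValueError(f"retention for {cond!r} must be in [0, 1]")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(design.seed if seed is None else seed), 0x747275])
    )
    gene_ids = [l.gene_id for l in annotation.loci]
    weights = rng.lognormal(mean=0.0, sigma=weight_sigma, size=len(gene_ids))
    rows = []
    for gene_id, w in zip(gene_ids, weights):
        for cond in design.conditions:
            rows.append(
                {
                    "gene_id": gene_id,
                    "biotype": annotation.biotypes[gene_id],
                    "condition": cond,
                    "retention": retention[cond],
                    "weight": float(w),
                }
            )
    return pd.DataFrame(rows)


def _sample_positions(
    rng: np.random.Generator, intervals: Sequence[GenomicInterval], n: int
) -> np.ndarray:
    """Draw ``n`` positions uniformly over the base set of the intervals."""
    lengths = np.array([iv.length for iv in intervals], dtype=np.int64)
    starts = np.array([iv.start for iv in intervals], dtype=np.int64)
    cum = np.cumsum(lengths)
    offsets = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, offsets, side="right")
    return starts[idx] + (offsets - (cum[idx] - lengths[idx]))


@dataclass
class SimReads:
    """Simulated per-sample read alignments plus the simulator's own bookkeeping."""

    reads: Dict[str, pd.DataFrame]
    counts: pd.DataFrame  # gene_id, sample_id, locus_count, exonic_count, intronic_count
    read_length: int

    def write_beds(self, out_dir: str | Path) -> Dict[str, Path]:
        """Write one BED6 file per sample; returns sample_id -> path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sample_id, df in self.reads.items():
            path = out_dir / f"{sample_id}.bed"
            df.to_csv(path, sep="\t", index=False, header=False)
            paths[sample_id] = path
        return paths


def simulate_read_ends(
    loci: Sequence[GeneLocus],
    truth: pd.DataFrame,
    design: SimDesign,
    mean_depth: float = 200.0,
    replicate_sigma: float = 0.1,
    read_length: int = 75,
    seed: int | None = None,
) -> SimReads:
    """Simulate per-sample read alignments whose 5' ends realize the truth table.

    For each gene and sample, ``N ~ Poisson(mean_depth * w * f)`` reads
    are drawn, where ``f`` is a per-sample log-normal library factor
    (sigma ``replicate_sigma``, mean one).  Each read is intronic with
    probability ``r`` — uniform over the gene's intron base set — and
    exonic otherwise — uniform over the super-exon base set.  Intronless
    genes receive only exonic reads (a positive ``r`` is demoted to 0 with
    a warning).  Reads are emitted as BED6 mates on either strand with the
    interval arranged so the 5' end is the placed position.

    The returned bookkeeping table records exactly which reads were placed
    intronic versus exonic, serving as the end-to-end counting oracle.
    """
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    base_seed = int(design.seed if seed is None else seed)
    truth_idx = truth.set_index(["gene_id", "condition"])
    warned_genes = set()

    reads: Dict[str, pd.DataFrame] = {}
    count_rows: List[tuple] = []
    for sample_id, cond, _rep in design.samples:
        rng = _sample_rng(base_seed, sample_id)
        lib_factor = (
            rng.lognormal(mean=-replicate_sigma**2 / 2, sigma=replicate_sigma)
            if replicate_sigma > 0
            else 1.0
        )
        chroms: List[str] = []
        starts: List[np.ndarray] = []
        ends: List[np.ndarray] = []
        names: List[str] = []
        strands: List[np.ndarray] = []
        for locus in loci:
            row = truth_idx.loc[(locus.gene_id, cond)]
            r, w = float(row["retention"]), float(row["weight"])
            if r > 0 and not locus.introns:
                if locus.gene_id not in warned_genes:
                    logger.warning(
                        "gene %s has no introns; treating retention %.3f as 0",
                        locus.gene_id,
                        r,
                    )
                    warned_genes.add(locus.gene_id)
                r = 0.0
            n = int(rng.poisson(mean_depth * w * lib_factor))
            n_intronic = int(rng.binomial(n, r)) if n else 0
            n_exonic = n - n_intronic
            pos = np.concatenate(
                [
                    _sample_positions(rng, locus.introns, n_intronic)
                    if n_intronic
                    else np.empty(0, dtype=np.int64),
                    _sample_positions(rng, locus.super_exons, n_exonic)
                    if n_exonic
                    else np.empty(0, dtype=np.int64),
                ]
            )
            read_strand = np.where(rng.random(n) < 0.5, "+", "-")
            # arrange the mate interval so its 5' end is exactly `pos`
            s = np.where(read_strand == "+", pos, np.maximum(0, pos + 1 - read_length))
            e = np.where(read_strand == "+", pos + read_length, pos + 1)
            chroms.extend([locus.chrom] * n)
            starts.append(s)
            ends.append(e)
            names.extend(
                f"{locus.gene_id}:{'i' if k < n_intronic else 'e'}{k}" for k in range(n)
            )
            strands.append(read_strand)
            count_rows.append((locus.gene_id, sample_id, n, n_exonic, n_intronic))
        reads[sample_id] = pd.DataFrame(
            {
                "chrom": chroms,
                "start": np.concatenate(starts) if starts else np.empty(0, dtype=np.int64),
                "end": np.concatenate(ends) if ends else np.empty(0, dtype=np.int64),
                "name": names,
                "score": 0,
                "strand": np.concatenate(strands) if strands else np.empty(0, dtype=str),
            }
        )
    counts = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    return SimReads(reads=reads, counts=counts, read_length=read_length)


def simulate_abundances(
    truth: pd.DataFrame,
    design: SimDesign,
    dispersion: float = 0.2,
    fold_changes: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-isoform FPKM-like abundance table (one isoform per gene).

    Sample abundances are log-normal around ``w * fold`` where ``fold``
    is the condition x biotype fold change versus control (default: CWC22
    knockdown doubles retained_intron and scales protein_coding by 0.7).
    ``dispersion`` is the log-normal sigma of mean-one multiplicative
    noise; 0 gives exact ratios.  Deterministic per seed.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    folds = DEFAULT_FOLD_CHANGES if fold_changes is None else fold_changes
    base_seed = int(design.seed if seed is None else seed)
    genes = (
        truth.drop_duplicates("gene_id")[["gene_id", "biotype", "weight"]]
        .reset_index(drop=True)
    )
    out = pd.DataFrame(
        {"isoform_id": genes["gene_id"] + ".1", "biotype": genes["biotype"]}
    )
    for sample_id, cond, _rep in design.samples:
        rng = _sample_rng(base_seed, "abund:" + sample_id)
        cond_folds = folds.get(cond, {})
        fold = genes["biotype"].map(lambda b: cond_folds.get(b, 1.0)).to_numpy(dtype=float)
        noise = (
            rng.lognormal(mean=-dispersion**2 / 2, sigma=dispersion, size=len(genes))
            if dispersion > 0
            else np.ones(len(genes))
        )
        out[sample_id] = genes["weight"].to_numpy() * fold * noise
    return out
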