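"""Intronic-read proportions, filtering, per-gene normalization and summaries.

The retention statistic per gene and sample is

    proportion = 1 - exonic_count / locus_count,

the fraction of gene-locus read 5' ends that fall outside the super-exon
union.  Genes are kept only if their intronic counts summed over all
samples reach a minimum (default 100).  Because exon-to-intron size ratios
differ between genes, proportions are then normalized per gene by dividing
by the gene's maximum across samples, so the sample with the highest
retention scores exactly 1.  Per-sample distributions are summarized by
the median and the 5th/95th percentiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Set

import numpy as np
import pandas as pd

from .read_counting import EndCount

__all__ = [
    "SampleSummary",
    "intron_proportion",
    "filter_min_intronic",
    "normalize_per_gene",
    "compute_retention",
    "summarize_sample",
    "summarize_all",
    "condition_contrast",
    "plot_sample_distributions",
]

logger = logging.getLogger(__name__)

RETENTION_COLUMNS = [
    "gene_id",
    "sample_id",
    "locus_count",
    "exonic_count",
    "intronic_count",
    "proportion",
    "normalized_proportion",
    "passed_filter",
]


@dataclass(frozen=True)
class SampleSummary:
    """Distribution summary of normalized proportions in one sample."""

    sample_id: str
    n_genes: int
    median: float
    p5: float
    p95: float

    def __post_init__(self) -> None:
        if not (self.p5 <= self.median <= self.p95):
            raise ValueError(
                f"{self.sample_id}: percentile order violated "
                f"(p5={self.p5}, median={self.median}, p95={self.p95})"
            )


def intron_proportion(count, exonic_count: int | None = None) -> float:
    """Proportion of intronic reads: ``1 - exonic/locus``.

    Accepts either an :class:`~intronscope.read_counting.EndCount` or the
    pair ``(locus_count, exonic_count)``.  A locus with zero reads has an
    undefined proportion (NaN): absence of evidence is not zero retention.
    """
    if isinstance(count, EndCount):
        locus_count, exonic = count.locus_count, count.exonic_count
    else:
        if exonic_count is None:
            raise TypeError("pass an EndCount or (locus_count, exonic_count)")
        locus_count, exonic = int(count), int(exonic_count)
    if not (0 <= exonic <= locus_count):
        raise ValueError(f"require 0 <= exonic ({exonic}) <= locus ({locus_count})")
    if locus_count == 0:
        return math.nan
    # (locus - exonic)/locus == 1 - exonic/locus, but exact in binary floats
    return (locus_count - exonic) / locus_count


def filter_min_intronic(
    counts: pd.DataFrame,
    threshold: int = 100,
    collapse_replicates: bool = False,
    design: pd.DataFrame | None = None,
) -> Set[str]:
    """Gene ids whose intronic counts summed over all samples reach the threshold.

    The default sums the per-sample intronic counts of every sample in the
    table (the conditions comprise the samples).  With
    ``collapse_replicates`` the per-condition replicate means are summed
    instead, which requires a design table mapping sample to condition.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if counts.empty:
        return set()
    if collapse_replicates:
        if design is None:
            raise ValueError("collapse_replicates requires a design table")
        cond = design.set_index("sample_id")["condition"]
        per_cond = (
            counts.assign(condition=counts["sample_id"].map(cond))
            .groupby(["gene_id", "condition"])["intronic_count"]
            .mean()
        )
        sums = per_cond.groupby("gene_id").sum()
    else:
        sums = counts.groupby("gene_id")["intronic_count"].sum()
    return set(sums.index[sums >= threshold])


def normalize_per_gene(values: Sequence[float] | pd.Series) -> np.ndarray:
    """Divide each defined value by the gene's maximum defined value.

    The sample with the highest proportion maps to exactly 1 (ties all map
    to 1).  If the maximum is 0, defined values stay 0; NaN entries stay
    NaN.  An all-NaN input is returned unchanged (logged).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or np.all(np.isnan(arr)):
        if arr.size:
            logger.warning("normalize_per_gene: all values undefined")
        return arr.copy()
    m = np.nanmax(arr)
    if m == 0:
        return arr.copy()
    return arr / m


def compute_retention(
    counts: pd.DataFrame,
    threshold: int = 100,
    collapse_replicates: bool = False,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-(gene, sample) retention table from a count table.

    Adds ``proportion`` (NaN where the locus has no reads),
    ``passed_filter`` (minimum summed intronic count) and
    ``normalized_proportion`` (per-gene max-normalized, defined only for
    genes passing the filter).
    """
    out = counts.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        locus = out["locus_count"].to_numpy(dtype=float)
        exonic = out["exonic_count"].to_numpy(dtype=float)
        prop = np.where(locus > 0, (locus - exonic) / np.where(locus > 0, locus, 1.0), np.nan)
    out["proportion"] = prop
    retained = filter_min_intronic(
        counts, threshold=threshold, collapse_replicates=collapse_replicates, design=design
    )
    out["passed_filter"] = out["gene_id"].isin(retained)
    out["normalized_proportion"] = np.nan
    mask = out["passed_filter"].to_numpy()
    if mask.any():
        norm = (
            out.loc[mask]
            .groupby("gene_id", group_keys=False)["proportion"]
            .apply(lambda s: pd.Series(normalize_per_gene(s), index=s.index))
        )
        out.loc[mask, "normalized_proportion"] = norm
    return out[RETENTION_COLUMNS]


def summarize_sample(
    values: Iterable[float], sample_id: str = ""
) -> SampleSummary:
    """Median and 5th/95th percentiles of one sample's normalized proportions.

    Percentiles use linear interpolation between closest ranks.  NaN
    entries are excluded and ``n_genes`` reflects only defined values.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError(f"sample {sample_id!r}: no defined normalized proportions")
    p5, med, p95 = np.percentile(arr, [5, 50, 95], method="linear")
    return SampleSummary(
        sample_id=sample_id, n_genes=int(arr.size), median=float(med), p5=float(p5), p95=float(p95)
    )


def summarize_all(
    retention: pd.DataFrame, design: pd.DataFrame, column: str = "normalized_proportion"
) -> pd.DataFrame:
    """Per-sample distribution summaries of retained genes, joined to the design."""
    rows = []
    meta = design.set_index("sample_id")
    for sample_id, group in retention[retention["passed_filter"]].groupby("sample_id"):
        s = summarize_sample(group[column], sample_id=sample_id)
        rows.append(
            {
                "sample_id": sample_id,
                "condition": meta.loc[sample_id, "condition"],
                "replicate": meta.loc[sample_id, "replicate"],
                "n_genes": s.n_genes,
                "median": s.median,
                "p5": s.p5,
                "p95": s.p95,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "condition", "replicate", "n_genes", "median", "p5", "p95"])


def condition_contrast(
    summaries: pd.DataFrame, control_condition: str = "control"
) -> pd.DataFrame:
    """Mean of replicate medians per condition and the delta versus control.

    Quantifies the knockdown-versus-control shift in the per-sample
    retention distributions.
    """
    if control_condition not in set(summaries["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent from summaries")
    mean_median = summaries.groupby("condition")["median"].mean()
    control = mean_median[control_condition]
    out = mean_median.rename("mean_median").reset_index()
    out["delta_vs_control"] = out["mean_median"] - control
    return out


def plot_sample_distributions(
    retention: pd.DataFrame,
    design: pd.DataFrame,
    path: str | Path,
    column: str = "normalized_proportion",
) -> None:
    """Box plot of per-sample normalized proportions, whiskers at the 5th/95th percentiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sample_ids = list(design["sample_id"])
    data = [
        retention.loc[
            retention["passed_filter"] & (retention["sample_id"] == s), column
        ].dropna()
        for s in sample_ids
    ]
    fig, ax = plt.subplots(figsize=(1.2 * len(sample_ids) + 1, 4))
    ax.boxplot(data, whis=(5, 95), showfliers=False, tick_labels=sample_ids)
    ax.set_ylabel("proportion of intronic reads (per-gene max = 1)")
    ax.set_ylim(-0.02, 1.02)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
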