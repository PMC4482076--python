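"""Per-biotype transcript-abundance-change matrix across knockdown contrasts.

Summarizes how each transcript class (protein_coding, retained_intron,
lincRNA, ...) responds to each knockdown relative to the control: per
isoform, abundances (FPKM-like) are averaged over a condition's
replicates, a pseudocount stabilizes ratios near zero, and the per-isoform
log2 fold changes are aggregated (mean by default) within each biotype.
The result is the biotype x contrast matrix behind a global heatmap view
of the perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

__all__ = ["BiotypeChangeMatrix", "biotype_change_matrix", "read_abundance_table"]


@dataclass
class BiotypeChangeMatrix:
    """Aggregated log2 fold changes per biotype (rows) and contrast (columns).

    ``n_isoforms`` holds the per-cell isoform count; a biotype appears
    only if it has at least one isoform.
    """

    log2fc: pd.DataFrame
    n_isoforms: pd.DataFrame
    pseudocount: float
    aggregator: str

    def to_tsv(self, path: str | Path) -> None:
        out = self.log2fc.copy()
        out.index.name = "biotype"
        out.to_csv(path, sep="\t")

    def plot_heatmap(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(2 + self.log2fc.shape[1], 1 + 0.4 * self.log2fc.shape[0]))
        vmax = max(1.0, float(np.nanmax(np.abs(self.log2fc.to_numpy()))))
        im = ax.imshow(self.log2fc.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
        ax.set_xticks(range(self.log2fc.shape[1]), self.log2fc.columns, rotation=45, ha="right")
        ax.set_yticks(range(self.log2fc.shape[0]), self.log2fc.index)
        fig.colorbar(im, ax=ax, label="log2 fold change")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV `isoform_id  biotype  <sample columns...>` table."""
    df = pd.read_csv(path, sep="\t")
    required = {"isoform_id", "biotype"}
    if not required <= set(df.columns):
        raise ValueError(f"abundance table must have columns {sorted(required)}")
    return df


def biotype_change_matrix(
    abundances: pd.DataFrame,
    design: pd.DataFrame,
    control_condition: str = "control",
    pseudocount: float = 0.1,
    aggregator: str = "mean",
) -> BiotypeChangeMatrix:
    """Compute the biotype x contrast matrix of aggregated log2 fold changes.

    Parameters
    ----------
    abundances : DataFrame
        Columns ``isoform_id``, ``biotype`` and one non-negative abundance
        column per sample in the design.
    design : DataFrame
        Columns ``sample_id`` and ``condition``; must include the control.
    control_condition : str
        Condition every other condition is contrasted against.
    pseudocount : float
        Added to both numerator and denominator per-condition means before
        taking log2; must be positive.
    aggregator : {'mean', 'median'}
        How per-isoform log2 ratios are combined within a biotype.

    Returns
    -------
    BiotypeChangeMatrix
        Columns named ``<condition>_vs_<control>``.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if aggregator not in ("mean", "median"):
        raise ValueError(f"aggregator must be 'mean' or 'median', got {aggregator!r}")
    conditions = list(dict.fromkeys(design["condition"]))
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent from design")

    sample_cols = [s for s in design["sample_id"]]
    missing = set(sample_cols) - set(abundances.columns)
    if missing:
        raise ValueError(f"abundance table lacks sample columns: {sorted(missing)}")
    values = abundances[sample_cols].to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundances are not allowed")

    # per-condition abundance = mean over that condition's replicates
    cond_means = {}
    for cond in conditions:
        cols = list(design.loc[design["condition"] == cond, "sample_id"])
        cond_means[cond] = abundances[cols].mean(axis=1)

    contrasts = [c for c in conditions if c != control_condition]
    ctrl = cond_means[control_condition] + pseudocount
    log2fc_cols = {}
    for cond in contrasts:
        log2fc_cols[f"{cond}_vs_{control_condition}"] = np.log2(
            (cond_means[cond] + pseudocount) / ctrl
        )
    per_isoform = pd.DataFrame(log2fc_cols)
    per_isoform["biotype"] = abundances["biotype"].to_numpy()

    grouped = per_isoform.groupby("biotype", sort=True)
    agg = grouped.agg(aggregator)
    n = grouped.size()
    n_isoforms = pd.DataFrame({col: n for col in agg.columns})
    return BiotypeChangeMatrix(
        log2fc=agg, n_isoforms=n_isoforms, pseudocount=pseudocount, aggregator=aggregator
    )
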