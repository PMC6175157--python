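"""Minimal per-stage summary figures (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel


def plot_window_scan(windows: pd.DataFrame, ax=None):
    """Manhattan-style plot of window variance percentages along the genome.

    Expects the additive-scan output columns
    (chrom, start_bp, end_bp, n_snps, pct_additive_variance).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for chrom, grp in windows.groupby("chrom", sort=False):
        mid = (grp["start_bp"] + grp["end_bp"]) / 2
        ax.scatter(mid + offset, grp["pct_additive_variance"], s=6)
        ticks.append(offset + mid.max() / 2)
        labels.append(str(chrom))
        offset += int(grp["end_bp"].max()) + 1
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("% additive variance")
    return ax


def plot_genotype_boxplot(phen: pd.DataFrame, panel: GenotypePanel, snp: str, ax=None):
    """Box plot of phenotype values by genotype class (AA/AB/BB) at one SNP."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    j = panel.snp_ids.index(snp)
    codes = dict(zip(panel.animal_ids, panel.codes[:, j]))
    values = {"AA": [], "AB": [], "BB": []}
    label = {0.0: "AA", 1.0: "AB", 2.0: "BB"}
    for animal, val in zip(phen["animal"].astype(str), phen["value"]):
        code = codes.get(animal)
        if code is not None and not np.isnan(code):
            values[label[code]].append(val)
    present = [k for k in ("AA", "AB", "BB") if values[k]]
    ax.boxplot([values[k] for k in present], tick_labels=present)
    ax.set_xlabel(f"{snp} genotype")
    ax.set_ylabel("phenotype")
    return ax
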