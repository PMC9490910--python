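"""Small plotting helpers: Manhattan and Q-Q panels for association
scans and the permutation histogram for the Ghat test."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["manhattan", "qq_plot", "ghat_histogram"]


def _axes(ax):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(9, 3))
    return ax


def manhattan(records: pd.DataFrame, value: str = "p", threshold=None, ax=None):
    """-log10 scatter of a per-variant result along the genome."""
    ax = _axes(ax)
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(records.groupby("chrom", sort=False)):
        x = sub["pos"].to_numpy() + offset
        y = -np.log10(sub[value].to_numpy(dtype=float))
        ax.scatter(x, y, s=4, color=f"C{i % 2}")
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(chrom))
        offset += sub["pos"].max()
    if threshold is not None:
        ax.axhline(-np.log10(threshold), ls="--", color="grey")
    ax.set_xticks(ticks, labels)
    ax.set_ylabel(f"-log10({value})")
    return ax


def qq_plot(p: np.ndarray, ax=None):
    """Observed vs expected -log10 p under uniformity."""
    ax = _axes(ax)
    p = np.sort(np.asarray(p, dtype=float))
    p = p[~np.isnan(p)]
    exp = -np.log10((np.arange(1, len(p) + 1) - 0.5) / len(p))
    ax.scatter(exp, -np.log10(p), s=4)
    lim = max(exp.max(), -np.log10(p.min()))
    ax.plot([0, lim], [0, lim], color="grey", ls="--")
    ax.set_xlabel("expected -log10(p)")
    ax.set_ylabel("observed -log10(p)")
    return ax


def ghat_histogram(result, ax=None):
    """Permutation null histogram with the observed Ghat marked."""
    ax = _axes(ax)
    ax.hist(result.perm_values, bins=40, color="lightsteelblue")
    ax.axvline(result.ghat, color="crimson")
    ax.set_xlabel("Ghat under permutation")
    ax.set_ylabel("count")
    return ax
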