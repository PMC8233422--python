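"""Figure helpers: MCMC trace plots, window-scan Manhattan plot, enrichment dot plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["trace_plot", "manhattan_plot", "enrichment_dotplot"]


def trace_plot(traces: dict[str, np.ndarray], path) -> None:
    names = list(traces)
    fig, axes = plt.subplots(len(names), 1, figsize=(8, 2.2 * len(names)), squeeze=False)
    for ax, name in zip(axes[:, 0], names):
        ax.plot(np.asarray(traces[name]), lw=0.6)
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("retained sample")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def manhattan_plot(window_table: pd.DataFrame, path, title: str = "") -> None:
    """Percentage of additive variance per window against genome position."""
    df = window_table.copy()
    chroms = list(pd.unique(df["chromosome"]))
    offset = 0
    xs, ys, colors = [], [], []
    ticks = []
    palette = ("#3b6aa0", "#9a4f3c")
    for k, c in enumerate(chroms):
        sub = df[df["chromosome"] == c]
        xs.append(sub["start_bp"].to_numpy() + offset)
        ys.append(sub["pct_var"].to_numpy())
        colors.extend([palette[k % 2]] * len(sub))
        ticks.append(offset + sub["start_bp"].max() / 2)
        offset += sub["start_bp"].max() + 1
    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.scatter(np.concatenate(xs), np.concatenate(ys), s=6, c=colors)
    ax.set_xticks(ticks, chroms)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("% additive variance (2-Mb window)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def enrichment_dotplot(results: pd.DataFrame, path, max_terms: int = 20) -> None:
    """Dot plot: % significant genes in term vs term, dot size -log10 P."""
    df = results.head(max_terms).copy()
    if df.empty:
        fig, ax = plt.subplots(figsize=(6, 2))
        ax.text(0.5, 0.5, "no terms", ha="center")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return
    df["pct_sig"] = df["g"] / df["K"] * 100.0
    df["mlogp"] = -np.log10(np.maximum(df["p_value"], 1e-300))
    fig, ax = plt.subplots(figsize=(7, 0.35 * len(df) + 1.5))
    ax.scatter(df["pct_sig"], range(len(df)), s=20 + 15 * df["mlogp"], c="#3b6aa0", alpha=0.8)
    ax.set_yticks(range(len(df)), df["term_name"], fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("% significant genes in term")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
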