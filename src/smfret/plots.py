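"""Cosmetic figures: FRET heatmap with threshold line, rate and RMSF bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_heatmap(heatmap, line=None, ax=None):
    """Donor-acceptor heatmap with the fitted threshold line overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    ax.pcolormesh(
        heatmap.donor_edges,
        heatmap.acceptor_edges,
        heatmap.counts.T,
        cmap="inferno",
        shading="auto",
    )
    if line is not None and np.isfinite(line.slope):
        x = np.array([heatmap.donor_edges[0], heatmap.donor_edges[-1]])
        ax.plot(x, line.slope * x + line.intercept, "w--", lw=1.5)
        ax.set_ylim(heatmap.acceptor_edges[0], heatmap.acceptor_edges[-1])
    ax.set_xlabel("donor intensity (counts)")
    ax.set_ylabel("acceptor intensity (counts)")
    return ax


def plot_rates(rate_estimates: dict, ax=None):
    """Bar chart of k_fold/k_unfold with CRLB error bars per condition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    labels = list(rate_estimates)
    x = np.arange(len(labels))
    kf = [r.k_fold for r in rate_estimates.values()]
    ku = [r.k_unfold for r in rate_estimates.values()]
    ef = [r.se_k_fold for r in rate_estimates.values()]
    eu = [r.se_k_unfold for r in rate_estimates.values()]
    ax.bar(x - 0.2, kf, 0.4, yerr=ef, capsize=3, label="$k_{fold}$")
    ax.bar(x + 0.2, ku, 0.4, yerr=eu, capsize=3, label="$k_{unfold}$")
    ax.set_xticks(x, labels)
    ax.set_ylabel("rate (s$^{-1}$)")
    ax.legend()
    return ax


def plot_rmsf(rmsf_results: dict, ax=None):
    """Bar chart of per-state mean RMSF with jackknife error bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    states = [s for s in ("folded", "unfolded") if s in rmsf_results]
    means = [rmsf_results[s]["mean_rmsf_nm"] for s in states]
    errs = [rmsf_results[s]["jackknife_se_nm"] for s in states]
    ax.bar(states, means, yerr=errs, capsize=4, color=["#4a6fa5", "#c06050"])
    ax.set_ylabel("RMSF (nm)")
    return ax


def save_run_figures(out_dir, classification_results, kinetics_results, rmsf_section):
    out = Path(out_dir)
    ax = plot_heatmap(classification_results.model.heatmap, classification_results.best_line)
    ax.figure.savefig(out / "heatmap.png", dpi=150, bbox_inches="tight")
    plt.close(ax.figure)

    ax = plot_rates({"run": kinetics_results.rates})
    ax.figure.savefig(out / "rates.png", dpi=150, bbox_inches="tight")
    plt.close(ax.figure)

    if rmsf_section and "error" not in rmsf_section:
        ax = plot_rmsf(rmsf_section)
        ax.figure.savefig(out / "rmsf.png", dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
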