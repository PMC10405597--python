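"""Static matplotlib figures for fits and pools (file output only)."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_fit(target, result, path):
    """Overlay target curve with the composite of an ensemble fit."""
    fig, ax = plt.subplots(figsize=(5, 4))
    combo = result.composite
    if result.target_kind == "iq":
        ax.errorbar(target.q_grid, target.intensity, yerr=target.sigma,
                    fmt=".", ms=2, color="k", alpha=0.4, label="experiment")
        scale = result.scale if result.scale is not None else 1.0
        ax.plot(combo.q_grid, scale * combo.intensity, color="C3",
                label=f"ensemble (χ²={result.chi2:.2f})")
        ax.set_yscale("log")
        ax.set_xlabel("q (Å$^{-1}$)")
        ax.set_ylabel("I(q)")
    else:
        if target.errors is not None:
            ax.errorbar(target.r_grid, target.p, yerr=target.errors,
                        fmt=".", ms=2, color="k", alpha=0.4, label="target P(r)")
        else:
            ax.plot(target.r_grid, target.p, "k.", ms=2, label="target P(r)")
        ax.plot(combo.r_grid, combo.p, color="C0",
                label=f"ensemble (χ²={result.chi2:.2f})")
        ax.set_xlabel("r (Å)")
        ax.set_ylabel("P(r)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rg_histogram(result, path, markers=None):
    """Percent contribution vs member Rg, with optional reference markers."""
    hist = result.rg_histogram()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(hist[:, 0], 100 * hist[:, 1], width=0.8, color="C0")
    for label, value in (markers or {}).items():
        ax.axvline(value, ls="--", lw=1, label=label)
    ax.set_xlabel("Rg (Å)")
    ax.set_ylabel("contribution (%)")
    if markers:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pool_rg(pool_a, pool_b, path, n_bins=20):
    """Rg densities of an original pool and its stride sub-selection."""
    all_rg = np.concatenate([pool_a.rg_values, pool_b.rg_values])
    edges = np.linspace(all_rg.min(), all_rg.max() + 1e-9, n_bins + 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.hist(pool_a.rg_values, bins=edges, density=True, histtype="step",
            color="k", label=f"original pool (n={len(pool_a)})")
    ax.hist(pool_b.rg_values, bins=edges, density=True, histtype="step",
            color="C3", label=f"sub-selected (n={len(pool_b)})")
    ax.set_xlabel("Rg (Å)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
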