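"""QQ and Manhattan plots for burden-scan diagnostics."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["qq_plot", "signed_log10_plot", "manhattan"]


def qq_plot(pvalues, path: str, label: str | None = None, lam: float | None = None):
    """Observed vs expected -log10 p with the unit diagonal."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    n = p.size
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    obs = -np.log10(np.clip(p, 1e-300, 1))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, exp.max()], [0, exp.max()], color="grey", lw=1)
    ax.scatter(exp, obs, s=6, color="#2166ac", label=label)
    if lam is not None:
        ax.text(0.05, 0.92, f"$\\lambda_{{GC}}$ = {lam:.2f}", transform=ax.transAxes)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    if label:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def signed_log10_plot(results_a, results_b, path: str, labels=("base", "base+metaPCs")):
    """Signed -log10 p per category before/after metadata-PC adjustment.

    Case/first-group enrichment plots positive, control enrichment negative.
    """
    def signed(rs):
        return [r.direction * -np.log10(max(r.p, 1e-300)) for r in rs]

    x = np.arange(len(results_a))
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.scatter(x, signed(results_a), s=8, label=labels[0], color="#b2182b")
    ax.scatter(x, signed(results_b), s=8, label=labels[1], color="#2166ac")
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel("category")
    ax.set_ylabel("signed $-\\log_{10} p$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def manhattan(window_results, path: str, threshold: float | None = None):
    """Manhattan plot over window midpoints, coloured by chromosome."""
    chroms = sorted({r.chrom for r in window_results})
    offset, offsets = 0, {}
    for c in chroms:
        offsets[c] = offset
        offset += max(r.end for r in window_results if r.chrom == c) + 1
    fig, ax = plt.subplots(figsize=(9, 3.5))
    for i, c in enumerate(chroms):
        rs = [r for r in window_results if r.chrom == c]
        x = [offsets[c] + (r.start + r.end) / 2 for r in rs]
        y = [-np.log10(max(r.p, 1e-300)) for r in rs]
        ax.scatter(x, y, s=4, color=["#2166ac", "#92c5de"][i % 2])
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
    ax.set_xlabel("genomic position")
    ax.set_ylabel("$-\\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
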