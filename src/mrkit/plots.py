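"""Optional scatter and leave-one-out forest plots (requires matplotlib).

The pipeline itself only exports plot *data*; these helpers render the
two standard panels from a harmonized set for quick inspection.
"""

from __future__ import annotations

import numpy as np

from .estimators import egger, ivw, leave_one_out, weighted_median
from .harmonize import HarmonizedSet


def _mpl():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib (pip install mrkit[plot])") from exc
    return plt


def scatter_plot(hset: HarmonizedSet, ax=None, seed: int = 0):
    """SNP outcome effects against exposure effects with fitted MR lines."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    bx, sx, by, sy = hset.arrays()
    ax.errorbar(bx, by, xerr=sx, yerr=sy, fmt="o", ms=3, lw=0.6, alpha=0.6,
                color="0.4", ecolor="0.7")
    xs = np.linspace(0, bx.max() * 1.05, 50)
    est_ivw, _ = ivw(hset, "random")
    ax.plot(xs, est_ivw.beta * xs, label=f"IVW ({est_ivw.beta:.3f})")
    est_eg, pleio = egger(hset)
    ax.plot(xs, pleio.intercept + est_eg.beta * xs, label=f"Egger ({est_eg.beta:.3f})")
    est_wm = weighted_median(hset, n_boot=200, seed=seed)
    ax.plot(xs, est_wm.beta * xs, label=f"Weighted median ({est_wm.beta:.3f})")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("SNP effect on exposure (SD)")
    ax.set_ylabel("SNP effect on outcome (SD)")
    ax.legend(fontsize=7)
    return ax


def loo_forest_plot(hset: HarmonizedSet, ax=None):
    """Leave-one-out pooled estimates, one row per dropped SNP."""
    plt = _mpl()
    loo = leave_one_out(hset)
    full, _ = ivw(hset, "random")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 0.12 * len(loo) + 1))
    ys = np.arange(len(loo))[::-1]
    betas = np.array([e.beta for _, e in loo])
    ses = np.array([e.se for _, e in loo])
    ax.errorbar(betas, ys, xerr=1.959964 * ses, fmt="o", ms=2, lw=0.7, color="0.3")
    ax.axvline(full.beta, color="firebrick", lw=1, label="all SNPs")
    ax.set_yticks(ys)
    ax.set_yticklabels([vid for vid, _ in loo], fontsize=4)
    ax.set_xlabel("pooled IVW estimate without this SNP")
    ax.legend(fontsize=7)
    return ax
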