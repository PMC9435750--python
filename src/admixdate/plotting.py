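"""Plots of admixture probability curves and their fitted decay."""

from __future__ import annotations

import numpy as np

from .curves import CurveSet
from .datefit import FitResult


def plot_curve_set(
    curves: CurveSet,
    fit: FitResult | None = None,
    pairs: list[tuple[str, str]] | None = None,
    path=None,
    max_panels: int = 9,
):
    """Scatter the scaled curves for the given surrogate pairs, overlaying
    the fitted exponential decay when a fit is supplied.  Returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if pairs is None:
        s = curves.surrogates
        pairs = [(u, v) for i, u in enumerate(s) for v in s[i:]][:max_panels]
    n = len(pairs)
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), squeeze=False)
    for ax, (u, v) in zip(axes.flat, pairs):
        g, y = curves.curve(u, v)
        ax.plot(g, y, ".", ms=3, color="k", alpha=0.6)
        if fit is not None:
            i, j = curves.surrogates.index(u), curves.surrogates.index(v)
            gg = np.linspace(g.min(), g.max(), 200)
            yy = fit.tau[i, j] + fit.delta[i, j] * np.exp(-gg / 100.0 * fit.lam)
            if fit.lam2 is not None and fit.delta2 is not None:
                yy = yy + fit.delta2[i, j] * np.exp(-gg / 100.0 * fit.lam2)
            ax.plot(gg, yy, "-", color="C3", lw=1.2)
        ax.set_title(f"{u} - {v}", fontsize=8)
        ax.set_xlabel("distance (cM)", fontsize=7)
        ax.set_ylabel("scaled prob.", fontsize=7)
        ax.tick_params(labelsize=6)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
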