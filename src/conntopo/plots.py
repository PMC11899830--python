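"""Scatter-with-fit plot export for structure-property models."""

from __future__ import annotations

import numpy as np

from .qspr import RegressionFit


def plot_fit(x, y, fit: RegressionFit, xlabel: str = "descriptor",
             ylabel: str = "property", path=None):
    """Scatter the data and overlay the fitted polynomial curve.

    ``fit`` must be a univariate (polynomial) model whose coefficients are
    powers of x.  Saves to ``path`` if given, else returns the figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xs = np.linspace(x.min(), x.max(), 200)
    design = np.column_stack([xs ** d for d in range(1, fit.p + 1)])
    ys = fit.coefficients[0] + design @ fit.coefficients[1:]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=24, color="tab:blue", zorder=3)
    ax.plot(xs, ys, color="tab:red",
            label=f"degree {fit.p}, $r^2$={fit.r_squared:.3f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
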