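"""Plain diagnostic plots (optional; needs matplotlib).

Histograms before/after transformation and outlier deletion, and the
age-versus-value scatter used to eyeball the age trend behind the rank
correlation.  These are working diagnostics, not publication figures.
"""

from __future__ import annotations

import numpy as np

from .transform import boxcox


def _plt():
    try:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plots need matplotlib (pip install refint[plots])") from exc
    return plt


def transformation_histograms(values, lam: float, final_values=None, path=None):
    """Histograms of raw, transformed, and (optionally) outlier-deleted data."""
    plt = _plt()
    values = np.asarray(values, dtype=float)
    panels = [("raw", values), (f"Box-Cox (lambda={lam:.3f})", boxcox(values, lam))]
    if final_values is not None:
        panels.append(("transformed, outliers deleted",
                       boxcox(np.asarray(final_values, dtype=float), lam)))
    fig, axes = plt.subplots(1, len(panels), figsize=(4 * len(panels), 3))
    for ax, (title, data) in zip(np.atleast_1d(axes), panels):
        ax.hist(data, bins=60, color="steelblue")
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig


def age_scatter(age, value, path=None, logy: bool = True):
    """Age versus analyte value, one point per subject."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(age, value, s=4, alpha=0.3, color="dimgray")
    if logy:
        ax.set_yscale("log")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("value (ug/L)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
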