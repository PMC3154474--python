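"""Basic heat-map and class-histogram rendering (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .compare import ClassHistogram, ComparisonMatrix

_CLASS_STYLES = {"None": ":", "default": "-"}


def heatmap(matrix: ComparisonMatrix, ax=None, cmap: str = "Greys"):
    """Parameters x comparisons heat map of |cell| values."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4 + 0.6 * len(matrix.data.columns),
                                      0.3 * len(matrix.data) + 1.5))
    values = np.abs(matrix.data.to_numpy(dtype=float))
    im = ax.imshow(values, aspect="auto", cmap=cmap)
    ax.set_xticks(range(len(matrix.data.columns)), matrix.data.columns,
                  rotation=45, ha="right")
    ax.set_yticks(range(len(matrix.data)), matrix.data.index, fontsize=7)
    label = {"z": "|Z|", "ks": "KS statistic", "ks_ratio": "KS ratio"}[matrix.statistic]
    ax.figure.colorbar(im, ax=ax, label=label)
    ax.figure.tight_layout()
    return ax


def class_histogram(hist: ClassHistogram, ax=None):
    """Overlaid per-class curves, jointly normalized; reference as vline."""
    if ax is None:
        _, ax = plt.subplots()
    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2.0
    for name, mass in hist.masses.items():
        style = _CLASS_STYLES.get(name, _CLASS_STYLES["default"])
        ax.plot(centers, mass, style, label=f"{name} ({hist.class_mass(name):.2f})")
    if hist.reference is not None:
        ax.axvline(hist.reference.value, linestyle="--", color="k",
                   label=hist.reference.source_tag or "reference")
    ax.set_xlabel(hist.parameter or "parameter value")
    ax.set_ylabel("fraction of all frames")
    ax.legend(fontsize=8)
    return ax
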