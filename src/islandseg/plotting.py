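"""Static plots mirroring the standard soma-to-input figures."""

from __future__ import annotations

import numpy as np


def plot_soma_to_inputs(record, input_positions, axes=(0, 1), ax=None):
    """Soma (blue), input cloud (gray) and mean input position (black ring).

    ``record`` is an :class:`~islandseg.asymmetry.AsymmetryRecord`;
    ``axes`` picks the two coordinate axes of the 2-D projection.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pts = np.atleast_2d(np.asarray(input_positions, dtype=float))
    i, j = axes
    ax.scatter(pts[:, i], pts[:, j], s=8, c="0.6", label="RGC inputs")
    ax.scatter([record.soma_position[i]], [record.soma_position[j]],
               s=60, c="tab:blue", label="soma")
    ax.scatter([record.mean_input_position[i]], [record.mean_input_position[j]],
               s=80, facecolors="none", edgecolors="k", label="mean input")
    ax.annotate(
        "", xy=(record.mean_input_position[i], record.mean_input_position[j]),
        xytext=(record.soma_position[i], record.soma_position[j]),
        arrowprops=dict(arrowstyle="->", color="k", lw=1),
    )
    ax.set_xlabel(f"axis {i} (μm)")
    ax.set_ylabel(f"axis {j} (μm)")
    ax.set_title(record.neuron_id)
    ax.set_aspect("equal")
    ax.legend(fontsize=8, frameon=False)
    return ax


def plot_null_distribution(result, ax=None):
    """Empirical (bars) vs exact (dots) captured-count null, with threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    n = result.model.n_cells
    x = np.arange(n + 1)
    ax.bar(x, result.empirical_pmf, color="0.8", label="Monte Carlo")
    ax.plot(x, result.exact_pmf, "k.", label="exact")
    for level, c in result.percentile_thresholds.items():
        ax.axvline(c + 0.5, color="r", ls="--", lw=1, label=f"{level:.0%} at {c}")
    if result.observed is not None:
        ax.axvline(result.observed, color="tab:blue", lw=1.5, label=f"observed {result.observed}")
    ax.set_xlabel("captured cells")
    ax.set_ylabel("probability")
    ax.legend(fontsize=8, frameon=False)
    return ax
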