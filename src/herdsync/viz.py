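"""Optional plotting helper: box plot of synchrony proportions by role."""

from __future__ import annotations

from .scoring import COMPARISON_ROLES, SyncMatrix

_ROLE_LABELS = {
    "neighbour1": "Nearest",
    "neighbour2": "2nd nearest",
    "neighbour3": "3rd nearest",
    "control": "Control",
}


def plot_sync_boxplot(matrix: SyncMatrix, expected: float | None = None,
                      ax=None, path=None):
    """Box plot of per-session synchrony proportions per comparison role.

    Parameters
    ----------
    matrix : SyncMatrix
    expected : float, optional
        Independence expectation drawn as a dotted reference line.
    ax : matplotlib Axes, optional
    path : optional
        If given, the figure is saved there.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    props = matrix.proportions()
    cols = [r.value for r in COMPARISON_ROLES]
    ax.boxplot([props[c] for c in cols],
               tick_labels=[_ROLE_LABELS[c] for c in cols])
    if expected is not None:
        ax.axhline(expected, linestyle=":", color="grey",
                   label=f"independence ({expected:.3f})")
        ax.legend(frameon=False)
    ax.set_ylabel(f"Proportion of synchronised scans ({matrix.mode})")
    ax.set_ylim(-0.02, 1.02)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
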