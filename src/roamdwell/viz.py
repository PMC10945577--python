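"""Optional diagnostic plots (requires matplotlib; install the ``plot``
extra). Nothing in the pipeline emits figures unless asked."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .types import IntervalFeature


def plot_speed_bend_scatter(
    intervals: Sequence[IntervalFeature],
    cutoff_um_s: float,
    path: str | Path,
) -> None:
    """Speed vs. bending-angle scatter with the horizontal cutoff line.

    One point per 10-s interval; points above the line are roaming. Saved
    to ``path`` (format from the file extension).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bends = [iv.mean_bend_deg for iv in intervals]
    speeds = [iv.mean_speed_um_s for iv in intervals]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(bends, speeds, s=8, alpha=0.5, edgecolors="none")
    ax.axhline(cutoff_um_s, color="crimson", lw=1.2, label=f"cutoff {cutoff_um_s:g} um/s")
    ax.set_xlabel("bending angle (deg)")
    ax.set_ylabel("speed (um/s)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
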