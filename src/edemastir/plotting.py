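"""Figure helpers: relaxation-trajectory panel and AHA bullseye summary."""

from __future__ import annotations

from typing import Dict, Iterable, Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .aha_segments import SEGMENTS_PER_LEVEL
from .mr_signal import REFERENCE_TISSUES, SequenceParams, TissueParams, relaxation_curves

__all__ = ["plot_relaxation_panel", "plot_bullseye"]


def plot_relaxation_panel(
    seq: SequenceParams,
    tissues: Sequence[TissueParams] = REFERENCE_TISSUES,
    path=None,
    n_points: int = 300,
):
    """Two-phase magnetization panel: Mz recovery over [0, TI] followed by
    transverse decay over [TI, TI+TE] for each tissue.

    Visualizes why the inversion pulse makes long T1 and long T2 act in the
    same direction for the remote/edema pair while nulling fat.
    """
    curves = relaxation_curves(tissues, seq, n_points=n_points)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for tissue in tissues:
        c = curves[tissue.name]
        (line,) = ax.plot(c.t_longitudinal, c.mz, label=f"{tissue.name} ({tissue.t1:.0f}/{tissue.t2:.0f} ms)")
        ax.plot(c.t_transverse, c.mxy, linestyle="--", color=line.get_color())
    ax.axvline(seq.ti, color="k", linewidth=0.8, linestyle=":")
    ax.axhline(0.0, color="k", linewidth=0.5)
    ax.set_xlabel("time after inversion (ms)")
    ax.set_ylabel("Mz (solid) / |Mxy| (dashed), fraction of M0")
    ax.set_title(f"STIR magnetization, TI {seq.ti:.0f} ms, TE {seq.te:.0f} ms")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_bullseye(grades_by_segment: Mapping[int, int], path=None, title: str = "segment grades"):
    """Bullseye of the 16-segment model colored by grade (1-4).

    Rings from outside in: basal, mid, apical.
    """
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    cmap = plt.get_cmap("YlOrRd")
    radii = {"basal": (2.0, 3.0), "mid": (1.0, 2.0), "apical": (0.0, 1.0)}
    for level, (first, count) in SEGMENTS_PER_LEVEL.items():
        width = 2 * np.pi / count
        r0, r1 = radii[level]
        for k in range(count):
            seg = first + k
            grade = grades_by_segment.get(seg, 1)
            ax.bar(
                x=k * width,
                height=r1 - r0,
                width=width,
                bottom=r0,
                align="edge",
                color=cmap((grade - 1) / 3),
                edgecolor="k",
                linewidth=0.5,
            )
            ax.text(k * width + width / 2, (r0 + r1) / 2, str(seg), ha="center", va="center", fontsize=7)
    ax.set_yticks([])
    ax.set_xticks([])
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
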