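"""Phonovibrogram (PVG): fold position x time map of edge displacement.

The PVG unfolds both vocal-fold edges into a single image: the upper half
shows the left fold (posterior at the top edge, anterior towards the
middle row), the lower half the right fold mirrored (anterior at the middle
row, posterior at the bottom edge), so the centre of the diagram is the
anterior glottis.  Pixel intensity is the instantaneous lateral
displacement of the edge from the glottal midline, normalized to [0, 1] by
the recording's maximum width — brightness increases with oscillation
amplitude, and a lesion-silenced region appears as a dark horizontal band
on the involved fold's half.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import EdgeTrajectory

__all__ = ["PVGMatrix", "compute_pvg", "render_pvg"]


@dataclass
class PVGMatrix:
    """PVG intensity matrix of shape (2 * n_positions, n_frames).

    Rows ``0 .. P-1``: left fold, posterior to anterior, top to middle.
    Rows ``P .. 2P-1``: right fold, anterior to posterior, middle to bottom.
    Values lie in [0, 1].
    """

    values: np.ndarray
    positions: np.ndarray
    fps: float

    @property
    def n_positions(self) -> int:
        return self.values.shape[0] // 2


def compute_pvg(traj: EdgeTrajectory) -> PVGMatrix:
    """Build the PVG matrix from an edge trajectory.

    An all-zero trajectory (phonatory silence) yields an all-zero matrix.
    """
    wl = traj.widths_left.T  # (P, T), row order = posterior..anterior
    wr = traj.widths_right.T
    upper = wl
    lower = wr[::-1, :]  # anterior..posterior, middle-to-bottom
    values = np.vstack([upper, lower])
    peak = values.max(initial=0.0)
    if peak > 0:
        values = values / peak
    return PVGMatrix(values=values, positions=traj.positions.copy(), fps=traj.fps)


def render_pvg(pvg: PVGMatrix, path, cmap: str = "magma") -> None:
    """Write the PVG as a PNG heat map.

    ``cmap="magma"`` is perceptually uniform; ``cmap="Reds_r"`` gives a
    red-tinted rendering closer to clinical PVG displays.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plt.imsave(path, pvg.values, cmap=cmap, vmin=0.0, vmax=1.0)
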