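"""Edge-trajectory container shared by every stage of the pipeline.

An :class:`EdgeTrajectory` stores, for each video frame and each of ``P``
sample positions along the glottal (anterior-posterior) axis, the lateral
half-width of the left and right vocal-fold edge measured from the glottal
midline.  Positions are normalized: ``p = 0`` is the posterior commissure,
``p = 1`` the anterior commissure.  Widths may be expressed either in pixels
(``units="px"``) or as a percentage of the total fold length
(``units="%FL"``), the unit in which all amplitude parameters are reported.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

__all__ = ["EdgeTrajectory"]


@dataclass
class EdgeTrajectory:
    """Per-frame, per-position half-widths of both vocal-fold edges.

    Parameters
    ----------
    widths_left, widths_right : ndarray, shape (n_frames, n_positions)
        Non-negative distance of each fold edge from the glottal midline.
    fps : float
        Sampling rate of the recording in frames per second.
    positions : ndarray, shape (n_positions,)
        Strictly increasing normalized axis coordinates in [0, 1];
        index 0 is posterior, the last index anterior.
    fold_length : float
        Reference glottal length (anterior-posterior commissure distance).
        In pixels when ``units == "px"``; by convention 100 when widths are
        already percentages of fold length.
    units : {"%FL", "px"}
        Unit of the stored widths.
    involved_side : {"left", "right", None}
        Side bearing the unilateral lesion, when known.
    """

    widths_left: np.ndarray
    widths_right: np.ndarray
    fps: float
    positions: np.ndarray
    fold_length: float = 100.0
    units: str = "%FL"
    involved_side: str | None = None

    def __post_init__(self) -> None:
        self.widths_left = np.asarray(self.widths_left, dtype=float)
        self.widths_right = np.asarray(self.widths_right, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.widths_left.ndim != 2:
            raise ValidationError("width matrices must be 2-D (frames x positions)")
        if self.widths_left.shape != self.widths_right.shape:
            raise ValidationError(
                f"width matrices differ in shape: {self.widths_left.shape} "
                f"vs {self.widths_right.shape}"
            )
        if self.positions.shape != (self.widths_left.shape[1],):
            raise ValidationError("positions length must match width columns")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any(self.widths_left < 0) or np.any(self.widths_right < 0):
            raise ValidationError("widths must be non-negative")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if self.units not in ("%FL", "px"):
            raise ValidationError(f"unknown units {self.units!r}")
        if self.involved_side not in (None, "left", "right"):
            raise ValidationError(f"invalid involved_side {self.involved_side!r}")

    @property
    def n_frames(self) -> int:
        return self.widths_left.shape[0]

    @property
    def n_positions(self) -> int:
        return self.widths_left.shape[1]

    @property
    def duration_ms(self) -> float:
        """Total sequence duration in milliseconds."""
        return 1000.0 * self.n_frames / self.fps

    def to_percent_fold_length(self) -> "EdgeTrajectory":
        """Return a copy with widths expressed in %FL.

        Pixel widths are normalized by the reference ``fold_length`` shared
        by both folds; a trajectory already in %FL is returned unchanged
        (same arrays, no copy).
        """
        if self.units == "%FL":
            return self
        factor = 100.0 / self.fold_length
        return replace(
            self,
            widths_left=self.widths_left * factor,
            widths_right=self.widths_right * factor,
            fold_length=100.0,
            units="%FL",
        )
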