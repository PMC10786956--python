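"""Semi-automatic vocal-fold edge extraction from a frame stack.

Mirrors the clinical workflow: the examiner marks five points on a single
representative frame — the posterior and anterior commissures, one point on
each fold's edge, and one point inside the glottal gap — and the software
propagates the edge detection to all frames and along the whole glottal
length.  The glottal axis runs through the two commissures; ``P``
evenly-spaced scanlines perpendicular to it sample the gap, and each
scanline's left/right half-width is the distance from the axis to the
sub-pixel threshold crossing of the image intensity on that side (0 where
the gap is closed).

Because endoscope motion over such a short sequence is negligible, neither
the axis nor the intensity threshold is re-estimated per frame: the Otsu
threshold computed inside a region of interest around the axis on the
representative frame is reused for the whole stack.

Coordinates are image row/column with the origin at the top-left; axis
position ``p`` is 0 at the posterior and 1 at the anterior commissure.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import opening as morphological_opening

from .errors import EmptyStackError, SeedingError, ValidationError
from .render import FrameStack
from .trajectory import EdgeTrajectory

__all__ = ["SeedPoints", "GlottalAxis", "SegConfig", "axis_from_seeds", "segment_glottis"]


@dataclass
class SeedPoints:
    """Five examiner-marked (row, col) points on one representative frame."""

    posterior: tuple[float, float]
    anterior: tuple[float, float]
    left_edge: tuple[float, float]
    right_edge: tuple[float, float]
    gap: tuple[float, float]
    frame_index: int = 0

    def __post_init__(self) -> None:
        if np.allclose(self.posterior, self.anterior):
            raise ValidationError("commissure points coincide: degenerate axis")


@dataclass
class GlottalAxis:
    """Directed glottal axis with perpendicular scanlines.

    ``normal`` points towards the side labelled *left*, fixed by the
    left-edge seed: whichever side of the directed axis that seed lies on
    becomes the left side.
    """

    posterior: np.ndarray
    anterior: np.ndarray
    direction: np.ndarray
    normal: np.ndarray
    length: float
    positions: np.ndarray  # normalized scanline coordinates in [0, 1]

    def scanline_origin(self, p: float) -> np.ndarray:
        return self.posterior + self.direction * (p * self.length)


@dataclass
class SegConfig:
    """Segmentation settings.

    ``roi_margin`` is the half-width (px) of the rectangular region of
    interest around the axis used both for Otsu thresholding and as the
    maximal measurable half-width.
    """

    n_positions: int = 64
    roi_margin: float = 24.0
    threshold: str = "otsu"
    morph_open: bool = True

    def __post_init__(self) -> None:
        if self.threshold != "otsu":
            raise ValidationError(f"unsupported threshold method {self.threshold!r}")


def axis_from_seeds(seeds: SeedPoints, n_positions: int = 64) -> GlottalAxis:
    """Construct the glottal axis and scanline geometry from seed points."""
    post = np.asarray(seeds.posterior, dtype=float)
    ant = np.asarray(seeds.anterior, dtype=float)
    v = ant - post
    length = float(np.hypot(*v))
    u = v / length
    # candidate normal: u rotated +90 degrees in (row, col) space
    normal = np.array([-u[1], u[0]])
    d_left = np.asarray(seeds.left_edge, dtype=float) - post
    if np.dot(d_left, normal) < 0:
        normal = -normal
    return GlottalAxis(
        posterior=post,
        anterior=ant,
        direction=u,
        normal=normal,
        length=length,
        positions=np.linspace(0.0, 1.0, n_positions),
    )


def _roi_slices(axis: GlottalAxis, margin: float, shape: tuple[int, int]):
    pts = np.stack([axis.posterior, axis.anterior])
    lo = np.floor(pts.min(axis=0) - margin).astype(int)
    hi = np.ceil(pts.max(axis=0) + margin).astype(int) + 1
    lo = np.clip(lo, 0, None)
    return slice(lo[0], min(hi[0], shape[0])), slice(lo[1], min(hi[1], shape[1]))


def _check_gap_seed(frame: np.ndarray, seeds: SeedPoints, axis: GlottalAxis,
                    config: SegConfig, tau: float) -> None:
    """Verify the gap seed lies inside a dark connected component."""
    dark = frame < tau
    if config.morph_open:
        dark = morphological_opening(dark, footprint=np.ones((3, 3), dtype=bool))
    labels = cc_label(dark, connectivity=2)
    r, c = int(round(seeds.gap[0])), int(round(seeds.gap[1]))
    if not (0 <= r < frame.shape[0] and 0 <= c < frame.shape[1]):
        raise SeedingError("gap seed outside the image")
    if labels[r, c] == 0:
        raise SeedingError(
            "gap seed does not fall inside a dark glottal-gap component "
            "on the representative frame"
        )


def _subpixel_widths(profiles: np.ndarray, offsets: np.ndarray, tau: float
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Half-widths from intensity profiles across the axis.

    ``profiles`` has shape (P, D) sampled at lateral ``offsets`` (1 px
    steps, negative = right side, positive = left side, 0 on the axis).
    For scanlines whose on-axis sample is below the threshold, the
    boundary on each side is located at the linearly-interpolated crossing
    of ``tau``; closed scanlines get zero widths.
    """
    n_p, n_d = profiles.shape
    c = int(np.nonzero(offsets == 0)[0][0])
    open_mask = profiles[:, c] < tau
    wl = np.zeros(n_p)
    wr = np.zeros(n_p)
    if not np.any(open_mask):
        return wl, wr

    def crossing(block: np.ndarray) -> np.ndarray:
        """Distance (samples) from column 0 to the first >= tau crossing."""
        above = block >= tau
        hit = above.any(axis=1)
        first = np.argmax(above, axis=1)  # 0 when no hit; masked below
        first = np.where(hit, first, block.shape[1] - 1)
        i0 = np.maximum(first - 1, 0)
        y0 = block[np.arange(len(block)), i0]
        y1 = block[np.arange(len(block)), np.maximum(first, 1)]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(y1 != y0, (tau - y0) / (y1 - y0), 0.0)
        dist = i0 + np.clip(frac, 0.0, 1.0)
        return np.where(hit, dist, float(block.shape[1] - 1))

    rows = np.nonzero(open_mask)[0]
    wl[rows] = crossing(profiles[rows, c:])
    wr[rows] = crossing(profiles[rows, c::-1])
    return wl, wr


def segment_glottis(
    frames: FrameStack, seeds: SeedPoints, config: SegConfig | None = None
) -> EdgeTrajectory:
    """Extract the edge trajectory of a whole frame stack.

    Returns widths in pixels (``units="px"``) with ``fold_length`` equal to
    the commissure distance; the ``involved_side`` recorded in the stack
    metadata, when present, is carried through.

    Raises
    ------
    EmptyStackError
        If the stack holds no frames.
    SeedingError
        If the gap seed is not inside a dark component on the
        representative frame.
    """
    if config is None:
        config = SegConfig()
    if frames.n_frames == 0:
        raise EmptyStackError("frame stack is empty")
    if not 0 <= seeds.frame_index < frames.n_frames:
        raise ValidationError(
            f"representative frame {seeds.frame_index} outside stack "
            f"of {frames.n_frames} frames"
        )

    axis = axis_from_seeds(seeds, n_positions=config.n_positions)
    rep = frames.frames[seeds.frame_index].astype(float)
    rs, cs = _roi_slices(axis, config.roi_margin, rep.shape)
    tau = float(threshold_otsu(rep[rs, cs]))
    _check_gap_seed(rep, seeds, axis, config, tau)

    # Sampling grid: for each scanline p and lateral offset d, an image point.
    d_max = int(np.ceil(config.roi_margin))
    offsets = np.arange(-d_max, d_max + 1, dtype=float)
    origins = axis.posterior[None, :] + axis.positions[:, None] * axis.length * axis.direction[None, :]
    coords = origins[:, None, :] + offsets[None, :, None] * axis.normal[None, None, :]
    coord_rows = coords[..., 0].ravel()
    coord_cols = coords[..., 1].ravel()
    shape = (len(axis.positions), len(offsets))

    wl = np.zeros((frames.n_frames, len(axis.positions)))
    wr = np.zeros_like(wl)
    for t in range(frames.n_frames):
        prof = ndi.map_coordinates(
            frames.frames[t].astype(float),
            [coord_rows, coord_cols],
            order=1,
            mode="nearest",
        ).reshape(shape)
        wl[t], wr[t] = _subpixel_widths(prof, offsets, tau)

    return EdgeTrajectory(
        widths_left=wl,
        widths_right=wr,
        fps=frames.fps,
        positions=axis.positions,
        fold_length=axis.length,
        units="px",
        involved_side=frames.meta.get("involved_side"),
    )
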