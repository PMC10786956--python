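"""Rasterize an edge trajectory into a synthetic endoscopic frame stack.

The renderer draws, for every frame, a dark glottal-gap region on a bright
mucosa background: at axis position ``s`` the gap spans the interval
``[-w_R(s), +w_L(s)]`` perpendicular to the glottal axis.  Pixel values use
exact area coverage along both the lateral and longitudinal pixel extent,
so edges are linearly anti-aliased and the rendered boundary encodes the
ground-truth width with sub-pixel fidelity — which is what makes the
renderer usable as an oracle for segmentation accuracy.

No attempt is made to render mucosa texture, color, or specular highlights;
the stack emulates geometry, not appearance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .trajectory import EdgeTrajectory

__all__ = ["RenderParams", "FrameStack", "render_frames"]


@dataclass
class RenderParams:
    """Geometry and photometry of the rendered stack."""

    shape: tuple[int, int] = (128, 128)
    fold_length_px: float = 96.0
    center: tuple[float, float] | None = None  # (row, col); image centre if None
    angle_deg: float = 0.0  # axis direction, 0 = horizontal (posterior left)
    mucosa_intensity: float = 200.0
    gap_intensity: float = 30.0
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class FrameStack:
    """Stack of 8-bit grayscale frames plus acquisition metadata."""

    frames: np.ndarray  # (T, H, W) uint8
    fps: float
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def render_frames(traj: EdgeTrajectory, render: RenderParams) -> FrameStack:
    """Render every frame of a trajectory as a grayscale image.

    Deterministic for a fixed ``render.seed``.  Raises
    :class:`GeometryError` when the glottis (axis plus maximal width) would
    not fit inside the image.
    """
    h, w = render.shape
    center = render.center if render.center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    length = float(render.fold_length_px)

    ang = np.deg2rad(render.angle_deg)
    u = np.array([np.sin(ang), np.cos(ang)])  # along-axis unit, (row, col)
    normal = np.array([-np.cos(ang), np.sin(ang)])  # left side of the directed axis

    posterior = np.asarray(center) - u * length / 2.0
    anterior = np.asarray(center) + u * length / 2.0

    traj_fl = traj.to_percent_fold_length()
    px = length / 100.0  # %FL -> px
    wl_px = traj_fl.widths_left * px
    wr_px = traj_fl.widths_right * px

    # Geometry check: axis endpoints displaced by the maximal width (plus a
    # 1 px anti-aliasing margin) must stay inside the image.
    max_w = max(wl_px.max(initial=0.0), wr_px.max(initial=0.0))
    for endpoint in (posterior, anterior):
        for side in (1.0, -1.0):
            r, c = endpoint + side * normal * (max_w + 1.0)
            if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
                raise GeometryError(
                    f"glottis (max width {max_w:.1f} px) does not fit inside "
                    f"a {h}x{w} image with the given axis placement"
                )

    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float), indexing="ij")
    d_row, d_col = rr - posterior[0], cc - posterior[1]
    s = d_row * u[0] + d_col * u[1]  # along-axis coordinate, px
    d = d_row * normal[0] + d_col * normal[1]  # lateral coordinate, +left

    s_flat = s.ravel()
    d_flat = d.ravel()
    s_norm = np.clip(s_flat / length, 0.0, 1.0)

    # longitudinal coverage of each pixel by the [0, length] axis interval
    cov_long = np.clip(
        np.minimum(s_flat + 0.5, length) - np.maximum(s_flat - 0.5, 0.0), 0.0, 1.0
    )

    rng = np.random.default_rng(render.seed)
    frames = np.empty((traj.n_frames, h, w), dtype=np.uint8)
    pos = traj_fl.positions
    for t in range(traj.n_frames):
        wl_t = np.interp(s_norm, pos, wl_px[t])
        wr_t = np.interp(s_norm, pos, wr_px[t])
        # lateral coverage of the pixel [d-0.5, d+0.5] by the gap [-wr, wl]
        cov_lat = np.clip(
            np.minimum(wl_t, d_flat + 0.5) - np.maximum(-wr_t, d_flat - 0.5),
            0.0,
            1.0,
        )
        coverage = (cov_lat * cov_long).reshape(h, w)
        img = render.mucosa_intensity + (
            render.gap_intensity - render.mucosa_intensity
        ) * coverage
        if render.noise_sd > 0:
            img = img + rng.normal(0.0, render.noise_sd, size=img.shape)
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    meta = {
        "fps": traj.fps,
        "fold_length_px": length,
        "axis_posterior": [float(posterior[0]), float(posterior[1])],
        "axis_anterior": [float(anterior[0]), float(anterior[1])],
        "seed": render.seed,
        "involved_side": traj.involved_side,
        "mucosa_intensity": render.mucosa_intensity,
        "gap_intensity": render.gap_intensity,
    }
    return FrameStack(frames=frames, fps=traj.fps, meta=meta)
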