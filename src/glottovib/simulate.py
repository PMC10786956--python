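"""Synthetic glottal-vibration generator with ground-truth parameters.

The simulator produces :class:`~glottovib.trajectory.EdgeTrajectory` objects
that emulate what kymographic edge tracking extracts from a high-speed
videoendoscopy (HSV) recording: two vocal-fold edges oscillating in
near-mirror motion at a fundamental frequency f0, sampled at ``fps`` frames
per second over ``n_frames`` frames (defaults 3200 fps / 2000 frames, i.e.
a 625 ms sequence).

Model
-----
Each fold's half-width from the glottal midline is a half-wave-rectified
sinusoid::

    w_F(p, t) = max(0, rest_F(p) + a_F(p) * sin(2*pi*f0*t/fps - lag_F(p)) + noise)

For perfect mirror-symmetric motion the two half-width signals are *in
phase* (both folds abduct and adduct together), so the resultant gap width
``g = w_L + w_R`` oscillates with amplitude ``a_L + a_R``.  All phase lags
are expressed as deviations of the right fold from this mirror reference.

A unilateral lesion is modelled as a raised-cosine spatial bump centred at a
normalized axis position: inside the bump, the involved fold's amplitude is
scaled by ``amplitude_gain`` (stiffening), its phase lags by
``added_phase_lag`` (increased inertia), and the *local rest width of both
folds* is shifted by ``closure_offset`` (a negative offset models a mass
occluding the gap and produces genuinely non-opening regions).

Cohort generation draws per-subject parameters from truncated normal
distributions, one spec per diagnosis group (norm / benign / malignant),
calibrated so that group medians of the downstream vibratory parameters are
ordered as observed clinically: amplitudes and open quotient decrease, and
asymmetry and phase-difference measures increase, from normophonic subjects
through benign to malignant lesions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DurationError, SamplingRateError, ValidationError
from .trajectory import EdgeTrajectory

__all__ = [
    "LesionModel",
    "VibrationParams",
    "TruncNorm",
    "GroupSpec",
    "CohortSpec",
    "simulate_trajectory",
    "simulate_cohort",
    "default_cohort_spec",
    "lesion_bump",
]


@dataclass
class LesionModel:
    """Unilateral lesion acting on a compact region of one fold.

    ``amplitude_gain`` multiplies the local oscillation amplitude of the
    involved fold (1 = no effect, 0 = phonatory silence); ``added_phase_lag``
    (degrees) delays the involved fold locally; ``closure_offset`` (%FL) is
    added to the local rest half-width of both folds, negative values
    narrowing or fully occluding the gap.
    """

    side: str = "right"
    center: float = 0.5
    extent: float = 0.25
    amplitude_gain: float = 0.5
    added_phase_lag: float = 0.0
    closure_offset: float = 0.0
    severity_label: str = "benign"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"lesion side must be left/right, got {self.side!r}")
        if not 0.0 <= self.amplitude_gain <= 1.0:
            raise ValidationError("amplitude_gain must lie in [0, 1]")
        if not 0.0 <= self.center <= 1.0:
            raise ValidationError("lesion center must lie in [0, 1]")
        if self.extent <= 0:
            raise ValidationError("lesion extent must be positive")


@dataclass
class VibrationParams:
    """Geometry and oscillation parameters of one simulated recording."""

    f0: float = 160.0
    fps: float = 3200.0
    n_frames: int = 2000
    n_positions: int = 64
    fold_length: float = 100.0
    base_amplitude_left: float = 4.2
    base_amplitude_right: float = 4.2
    amplitude_profile: str = "half-sine"
    rest_halfwidth: float = 1.5
    phase_lag_right: float = 0.0
    noise_sd: float = 0.0
    lesion: LesionModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValidationError("f0 must be positive")
        if self.n_positions < 8:
            raise ValidationError("need at least 8 axis positions")
        if self.base_amplitude_left < 0 or self.base_amplitude_right < 0:
            raise ValidationError("amplitudes must be non-negative")
        if not 0.0 <= self.phase_lag_right < 360.0:
            raise ValidationError("phase_lag_right must lie in [0, 360)")
        if self.amplitude_profile not in ("half-sine", "constant"):
            raise ValidationError(
                f"unknown amplitude_profile {self.amplitude_profile!r}"
            )


def lesion_bump(positions: np.ndarray, lesion: LesionModel) -> np.ndarray:
    """Raised-cosine spatial weight of a lesion, 1 at its centre, 0 outside
    ``[center - extent, center + extent]``."""
    u = (np.asarray(positions, float) - lesion.center) / lesion.extent
    bump = 0.5 * (1.0 + np.cos(np.pi * np.clip(u, -1.0, 1.0)))
    bump[np.abs(u) >= 1.0] = 0.0
    return bump


def simulate_trajectory(params: VibrationParams) -> EdgeTrajectory:
    """Simulate an edge trajectory from explicit vibration parameters.

    Deterministic for a fixed ``params.seed``.  Widths are produced in %FL.

    Raises
    ------
    SamplingRateError
        If ``fps <= 2 * f0`` (oscillation not resolvable).
    DurationError
        If the sequence holds fewer than two full periods.
    """
    if params.fps <= 2.0 * params.f0:
        raise SamplingRateError(
            f"fps={params.fps} does not resolve f0={params.f0} Hz "
            "(need fps > 2*f0)"
        )
    if params.n_frames < 2.0 * params.fps / params.f0:
        raise DurationError(
            f"{params.n_frames} frames hold fewer than two periods of "
            f"f0={params.f0} Hz at {params.fps} fps"
        )

    p = np.linspace(0.0, 1.0, params.n_positions)
    if params.amplitude_profile == "half-sine":
        profile = np.sin(np.pi * p)
    else:
        profile = np.ones_like(p)
    amp = {
        "left": params.base_amplitude_left * profile,
        "right": params.base_amplitude_right * profile,
    }
    rest = {
        "left": np.full_like(p, params.rest_halfwidth),
        "right": np.full_like(p, params.rest_halfwidth),
    }
    lag_deg = {"left": np.zeros_like(p), "right": np.full_like(p, params.phase_lag_right)}

    if params.lesion is not None:
        bump = lesion_bump(p, params.lesion)
        side = params.lesion.side
        amp[side] = amp[side] * (1.0 - (1.0 - params.lesion.amplitude_gain) * bump)
        lag_deg[side] = lag_deg[side] + params.lesion.added_phase_lag * bump
        # The occluding mass narrows the gap on both sides of the midline,
        # over a core narrower than the stiffened region (the mass sits at
        # the lesion centre; stiffening spreads through the fold tissue).
        core = replace(params.lesion, extent=0.6 * params.lesion.extent)
        closure_bump = lesion_bump(p, core)
        for s in ("left", "right"):
            rest[s] = rest[s] + params.lesion.closure_offset * closure_bump

    theta = 2.0 * np.pi * params.f0 * np.arange(params.n_frames) / params.fps
    rng = np.random.default_rng(params.seed)

    widths = {}
    for s in ("left", "right"):
        phase = theta[:, None] - np.deg2rad(lag_deg[s])[None, :]
        w = rest[s][None, :] + amp[s][None, :] * np.sin(phase)
        if params.noise_sd > 0:
            w = w + rng.normal(0.0, params.noise_sd, size=w.shape)
        widths[s] = np.maximum(w, 0.0)

    involved = params.lesion.side if params.lesion is not None else None
    return EdgeTrajectory(
        widths_left=widths["left"],
        widths_right=widths["right"],
        fps=params.fps,
        positions=p,
        fold_length=params.fold_length,
        units="%FL",
        involved_side=involved,
    )


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncNorm:
    """Truncated normal draw spec: mean, sd, and physical bounds."""

    mean: float
    sd: float
    low: float = -np.inf
    high: float = np.inf

    def draw(self, rng: np.random.Generator, size=None):
        if self.sd == 0:
            return np.full(size, self.mean) if size else self.mean
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return sps.truncnorm.rvs(
            a, b, loc=self.mean, scale=self.sd, size=size, random_state=rng
        )


@dataclass
class GroupSpec:
    """Per-subject parameter distributions for one diagnosis group."""

    f0: TruncNorm = field(default_factory=lambda: TruncNorm(160.0, 30.0, 90.0, 300.0))
    base_amplitude: TruncNorm = field(
        default_factory=lambda: TruncNorm(4.2, 0.7, 0.5, 12.0)
    )
    # relative L/R imbalance delta: a_L = A(1+d/2), a_R = A(1-d/2)
    amplitude_imbalance_sd: float = 0.25
    rest_halfwidth: TruncNorm = field(
        default_factory=lambda: TruncNorm(1.7, 0.4, 0.4, 4.0)
    )
    phase_lag_sd: float = 20.0  # half-normal sd of global right-fold lag (deg)
    noise_sd: float = 0.15
    lesion: bool = False
    lesion_gain: TruncNorm = field(default_factory=lambda: TruncNorm(0.55, 0.15, 0.0, 1.0))
    lesion_added_lag: TruncNorm = field(default_factory=lambda: TruncNorm(25.0, 12.0, 0.0, 180.0))
    lesion_closure: TruncNorm = field(default_factory=lambda: TruncNorm(-2.0, 1.5, -10.0, 0.0))
    lesion_center: TruncNorm = field(default_factory=lambda: TruncNorm(0.5, 0.1, 0.2, 0.8))
    lesion_extent: TruncNorm = field(default_factory=lambda: TruncNorm(0.25, 0.05, 0.08, 0.45))
    severity_label: str = "benign"


@dataclass
class CohortSpec:
    """Group sizes and per-group parameter distributions for a study cohort."""

    sizes: dict[str, int]
    groups: dict[str, GroupSpec]
    n_frames: int = 2000
    fps: float = 3200.0
    n_positions: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.sizes.values()):
            raise ValidationError("group sizes must be non-negative")
        missing = set(self.sizes) - set(self.groups)
        if missing:
            raise ValidationError(f"no GroupSpec for groups: {sorted(missing)}")


def default_cohort_spec(
    seed: int = 0, sizes: dict[str, int] | None = None
) -> CohortSpec:
    """Study-calibrated cohort: 50 normophonic, 85 benign, 40 malignant.

    Benign lesions are soft (moderate amplitude loss, small phase lag, mild
    gap narrowing); malignant infiltration stiffens the fold (strong
    amplitude loss, large phase lag, deeper occlusion).  Spreads are chosen
    so group medians of the vibratory parameters are reliably ordered while
    individual subjects overlap substantially, as in clinical data.
    """
    if sizes is None:
        sizes = {"norm": 50, "benign": 85, "malignant": 40}
    groups = {
        "norm": GroupSpec(),
        "benign": GroupSpec(
            base_amplitude=TruncNorm(4.0, 0.7, 0.5, 12.0),
            rest_halfwidth=TruncNorm(1.25, 0.35, 0.25, 3.0),
            phase_lag_sd=30.0,
            lesion=True,
            lesion_gain=TruncNorm(0.55, 0.15, 0.0, 1.0),
            lesion_added_lag=TruncNorm(35.0, 10.0, 0.0, 180.0),
            lesion_closure=TruncNorm(-4.0, 2.0, -12.0, 0.0),
            severity_label="benign",
        ),
        "malignant": GroupSpec(
            base_amplitude=TruncNorm(3.8, 0.7, 0.5, 12.0),
            rest_halfwidth=TruncNorm(0.5, 0.2, 0.1, 1.5),
            phase_lag_sd=45.0,
            lesion=True,
            lesion_gain=TruncNorm(0.22, 0.13, 0.0, 1.0),
            lesion_added_lag=TruncNorm(100.0, 20.0, 0.0, 180.0),
            lesion_closure=TruncNorm(-6.5, 2.5, -14.0, 0.0),
            lesion_extent=TruncNorm(0.30, 0.07, 0.08, 0.5),
            severity_label="malignant",
        ),
    }
    return CohortSpec(sizes=sizes, groups=groups, seed=seed)


def _draw_subject_params(
    spec: CohortSpec, gspec: GroupSpec, rng: np.random.Generator, seed: int
) -> VibrationParams:
    amp = float(gspec.base_amplitude.draw(rng))
    delta = rng.normal(0.0, gspec.amplitude_imbalance_sd)
    a_left = max(amp * (1.0 + delta / 2.0), 0.0)
    a_right = max(amp * (1.0 - delta / 2.0), 0.0)
    lag = float(abs(rng.normal(0.0, gspec.phase_lag_sd)) % 360.0)
    lesion = None
    if gspec.lesion:
        lesion = LesionModel(
            side=str(rng.choice(["left", "right"])),
            center=float(gspec.lesion_center.draw(rng)),
            extent=float(gspec.lesion_extent.draw(rng)),
            amplitude_gain=float(gspec.lesion_gain.draw(rng)),
            added_phase_lag=float(gspec.lesion_added_lag.draw(rng)),
            closure_offset=float(gspec.lesion_closure.draw(rng)),
            severity_label=gspec.severity_label,
        )
        # The whole involved fold carries the inertial lag, so the global
        # lag and the lesion's local lag act on the same fold: a left-sided
        # lesion makes the *left* fold lag, i.e. the right fold leads.
        if lesion.side == "left" and lag > 0:
            lag = 360.0 - lag
    return VibrationParams(
        f0=float(gspec.f0.draw(rng)),
        fps=spec.fps,
        n_frames=spec.n_frames,
        n_positions=spec.n_positions,
        base_amplitude_left=a_left,
        base_amplitude_right=a_right,
        rest_halfwidth=float(gspec.rest_halfwidth.draw(rng)),
        phase_lag_right=lag,
        noise_sd=gspec.noise_sd,
        lesion=lesion,
        seed=seed,
    )


def simulate_cohort(
    spec: CohortSpec, return_trajectories: bool = False
) -> tuple[pd.DataFrame, list[EdgeTrajectory]]:
    """Simulate a full cohort and compute its vibratory-parameter table.

    Returns a tuple ``(table, trajectories)``.  ``table`` has one row per
    subject with columns ``subject_id``, ``diagnosis``, the 14 vibratory
    parameters and ``F0`` (the parameter table consumed by the statistics
    stage).  ``trajectories`` is populated only when ``return_trajectories``
    is true (study-scale cohorts are large).  Fully reproducible from
    ``spec.seed``.
    """
    from .stv import compute_stv  # local import: stv depends on kymography only

    master = np.random.default_rng(spec.seed)
    rows = []
    trajs: list[EdgeTrajectory] = []
    sid = 0
    for group in spec.sizes:
        gspec = spec.groups[group]
        for _ in range(spec.sizes[group]):
            subject_seed = int(master.integers(0, 2**31 - 1))
            params = _draw_subject_params(
                spec, gspec, np.random.default_rng(subject_seed), subject_seed
            )
            traj = simulate_trajectory(params)
            if not gspec.lesion:
                traj = replace(traj, involved_side=None)
            summary = compute_stv(traj)
            row = {"subject_id": f"S{sid:04d}", "diagnosis": group}
            row.update(summary.to_dict())
            rows.append(row)
            if return_trajectories:
                trajs.append(traj)
            sid += 1
    return pd.DataFrame(rows), trajs
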