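"""The 14 short-term-variability (STV) vibratory parameters.

STV parameters summarize properties common to all vibratory cycles of one
recording, per axis position, then averaged over cycles and positions.
Four families are computed from an edge trajectory and its detected cycles:

* **Amplitude measures** — ``AmpAvg``, ``AmpAvg_2/3`` (resultant gap-width
  amplitude for the whole glottis / its middle third) and, for unilateral
  lesions, ``AmpInvolvedAvg`` / ``AmpHealthyAvg`` (per-fold amplitudes of
  the involved and contralateral fold).  Amplitude is half the peak-to-peak
  excursion of the relevant signal within a cycle, in %FL (percent of fold
  length).
* **Glottal dynamic characteristics** — ``OQAvg``, ``OQAvg_2/3`` (open
  quotient: fraction of the cycle the gap is open), ``RGGA`` (ratio of
  minimal to maximal glottal area within a cycle), ``NonOpening`` /
  ``NonClosing`` (percent of the glottal length that never opens / never
  closes).
* **Symmetry measures** — ``AmplAsymAvg``, ``AmplAsymAvg_2/3`` (relative
  left/right amplitude difference), ``PhaseAsymAvg``, ``PhaseAsymAvg_2/3``
  (deficit of the resultant amplitude relative to the sum of the individual
  fold amplitudes, which grows with interfold phase lag), and
  ``AbsPhaseDiffAvg`` (mean absolute interfold phase difference at F0, in
  degrees; 0 for perfectly mirror-symmetric motion).
* **F0** — fundamental frequency from cycle detection.

Openness is judged against a threshold ``eps`` equal to 5% of the
recording's maximum gap width, which makes the open/closed decision robust
to sub-pixel measurement noise.  The middle third is the closed interval
``p in [1/3, 2/3]``, the region where oscillation amplitude normally peaks.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SilentGlottisError
from .kymography import (
    CycleSet,
    GlottalWaveforms,
    detect_cycles,
    glottal_waveforms,
    require_cycles,
)
from .trajectory import EdgeTrajectory

__all__ = [
    "AmplitudeProfile",
    "STVSummary",
    "PARAMETER_NAMES",
    "cycle_profile",
    "amplitude_measures",
    "dynamic_measures",
    "symmetry_measures",
    "compute_stv",
]

#: Serialization order of the 14 parameters plus fundamental frequency.
PARAMETER_NAMES = (
    "AmpAvg",
    "AmpAvg_2/3",
    "AmpInvolvedAvg",
    "AmpHealthyAvg",
    "OQAvg",
    "OQAvg_2/3",
    "RGGA",
    "NonOpening",
    "NonClosing",
    "AmplAsymAvg",
    "AmplAsymAvg_2/3",
    "PhaseAsymAvg",
    "PhaseAsymAvg_2/3",
    "AbsPhaseDiffAvg",
    "F0",
)

_MIDDLE_LO, _MIDDLE_HI = 1.0 / 3.0, 2.0 / 3.0
_TINY = 1e-12


@dataclass
class AmplitudeProfile:
    """Per-cycle, per-position amplitudes and open fractions.

    All amplitude arrays have shape (n_cycles, n_positions) and are in the
    trajectory's width units (%FL after normalization).  ``opens``/
    ``closes`` flag positions that open (gap exceeds ``eps``) at least once
    / close at least once during the analyzed cycles.
    """

    amp_left: np.ndarray
    amp_right: np.ndarray
    amp_res: np.ndarray
    oq: np.ndarray
    opens: np.ndarray
    closes: np.ndarray
    positions: np.ndarray
    eps: float

    @property
    def middle_mask(self) -> np.ndarray:
        return (self.positions >= _MIDDLE_LO - 1e-9) & (
            self.positions <= _MIDDLE_HI + 1e-9
        )


def _segment_reduce(op, arr: np.ndarray, boundaries: np.ndarray) -> np.ndarray:
    """Apply a ufunc reduction over cycle segments along axis 0."""
    b0, b_last = boundaries[0], boundaries[-1]
    idx = boundaries[:-1] - b0
    return op.reduceat(arr[b0:b_last], idx, axis=0)


def cycle_profile(
    traj: EdgeTrajectory, cycles: CycleSet, eps_frac: float = 0.05
) -> AmplitudeProfile:
    """Per-cycle amplitude/open-quotient profile of a trajectory.

    Only complete cycles (between the first and last detected boundary) are
    analyzed; incomplete leading/trailing cycles are discarded.
    """
    traj = traj.to_percent_fold_length()
    require_cycles(cycles, minimum=1)
    b = cycles.boundaries
    wl, wr = traj.widths_left, traj.widths_right
    g = wl + wr

    amp = {}
    for key, sig in (("left", wl), ("right", wr), ("res", g)):
        hi = _segment_reduce(np.maximum, sig, b)
        lo = _segment_reduce(np.minimum, sig, b)
        amp[key] = 0.5 * (hi - lo)

    eps = eps_frac * float(g[b[0] : b[-1]].max(initial=0.0))
    open_counts = _segment_reduce(np.add, (g > eps).astype(float), b)
    seg_len = np.diff(b).astype(float)[:, None]
    oq = open_counts / seg_len

    window = g[b[0] : b[-1]]
    opens = window.max(axis=0) > eps
    closes = window.min(axis=0) <= eps

    return AmplitudeProfile(
        amp_left=amp["left"],
        amp_right=amp["right"],
        amp_res=amp["res"],
        oq=oq,
        opens=opens,
        closes=closes,
        positions=traj.positions,
        eps=eps,
    )


def _cycle_then_position_mean(values: np.ndarray, pos_mask: np.ndarray) -> float:
    """Average over cycles, then over the selected positions."""
    if not np.any(pos_mask):
        return float("nan")
    return float(values.mean(axis=0)[pos_mask].mean())


def amplitude_measures(
    profile: AmplitudeProfile, involved_side: str | None = None
) -> dict[str, float]:
    """Average resultant and per-fold amplitudes (whole glottis and middle
    third), in %FL.

    Per-fold measures (involved/healthy) are produced only when
    ``involved_side`` is given — they are meaningful only for unilateral
    lesions.
    """
    all_pos = np.ones_like(profile.opens, dtype=bool)
    out = {
        "AmpAvg": _cycle_then_position_mean(profile.amp_res, all_pos),
        "AmpAvg_2/3": _cycle_then_position_mean(profile.amp_res, profile.middle_mask),
    }
    if involved_side is not None:
        per_fold = {"left": profile.amp_left, "right": profile.amp_right}
        healthy_side = "right" if involved_side == "left" else "left"
        out["AmpInvolvedAvg"] = _cycle_then_position_mean(
            per_fold[involved_side], all_pos
        )
        out["AmpHealthyAvg"] = _cycle_then_position_mean(
            per_fold[healthy_side], all_pos
        )
    return out


def dynamic_measures(
    profile: AmplitudeProfile, wave: GlottalWaveforms, cycles: CycleSet
) -> dict[str, float]:
    """Open quotient, relative glottal gap area, and non-opening/-closing
    percentages.

    ``OQAvg`` averages only positions that open at least once; positions
    that never open are captured by ``NonOpening`` instead.  ``RGGA`` is
    undefined (NaN) for a silent glottis (maximal area 0 in some cycle).
    """
    b = cycles.boundaries
    out: dict[str, float] = {}

    out["OQAvg"] = 100.0 * _cycle_then_position_mean(profile.oq, profile.opens)
    out["OQAvg_2/3"] = 100.0 * _cycle_then_position_mean(
        profile.oq, profile.opens & profile.middle_mask
    )

    area_hi = _segment_reduce(np.maximum, wave.area[:, None], b)[:, 0]
    area_lo = _segment_reduce(np.minimum, wave.area[:, None], b)[:, 0]
    if np.any(area_hi <= 0):
        out["RGGA"] = float("nan")
    else:
        out["RGGA"] = 100.0 * float(np.mean(area_lo / area_hi))

    out["NonOpening"] = 100.0 * float(np.mean(~profile.opens))
    out["NonClosing"] = 100.0 * float(np.mean(~profile.closes))
    return out


def _phase_difference_deg(
    traj: EdgeTrajectory, cycles: CycleSet, profile: AmplitudeProfile
) -> np.ndarray:
    """Per-position interfold phase difference at F0, degrees in (-180, 180].

    Each fold's width signal is demodulated at the detected fundamental
    frequency over the complete-cycle window (a single-bin discrete Fourier
    transform, i.e. band-limiting to F0); the phase difference is the
    circular angle between the two complex amplitudes.  Positions where
    either fold barely oscillates (demodulated amplitude below 1% of the
    recording maximum) are returned as NaN — their phase is noise.
    """
    b0, b_last = cycles.boundaries[0], cycles.boundaries[-1]
    t = np.arange(b0, b_last)
    carrier = np.exp(-2j * np.pi * t / cycles.period)[:, None]
    z_left = (traj.widths_left[b0:b_last] * carrier).sum(axis=0)
    z_right = (traj.widths_right[b0:b_last] * carrier).sum(axis=0)

    n = len(t)
    amp_left = 2.0 * np.abs(z_left) / n
    amp_right = 2.0 * np.abs(z_right) / n
    floor = max(0.01 * max(amp_left.max(initial=0.0), amp_right.max(initial=0.0)), _TINY)

    diff = np.degrees(np.angle(z_left * np.conj(z_right)))
    diff[(amp_left < floor) | (amp_right < floor)] = np.nan
    return diff


def symmetry_measures(
    profile: AmplitudeProfile, traj: EdgeTrajectory, cycles: CycleSet
) -> dict[str, float]:
    """Amplitude asymmetry, phase asymmetry, and absolute phase difference.

    * ``AmplAsym(p,k) = 100 |a_L - a_R| / (a_L + a_R)``
    * ``PhaseAsym(p,k) = 100 max(0, 1 - a_res / (a_L + a_R))`` — zero for
      in-phase mirror motion, growing as interfold lag reduces the
      resultant amplitude below the sum of the individual ones.
    * ``AbsPhaseDiffAvg`` — mean absolute interfold phase lag at F0.

    Cells with ``a_L + a_R = 0`` are excluded.  A completely silent glottis
    raises :class:`SilentGlottisError`.
    """
    a_l, a_r, a_res = profile.amp_left, profile.amp_right, profile.amp_res
    total = a_l + a_r
    valid = total > _TINY
    if not np.any(valid):
        raise SilentGlottisError("no oscillation: symmetry measures undefined")

    with np.errstate(invalid="ignore", divide="ignore"):
        ampl_asym = np.where(valid, 100.0 * np.abs(a_l - a_r) / total, np.nan)
        phase_asym = np.where(
            valid, 100.0 * np.clip(1.0 - a_res / total, 0.0, None), np.nan
        )

    middle = profile.middle_mask

    def _masked_mean(cells: np.ndarray, pos_mask: np.ndarray) -> float:
        sub = cells[:, pos_mask]
        counts = np.isfinite(sub).sum(axis=0)
        with np.errstate(invalid="ignore"):
            per_pos = np.nansum(sub, axis=0) / counts
        per_pos = per_pos[counts > 0]
        return float(per_pos.mean()) if per_pos.size else float("nan")

    all_pos = np.ones(profile.positions.shape, dtype=bool)
    out = {
        "AmplAsymAvg": _masked_mean(ampl_asym, all_pos),
        "AmplAsymAvg_2/3": _masked_mean(ampl_asym, middle),
        "PhaseAsymAvg": _masked_mean(phase_asym, all_pos),
        "PhaseAsymAvg_2/3": _masked_mean(phase_asym, middle),
    }

    diff = _phase_difference_deg(traj.to_percent_fold_length(), cycles, profile)
    finite = np.abs(diff[np.isfinite(diff)])
    out["AbsPhaseDiffAvg"] = float(finite.mean()) if finite.size else float("nan")
    return out


@dataclass
class STVSummary:
    """The 14 scalar vibratory parameters plus F0 for one recording."""

    values: dict[str, float]
    involved_side: str | None = None
    flags: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_dict(self) -> dict[str, float]:
        """Parameter dict in canonical order; absent per-fold measures NaN."""
        return {name: self.values.get(name, float("nan")) for name in PARAMETER_NAMES}


def compute_stv(
    traj: EdgeTrajectory,
    cycles: CycleSet | None = None,
    eps_frac: float = 0.05,
    min_cycles: int = 3,
) -> STVSummary:
    """Full STV analysis of one edge trajectory.

    Detects cycles when ``cycles`` is not supplied, then aggregates
    amplitude, dynamic, and symmetry measures plus F0.  Per-fold amplitude
    measures are present only when the trajectory carries an
    ``involved_side`` (unilateral lesion); they are NaN otherwise.
    """
    traj = traj.to_percent_fold_length()
    wave = glottal_waveforms(traj)
    if cycles is None:
        cycles = detect_cycles(wave)
    require_cycles(cycles, minimum=min_cycles)

    profile = cycle_profile(traj, cycles, eps_frac=eps_frac)
    values: dict[str, float] = {}
    flags: list[str] = []
    values.update(amplitude_measures(profile, traj.involved_side))
    values.update(dynamic_measures(profile, wave, cycles))
    if not np.isfinite(values["RGGA"]):
        flags.append("RGGA undefined: glottis silent in some cycle")
    try:
        values.update(symmetry_measures(profile, traj, cycles))
    except SilentGlottisError:
        flags.append("symmetry measures undefined: silent glottis")
        for name in (
            "AmplAsymAvg",
            "AmplAsymAvg_2/3",
            "PhaseAsymAvg",
            "PhaseAsymAvg_2/3",
            "AbsPhaseDiffAvg",
        ):
            values[name] = float("nan")
    values["F0"] = cycles.f0
    return STVSummary(
        values=values, involved_side=traj.involved_side, flags=tuple(flags)
    )
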