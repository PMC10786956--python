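"""Glottal waveforms, cycle detection, and kymogram extraction.

The temporal unit of all vibratory-parameter analysis is the glottal cycle.
Cycles are detected on the glottal area waveform ``A(t)``: the period comes
from the first peak of the autocorrelation of the mean-removed signal
(with parabolic sub-sample interpolation), and cycle boundaries are placed
at local minima of ``A(t)`` nearest each period multiple.  The height of the
autocorrelation peak acts as a periodicity confidence; signals below the
confidence threshold raise :class:`~glottovib.errors.AperiodicityError`
rather than yielding meaningless cycles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AperiodicityError, InsufficientCyclesError, ValidationError
from .trajectory import EdgeTrajectory

__all__ = [
    "GlottalWaveforms",
    "CycleSet",
    "Kymogram",
    "glottal_waveforms",
    "detect_cycles",
    "extract_kymogram",
]

#: Default minimum autocorrelation peak height accepted as periodic.
CONFIDENCE_THRESHOLD = 0.3


@dataclass
class GlottalWaveforms:
    """Resultant gap width ``g(p, t)`` and glottal area proxy ``A(t)``.

    ``width`` has shape (n_frames, n_positions); ``area`` is the mean gap
    width over positions scaled by the fold length (an area up to the
    constant position spacing).
    """

    width: np.ndarray
    area: np.ndarray
    fps: float


@dataclass
class CycleSet:
    """Detected vibratory cycles of one recording.

    ``boundaries`` are frame indices of consecutive cycle starts (area
    minima); cycle ``k`` spans frames ``boundaries[k] .. boundaries[k+1]``.
    """

    boundaries: np.ndarray
    period: float
    f0: float
    confidence: float

    @property
    def n_cycles(self) -> int:
        return max(len(self.boundaries) - 1, 0)


@dataclass
class Kymogram:
    """Left/right edge width series at a single axis position."""

    left: np.ndarray
    right: np.ndarray
    position: float
    position_index: int
    label: str
    fps: float


def glottal_waveforms(traj: EdgeTrajectory) -> GlottalWaveforms:
    """Resultant width and area waveforms of a trajectory."""
    g = traj.widths_left + traj.widths_right
    area = g.mean(axis=1) * traj.fold_length
    return GlottalWaveforms(width=g, area=area, fps=traj.fps)


def _autocorr_period(x: np.ndarray) -> tuple[float, float]:
    """Period (samples) and confidence from the first autocorrelation peak.

    The first peak after the autocorrelation's first negative excursion is
    located as the global maximum of the remaining lags up to half the
    signal length; its position is refined by parabolic interpolation and
    its (normalized) height is returned as the confidence.
    """
    x = np.asarray(x, float)
    x = x - x.mean()
    n = len(x)
    if n < 4 or not np.any(x):
        return np.nan, 0.0
    acf = np.correlate(x, x, mode="full")[n - 1 :]
    if acf[0] <= 0:
        return np.nan, 0.0
    acf = acf / acf[0]
    limit = n // 2
    negative = np.nonzero(acf[:limit] < 0)[0]
    if len(negative) == 0:
        return np.nan, float(np.max(acf[1:limit], initial=0.0))
    k0 = negative[0]
    k = int(k0 + np.argmax(acf[k0:limit]))
    if 0 < k < len(acf) - 1:
        y0, y1, y2 = acf[k - 1], acf[k], acf[k + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    return k + shift, float(acf[k])


def detect_cycles(
    wave: GlottalWaveforms, confidence_threshold: float = CONFIDENCE_THRESHOLD
) -> CycleSet:
    """Detect cycle boundaries and fundamental frequency from ``A(t)``.

    Raises
    ------
    AperiodicityError
        If the autocorrelation confidence falls below
        ``confidence_threshold`` (e.g. white-noise or silent input).
    """
    area = np.asarray(wave.area, float)
    period, confidence = _autocorr_period(area)
    if not np.isfinite(period) or confidence < confidence_threshold:
        raise AperiodicityError(confidence, confidence_threshold)

    n = len(area)
    half = max(int(round(period / 4.0)), 1)
    start = int(np.argmin(area[: int(np.ceil(period))]))
    boundaries = []
    k = 0
    while True:
        center = start + k * period
        if round(center) > n - 1:
            break
        lo = max(int(round(center - half)), 0)
        hi = min(int(round(center + half)) + 1, n)
        b = lo + int(np.argmin(area[lo:hi]))
        if not boundaries or b > boundaries[-1]:
            boundaries.append(b)
        k += 1
    boundaries = np.asarray(boundaries, dtype=int)
    return CycleSet(
        boundaries=boundaries,
        period=float(period),
        f0=float(wave.fps / period),
        confidence=confidence,
    )


def require_cycles(cycles: CycleSet, minimum: int = 3) -> None:
    """Raise unless at least ``minimum`` complete cycles were detected."""
    if cycles.n_cycles < minimum:
        raise InsufficientCyclesError(
            f"only {cycles.n_cycles} complete cycles detected; need {minimum}"
        )


_PART_LABELS = (("posterior", 0.17), ("middle", 0.5), ("anterior", 0.83))


def extract_kymogram(traj: EdgeTrajectory, p: float) -> Kymogram:
    """Kymogram (edge-width time series) at the scanline nearest ``p``.

    Nearest-index selection, no interpolation: the kymogram shows raw
    measurements.  The label names the functional part of the glottis
    (posterior / middle / anterior) whose representative position is
    closest to ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"kymogram position {p} outside [0, 1]")
    idx = int(np.argmin(np.abs(traj.positions - p)))
    label = min(_PART_LABELS, key=lambda lp: abs(lp[1] - p))[0]
    return Kymogram(
        left=traj.widths_left[:, idx].copy(),
        right=traj.widths_right[:, idx].copy(),
        position=float(traj.positions[idx]),
        position_index=idx,
        label=label,
        fps=traj.fps,
    )
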