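"""STV parameter formulas against closed-form and hand-computed oracles."""
from dataclasses import replace

import numpy as np
import pytest

from glottovib import (
    EdgeTrajectory,
    LesionModel,
    VibrationParams,
    compute_stv,
    cycle_profile,
    detect_cycles,
    glottal_waveforms,
    simulate_trajectory,
)
from glottovib.errors import InsufficientCyclesError
from glottovib.kymography import CycleSet
from glottovib.stv import PARAMETER_NAMES, amplitude_measures
from tests.conftest import make_trajectory


def stv(traj, **kw):
    return compute_stv(traj, **kw)


class TestAmplitudeMeasures:
    def test_hand_computed_resultant_and_per_fold(self, constant_symmetric_traj):
        # a_L = a_R = 4 %FL in mirror phase, rest 5: no clamping, so the
        # resultant gap amplitude is a_L + a_R = 8 and each fold's is 4.
        traj = replace(constant_symmetric_traj, involved_side="right")
        s = stv(traj)
        assert s["AmpAvg"] == pytest.approx(8.0, abs=0.1)
        assert s["AmpInvolvedAvg"] == pytest.approx(4.0, abs=0.05)
        assert s["AmpHealthyAvg"] == pytest.approx(4.0, abs=0.05)

    def test_zero_oscillation_gives_zero_amplitudes(self):
        traj = make_trajectory(np.full((64, 16), 3.0))
        cycles = CycleSet(np.arange(0, 64, 16), 16.0, 200.0, 1.0)
        profile = cycle_profile(traj, cycles)
        out = amplitude_measures(profile, involved_side="left")
        assert all(v == 0.0 for v in out.values())

    def test_middle_third_exceeds_whole_for_halfsine_profile(self):
        s = stv(simulate_trajectory(VibrationParams(noise_sd=0.0, rest_halfwidth=6.0)))
        assert s["AmpAvg_2/3"] > s["AmpAvg"]

    def test_per_fold_measures_absent_without_involved_side(self):
        s = stv(simulate_trajectory(VibrationParams(noise_sd=0.0)))
        assert "AmpInvolvedAvg" not in s.values
        assert np.isnan(s.to_dict()["AmpInvolvedAvg"])


class TestDynamicMeasures:
    def test_open_quotient_closed_form(self):
        # g = max(0, sin(2 pi t/T) - 0.5)*c opens for 120/360 of each cycle
        n, period = 2000, 200
        t = np.arange(n)
        g = np.maximum(0.0, np.sin(2 * np.pi * t / period) - 0.5)[:, None]
        g = g * np.ones((1, 16)) * 3.0
        s = stv(make_trajectory(g))
        assert s["OQAvg"] == pytest.approx(100.0 / 3.0, abs=1.0)

    def test_always_open_glottis(self):
        traj = simulate_trajectory(
            VibrationParams(amplitude_profile="constant", rest_halfwidth=6.0,
                            base_amplitude_left=4.0, base_amplitude_right=4.0,
                            noise_sd=0.0)
        )
        s = stv(traj)
        assert s["NonClosing"] == 100.0
        assert s["OQAvg"] == 100.0
        assert s["NonOpening"] == 0.0

    def test_nonopening_extent_matches_analytic_prediction(self):
        # occlusion bump forces closure where bump >= 0.25, i.e. within
        # 2/3 of the closure core around the centre
        core_extent = 0.6 * 0.15
        les = LesionModel(side="left", center=0.5, extent=0.15,
                          amplitude_gain=1.0, closure_offset=-20.0)
        p = VibrationParams(f0=200.0, base_amplitude_left=4.0,
                            base_amplitude_right=4.0,
                            amplitude_profile="constant", rest_halfwidth=1.0,
                            noise_sd=0.0, lesion=les)
        s = stv(simulate_trajectory(p))
        predicted = 100.0 * 2.0 * (2.0 / 3.0) * core_extent
        spacing = 100.0 / p.n_positions
        assert s["NonOpening"] == pytest.approx(predicted, abs=1.5 * spacing)


class TestSymmetryMeasures:
    def test_mirror_symmetry_zeroes_all_asymmetries(self, constant_symmetric_traj):
        s = stv(constant_symmetric_traj)
        for name in ("AmplAsymAvg", "AmplAsymAvg_2/3", "PhaseAsymAvg",
                     "PhaseAsymAvg_2/3", "AbsPhaseDiffAvg"):
            assert abs(s[name]) < 1e-6, name

    def test_forced_amplitude_asymmetry_value(self):
        # a_L = 3, a_R = 1 everywhere: AmplAsym = 100*|3-1|/4 = 50
        p = VibrationParams(base_amplitude_left=3.0, base_amplitude_right=1.0,
                            amplitude_profile="constant", rest_halfwidth=5.0,
                            noise_sd=0.0)
        s = stv(simulate_trajectory(p))
        assert s["AmplAsymAvg"] == pytest.approx(50.0, abs=0.5)

    def test_sixty_degree_lag_phase_measures(self):
        # equal sinusoids, one fold lagging 60 deg: resultant amplitude
        # 2 a cos(30 deg) -> PhaseAsym = 100(1-cos 30) ~ 13.4; lag = 60
        p = VibrationParams(f0=200.0, base_amplitude_left=4.0,
                            base_amplitude_right=4.0,
                            amplitude_profile="constant", rest_halfwidth=6.0,
                            phase_lag_right=60.0, noise_sd=0.0)
        s = stv(simulate_trajectory(p))
        assert s["PhaseAsymAvg"] == pytest.approx(100 * (1 - np.cos(np.pi / 6)), abs=0.6)
        assert s["AbsPhaseDiffAvg"] == pytest.approx(60.0, abs=2.0)

    def test_left_right_swap_invariance(self):
        p = VibrationParams(base_amplitude_left=3.0, base_amplitude_right=5.0,
                            phase_lag_right=40.0, noise_sd=0.0, rest_halfwidth=6.0)
        traj = simulate_trajectory(p)
        swapped = EdgeTrajectory(
            widths_left=traj.widths_right, widths_right=traj.widths_left,
            fps=traj.fps, positions=traj.positions,
        )
        a, b = stv(traj), stv(swapped)
        for name in ("AmplAsymAvg", "PhaseAsymAvg", "AbsPhaseDiffAvg"):
            assert a[name] == pytest.approx(b[name], rel=1e-9), name

    def test_phase_difference_invariant_to_lag_sign(self):
        base = dict(base_amplitude_left=4.0, base_amplitude_right=4.0,
                    amplitude_profile="constant", rest_halfwidth=6.0,
                    noise_sd=0.0)
        lead = stv(simulate_trajectory(VibrationParams(phase_lag_right=30.0, **base)))
        lag = stv(simulate_trajectory(VibrationParams(phase_lag_right=330.0, **base)))
        assert lead["AbsPhaseDiffAvg"] == pytest.approx(lag["AbsPhaseDiffAvg"], abs=0.1)


class TestComputeStv:
    def test_middle_third_equals_whole_for_position_independent_motion(
        self, constant_symmetric_traj
    ):
        s = stv(constant_symmetric_traj)
        assert s["AmpAvg_2/3"] == pytest.approx(s["AmpAvg"], rel=1e-9)
        assert s["OQAvg_2/3"] == pytest.approx(s["OQAvg"], rel=1e-9)

    def test_parameter_recovery_noise_free(self):
        """Injected per-fold amplitudes within 2% and lag within 2 deg."""
        p = VibrationParams(f0=212.0, base_amplitude_left=3.5,
                            base_amplitude_right=4.5,
                            amplitude_profile="constant", rest_halfwidth=10.0,
                            phase_lag_right=25.0, noise_sd=0.0,
                            lesion=LesionModel(side="right", amplitude_gain=1.0))
        s = stv(simulate_trajectory(p))
        assert s["AmpInvolvedAvg"] == pytest.approx(4.5, rel=0.02)
        assert s["AmpHealthyAvg"] == pytest.approx(3.5, rel=0.02)
        assert s["AbsPhaseDiffAvg"] == pytest.approx(25.0, abs=2.0)

    def test_aggregation_exposes_all_parameters(self, constant_symmetric_traj):
        d = stv(replace(constant_symmetric_traj, involved_side="left")).to_dict()
        assert tuple(d) == PARAMETER_NAMES
        assert all(np.isfinite(v) for v in d.values())

    def test_too_few_cycles_raises(self):
        traj = simulate_trajectory(VibrationParams(f0=100.0, n_frames=80))
        with pytest.raises(InsufficientCyclesError):
            compute_stv(traj)

    def test_golden_benign_fixture_regression(self):
        """Frozen output of this implementation on a seeded lesioned case."""
        les = LesionModel(side="right", center=0.5, extent=0.25,
                          amplitude_gain=0.55, added_phase_lag=30.0,
                          closure_offset=-3.0, severity_label="benign")
        p = VibrationParams(f0=180.0, noise_sd=0.15, phase_lag_right=20.0,
                            lesion=les, seed=42)
        got = stv(simulate_trajectory(p)).to_dict()
        golden = {
            "AmpAvg": 3.230055268261647,
            "AmpAvg_2/3": 3.389247378013374,
            "AmpInvolvedAvg": 1.5725822282292732,
            "AmpHealthyAvg": 1.7924911096833196,
            "OQAvg": 72.15312103657449,
            "OQAvg_2/3": 57.05769183903857,
            "RGGA": 5.886751232745582,
            "NonOpening": 0.0,
            "NonClosing": 15.625,
            "AmplAsymAvg": 9.876010006031985,
            "AmplAsymAvg_2/3": 22.170204887446445,
            "PhaseAsymAvg": 5.9043647135969435,
            "PhaseAsymAvg_2/3": 7.6057812285668085,
            "AbsPhaseDiffAvg": 27.6213891480879,
            "F0": 179.98452290342786,
        }
        for name, expected in golden.items():
            assert got[name] == pytest.approx(expected, rel=1e-9), name
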