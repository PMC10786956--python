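# glottovib

Kymographic analysis of vocal-fold vibration from laryngeal high-speed
videoendoscopy (HSV), for voice scientists and laryngology researchers
studying how organic glottal lesions — benign masses and early glottic
cancer — alter phonatory oscillation.

HSV records the glottis at thousands of frames per second, resolving
individual vibratory cycles.  From the tracked fold-edge trajectories,
`glottovib` computes the **short-term-variability (STV) parameters**:
amplitude measures (AmpAvg, AmpAvg_2/3, AmpInvolvedAvg, AmpHealthyAvg, in
%FL — percent of fold length), glottal dynamic characteristics (OQAvg,
OQAvg_2/3, RGGA, NonOpening, NonClosing), symmetry measures (AmplAsymAvg,
AmplAsymAvg_2/3, PhaseAsymAvg, PhaseAsymAvg_2/3, AbsPhaseDiffAvg), and
fundamental frequency F0.  For one axis position `p` and cycle `k`,

    amplitude  a(p,k)       = ½ · peak-to-peak excursion within the cycle
    open quotient OQ(p,k)   = #frames with g(p,t) > ε  /  cycle length
    AmplAsym(p,k)           = 100 · |a_L − a_R| / (a_L + a_R)
    PhaseAsym(p,k)          = 100 · max(0, 1 − a_res / (a_L + a_R))
    AbsPhaseDiff(p)         = |circular lag between w_L and w_R at F0|

where `g = w_L + w_R` is the gap width and ε an openness threshold (5% of
the recording maximum).  The phonovibrogram (PVG) visualizes both folds'
edge displacement as a position × time intensity map.  At cohort level
the package runs the clinical statistical workflow: Shapiro–Wilk-routed
two-/three-group comparisons with post hoc tests (Fisher LSD / Dunn–
Bonferroni), and two-variant ROC analysis (norm vs lesion; benign vs
malignant) with booster/inhibitor orientation, DeLong confidence
intervals, and Youden-index cut-points.

Because raw clinical HSV recordings are not publicly available, the
package includes a ground-truthed synthetic generator: two fold edges in
near-mirror oscillation (3200 fps, 2000 frames = 625 ms by default), a
raised-cosine unilateral lesion model (local stiffening, phase lag, and
gap occlusion), a frame-stack renderer with exact-coverage anti-aliasing,
and a 175-subject cohort generator (50 normophonic / 85 benign / 40
malignant) calibrated to reproduce the clinically observed group-median
orderings.

## Worked example

Simulate a malignant-type lesion recording, analyze it, and inspect the
parameters:

```python
from glottovib import (LesionModel, VibrationParams, simulate_trajectory,
                       compute_stv)

lesion = LesionModel(side="right", center=0.5, extent=0.3,
                     amplitude_gain=0.2, added_phase_lag=60.0,
                     closure_offset=-4.0, severity_label="malignant")
params = VibrationParams(f0=180.0, noise_sd=0.15, lesion=lesion, seed=1)
summary = compute_stv(simulate_trajectory(params))
for name in ("F0", "AmpAvg", "AmpInvolvedAvg", "AmpHealthyAvg",
             "AmplAsymAvg", "AbsPhaseDiffAvg", "OQAvg", "NonOpening"):
    print(f"{name:16s} {summary[name]:8.2f}")
```

prints

```
F0                 179.98
AmpAvg               2.86
AmpInvolvedAvg       1.27
AmpHealthyAvg        1.66
AmplAsymAvg         23.74
AbsPhaseDiffAvg     12.54
OQAvg               68.06
NonOpening           0.00
```

— the involved (right) fold vibrates at roughly three quarters of the
healthy fold's amplitude (1.27 vs 1.66 %FL) and amplitude asymmetry is
elevated to ~24%: the vibratory signature of a stiff infiltrating lesion.
(A deeper `closure_offset` produces non-opening regions as well.)

The same pipeline is scriptable from the shell:

```bash
glottovib simulate --preset malignant --seed 1 --out traj.csv
glottovib render   --traj traj.csv --out frames/
glottovib segment  --frames frames/ --seeds seeds.json --out traj_seg.csv
glottovib analyze  --traj traj_seg.csv --out results/
glottovib cohort   --seed 1 --out cohort.csv
glottovib report   --cohort cohort.csv --out report/
```

`report/` then contains the omnibus table and one ROC table per variant
(Parameter, Booster/Inhibitor, AUC, CI bounds, p, Youden index, Cutting
point, Sensitivity, Specificity), sorted by AUC.

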