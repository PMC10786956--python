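# Methods

## Problem and scope

`glottovib` analyzes vocal-fold vibration as captured by laryngeal
high-speed videoendoscopy (HSV).  The analysis unit is the *edge
trajectory*: for each frame and each of `P` positions along the glottal
axis, the lateral half-width of the left and right fold edge from the
glottal midline.  From a trajectory the pipeline derives glottal
waveforms, vibratory cycles, the 14 short-term-variability (STV)
parameters plus fundamental frequency, and the phonovibrogram; at cohort
level it runs normality-routed group comparisons, post hoc tests, and a
two-variant ROC/Youden classification workflow (normophonic vs any
organic lesion; benign vs malignant lesion).

Real HSV recordings of this kind are not publicly deposited, so the
package ships a first-class synthetic generator that produces
ground-truthed trajectories, rendered frame stacks, and study-sized
cohorts.  All quantitative validation rests on that ground truth.

## Vibration model

Each fold's half-width is a half-wave-rectified sinusoid

    w_F(p, t) = max(0, rest_F(p) + a_F(p) sin(2π f0 t / fps − lag_F(p)) + ε)

with `ε ~ N(0, noise_sd²)` i.i.d. measurement noise.  Conventions:

* **Mirror symmetry = in-phase half-widths.**  When both folds abduct and
  adduct together (perfect mirror motion), `w_L` and `w_R` rise and fall
  together, and the gap width `g = w_L + w_R` oscillates with amplitude
  `a_L + a_R`.  All phase lags are deviations from this reference; in
  fold-displacement coordinates this is the usual 180° anti-phase motion.
* **Rectification** at zero width is the simplest mechanism producing an
  open quotient below 100% and non-opening regions.
* **Amplitude profile** along the axis is a half-sine `sin(πp)` by default
  (oscillation peaks mid-glottis, vanishes at the commissures); a constant
  profile is available for closed-form fixtures.
* **Units**: widths are generated directly in %FL (percent of fold
  length), so injected amplitudes are exact ground truth for recovery
  tests.  Pixel-unit trajectories (from segmentation) are normalized by
  the commissure distance measured on the reference frame.

### Lesion model

A unilateral lesion is a raised-cosine bump
`b(p) = ½(1 + cos(π(p − c)/e))` on `[c − e, c + e]`:

* `amplitude_gain ∈ [0, 1]` scales the involved fold's amplitude inside
  the bump (tissue stiffening; 0 = phonatory silence);
* `added_phase_lag` (degrees) delays the involved fold inside the bump
  (added inertia); in cohorts the subject's whole-fold lag is assigned to
  the involved fold too, so local and global lags add constructively;
* `closure_offset` (%FL, typically negative) shifts the *local rest width
  of both folds* over a core 0.6× as wide as the stiffened region.  The
  occluding mass sits between the free edges, so it narrows the gap from
  both sides; a one-sided offset could never close the glottis (the
  healthy fold would keep opening) and could not produce the non-opening
  regions characteristic of entrapped masses.

## Cycle detection

Cycles are detected on the glottal area waveform `A(t)` (mean gap width ×
fold length).  The period is the first peak of the autocorrelation of the
mean-removed signal — located as the global maximum beyond the first
negative excursion, refined by parabolic interpolation — and the
normalized peak height is a periodicity confidence.  Signals with
confidence below 0.3 (default) raise an aperiodicity error naming the
confidence rather than returning meaningless cycles.  Cycle boundaries
are the local minima of `A(t)` nearest each period multiple; incomplete
leading/trailing cycles are discarded, and at least 3 complete cycles are
required for STV analysis.  A 2000-frame sequence at 3200 fps holds
~60–160 cycles at speaking fundamental frequencies, all of which are
analyzed.

## STV parameters

Per cycle `k` and position `p`, amplitude is **half the peak-to-peak
excursion** within the cycle — of `g` for the resultant amplitude, of
`w_F` for per-fold amplitudes (standard kymographic convention).
Averaging is over cycles first, then positions.  The middle third is the
closed interval `p ∈ [1/3, 2/3]` (the region of maximal amplitude).
Openness uses a threshold `ε = 5%` of the recording's maximum gap width,
robust to sub-pixel noise and configurable.

* `AmpAvg`, `AmpAvg_2/3`: mean resultant amplitude (whole glottis /
  middle third), %FL.
* `AmpInvolvedAvg`, `AmpHealthyAvg`: mean per-fold amplitudes, reported
  only when an involved side is recorded (unilateral lesions).
* `OQAvg`, `OQAvg_2/3`: open quotient = fraction of cycle frames with
  `g > ε`, averaged over positions that open at least once (never-opening
  positions are counted by `NonOpening` instead, not mixed into OQ).
* `RGGA`: mean over cycles of min area / max area, ×100; undefined
  (NaN, flagged) if the glottis is silent in some cycle.
* `NonOpening` / `NonClosing`: percent of positions whose gap never
  exceeds / never falls to `ε` during the analyzed cycles.
* `AmplAsym(p,k) = 100·|a_L − a_R| / (a_L + a_R)`; cells with zero total
  amplitude excluded.
* `PhaseAsym(p,k) = 100·max(0, 1 − a_res/(a_L + a_R))`: for equal-amplitude
  sinusoids with interfold lag Δ the resultant amplitude is
  `2a·cos(Δ/2)`, so this measure is `100(1 − cos(Δ/2))` — zero for mirror
  motion, growing with lag.
* `AbsPhaseDiffAvg` (degrees): each fold's width signal is demodulated at
  the detected F0 over the complete-cycle window (single-bin DFT =
  band-limiting at F0); the per-position phase difference is the circular
  angle between the two complex amplitudes, wrapped to (−180°, 180°],
  averaged in absolute value over positions.  Positions where either
  fold's demodulated amplitude is below 1% of the recording maximum are
  excluded — their phase is noise (this matters for silenced lesion
  cores).  Reported in degrees; whether such measures are degrees or
  percent-of-period varies in the literature, so the unit is a documented
  choice here.

## Phonovibrogram

The PVG is a `(2P × T)` matrix: rows 0..P−1 show the left fold posterior→
anterior (top to middle), rows P..2P−1 the right fold anterior→posterior
(middle to bottom), so the diagram centre is the anterior glottis.
Intensity is the instantaneous edge displacement normalized to [0, 1] by
the recording's maximum width; brightness therefore grows with
oscillation amplitude and a silenced lesion region appears as a dark
horizontal band.  Phase-coded colouring schemes are deliberately not
used — only brightness-amplitude monotonicity is asserted.  Rendering
defaults to a perceptually uniform sequential colormap (`magma`), with a
red-tinted option (`Reds_r`) for a clinical look.

## Rendering and segmentation

The renderer rasterizes a trajectory as a dark gap polygon on bright
mucosa using exact area coverage in both the lateral and longitudinal
pixel direction (linear anti-aliasing), which makes the stack an oracle:
the column-wise darkness integral equals the ground-truth gap width to
well under a pixel.  Mucosa texture, colour, glare, and camera motion are
out of scope.

Segmentation mirrors the clinical semi-automatic procedure: five
examiner-marked points on one representative frame (two commissures, one
point per fold edge, one in the gap).  The glottal axis runs through the
commissures; the left side is whichever side of the directed axis the
left-edge seed lies on.  An Otsu threshold computed in a region of
interest around the axis on the representative frame is reused for every
frame (endoscope motion over a 625 ms sequence is negligible, so there is
no per-frame re-centering).  Along each of `P` perpendicular scanlines the
left/right half-width is the distance from the axis to the linearly
interpolated threshold crossing (sub-pixel); scanlines whose on-axis
sample is not dark get zero widths, and frames with no gap are recorded
as all-zero, not missing.  A 3×3 morphological opening suppresses salt
noise before the seed-component check.  The published edge-tracking
software's algorithm is proprietary; this module is a functional stand-in
validated only against the synthetic renderer (width RMSE ≤ 1 px and
end-to-end amplitude error well under 5% at zero pixel noise).

## Cohort generator

Per-subject parameters are drawn from truncated normal distributions
(truncated at physical bounds), one spec per diagnosis group, with group
sizes 50 (norm), 85 (benign), 40 (malignant) by default.  Key defaults:

| quantity | norm | benign | malignant |
|---|---|---|---|
| per-fold base amplitude (%FL) | 4.2 ± 0.7 | 4.0 ± 0.7 | 3.8 ± 0.7 |
| rest half-width (%FL) | 1.7 ± 0.4 | 1.25 ± 0.35 | 0.5 ± 0.2 |
| whole-fold lag scale (half-normal σ, deg) | 20 | 30 | 45 |
| lesion amplitude gain | — | 0.55 ± 0.15 | 0.22 ± 0.13 |
| lesion added lag (deg) | — | 35 ± 10 | 100 ± 20 |
| lesion closure offset (%FL) | — | −4 ± 2 | −6.5 ± 2.5 |
| lesion extent (normalized) | — | 0.25 ± 0.05 | 0.30 ± 0.07 |

F0 is 160 ± 30 Hz in every group (fundamental frequency does not
discriminate).  The left/right lesion side is drawn uniformly; the
subject's whole-fold lag is assigned to the involved fold.  Additive
width noise is 0.15 %FL.  These values were calibrated once so that the
group *medians* of the vibratory parameters are reliably ordered —
amplitudes and open quotient decreasing, asymmetry and phase difference
increasing, norm → benign → malignant — while individual subjects
overlap heavily, as clinical cohorts do.  No published quantitative
lesion biomechanics exist, so magnitudes are plausible rather than
fitted; the generator reproduces ordering structure, not patient-level
medians or AUCs.

What the generator does **not** emulate: mucosal-wave propagation,
vertical phase differences, irregular (aperiodic) phonation, left-right
F0 differences, imaging artifacts.  Passing tests therefore demonstrate
correctness of the measurement and statistics machinery on
well-understood signals, not clinical performance on real recordings.

## Statistics

* **Routing**: Shapiro–Wilk per group at α = 0.05; any failing group
  routes the whole comparison non-parametric (t test / one-way ANOVA vs
  Mann–Whitney U / Kruskal–Wallis).  A constant sample routes
  non-parametric (W is undefined there).
* **Post hoc**: Fisher LSD (pairwise t on the pooled ANOVA error term,
  unadjusted by construction) on the parametric route; Dunn's rank test
  with tie correction and Bonferroni adjustment on the non-parametric
  route.  Running post hocs after a non-significant omnibus warns rather
  than errors.
* **ROC**: empirical curve over candidate thresholds at midpoints between
  consecutive distinct values plus ±∞; AUC by the trapezoidal rule.  Each
  parameter is oriented as *booster* (higher value ⇒ higher risk) or
  *inhibitor* (lower value ⇒ higher risk) so the reported AUC is ≥ 0.5.
  The AUC confidence interval and the p-value against 0.5 use DeLong's
  structural-components variance; under perfect separation (zero
  variance) the CI degenerates to a point.
* **Youden cut-point**: threshold maximizing J = sensitivity +
  specificity − 1; among ties, the smallest threshold in oriented units
  (deterministic).  Sensitivity and specificity are reported as fractions
  and formatted as percentages only in rendering.
* **Study driver**: per parameter, three-group omnibus + post hoc pairs;
  involved-vs-healthy amplitude comparisons within the benign and within
  the malignant group; both ROC variants with cut-points, sorted by AUC.
  Per-fold amplitude parameters are skipped in the norm-vs-lesion variant
  (they are undefined for normophonic subjects).

## Numerical choices and degenerate inputs

* Opening threshold ε = 5% of maximum width (configurable); amplitude
  floor for phase inclusion 1% of maximum demodulated amplitude.
* Discrete sampling bounds accuracy: with ~16 frames per cycle the peak
  of a sinusoid is underestimated by up to ~2%, which sets the tolerance
  of the amplitude-recovery guarantees; phase demodulation over the full
  window is far more accurate (≪ 1°).
* Silent glottis: symmetry measures and RGGA become NaN with an explicit
  flag; an all-zero trajectory yields an all-zero PVG.
* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  trajectories, frame stacks, and cohorts.

## Verification problem sizes

Default analyses use the acquisition geometry (2000 frames, 3200 fps,
64 positions).  The imaging round-trip check uses a 200-frame, 128×128 px
stack; ROC oracle checks use 200 random datasets with n ≤ 50 per class;
the type-I-error simulation uses 1000 replicates at the study's group
sizes; the cohort-ordering check simulates 20 full 175-subject cohorts.

## Known limitations

* The segmentation stand-in assumes high-contrast, glare-free imagery.
* Exact formulas of the clinical software are unpublished
  (supplementary/proprietary); definitions here follow the verbal
  descriptions plus standard kymographic conventions, and the phase
  difference unit (degrees) is a convention choice, not a claim of
  equivalence with the published normative values.
* Patient-level medians and AUCs of the original cohorts are not
  reproducible without the raw recordings; direction properties and
  internal consistencies are the testable surface.
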