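# Methods

This note documents the models, estimators and numerical choices behind
`gcmotility`, and what the synthetic-data validation does and does not
establish.

## 1. The synthetic world

### 1.1 Lamellipodium movies

The generator renders a single lamellipodium whose leading edge moves along
the image columns. The edge trajectory is an asymmetric sawtooth:
protrusion at rate `v_p` over the persistence length `dl`, then retraction
at the retrograde rate `v_r`, so that one cycle lasts exactly `T`. The
three parameters are linked by `T = dl/v_p + dl/v_r`; `MotilityParams`
treats `T`, `dl` and `v_r` as primary (defaults: the control-condition
values 86.5 s, 1.48 μm, 0.08 μm/s) and derives `v_p` (≈ 0.022 μm/s for the
defaults). Supplying an inconsistent `protrude_rate_um_s` is an error
rather than a silent re-interpretation.

Each frame is a 1-D intensity profile broadcast across rows plus i.i.d.
Gaussian pixel noise (sd 5 intensity units on a background of 100 — camera
noise is not characterised in the source experiments; this gives a
realistic ~16:1 contrast-to-noise ratio). The scene has three layers, all
functions of the column coordinate:

| layer | extent | height | rendering |
|---|---|---|---|
| bulk | from the field edge to ~1.2 μm behind the edge | 0 | contrast 80, mild defocus attenuation `1/(1+0.05·Δh)`, Gaussian blur σ = 0.3 px/μm·Δh; carries dark texture dips (depth 0.5, σ 0.15 μm, ~1.2 μm spacing) that translate rearward at `v_r` during retraction |
| sheet band | 1 μm strip behind the rim | `h_e(t)` | thin phase object: deviation `60·(1−exp(−Δh))`, zero at its own height |
| rim | outermost 0.2 μm | `h_e(t)` | dense edge bundle: contrast 120, blurred but not bleached by defocus |

The split reconciles two facts the analysis relies on: the leading edge
must stay trackable in the height-0 plane at every cycle phase (the rim),
while the defocus criterion — *in focus ⇔ intensity equalises with the
plane background* — must identify the sheet's height (the band). A
single-layer scene cannot do both, because a phase object in focus is, by
that criterion, invisible. The edge height `h_e(t)` follows a trapezoidal
lift profile: zero during protrusion, rising during retraction to a 5 μm
plateau near maximal retraction, returning to zero at the cycle boundary.

Defaults the experiments leave unstated, declared once here: pixel size
0.1 μm (100× objective on a typical CCD), image 80×160 px with the cell
base at 30% of the field width (so the plane median is genuinely the
background even at maximal protrusion), defocus blur 0.3 px per μm. The
frame interval must lie in the 1–10 s acquisition band.

Ground truth (exact edge position and height per frame) is stored with the
stack and written as a sidecar CSV next to the TIFF.

### 1.2 Bead traces

The bead is driven at scheduled constant velocities (push/retraction
events along ±x, ±y, ±z); between events the trap relaxes the deflection
exponentially (τ = 0.25 s) and the recorded signal fluctuates with
thermal noise (default sd 6 nm ≈ √(k_BT/k_xy) at k_xy = 0.10 pN/nm,
room temperature). Whenever the recorded lateral excursion exceeded the
200 nm threshold at the previous sample, the stage jumps so the bead
returns to the trap centre; the axial direction is never recentered.
Ground-truth force is stiffness × the noiseless deflection. There is no
Brownian-dynamics correlation structure and no hydrodynamic coupling —
deliberately out of scope.

### 1.3 Filopodia

Straight rods of ~1 px antialiased width elongate from fixed bases at a
constant rate until a maximum length. The default layout places bases on a
small hub with rods radiating outward (distinct filopodia, as around a
growth-cone periphery); explicit bases/angles support crossing-rod
fixtures.

## 2. Estimators

### 2.1 Edge extraction and tracking

The DoG response (σ = 1 and 3 px by default; the source analysis names the
filter but not its scales) is sampled along the user's or the automatic
sampling line (through the cell centroid, perpendicular to the blob's
elongation axis). The edge position is the *outermost zero crossing* of
the response whose flanking lobes are significant (≥ k·sd approaching, ≥
k·sd/2 beyond, opposite signs; k = 2). The zero crossing gives sub-pixel
localisation (≤ 0.5 px error on noiseless renders) and the lobe test
rejects sign flips in flat noise. Gap frames are linearly interpolated and
flagged; > 10 % gaps adds a warning, no edge anywhere is an error.

### 2.2 Cycle metrics

Cycles are delimited by local minima of the 3-frame-smoothed profile with
≥ 20 s separation. Period = mean inter-minimum interval; persistence = per
cycle, the raw maximum minus the raw minimum near the cycle-start minimum
(the ±1-frame neighbourhood absorbs the smoothing shift). Both carry a
quantisation floor of about one frame interval / the sampling loss of a
sawtooth extremum — at 5 s sampling the persistence readout is biased
about −0.08 μm, at 2 s about −0.04 μm, which is why amplitude recovery is
run at the fast end of the acquisition band.

### 2.3 Retrograde flow

Retraction windows are the maximal runs of frames whose centered edge
velocity is below half the 10th-percentile velocity (this excises the
mixed transition frames at cycle extrema). Within a window, candidate
rates on a ±0.25 μm/s grid (step 0.0025 μm/s) shear the kymograph columns;
the score is the variance of the time-averaged sheared profile, and the
grid optimum is refined by a parabolic fit. The reported rate is the mean
|slope| across windows. The scan is exhaustive rather than gradient-based
— streak scoring is multi-modal. Validity requires the total shear to stay
well below the window's spatial extent; with ≤ 20 s windows and a 160 px
line this holds with a wide margin.

### 2.4 Defocus heights

Background = exact plane median; tolerance defaults to 1.5 × robust sd
(1.4826·MAD) of the plane. A pixel is in focus when |I − background| ≤ tol
*and* its local intensity gradient (after σ = 1 px smoothing) is below
tol/2: a pixel on the flank of a defocus halo crosses the background level
without being in focus, and the gradient test removes exactly those
pixels. The ROI is data-driven: pixels whose deviation exceeds 3 × tol at
*any* imaged height (cell material is visible somewhere in the stack;
uniform background is not). Frames whose total in-focus population is
below 1 % of the ROI are emitted as zero columns and flagged instead of
being normalised from a handful of noise pixels. Columns therefore sum to
exactly 1 or exactly 0.

### 2.5 Forces and events

Force conversion is Hooke's law with (k_xy, k_z) = (0.10, 0.08) pN/nm by
default. Compensation adds the negated stage displacement to the QPD
signal; with a frozen stage it is the identity to machine precision, and
stage jumps without a preceding threshold crossing are flagged. Events are
maximal intervals with |F| ≥ 1 pN for ≥ 2 s (gaps < 1 s merged; both
floors are declared here — the source segments events by eye). The axis is
vertical iff peak |F_z| exceeds the peak lateral magnitude; the sense
compares the dominant deflection with a per-recording away-from-cell unit
vector (for the axial component, up = push). Reported maxima use |F_z| for
VP/VR and √(F_x²+F_y²) for LP/LR.

### 2.6 Protrusion rate

Each compensated path is projected on its net direction of motion; rising
phases are runs of smoothed velocity ≥ 5 nm/s lasting ≥ 2 s. Traces are
aligned to the first usable one by maximizing the cross-correlation of
smoothed velocities over integer lags within ±2 s of the onset difference
(raw-velocity correlation at 20 Hz is noise-dominated), averaged over the
common support, and the least-squares slope of the averaged rising phase —
with 0.5 s trimmed at each end to drop the smoothing corners — is the
rate.

### 2.7 Filopodia

Frames are thresholded at half the ridge amplitude, skeletonized, and each
tip moves to the nearest skeleton endpoint within 10 px, then is refined
to the sub-pixel half-maximum crossing along the base→tip ray (≤ 0.5 px
geometric bias from the antialiased cap). Length is the straight
base-to-tip distance (the fixtures are straight rods; arc length is
available for curved inputs). Growth rate is the least-squares slope over
the longest run of smoothed length increase ≥ 0.01 μm/s, with one corner
frame trimmed at each end.

### 2.8 Statistics

Mean ± SEM (SEM flagged undefined at n = 1). Group comparison is the
Welch two-sample t-test (the source says only "Student t-test"; unequal
variances are the safe default), two-sided; a paired variant exists for
before/after measurements on the same growth cone but unpaired is the
default. The normality screen is a chi-square goodness-of-fit against the
fitted normal with Sturges' bin count, equal-probability bins and
dof = bins − 3; under the null it rejects at ~5 % (verified by simulation
in the acceptance suite). No multiple-testing correction is applied,
matching per-comparison reporting.

## 3. What a green test establishes — and what it does not

The synthetic movies share the *statistical structure* the estimators
assume (sawtooth edge, rigid retrograde texture, defocus-attenuating
sheet, Hookean bead) but are not physically faithful phase-contrast
optics: there is no halo ringing, no shot noise, one lamellipodium per
field, and texture translates rigidly. Parameter recovery therefore
validates the estimator implementations and their quantisation behaviour,
not their robustness to every artefact of real recordings. The defocus
analysis in particular leans on the generator's phase-object contract; on
real data the tolerance, gradient threshold and ROI choice are the knobs
that matter and are all exposed.

## 4. Known limitations

* Persistence and period inherit one-frame quantisation; measure at the
  fast end of the acquisition band when amplitudes matter.
* The flow score compares variances across slightly different valid-row
  counts; for shears approaching the window height it biases toward
  smaller slopes (not reachable with physiological rates and default
  geometry).
* The tip tracker assumes ridges well separated at the half-maximum level;
  filopodia merging side-by-side for many pixels will fuse skeletons.
* `normality_check` requires n ≥ 20; below that the screen is skipped by
  the caller, not silently passed.
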