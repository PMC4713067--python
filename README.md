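# gcmotility

Quantification of growth-cone motility and force generation from time-lapse
microscopy and optical-tweezers recordings — with a synthetic-data generator
that makes every stage testable by parameter recovery.

Developing neurons explore their surroundings with growth cones whose
lamellipodia undergo cyclic protrusion/retraction and whose filopodia
elongate to probe the environment. This package implements the standard
measurements of that behaviour:

* **Kymograph analysis (lamellipodia).** The leading edge is extracted from
  the height-0 phase-contrast plane with a difference-of-Gaussians (DoG)
  filter and tracked along a sampling line. From the edge profile and the
  kymograph it measures the cycle period *T* (s), the persistence length
  *dl* (μm; the maximal excursion before retraction starts) and the
  retrograde flow rate *dx/dt* (μm/s; the slope of the dark streaks that
  rearward-moving actin features draw in the kymograph).
* **Defocus-based height analysis.** In a Z-stack (planes at 0–6 μm above
  the coverslip), a pixel of the thin lamellipodial sheet is *in focus* at
  the plane where its intensity equalises with the plane's background
  (median). The fraction of in-focus pixels per height, normalised across
  heights, tracks the vertical lift of the lamellipodium during retraction.
* **Optical-trap force analysis.** Bead deflection from the trap centre maps
  to force through the calibrated stiffness, F = (k_xy·x, k_xy·y, k_z·z).
  When the lateral excursion r = √(x²+y²) exceeds the detector's linear
  range (200 nm), a nanopositioner recenters the bead; the compensated
  trajectory splices the stage motion back into the bead path. Force
  episodes are classified into the four stereotyped behaviours — vertical
  push (VP), vertical retraction (VR), lateral push (LP), lateral retraction
  (LR) — and the lamellipodial protrusion rate is the slope of aligned,
  averaged compensated traces.
* **Filopodia tracking.** Tips are followed as ridge-skeleton endpoints with
  sub-pixel refinement; maximum length and growth rate come from the tracked
  length-vs-time series.
* **Statistics.** Mean ± SEM summaries, Welch t-tests between conditions,
  and a chi-square normality screen.

Because no primary recordings are distributed, the `synthetic` module
renders image stacks (sawtooth leading edge, retrograde texture, vertical
lift, defocus blur) and bead traces (scheduled push/retraction events,
thermal noise, feedback recentering) with known ground truth; every
estimator is validated by recovering the generator's parameters.

## Worked example

```python
import numpy as np
from gcmotility import synthetic as syn, kymograph as ky

params = syn.MotilityParams(period_s=86.5, persistence_um=1.48,
                            retro_rate_um_s=0.08, n_cycles=5, seed=1)
cfg = syn.ImagingConfig(heights_um=(0.0,), frame_interval_s=5.0)
stack = syn.generate_lamellipodium_stack(params, cfg)

metrics, profile, kymo = ky.analyze_stack(stack)
print(f"T = {metrics.period_s:.1f} s, dl = {metrics.persistence_um:.2f} um, "
      f"dx/dt = {metrics.retro_rate_um_s:.3f} um/s over {metrics.n_cycles} cycles")
```

prints

```
T = 86.7 s, dl = 1.39 um, dx/dt = 0.080 um/s over 3 cycles
```

i.e. the estimator recovers the generated 86.5 s period and 0.08 μm/s flow
from the rendered movie (the persistence readout at 5 s sampling carries the
expected one-frame quantisation loss; sampling at 2 s recovers 1.44 μm).

The same round trip for a trapped-bead push:

```python
from gcmotility import force as fo
cfg = syn.BeadSimConfig(thermal_sd_nm=0.0,
                        event_schedule=[syn.BeadEvent(2.0, "+x", 14.0, 10.0)])
ft = fo.force_trace(syn.generate_bead_trace(cfg))
ev = fo.analyze_events(ft, away_vector=(1, 0, 0))[0]
print(ev.behaviour, round(ev.max_force_pn, 1), "pN")   # -> LP 14.0 pN
```

A thin CLI wraps the pipeline: `gcmotility all --seed 1 --outdir out`
(subcommands `simulate`, `kymo`, `height`, `force`, `filo`, `stats`, `all`).

## Acceptance script

`scripts/acceptance.py` recomputes the headline recoveries from scratch —
it sets the generators to the published control / drug-condition means
(cycle period under control and 20 μM EHop-016, persistence length,
retrograde flow rate, the 140 nm lateral-push force at k_xy = 0.10 pN/nm,
the 100 nm/s protrusion rate, and the control filopodium length and growth
rate), runs the corresponding estimator on freshly generated data, and
writes the recovered values to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
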