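# vencstrain

Quantification of **longitudinal myocardial strain from in-plane
velocity-encoded (phase-contrast) CMR**, with a fully synthetic validation
bench: an analytic phantom simulator and an independent optical
grid-tracking oracle.

## The problem and the method

Regional left-ventricular function is usually judged visually. Velocity-
encoded cine MRI measures the in-plane tissue velocity field directly, so
a delineated myocardium can be *tracked* through the cardiac cycle and
deformation quantified. In long-axis views (2CH/3CH/4CH) the myocardium is
a U-shaped band and through-plane motion is small, which makes in-plane
tracking well posed for longitudinal strain.

The pipeline:

1. **Delineation (input).** Endocardial and epicardial contours at end
   diastole; the band is parameterized by material coordinates
   `(s, d)` — normalized arc-length base→apex→base, and transmural depth.
2. **Tracking.** The in-plane velocity of the tissue is modelled as
   `v(x) = Σᵢ aᵢ φᵢ(x)` with 7 local basis functions `φᵢ` distributed
   equally along the mid-wall centerline (a partition of unity in
   arc-length). Per timeframe the 2-D coefficients `aᵢ` solve a linear
   least-squares fit to the measured velocity (decoded from phase via
   `v = VENC·φ/π`) sampled at the current material-point positions, with a
   smoothness penalty on neighboring coefficients and an optional
   correction term that pulls chosen boundary nodes toward manually placed
   targets. Points are advected frame to frame; the cycle-closure error is
   reported.
3. **Strain.** The deformation gradient `F = ∂x/∂X` comes from finite
   differences on the material grid; the Green–Lagrange tensor
   `E = ½(FᵀF − I)` is decomposed along the local longitudinal (centerline
   tangent) and radial (wall normal) directions; `e_long = l̂ᵀE l̂`.
   Negative longitudinal strain is shortening. Global strain is the
   unweighted mean over all material points; sector strain follows the
   AHA 17-segment model, and per-sector values can be expressed as percent
   of a supplied normal map. Radial strain is computed by the same path
   but flagged experimental (voxel size ≈ wall thickening).
4. **Validation bench.** `phantom_sim` renders analytic deformations
   (U-shaped phantom, 100 × 70 mm envelope, 15 mm peak longitudinal
   compression; synthetic ventricles with prescribed per-sector strain)
   both as velocity-encoded cines (VENC 20 cm/s, 1.5 mm pixels, seeded
   phase noise, phase wrapping) and as grid-dot videos.
   `optical_oracle` measures strain from the video completely
   independently: matched filtering, predict-and-snap point tracking,
   cubic up-sampling to a dense displacement field, numerical
   differentiation. `reporting_stats` provides Bland–Altman agreement,
   remote/infarct classification from scar transmurality, and observer
   difference summaries.

## Worked example

```python
import numpy as np
import vencstrain as vs
from vencstrain import phantom_sim as ps

# simulate a noise-free compression of a strip phantom (lambda = 0.85)
spec = ps.PhantomSpec(geometry="STRIP", noise_sd=0.0)
series, truth, contours = ps.render_velocity_series(spec)

model = vs.build_model(contours)              # material grid 64 x 8
traj = vs.track_cycle(series, model)          # 7-basis velocity tracking
field = vs.compute_strain_field(traj, model)  # Green-Lagrange strain

print(f"peak global longitudinal strain: {field.global_curve().min():+.4f}")
print(f"analytic value (0.85^2-1)/2:     {(0.85**2 - 1) / 2:+.4f}")
print(f"cycle closure error: {vs.tracking.closure_error(traj):.3f} mm")
```

prints

```
peak global longitudinal strain: -0.1384
analytic value (0.85^2-1)/2:     -0.1388
cycle closure error: 0.189 mm
```

i.e. the tracked strain recovers the closed-form Green–Lagrange value of a
15 % uniaxial compression to ≈ 0.0004 strain with a sub-pixel cycle-closure
drift.

The same workflow is scriptable from the shell:

```bash
vencstrain simulate --geometry U_PHANTOM --seed 1 --out sim/
vencstrain track --series sim/series.npz --contours sim/contours.json --out traj/
vencstrain strain --traj traj/ --out report/
```

## Data formats

* **Native container**: a `.npz` archive (magnitude + phase images + JSON
  metadata block with VENC, pixel spacing, frame times, view label).
* **NIfTI**: `<stem>_mag.nii`, `<stem>_velx.nii`, `<stem>_vely.nii` plus a
  `<stem>_meta.json` sidecar.
* **DICOM**: a directory with SeriesNumber 1/2/3 = magnitude / x-phase /
  y-phase, phase decoded through RescaleSlope/Intercept to radians, VENC
  from a `venc.json` sidecar.
* Contours and correction points are JSON; reports and strain curves are
  CSV.

Conventions: 0-based pixel indices, physical position = index × spacing,
x = column (rightward), y = row (downward); geometry in mm, velocity in
cm/s, time in ms.
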