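# Methods

This note documents the models, numerical choices and known limitations of
the package; it is the reference for *why* the defaults are what they are.

## Deformation model

The in-plane tissue velocity inside the myocardial band is modelled as

    v(x, t) = Σᵢ aᵢ(t) φᵢ(x),        i = 1..n_basis (default 7)

where each `φᵢ` is a scalar bump in the arc-length coordinate `s(x)` of the
point's nearest foot on the *reference* mid-wall centerline, and each
coefficient `aᵢ` is a 2-D velocity. The model therefore spans velocity
fields that vary along the myocardium but are constant across the wall —
the mechanical prior being that in a long-axis view the dominant motion is
a base-to-apex contraction pattern with limited transmural velocity
gradient.

**Kernel family.** The bumps are piecewise-linear "hats" of half-width one
center spacing, with centers equally distributed at `s = k/(n−1)` so the
first and last sit on the basal ends of the band. This family was chosen
over smooth Gaussians after a design study on analytic phantoms:

* hats form an *exact* partition of unity with *exact linear precision* in
  `s`, so constant fields (rigid translation) and linear-in-arc-length
  fields (uniform strain) are represented without bias;
* partition-of-unity-normalized Gaussians at any width either flatten near
  the band ends (narrow kernels: global strain biased low by several
  percent of its value in noise-free uniform compression) or smear
  sector-scale contrast (wide kernels: a sector with 60 % of normal strain
  is read back near 84 %);
* each hat coefficient influences only its two neighboring cells — the
  sharpest localization a partition of unity allows — and the resulting
  normal equations are perfectly conditioned.

The price is C⁰ (not smooth) spatial variation of the fitted velocity;
strain is computed from tracked positions on the material grid, so this
does not propagate kinks into the strain tensor.

**Fit.** Per timeframe the coefficients minimize

    J(a) = Σ_x ‖v_meas(x) − Σᵢ aᵢφᵢ(x)‖²
         + λ_s · σ · Σ_{i~j} ‖aᵢ − aⱼ‖²
         + λ_c · σ · Σ_k ‖p_k + dt·v(p_k) − p_k^corr‖²/(0.01·dt)²

solved in closed form (normal equations). `x` runs over the current
(Lagrangian) positions of all tracked points; `v_meas` is sampled
bilinearly from the decoded velocity images. `σ = trace(ΦᵀΦ)/n` (the mean
diagonal of the data normal matrix) makes both penalty weights
dimensionless. Defaults: `λ_s = 0.003`, `λ_c = 10`. The smoothness weight
is intentionally gentle: the design study showed that a first-difference
penalty at strengths comparable to the data term biases the linear
(uniform-strain) coefficient profile at the band ends by several percent,
while the per-frame fit is already heavily overdetermined (hundreds of
samples for 14 coefficients), so little spatial damping is needed; the
residual noise in tracked positions is a *temporal* random walk that a
spatial penalty cannot remove. `λ_s = 0.003` is the largest decade-scale
value whose noise-free uniform-compression bias stays below the basis
representation error (< 0.001 strain).

**Corrections.** A correction point `(frame, node, target)` adds a row
that asks the node's post-step position to hit the target; it affects the
fit of its own frame onward only (no backward smoothing in time). With
`λ_c = 10` the correction carries ~10× the weight of a typical data row;
consistent corrections leave the solution unchanged.

**Time integration.** Forward Euler per frame interval (`dt` from the
frame times; the wrap-around interval is the mean dt). A midpoint option
exists; the dominant temporal error is frame-rate truncation, which at 20
frames/cycle causes transient position errors up to ~0.5 mm at peak
acceleration that largely cancel by peak systole. The cycle-closure error
(RMS distance of the once-more-advected final frame from the reference) is
always reported and never silently corrected; an optional linear drift
compensation is off by default.

## Geometry

Material coordinates `(s, d)` parameterize the band as the transmural
blend `X(s,d) = (1−d)·endo(s) + d·epi(s)` with both contours resampled at
matched normalized arc-length (base endpoints aligned). The inverse map is
solved patchwise by Newton iteration on the piecewise-bilinear band, so
position ↔ (s, d) round-trips to machine precision. The centerline is the
`d = ½` curve; longitudinal = its unit tangent, radial = the orthogonal
unit vector pointing endo→epi. The default material grid is 64 (s) × 8 (d)
points — much finer than 1.5 mm pixels across a ~10 mm wall — with
boundary nodes at the same arc-length stations so boundary-driven interior
interpolation is exact at grid points. Interior points may alternatively
be slaved to the boundary through the linear transmural blend
(`interior_mode="boundary"`); the default advects all points directly.

AHA mapping: each wall is split into basal/mid/apical thirds by
arc-length; the apex cap is `s ∈ [0.45, 0.55]`; the view→segment tables
are `2CH→(1,7,13,17,15,10,4)`, `3CH→(2,8,14,17,16,11,5)`,
`4CH→(3,9,14,17,16,12,6)`; shared segments are averaged across views.

## Strain

`F` by second-order central differences on the `(s, d)` grid (one-sided,
second-order at edges), mapped through the reference-grid Jacobian;
`E = ½(FᵀF − I)`; directional strains are quadratic forms along the
*reference* direction fields. Peak systolic strain is the most negative
longitudinal value (most positive for radial thickening) over the cycle;
a last-frame ("end") mode is switchable. Global strain is the unweighted
mean over all material points of all available views (views must share a
frame count). Points where a grid cell collapses (det F ≤ 0) are flagged
and excluded from aggregates. Radial strain is produced by the identical
path but labelled experimental: with 1.5 mm voxels against 2–4 mm of wall
thickening its variability is intrinsically high.

## Synthetic-data generator

The generator *is* the study-condition definition; its defaults are:

* **U phantom**: outer envelope 100 × 70 mm, limb width 20 mm, peak
  longitudinal compression 15 mm (λ = 0.85, e_long = −0.13875), raised-
  cosine temporal profile over a 1000 ms cycle (periodic, differentiable,
  cycle-closing), transverse coupling area-preserving ("incompressible";
  a pure-uniaxial no-bulge mode exists for closed-form tests). A straight
  STRIP geometry provides the fully in-span uniaxial case; rigid
  translation and rotation motions support invariance tests.
* **Imaging**: 1.5 × 1.5 mm pixels, VENC 20 cm/s, 20 timeframes. Phase
  noise is additive Gaussian *on the wrapped phase* (SD 0.05·π rad ≈
  1 cm/s of velocity noise), matching acquisition physics; velocities
  beyond VENC alias exactly as a scanner reconstruction would. For the
  affine motions the velocity formula is evaluated at every pixel (its own
  analytic continuation outside the phantom); for the ventricle, velocity
  is interpolated from the deformed material grid and nearest-extended
  outside the band. Either way, bilinear sampling at boundary nodes is not
  contaminated by zero-velocity background (a partial-volume artifact that
  would otherwise bias edge strain and which this simulator deliberately
  excludes — real acquisitions do suffer from it).
* **Synthetic ventricle**: U-shaped long-axis model with endocardial apex
  radius 22 mm (≈ LVEDD 44 mm), wall 10 mm, limb length 45 mm (epicardial
  base–apex length ≈ 77 mm) — mid-normal adult dimensions. Among equally
  realistic shapes the rounder apex was preferred because the 7-basis
  model under-resolves sharply curved apices (see Limitations). Per-sector
  strain targets are realized *exactly*: every transmural fiber line is
  rebuilt by integrating its own tangent scaled by
  `λ(s) = √(1 + 2·e_target(segment(s)))` outward from the fixed apex, so
  the longitudinal fiber stretch equals `λ(s)` at every point and depth
  and the base moves toward the apex as in systole.
* **Grid video**: dots of 1 mm radius on a 5 mm grid, rendered
  antialiased at 1080 × 720; exact dot-center trajectories are exported.

What the simulator does **not** emulate: k-space acquisition, echo-train
artifacts, ghosting, through-plane motion, eddy-current background phase,
realistic myocardial texture, or the gelatin phantom's true material
response. Passing tests therefore demonstrate correctness of the
*computational* pipeline under the stated noise model, not robustness to
every acquisition artifact of real scans.

## Validation experiments

* **Cross-method phantom experiment** (the reproduction script): the same
  analytic compression is measured by both pipelines; strain is compared
  in three ROIs (two limbs, base) over all timeframes, each along its
  local wall direction (limb axis in the limbs, transverse at the base).
  The optical tracker is given the known rig motion as a per-frame prior
  and a search radius of half the dot spacing, as a physical validation
  rig with a driven piston would allow. Typical result: SD of paired
  differences ≈ 0.010 strain over 60 pairs.
* **Sector recovery**: per-sector percent-of-normal under the default
  phase noise scatters by ~4–5 percentage points per realization (set by
  the band pixel count and frame count), so the recovery experiment
  averages three independent noise realizations; the infarct-like sector
  is placed basally (segment 4, the classic inferior territory).

## Known limitations

* The 7-coefficient, arc-length-parameterized velocity model cannot
  represent transmural velocity gradients. Consequences: (i) rigid
  *rotation* produces residual strain ≈ θ/2 at total angle θ — the
  pipeline-level rotation-invariance check uses a small-angle jitter,
  while exact Green–Lagrange rotation invariance is verified at trajectory
  level; (ii) strain components carried purely by transmural motion (e.g.
  the limb-axis strain at the very bottom of the U phantom) are invisible
  to the velocity pipeline (the optical oracle sees them).
* Apex resolution: the tangent direction rotates 180° across the apex arc,
  which 7 basis cells resolve only partially; the apex-sector strain is
  systematically underestimated by ~0.01 strain at the default ventricle
  geometry (more for sharper apices).
* Sector contrast is low-pass filtered at the basis-cell scale: a
  single-sector strain deficit is recovered at roughly 75–100 % of its
  true contrast depending on where the sector sits relative to the basis
  nodes (end sectors best).
* Whether the coefficients should be refit against velocities sampled at
  reference (Eulerian) or tracked (Lagrangian) positions is ambiguous in
  principle; Lagrangian sampling is used, consistent with following
  material points.
* No torsion, rotation, circumferential strain, or strain rate; the
  vendor phase-scaling convention is assumed linear (`v = VENC·φ/π`).
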