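# Methods

`phalanxfem` computes the internal bending loads carried by a fixation
plate bridging a mid-diaphyseal gap osteotomy of a proximal phalanx during
a simulated rehabilitation exercise (full finger flexion). The measurement
principle: a compliant plate with known material properties spans a 3 mm
fracture gap; the rigid-body motion of each bone fragment is tracked
optically; a specimen-specific finite element model driven by the measured
relative motion yields the force and moment resultants transmitted through
the plate's mid-section. This note documents the model, the synthetic data
that stands in for cadaver inputs, the numerical choices, and what the
package's tests do and do not establish.

## Pipeline model

1. **Imaging.** The post-operative scan fixes the construct pose; the
   pre-operative scan carries artifact-free geometry and per-voxel mineral
   density. Bone is segmented by inclusive HU thresholding (default
   400–4000 HU) followed by morphological closing (ball, default radius 2
   voxels; the erosion treats out-of-image voxels as foreground so masks
   touching the image border are preserved). An optional per-slice hole
   fill absorbs enclosed marrow/trabecular space; it is off by default
   because the synthetic phantom's validation math assumes a cortex-only
   mask. The pre-op volume is rigidly co-registered to the post-op pose by
   maximizing normalized mutual information, NMI = (H(A)+H(B))/H(A,B), over
   the 6 rigid DOFs with multi-resolution Nelder–Mead (restarted with a
   shrinking simplex per level). Two safeguards matter in practice and are
   part of the method: poses that lose more than half of the starting
   field-of-view overlap are rejected outright (otherwise NMI rewards
   matching background against background), and both images are Gaussian
   pre-smoothed by one voxel before the metric (on piecewise-constant
   images the raw NMI peak is displaced by interpolation artifacts; a
   one-voxel blur restores an unbiased peak). The registered pre-op mask is
   cropped to the osteotomy: voxels within the gap slab
   |(c − c₀)·n| < g/2 are removed and the rest partitioned by the sign of
   the projection into proximal and distal fragments.
2. **Density → stiffness.** Density is an affine map of HU (identity by
   default — calibration constants are scanner-specific configuration),
   clamped at zero. Element moduli follow a power law
   E = E₀ (ρ/ρ₀)^k with defaults E₀ = 10 GPa at ρ₀ = 1000 mg HA/cm³ and
   k = 1.5. These constants are deliberately configuration, not claims: any
   published density–modulus law can be supplied. A floor (0.01 MPa) keeps
   the stiffness matrix regular for near-empty elements.
3. **Plate material.** The plate polymer (PEEK) is calibrated from uniaxial
   dog-bone tension data: E by OLS over a low-strain window (default
   0.05–0.25% strain), ν from lateral vs axial strain, yield by the 0.2%
   offset construction, and a (plastic strain, stress) table from the
   post-yield samples. Engineering stress/strain throughout, consistent
   with the small-displacement FE. The reference constants are
   E = 1740.5 MPa, ν = 0.3779, yield 100.3 MPa.
4. **Kinematics.** Fragment poses come from ≥3 labelled optical markers per
   fragment via the SVD (Kabsch) rigid fit with a reflection guard. The FE
   drive is the relative transform T_rel = T_prox⁻¹ ∘ T_dist (common-mode
   hand motion cancels exactly), reported at the plate's distal reference
   divot and discretized into 10 evenly spaced steps by constant-axis
   (geodesic) interpolation about the divot. Linear matrix interpolation is
   rejected because it leaves SO(3).
5. **FE model.** Fragment masks are coarsened to bricks of roughly the
   target edge length (a brick is kept when at least half filled; its
   modulus uses the mean density over the whole brick, zeros included,
   which softens partial boundary bricks and improves mesh-size
   stability). Each brick splits into 6 straight-sided quadratic
   tetrahedra (Kuhn split, consistent diagonals) promoted by global
   mid-edge insertion; 4-point Gauss quadrature integrates the stiffness
   exactly for straight elements. The plate is meshed the same way from
   its parametric description; its holes are carved by brick-centre tests,
   so the plate mesh edge should stay ≤ about a third of the hole diameter
   (default 0.5 mm for 1.5 mm holes). Screws are not meshed: every
   hole-boundary plate node with a bone surface node within 1 mm has its
   three DOFs eliminated to that nearest node (master–slave ties).
   Boundary conditions: the proximal fragment's far end cap is clamped;
   the distal end cap follows the step transform rigidly. Plate–bone and
   bone–bone contact is off by default — under rehabilitation-scale motion
   the 3 mm gap cannot close, and tensile lift-off of the plate underside
   is assumed; the tie constraints alone transmit the load. For
   gap-closure studies a penalty contact option (`contact: penalty`) keeps
   each osteotomy face from crossing the gap midplane: node-to-plane
   springs with stiffness 100× the largest stiffness diagonal, enforced by
   an active-set iteration (and, when active, per-step solves replace the
   proportional ramp, since contact breaks superposition).
6. **Solver modes.** The default mode is linear small-strain with
   proportional displacement loading: the final pose's prescribed
   displacement is ramped linearly over the 10 steps from one factorized
   solve, exactly as a linear static analysis treats a ramp amplitude, and
   section quantities are evaluated in the reference configuration (the
   deformed-position correction is second order and inconsistent with
   linearized equilibrium). The optional `incremental` mode imposes each
   geodesic pose exactly, updates nodal coordinates and reassembles after
   every step — a first-order account of geometric nonlinearity — and then
   evaluates the section in the deformed configuration with the cut plane
   tangent to the deformed centerline. At the ~2° relative rotations of
   interest the two agree to well under a percent; output metadata records
   the mode. Plasticity is carried in the material model but not in the
   solver: the computed plate stresses sit far below the 100.3 MPa yield
   (a warning is emitted if any element's von Mises stress crosses it).
7. **Section resultants.** The bending moment is evaluated at the plate
   mid-length: element-internal nodal forces of the plate elements are
   summed over all plate nodes distal to the cut plane, with moments about
   the section point. The convention is the action of the distal segment
   on the proximal one; evaluating from the other side flips the sign
   exactly (a useful self-check, ≤1e−6 relative). The scalar "bending
   moment" is √(M₁² + M₂²) over the two transverse axes; torsion about the
   tangent is reported separately and excluded. The headline quantity is
   the maximum of this scalar over the steps.
8. **Statistics.** Specimen × digit × repeat maxima are aggregated as
   means ± sample SD and compared with one-way ANOVAs (between/within
   decomposition, F-distribution p) by specimen and by digit.

## Synthetic data: what it emulates and what it does not

The generator produces every pipeline input with known ground truth:

- **Phantom** (`PhantomSpec`): an HR-pQCT-like volume (default 82 µm
  isotropic voxels) of an idealized phalanx — a hollow cortical cylinder,
  default outer radius 4 mm, cortical thickness 1.5 mm, length 24 mm, with
  a 3 mm transverse gap at mid-length; cortex 1600 HU, marrow 100 HU,
  background 0 HU, optional Gaussian HU noise. Voxels are classified by
  centre (no partial-volume blur) and the grid is snapped so the osteotomy
  plane falls on voxel boundaries; voxel counts therefore match analytic
  volumes to discretization accuracy, and the generator returns exact
  per-fragment masks as oracles. An idealized cylinder, not an anatomical
  phalanx, is deliberate: the method is geometry-agnostic and the oracle
  math requires analyzable shapes.
- **Plate** (`PlateSpec`): a de-featured rectangular plate, default
  24 × 4 × 1.5 mm with four 1.5 mm through-holes, two per fragment, 5 mm
  apart and 5 mm from the fracture line, and two top-surface reference
  divots midway between each hole pair. The overall dimensions are
  configuration stand-ins (the physical plate's CAD dimensions are not
  published); hole placement is the surgical-guide geometry.
- **Markers**: rigid distal-fragment trajectories sampled as labelled
  frames (geodesic interpolation about the distal divot), proximal side
  static, optional isotropic Gaussian noise (default 0.05 mm in the
  pipeline, camera-class precision).
- **Dog-bone curves**: bilinear elastic–plastic with the kink placed
  analytically so the 0.2%-offset yield equals the requested value
  exactly; default hardening modulus 50 MPa (PEEK shows a near-plateau
  post-yield at these rates); lateral strain is elastic −νε plus an
  incompressible plastic part.

Not emulated: trabecular microstructure, beam hardening and scanner
artifacts, soft tissue, screw thread mechanics, anatomical cross-section
variation along the shaft. Consequently the tests establish the
*correctness of the computational chain* (segmentation → registration →
meshing → solve → resultants against analytic oracles), and that
rehabilitation-scale relative motions on a phalanx-scale construct produce
single-digit N·mm plate moments — not a numeric reproduction of any
cadaver-specific value.

## Reference problem sizes

The reference phantom model is meshed at bone edge lengths of 1.0 mm
(≈10k elements) and 0.5 mm (≈40k elements) with the plate fixed at 0.5 mm
— mirroring the strategy of refining bone while holding the plate at its
convergence-verified resolution. The imposed reference motion is a 2°
flexion rotation about the distal divot plus a 0.1 mm translation; between
those two resolutions the maximum bending moment changes by about 1%,
within the 5% convergence criterion the pipeline adopts. Pipeline test
configurations use coarser voxels (0.25–0.4 mm) and meshes where a test's
purpose does not depend on resolution; each test states its sizes.

## Numerical choices and degenerate inputs

- Rigid fits reject collinear marker sets (rotation about the line is
  unobservable); the reflection guard flips the smallest singular vector.
- Geodesic step generation rejects rotations ≥180° (axis ambiguity).
- Registration is a local search: it assumes a roughly correct initial
  pose and is validated for misalignments of a few degrees / ~1 mm. The
  simplex scale tracks the expected misalignment, not the pyramid level;
  results never degrade below the initial metric value, and <10% remaining
  overlap sets a warning flag.
- The segmentation raises on empty masks, naming the thresholds; the crop
  raises if either fragment would be empty; the mesher raises if
  coarsening removes all material.
- Empty centerline slabs are filled from their nearest neighbours; more
  than 25% empty aborts. The cut raises if a tie pair straddles the plane.
- Ties deduplicate slaves (a node is slave in at most one constraint) and
  raise when a hole has no bone within the search radius.
- The direct sparse LU (symmetric-pattern ordering) is the primary solver;
  an ILU-preconditioned CG (rtol 1e−10) is the fallback.
- Determinism: every stochastic input draws from a seeded generator;
  specimen/digit variation uses deterministic seed sequences derived from
  the run seed, so identical seeds give byte-identical outputs.

## Specimen variation in synthetic studies

Real studies vary by donor and digit. Synthetic runs emulate this with
seeded jitter per (specimen, digit): ±5% outer radius, ±5% cortical HU,
±15% flexion angle, ±20% divot translation; repeats within a digit differ
only through marker measurement noise. This gives the ANOVA stage real
group structure without claiming anatomical realism.

## Known limitations

- Elastic-only solver (yield exceedance warns rather than redistributes).
- Nearest-node ties are stiffer than surface-interpolated ties; at the
  default mesh sizes this is within the mesh-convergence tolerance.
- The incremental geometric mode is first-order (no stress-stiffening
  matrix), adequate for the ≤2° motions studied.
- Frictionless contact for gap closure exists as a penalty option but is
  not exercised by the default pipeline (the gap never closes at
  rehabilitation-scale motion).
- Registration recovers rotations only about axes the image content makes
  observable; a plain cylinder leaves its own axis free (the pipeline's
  density mapping is invariant to that rotation, so it is harmless there).
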