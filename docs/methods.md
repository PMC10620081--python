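# Methods

## Physical model

Temporal interference stimulation superposes two sinusoidal electric
fields E₁(t), E₂(t) at nearby kHz frequencies f₁, f₂. Projected on a unit
direction **n**, the summed waveform has a beat envelope that oscillates at
Δf = f₁ − f₂ between |(E₁+E₂)·n| and |(E₁−E₂)·n|; its peak-to-trough
extent, the envelope-modulation amplitude, is

|E_AM| = ||(E₁+E₂)·n| − |(E₁−E₂)·n|| = 2·min(|E₁·n|, |E₂·n|),

and the beat-cycle peak of the projection (the absolute amplitude) is
|E₁·n| + |E₂·n|. The identity with 2·min is algebraic; the package also
checks both forms against a numerically simulated two-tone envelope (dense
sampling of one beat, Hilbert magnitude), which agrees to ~1e-11 relative.
Consequences used throughout: 0 ≤ eam ≤ eabs, symmetry under swapping the
pairs, and degree-1 homogeneity in a joint current scaling.

At kHz frequencies in head tissue, ohmic currents dominate displacement
currents and the wavelength far exceeds the head, so each pair's field is
the solution of the electro-quasistatic problem ∇·σ∇φ = 0 with a real
conductivity σ. The problem is linear: each pair is solved once at an
arbitrary 1 V, normalized to 1 mA of injected current, and every
stimulation condition or steering ratio is obtained by scalar rescaling —
never by re-solving.

## Discretization and solver

The conducting voxels of the phantom form trilinear hexahedral finite
elements with an element-constant conductivity tensor
σ = σₜI + (σₗ−σₜ)nnᵀ (σI where isotropic). The energy formulation gives a
symmetric positive-definite stiffness matrix for any symmetric
positive-definite tensor field; the system is solved with Jacobi-scaled
conjugate gradients (default relative residual 1e-8, iteration cap
50 000, both configurable). Electrode patches are Dirichlet voxel sets at
±V/2 on the scalp surface (spherical caps of configurable area, default
2.25 cm² matching 1.5 cm × 1.5 cm pads, 3.14 cm² available to mirror a
2 cm disc); the outer boundary is insulating; voxels disconnected from the
electrode component are dropped; anode and cathode in different conducting
components is an error.

Two properties motivated this discretization over a face-flux
finite-difference stencil. First, the piecewise-(tri)linear solutions of
the uniform-field and layered-slab problems lie in the trial space, so
those analytic cases are reproduced to solver precision at any grid.
Second, the injected current has a variationally consistent form — the sum
of reaction currents (Kφ)ₙ over an electrode's Dirichlet nodes — which is
the discrete version of integrating the normal current density j = σE over
a closed surface around the electrode. With it, charge conservation for
any closed voxel surface enclosing neither electrode holds to solver
tolerance by construction (`region_current`). An independent two-point
face-flux integral of σE (`surface_current`) is kept as a cross-check; the
two agree exactly for uniform fields and to well under 0.5% of the
injected current elsewhere.

The voxel potential is the mean of the eight nodal values and E is the
element-center shape-function gradient (equivalent to central differences
of the nodal field), NaN outside the conducting domain.

## Synthetic phantom: what it emulates, and what it does not

The default phantom is five concentric shells with outer radii 80, 74,
68, 63, 56 mm (scalp 6 mm, skull 6 mm, CSF 5 mm, gray 7 mm, white core)
and conductivities 0.4, 0.008, 1.79, 0.28, 0.13 S/m — configuration
defaults from the conductivity meta-analysis literature, not fitted
values. Shell thicknesses were chosen to exceed the voxel diagonal at the
default 2.5 mm resolution so the thin resistive/conductive layers are
watertight when rasterized. The grid is sized so the sphere center falls
on a voxel center, keeping mirror-symmetric montages exactly symmetric on
the grid.

The deep target is a 6 mm-radius tube around a banana-shaped centerline in
the left hemisphere ((−18, 24, 0) → (−30, 0, 0) → (−18, −24, 0) mm, long
axis along y, anterior = +y, conductivity = gray). Tube rasterization
excludes the spherical end caps (voxels whose nearest centerline point is
an endpoint), so the voxel count tracks the analytic cylinder volume.
Parcellation into Ant/Mid/Post uses arc-length thirds of the centerline
measured from the anterior end — a coordinate-free stand-in for
atlas-based longitudinal splits, which are anatomy-specific.

The orientation field **n** — the direction fields are projected on —
defaults to **radial** throughout the brain including the target. Radial
is the natural proxy for the dominant cellular axis on a spherical brain:
cortical pyramidal neurons point radially, and the deep target's
pyramidal axis is transverse to its long axis, which at the target's
lateral position is again close to radial. Uniform-vector and
tangent-to-centerline (`along_target_axis`) modes are available and can be
composed (e.g. radial cortex with a tangential target).

Electrode placement follows fractional half-circumference rules: in a
given axial plane, the half circumference H is measured from the nasion
(anterior point) around one hemisphere, and an electrode sits at
`fraction·H + offset`. The default rules put the target-side pair anchors
at 0.5H ∓ 2.5 cm (5 cm between centers, nasion plane) and the
contralateral anchors at 0.2H − 1 cm and 0.7H + 1 cm (16 cm apart for
H = 28 cm) in an eyebrow-level plane 20 mm higher; pairs are (e1, e2) and
(e3, e4). A mirror-symmetric variant (both planes at the nasion level,
contralateral electrodes at 0.5H ∓ 6 cm) is provided for steering
experiments, where the 1:1 ratio must center the modulation locus on the
target midpoint by symmetry.

What the sphere does **not** emulate: gyral folding and sulcal CSF,
ventricles, skull inhomogeneity (no cancellous/cortical split), real fiber
architecture, and electrode–skin contact impedance. Passing tests
therefore demonstrate that the algorithms honor the physics and the
qualitative geometry of deep-target interference — not that any absolute
V/m value transfers to a human head; anatomy-dependent published values
are treated as qualitative expectations only.

## Recording generation and envelope analysis

The synthetic recording is, per contact k,
A₁ₖ·sin(2πf₁t) + A₂ₖ·sin(2πf₂t) + N(0, σ²) in mV at 30 kS/s (default),
reproducible under a fixed seed. White Gaussian noise is the only noise
term; drift, line interference and biological background are not modeled.
One subtlety: at fs = 30 kS/s the 2000/2005 Hz pair is exactly
6000-sample periodic, so the sample maximum plateaus ~0.3% below A₁+A₂;
with an incommensurate rate the maximum converges to A₁+A₂ (the test
suite checks both behaviors).

Analysis defaults follow the measurement protocol: first-order Butterworth
bandpass (0.5–5 kHz TI band or 1–40 Hz tACS band), envelope = |analytic
signal| low-passed by a first-order 0.5 kHz Butterworth, statistics over
25 × 1 s epochs. All filters are zero-phase (forward–reverse) by default,
which avoids phase-distorting the envelope; the causal single-pass variant
is a flag. Per epoch the envelope max/min and the signal max are taken,
excluding the first and last 100 ms of the trace to avoid filter edge
transients; then

* modulation amplitude = mean of (max − min)/2  → min(A₁, A₂) on a clean
  two-tone (the alternative protocol reading, mean of (max + min)/2, is
  available as `stat_mode="mean_of_extrema"`);
* absolute amplitude = median of the per-epoch signal maxima → A₁ + A₂;
* modulation ratio = mean of (max − min)/max → 2·min/(A₁+A₂). This
  envelope-depth definition reaches ~1 for balanced fields at depth; the
  literal half-difference reading, which saturates at 0.5, is available as
  `ratio_mode="half_difference"`.

Epoch extrema are plain sample extrema; robustness to noise comes from
epoch averaging, not trimming. Field strength along the shaft is
|Δvalue|/Δdepth per neighboring contact pair (mV/mm ≡ V/m), and 2D maps
apply a 3-point moving average along each electrode's contacts
(edge-replicated) before bilinear interpolation onto a 100 × 151
(electrode × depth) grid.

Convention note: the field metric |E_AM| equals the envelope max − min
(2·min of the projected amplitudes), while the recording metric is the
half difference (min itself). Cross-module consistency tests state the
factor explicitly: a recording generated from the solved per-pair
projected amplitudes yields contact modulation amplitudes equal to eam/2
within 5%.

## ROI summaries, steering, and the qualitative orderings

ROI statistics are medians (with s.d. and voxel counts); normalization is
either to the target ROI median (target ≡ 1) or
fraction-of-subregion-sum over the target thirds (fractions sum to 1).
Steering sweeps hold I₁+I₂ fixed over ratios {3:1, 2:1, 1:1, 1:2, 1:3}
(default total 4 mA) and report subregion fractions plus the eam-weighted
centroid in arc-length mm from the anterior end. Because eam is
2·min(I₁p₁, I₂p₂), once one pair's scaled projection is the pointwise
minimum over the whole target the map shape becomes invariant to further
ratio changes — centroid curves therefore show plateaus at extreme
ratios, and monotonicity is asserted non-strictly with a strict overall
shift between 3:1 and 1:3. Peak-voxel reports break ties at the lowest
linear index.

The deep-vs-superficial comparison uses three 10 mm spherical gray-matter
ROIs at mid-gray depth beneath the two target-side electrodes and beneath
their arc midpoint. The qualitative expectation — target median eam above
the pooled overlying-cortex eam, pooled cortex eabs above target eabs —
holds on the default phantom (ratios ≈ 1.06 and ≈ 1.25 at 1 mA per pair)
and is asserted as inequalities only. The pooled (not per-ROI) comparison
is the deliberate choice: the mid-cortex point midway between the two
same-side electrodes sees near-balanced pair fields for geometric reasons
and individually rivals the target's modulation on a smooth sphere.

## Numerical and design choices

* Coordinates: world mm, right-handed, sphere centered at the origin;
  voxel indices 0-based; target long axis along +y, anterior = +y.
* Solver tolerance 1e-8 (relative residual), CG with Jacobi scaling;
  non-convergence within the iteration cap raises rather than returning a
  degraded field.
* Orientation vectors are unit norm to 1e-9 where defined, NaN elsewhere;
  exposure maps are NaN outside the brain/orientation support.
* The exposure path evaluates only the projected metrics along the given
  orientation field; an orientation-free "maximal modulation over all
  directions" variant is intentionally out of scope.
* Sham conditions (0 + 0 mA) produce identically zero modulation maps and
  exercise the full pipeline.
* All randomness flows from a single master seed; pipeline re-runs are
  byte-identical at the CSV/JSON level (no timestamps in outputs).
* Default problem sizes: 2.5 mm voxels (67³ grid, ~300 k conducting
  voxels) for the study phantom; 20–22-voxel slabs for analytic checks;
  25 s at 30 kS/s for recordings. These sizes keep each pair solve at a
  few seconds on one CPU while leaving shells watertight and the beat
  statistics well-resolved.

## Known limitations

* The spherical phantom cannot reproduce anatomy-specific published field
  values; only orderings and mechanisms are checked.
* Electrode patches are rasterized spherical caps; the true pad shape
  (square with rounded corners) and contact impedance are not modeled.
* No frequency dependence of conductivity and no displacement currents
  (quasistatic, single real solve per pair).
* The synthetic recording has no stimulation artifact or biological
  signal, so artifact-rejection behavior of the filters is untested.
* White-matter anisotropy is supported (σₗ/σₜ tensors from the orientation
  field) but disabled in the default sphere, which lacks meaningful fiber
  geometry.
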