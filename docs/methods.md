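# Methods

This note documents the models, parameter choices and numerical decisions
behind `shg4d`, in the order data flows through the pipeline.

## Data model

A time point is a two-channel 3D grid (`VoxelStack`): forward-detected and
epi-detected SHG intensity, arrays indexed (z, y, x), voxel spacing
(dx, dy, dz) in μm, and a timestamp in minutes with t = 0 at drug
addition.  A `StackSeries` requires strictly increasing timestamps and one
grid geometry throughout; differing stack depths across *samples* are fine
(each sample is its own series), differing depths within a series are a
hard error.  Timestamps live in the manifest, not in microscope metadata —
conversion from proprietary formats is upstream of this package.

Axis semantics follow the standard mounting of a thin section: the cut
length is glued along y, the width (outer to inner surface of the dura,
the swelling direction) lies along x, and the cut thickness (~30 μm)
along the optical axis z.  "Height is unaffected by swelling" is therefore
a z-statement, and tilt is a rotation of this slab relative to the grid.

## Phantom generator

The generator is not a test fixture but the package's study-condition
definition: it emulates exactly the structure the analysis assumes, with
closed-form ground truth.

- **Geometry.** A box of baseline width w₀, length L and height h₀,
  rotated by Rx(αx)·Ry(αy) about the grid centre.  A voxel belongs to the
  envelope if its centre, rotated into the slab frame, lies inside the
  box.  Containment of the swollen, tilted box is checked per timestamp;
  violation names the first offending time.
- **Swelling law** w(t) = w₀(1 + A(1 − e^(−t/τ_s))).  Observed swelling
  curves saturate over tens of minutes but no mechanistic form is
  established; the saturating exponential is an explicit stand-in, not a
  biological claim.  Height and length are constant.
- **Intensity regimes.**
  - *inert*: expected emission I₀·texture, constant in time.
  - *dilution*: ellipsoidal voids of zero emission appear inside the
    envelope (Poisson count at `void_rate_per_min`, appearance times
    uniform over the series, positions in material coordinates so they
    ride along with the stretching width, radii capped for full
    enclosure).  The emitting voxels are renormalised each timestamp so
    the expected envelope total equals the intact baseline total —
    conservation holds by construction, modelling the same collagen
    redistributed over a larger volume.
  - *destruction*: per-voxel emission scaled by e^(−t/τ_d).
- **Texture** is a sinusoidal stripe pattern across the width
  (period 12 μm, contrast 0.2 by default), mimicking fiber bundles; it is
  cosmetic, present to exercise segmentation robustness.
- **Channels and noise.** Epi expectation = β·forward (default β = 0.5).
  Noise is applied last and independently per channel: Poisson counts at
  gain g (observed = Poisson(E·g)/g, so baseline SNR = √(I₀·g); the
  default I₀ = 100, g = 1 gives SNR ≈ 10) plus additive Gaussian read
  noise (sd 2), clipped at zero.  All randomness derives from one
  `SeedSequence`, so identical specs give bit-identical series.
- **Defaults** mirror the targeted acquisition: 512×512 px over
  450×450 μm, 61 slices at 1 μm, h₀ = 30 μm, timestamps spanning ~50 min
  with the first stack a few minutes after drug addition.  Tests and the
  acceptance script use smaller grids (≈10⁵–10⁶ voxels, 1–2 μm pitches) —
  a package choice that keeps suites fast; the dynamics parameters (A,
  τ_s, τ_d, SNR, time spans) are never scaled down.

The 2D phantom is a bright strip on a dark background whose two sides
expand by independent saturating-exponential factors at 1 frame s⁻¹;
`Phantom2DSpec.doubling()` solves the growth factor so the true area
ratio is exactly 2 at a chosen time.

What the phantoms do **not** emulate: optical PSF blur, depth-dependent
attenuation, polarization dependence of SHG, realistic fibril
architecture, or sample drift.  Passing tests therefore demonstrate the
correctness and calibration of the *feature extraction*, not robustness
to every artefact of real microscopy.

## Segmentation

Per time point, on the forward channel only (geometry is most reliable
there; epi feeds intensity features):

1. Gaussian smoothing, σ = 1 voxel.
2. Background floor = median + k·sd (k = 3) of the darkest quartile of
   border voxels.  If zero-clipping of read noise makes that quartile
   degenerate (all zeros), the sd falls back to the whole border's spread.
   The floor prevents Otsu collapse when the foreground fades.
3. Threshold = max(floor, Otsu of the smoothed stack), **applied to the
   raw channel**.  Estimating on smoothed data stabilises the threshold;
   applying it to raw voxels avoids the systematic erosion of box edges
   that thresholding a blurred image causes (a blurred right-angle edge
   falls below any mid-level threshold, and no closing radius repairs a
   straight groove).  Noise-induced pits are instead repaired by steps
   4–5.  Because every quantity in the threshold is homogeneous of degree
   one in intensity, masks are invariant under global intensity scaling.
4. 26-connected components; keep the largest plus any component whose
   voxels come within d = 5 μm (centre-to-centre, anisotropic EDT) of it —
   drifting fragments still belong to the sample; farther components are
   discarded as debris.
5. Morphological closing (ball, r = 2 voxels, zero-padded) and filling of
   cavities fully enclosed in 3D.  Enclosed voids count as sample volume:
   the conservation signature (Ī falls while ∑I is steady) is only
   arithmetically possible if the space between drifting bundles is part
   of the measured volume.
6. Fewer than `min_voxels` (100) survivors → the record is flagged
   "sample left the imaging volume or signal lost" and omitted.

All parameters and derived values (threshold, floor, components merged,
cavity voxels filled) are recorded in the mask provenance and in the run
record.

## Morphometry

Volume is exact voxel counting: V = N·dx·dy·dz.

Width and height are measured in the principal frame: the eigenvectors of
the second-moment tensor of the mask's voxel coordinates (in μm), ordered
by descending extent (length, width, height), each signed toward its
nearest grid axis.  Near-degenerate eigenvalue blocks (relative gap
< 10⁻⁶) snap to grid axes with preference order y, x, z, making the
axis choice deterministic for cubes and near-isotropic blobs.  Tilt
angles (axis vs nearest grid axis) are reported per time point for QC;
the rotation is re-estimated at every time point because swelling changes
the shape.

Mean height = the occupancy-weighted mean, over occupied (length, width)
bins, of the occupied extent of the height coordinate in the bin, with a
closed-extent convention (max − min + one voxel pitch); mean width is the
same construction over (length, height) bins.  Bin size is the voxel
pitch of the grid axis nearest each principal axis.  Two deliberate
choices here:

- *Per-bin extents, not bounding boxes*: bounding boxes inflate under
  noise and ragged edges; per-bin extents measure the typical thickness.
- *Occupancy weighting*: at small tilts the rotated voxel lattice aliases
  against the bin grid and produces sliver bins holding a handful of
  surface voxels with near-zero extents.  An unweighted bin mean is
  biased low by several percent in that regime; weighting each bin by its
  voxel count (equivalently, averaging column extents over voxels)
  removes the bias and is a no-op for axis-aligned solid slabs, so exact
  cases stay exact.

Intensity features are plain means and sums over the mask per channel;
∑I ≡ Ī·N is asserted on every call.  Cavity voxels are inside the mask
and contribute their (near-zero) recorded signal.

## Trajectories and classification

Records beyond the crop limit (default 50 min, boundary inclusive) or
flagged empty are dropped; fewer than two usable records make the
trajectory undefined.  Percent changes are taken against the first
retained record — in real acquisitions that baseline sits 2–5 min after
drug addition, so any swelling faster than the mounting time is invisible
to the 4D pipeline (that is what the 2D module is for).

Correlations report the time-ordered (x(t), y(t)) path, the least-squares
slope through the origin (both percent-change coordinates are anchored at
0 at baseline) and Pearson's r; a zero-variance x is rejected, a
zero-variance y yields r = NaN.

The mode call uses R = median over post-baseline time points of
∑I_f(t)/∑I_f(t₀) (the baseline's trivial ratio of 1 is excluded) and
W = max Δw%.  Defaults τ_R = 0.15, τ_W = 10 percent points are
calibration choices validated on phantoms: measured ∑I on conserving
phantoms stays within a few percent of flat, destruction phantoms with
τ_d ≤ 30 min fall below 1 − τ_R within two time points, and noise-driven
width excursions of inert phantoms stay well under 10 points.  The epi
retention is reported alongside but does not enter the rule.

## 2D area analysis

Frame classification is the 2D sibling of the volumetric policy
(smoothed Otsu, 8-connected largest component, hole fill) with a polarity
contract: "bright", "dark", or "auto" (the class occupying less of the
frame border is taken as sample).  A seeded mode trains a logistic model
on intensity, smoothed intensity and local-sd features from user
scribbles, as a transparent replacement for GUI-trained pixel
classifiers on textured real images.

The per-side split runs along the first frame's principal (long) axis
through its centroid; "left" is the smaller-x side.  Side ratios compare
each side's area to its own baseline.  Interval maps label each pixel
with the 10 s interval in which it first joined the mask; for
monotonically growing samples they tile final-minus-first exactly, which
is asserted on noiseless phantoms.

## Numerical and degenerate-input conventions

- Single-voxel masks are rejected (no axes); empty masks are errors.
- Otsu uses 256 bins; the threshold lies in the gap between background
  and foreground modes, so scale invariance is exact in practice and is
  tested at c ∈ {0.5, 2, 3.7}.
- Voxel data are stored float32; derived statistics use float64.
- Feature CSVs are written at full repr precision and read back with
  round-trip float parsing, so tables round-trip exactly.

## Known limitations

- The swelling law and void model are stand-ins; the generator's realism
  bounds what validation can claim (see above).
- Mean width/height lack an operational community definition; the
  per-bin-extent definition here is an explicit, documented choice.
- Very low SNR (≲ 2) destruction-mode stacks may produce unusable masks
  before the floor flags them; geometry from such records is unreliable,
  though the mode call (driven by earlier, brighter records) is not.
- The classifier thresholds are phantom-calibrated defaults, not
  universal constants; real studies should inspect the R and W
  statistics, which are always reported next to the label.
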