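# shg4d

Feature extraction and damage-mode classification for 4D (x, y, z, t)
second-harmonic-generation (SHG) microscopy of collagenous thin sections.

## The problem

When a drug solution is applied to a thin section of dura mater — a dense
type-I-collagen network — the tissue may swell, tear open, or lose its
molecular order, over time scales from seconds to an hour.  Time series of
two-channel (forward- and epi-detected) SHG z-stacks capture these dynamics
in full 3D, but turning the stacks into numbers is nontrivial: the section
is tilted in the imaging frame, its overall brightness changes as the drug
acts, and holes torn between fiber bundles must be distinguished from
regions of genuinely lost signal.

`shg4d` implements that analysis as a tested, reusable pipeline:

1. **Segmentation** of the joint tissue volume per time point
   (per-time-point Otsu with a border-derived background floor,
   drifting-fragment merging within a distance *d*, morphological closing,
   and filling of enclosed cavities — holes count as sample volume).
2. **Tilt-corrected morphometry**: volume *V* by voxel counting; mean
   width *w* and mean height *h* as occupancy-weighted per-bin occupied
   extents in the principal frame of the mask's second-moment tensor.
3. **Intensity features**: mean (Ī) and cumulative (∑I) SHG signal per
   channel over the sample volume.
4. **Trajectories**: percent changes against the first retained record,
   cropped to 50 min, with 2D feature correlations (Δw% vs ΔĪ%, Δw% vs
   Δ∑I%, Ī_f vs Ī_epi).
5. **Mode-of-action call** from an intensity-conservation argument.  With
   the cumulative retention R = median_t ∑I(t)/∑I(t₀) and the width gain
   W = max Δw%:

   | R ≥ 1 − τ_R, W < τ_W | R ≥ 1 − τ_R, W ≥ τ_W | R < 1 − τ_R |
   |---|---|---|
   | inert | bundle_drifting | intrinsic_destruction |

   Fiber bundles drifting apart conserve emitting material (Ī falls as
   1/(1+Δw) while ∑I stays flat); degradation of the collagen's molecular
   order reduces both.
6. **2D area swelling** for dynamics too fast for z-stacks: frame-wise
   sample classification at 1 frame s⁻¹, area ratio to the first frame,
   per-side (left/right of the original margin) ratios and 10 s interval
   maps.

Because real acquisitions of this kind are rarely shareable, the package
ships a first-class **phantom generator**: a tilted ~30 μm slab with
fibrous texture whose width swells as w(t) = w₀(1 + A(1 − e^(−t/τ_s)))
while its height stays constant, under three intensity regimes (inert;
signal-conserving dilution with void formation; per-voxel exponential
decay), with two coupled detection channels (epi = β·forward) and
shot/read noise.  Every phantom has a closed-form ground-truth oracle, so
the whole pipeline is validated end to end.

## Worked example

```python
import numpy as np
import shg4d as s

# a swelling, signal-conserving phantom: A = 0.5, tau_s = 6 min
spec = s.PhantomSpec(
    nx=128, ny=96, nz=44, dx=1.0, dy=1.5, dz=1.0,
    w0=60.0, length=120.0, h0=30.0, tilt_y_deg=5.0,
    swell_amplitude=0.5, tau_s_min=6.0, mode="dilution",
    timestamps=tuple(np.linspace(0.0, 50.0, 8)), seed=11,
)
series = s.generate_stack_series(spec)
traj = s.build_trajectory(series)
row = traj.table.iloc[-1]
print(f"dw%  = {row['dw_pct']:+.1f}")
print(f"dI%  = {row['dimean_f_pct']:+.1f}")
print(f"dSI% = {row['disum_f_pct']:+.1f}")
print(s.classify_mode(traj).label)
```

prints

```
dw%  = +49.9
dI%  = -33.3
dSI% = +0.1
bundle_drifting
```

The width has grown ~50 %, the mean SHG signal per volume has dropped by
the conservation value 1 − 1/1.5 ≈ 33 %, the cumulative signal is flat —
the signature of fiber bundles drifting apart rather than collagen
degradation, so the mode call is `bundle_drifting`.

The same pipeline is available from the shell:

```sh
shg4d simulate-4d --mode dilution --amplitude 0.5 --seed 3 --out sim/
shg4d analyze-4d  --manifest sim/stack_manifest.csv --out analysis/
shg4d report      --analysis-dir analysis/
shg4d simulate-2d --seed 4 --out sim2d/
shg4d analyze-2d  --manifest sim2d/frame_manifest.csv --out analysis2d/
```

Each run writes feature CSVs, correlation paths, plots, a mode report and
a `run_record.json` (config + hash + version) for reproducibility.

## Layout

- `src/shg4d/phantom.py` — synthetic 4D/2D phantoms + analytic oracles
- `src/shg4d/stack_io.py` — TIFF stack series, manifests, feature tables
- `src/shg4d/segmentation.py` — joint-tissue-volume masks
- `src/shg4d/geometry.py` — principal axes, V/w/h, Ī/∑I
- `src/shg4d/trajectory.py` — trajectories, correlations, mode calls
- `src/shg4d/area2d.py` — 2D area-swelling analysis
- `src/shg4d/cli.py`, `src/shg4d/plotting.py` — entry points and figures

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
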