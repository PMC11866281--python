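"""Synthetic 4D SHG phantoms with analytic ground truth.

The phantom emulates the geometry and dynamics the downstream analysis
assumes: a thin (~30 μm) collagenous section mounted with its length glued
along y, its width along x and its cut thickness along the optical axis z,
possibly tilted relative to the imaging grid.  Over tens of minutes the
width swells following a saturating exponential while the height stays
constant.  Two detection channels (forward and epi) view the same emission
with a fixed coupling ratio β; shot noise (Poisson at a configurable gain)
and Gaussian read noise are applied last.

Three intensity regimes distinguish the modes of action the analysis must
separate:

``inert``
    expected per-voxel emission is constant in time (control);
``dilution``
    the same total material redistributes into a larger envelope: voids of
    zero emission appear inside the tissue while the *cumulative* expected
    signal over the envelope is conserved exactly (fiber bundles drifting
    apart);
``destruction``
    per-voxel emission decays as exp(−t/τ_d) (loss of molecular order),
    reducing mean and cumulative signal together.

Every spec has a closed-form oracle (:func:`ground_truth`) giving the true
volume, width, height and intensity trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .area2d import FrameSeries2D
from .stack_io import StackSeries, VoxelStack

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "Phantom2DSpec",
    "generate_stack_series",
    "ground_truth",
    "envelope_mask",
    "generate_area_lapse",
]

Mode = Literal["inert", "dilution", "destruction"]


def _rotation_matrix(tilt_x_deg: float, tilt_y_deg: float) -> np.ndarray:
    """Slab-frame -> lab-frame rotation, R = Rx(αx) @ Ry(αy), acting on (x, y, z)."""
    ax, ay = math.radians(tilt_x_deg), math.radians(tilt_y_deg)
    rx = np.array(
        [
            [1, 0, 0],
            [0, math.cos(ax), -math.sin(ax)],
            [0, math.sin(ax), math.cos(ax)],
        ]
    )
    ry = np.array(
        [
            [math.cos(ay), 0, math.sin(ay)],
            [0, 1, 0],
            [-math.sin(ay), 0, math.cos(ay)],
        ]
    )
    return rx @ ry


@dataclass
class PhantomSpec:
    """Generative parameters for a tilted swelling-slab phantom.

    Defaults follow the acquisition geometry of the imaging protocol this
    package targets: 512×512 px covering 450×450 μm, 61 slices at 1 μm
    z-spacing, a ~30 μm thick section, and a ~50 min time series whose first
    stack lands a few minutes after drug addition.
    """

    # grid
    nx: int = 512
    ny: int = 512
    nz: int = 61
    dx: float = 450.0 / 512
    dy: float = 450.0 / 512
    dz: float = 1.0
    # slab geometry (μm)
    w0: float = 150.0
    length: float = 380.0
    h0: float = 30.0
    tilt_x_deg: float = 0.0
    tilt_y_deg: float = 0.0
    # swelling kinetics: w(t) = w0 * (1 + A * (1 - exp(-t / tau_s)))
    swell_amplitude: float = 0.0
    tau_s_min: float = 10.0
    # intensity regime
    mode: Mode = "inert"
    tau_d_min: float = 20.0
    # voids (dilution mode only): expected count = void_rate_per_min * t_last
    void_rate_per_min: float = 1.0
    void_radius_um: tuple[float, float] = (3.0, 6.0)
    # fibrous texture: stripes parallel to the fiber (length) axis
    stripe_period_um: float = 12.0
    stripe_contrast: float = 0.2
    # channels and noise
    base_intensity: float = 100.0
    beta: float = 0.5
    gain: float = 1.0  # shot noise: counts ~ Poisson(E * gain) / gain; 0 disables
    read_noise_sd: float = 2.0
    # time base (minutes since drug addition)
    timestamps: tuple[float, ...] = (3.0, 8.0, 13.0, 19.0, 25.0, 31.0, 38.0, 44.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.timestamps = tuple(float(t) for t in self.timestamps)
        if not self.timestamps or np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be nonempty and strictly increasing")
        if self.swell_amplitude < 0:
            raise ValueError("swelling amplitude must be >= 0")
        if self.tau_s_min <= 0 or self.tau_d_min <= 0:
            raise ValueError("time constants must be positive")
        if self.beta <= 0:
            raise ValueError("channel ratio beta must be positive")
        if min(self.w0, self.length, self.h0) <= 0:
            raise ValueError("slab dimensions must be positive")
        if self.stripe_contrast < 0 or self.stripe_contrast >= 1:
            raise ValueError("stripe contrast must be in [0, 1)")

    # -- geometry ---------------------------------------------------------
    def width_at(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.w0 * (1.0 + self.swell_amplitude * (1.0 - np.exp(-t / self.tau_s_min)))

    @property
    def rotation(self) -> np.ndarray:
        return _rotation_matrix(self.tilt_x_deg, self.tilt_y_deg)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)

    @property
    def grid_half_extent(self) -> np.ndarray:
        return 0.5 * np.array([self.nx * self.dx, self.ny * self.dy, self.nz * self.dz])

    def check_containment(self) -> None:
        """Raise if the tilted slab leaves the grid at any timestamp."""
        r = self.rotation
        half = self.grid_half_extent
        for t in self.timestamps:
            w = float(self.width_at(t))
            corners = np.array(
                [
                    [sx * w / 2, sy * self.length / 2, sz * self.h0 / 2]
                    for sx in (-1, 1)
                    for sy in (-1, 1)
                    for sz in (-1, 1)
                ]
            )
            lab = corners @ r.T
            if np.any(np.abs(lab) > half[None, :]):
                raise ValueError(
                    f"slab exceeds the imaging grid after tilt/swelling at "
                    f"t = {t:g} min (width {w:.1f} μm); enlarge the grid or "
                    "reduce tilt/amplitude"
                )


def _lab_coordinates(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre coordinates (μm, grid-centred), broadcastable to (nz, ny, nx)."""
    x = (np.arange(spec.nx) + 0.5) * spec.dx - spec.nx * spec.dx / 2
    y = (np.arange(spec.ny) + 0.5) * spec.dy - spec.ny * spec.dy / 2
    z = (np.arange(spec.nz) + 0.5) * spec.dz - spec.nz * spec.dz / 2
    return (
        x[None, None, :],
        y[None, :, None],
        z[:, None, None],
    )


def _slab_coordinates(spec: PhantomSpec):
    """Slab-frame coordinates q = R^T p for every voxel centre."""
    px, py, pz = _lab_coordinates(spec)
    r = spec.rotation
    qx = r[0, 0] * px + r[1, 0] * py + r[2, 0] * pz
    qy = r[0, 1] * px + r[1, 1] * py + r[2, 1] * pz
    qz = r[0, 2] * px + r[1, 2] * py + r[2, 2] * pz
    return qx, qy, qz


def envelope_mask(spec: PhantomSpec, t: float) -> np.ndarray:
    """True tissue-envelope mask (voids included) at time ``t`` minutes."""
    qx, qy, qz = _slab_coordinates(spec)
    w = float(spec.width_at(t))
    return (
        (np.abs(qx) <= w / 2)
        & (np.abs(qy) <= spec.length / 2)
        & (np.abs(qz) <= spec.h0 / 2)
    )


@dataclass
class _Void:
    center_frac: tuple[float, float, float]  # fractions of (w, length, h0)
    radius_um: float
    t_appear_min: float


def _sample_voids(spec: PhantomSpec, rng: np.random.Generator) -> list[_Void]:
    """Voids fully enclosed in the baseline envelope; positions are material
    coordinates, so they ride along (and stretch) with the swelling width."""
    if spec.mode != "dilution" or spec.void_rate_per_min <= 0:
        return []
    t_last = spec.timestamps[-1]
    n = int(rng.poisson(spec.void_rate_per_min * t_last))
    r_lo, r_hi = spec.void_radius_um
    voids = []
    margin = 2.0 * max(spec.dx, spec.dy, spec.dz)
    for _ in range(n):
        r = float(rng.uniform(r_lo, r_hi))
        # cap the radius so enclosure in the thin height direction is possible
        r = min(r, spec.h0 / 2 - margin - 1e-6) if spec.h0 / 2 > margin else 0.0
        if r <= 0:
            continue
        lim = [
            max(0.0, 0.5 - (r + margin) / spec.w0),
            max(0.0, 0.5 - (r + margin) / spec.length),
            max(0.0, 0.5 - (r + margin) / spec.h0),
        ]
        c = tuple(float(rng.uniform(-l, l)) for l in lim)
        voids.append(_Void(c, r, float(rng.uniform(0.0, t_last))))
    return voids


def _expected_forward(
    spec: PhantomSpec, t: float, voids: Sequence[_Void]
) -> tuple[np.ndarray, np.ndarray]:
    """Expected forward-channel field and the envelope mask at time ``t``."""
    qx, qy, qz = _slab_coordinates(spec)
    w = float(spec.width_at(t))
    env = (
        (np.abs(qx) <= w / 2)
        & (np.abs(qy) <= spec.length / 2)
        & (np.abs(qz) <= spec.h0 / 2)
    )
    texture = 1.0 + spec.stripe_contrast * np.cos(2 * np.pi * qx / spec.stripe_period_um)
    e = np.where(env, spec.base_intensity * texture, 0.0)

    if spec.mode == "destruction":
        e *= math.exp(-t / spec.tau_d_min)
    elif spec.mode == "dilution":
        stretch = w / spec.w0  # material stretched along width
        emit = env.copy()
        for v in voids:
            if t < v.t_appear_min:
                continue
            cx, cy, cz = v.center_frac
            d2 = (
                ((qx - cx * w) / stretch) ** 2
                + (qy - cy * spec.length) ** 2
                + (qz - cz * spec.h0) ** 2
            )
            emit &= d2 > v.radius_um**2
        e = np.where(emit, e, 0.0)
        # signal-conserving dilution: the material total is invariant, so the
        # envelope sum is pinned to the intact baseline total
        s_ref = _intact_sum(spec)
        s_now = float(e.sum())
        if s_now <= 0:
            raise ValueError(f"dilution phantom lost all emitting voxels at t = {t:g} min")
        e *= s_ref / s_now
    return e, env


def _intact_sum(spec: PhantomSpec) -> float:
    """Envelope sum of the intact (void-free) field at the first timestamp."""
    qx, qy, qz = _slab_coordinates(spec)
    w = float(spec.width_at(spec.timestamps[0]))
    env = (
        (np.abs(qx) <= w / 2)
        & (np.abs(qy) <= spec.length / 2)
        & (np.abs(qz) <= spec.h0 / 2)
    )
    texture = 1.0 + spec.stripe_contrast * np.cos(2 * np.pi * qx / spec.stripe_period_um)
    return float((spec.base_intensity * texture)[env].sum())


def generate_stack_series(spec: PhantomSpec) -> StackSeries:
    """Render the phantom as a two-channel :class:`StackSeries`.

    Noise is applied last (independently per channel); the whole series is a
    pure function of the spec, so identical specs give bit-identical output.
    """
    spec.check_containment()
    ss = np.random.SeedSequence(spec.seed)
    void_rng = np.random.default_rng(ss.spawn(1)[0])
    voids = _sample_voids(spec, void_rng)
    noise_seeds = ss.spawn(len(spec.timestamps))

    stacks = []
    for t, child in zip(spec.timestamps, noise_seeds):
        e_f, _ = _expected_forward(spec, t, voids)
        e_epi = spec.beta * e_f
        rng = np.random.default_rng(child)
        channels = []
        for e in (e_f, e_epi):
            obs = e
            if spec.gain > 0:
                obs = rng.poisson(e * spec.gain).astype(np.float64) / spec.gain
            if spec.read_noise_sd > 0:
                obs = obs + rng.normal(0.0, spec.read_noise_sd, size=e.shape)
            channels.append(np.clip(obs, 0.0, None).astype(np.float32))
        stacks.append(
            VoxelStack(
                forward=channels[0],
                epi=channels[1],
                spacing=spec.spacing,
                timestamp_min=t,
            )
        )
    return StackSeries(stacks=stacks, metadata={"phantom_mode": spec.mode, "seed": spec.seed})


@dataclass
class GroundTruth:
    """Closed-form feature trajectories of a phantom spec.

    Intensity sums are in voxel-sum units (sum of voxel values), i.e.
    ``Isum* = Imean* × V* / voxel volume``, matching what the measurement
    pipeline reports.  Texture ripple is ignored (its envelope mean is ~1).
    """

    timestamps: np.ndarray
    volume_um3: np.ndarray
    width_um: np.ndarray
    height_um: np.ndarray
    imean_f: np.ndarray
    isum_f: np.ndarray
    imean_epi: np.ndarray
    isum_epi: np.ndarray
    mode: str

    def pct_change(self, name: str) -> np.ndarray:
        """Percent change of a field relative to the first timestamp."""
        x = getattr(self, name)
        return 100.0 * (x - x[0]) / x[0]


def ground_truth(spec: PhantomSpec) -> GroundTruth:
    t = np.asarray(spec.timestamps, dtype=float)
    w = spec.width_at(t)
    v = w * spec.length * spec.h0
    vv = spec.dx * spec.dy * spec.dz
    i0 = spec.base_intensity
    if spec.mode == "dilution":
        isum = np.full_like(t, i0 * v[0] / vv)
    elif spec.mode == "destruction":
        isum = i0 * v / vv * np.exp(-t / spec.tau_d_min)
    else:
        isum = i0 * v / vv
    imean = isum * vv / v
    return GroundTruth(
        timestamps=t,
        volume_um3=v,
        width_um=w,
        height_um=np.full_like(t, spec.h0),
        imean_f=imean,
        isum_f=isum,
        imean_epi=spec.beta * imean,
        isum_epi=spec.beta * isum,
        mode=spec.mode,
    )


def random_mode_spec(mode: Mode, seed: int, **overrides) -> PhantomSpec:
    """Randomised phantom spec for mode-recovery validation.

    Draws swelling amplitude A ∈ [0.2, 0.8], swelling time constant
    τ_s ∈ [5, 20] min, destruction decay τ_d ∈ [10, 30] min, baseline SNR
    ∈ [5, 10] (via the shot-noise gain) and a modest tilt, on a compact grid
    sized so the slab stays contained at every draw.  Inert (control)
    phantoms do not swell.  The returned spec is deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    swell = 0.0 if mode == "inert" else float(rng.uniform(0.2, 0.8))
    snr = float(rng.uniform(5.0, 10.0))
    params = dict(
        nx=96, ny=72, nz=48, dx=1.5, dy=2.0, dz=1.0,
        w0=50.0, length=120.0, h0=26.0,
        tilt_x_deg=float(rng.uniform(0.0, 3.0)),
        tilt_y_deg=float(rng.uniform(0.0, 8.0)),
        swell_amplitude=swell,
        tau_s_min=float(rng.uniform(5.0, 20.0)),
        mode=mode,
        tau_d_min=float(rng.uniform(10.0, 30.0)),
        stripe_period_um=float(rng.uniform(8.0, 16.0)),
        base_intensity=100.0,
        gain=snr**2 / 100.0,  # SNR = sqrt(base_intensity * gain) at baseline
        read_noise_sd=2.0,
        timestamps=(3.0, 12.0, 21.0, 31.0, 40.0, 50.0),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    params.update(overrides)
    return PhantomSpec(**params)


# ---------------------------------------------------------------------------
# 2D area-swelling phantom (light-microscopy time lapse at 1 frame/s)
# ---------------------------------------------------------------------------


@dataclass
class Phantom2DSpec:
    """A bright strip on a dark background whose width expands laterally.

    The two sides of the original margin may expand by different asymptotic
    factors (``growth_left``/``growth_right``), modelling laterally
    inhomogeneous swelling; both follow a saturating exponential with time
    constant ``tau_a_s`` seconds.
    """

    nx: int = 320
    ny: int = 240
    pixel_size_um: float = 2.0
    halfwidth0_um: float = 80.0  # per-side baseline half-width
    halfheight_um: float = 150.0
    growth_left: float = 2.0
    growth_right: float = 2.0
    tau_a_s: float = 10.0
    duration_s: float = 40.0
    frame_interval_s: float = 1.0
    fg_intensity: float = 150.0
    bg_intensity: float = 20.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.growth_left < 1 or self.growth_right < 1:
            raise ValueError("growth factors must be >= 1 (no shrinking strips)")
        if self.tau_a_s <= 0 or self.frame_interval_s <= 0:
            raise ValueError("time constants must be positive")

    @classmethod
    def doubling(cls, t_double_s: float = 30.0, tau_a_s: float = 10.0, **kw) -> "Phantom2DSpec":
        """Spec whose true area exactly doubles at ``t_double_s`` seconds."""
        g = 1.0 + 1.0 / (1.0 - math.exp(-t_double_s / tau_a_s))
        return cls(growth_left=g, growth_right=g, tau_a_s=tau_a_s, **kw)

    @property
    def frame_times(self) -> np.ndarray:
        n = int(math.floor(self.duration_s / self.frame_interval_s)) + 1
        return np.arange(n) * self.frame_interval_s

    def side_halfwidth(self, t: float | np.ndarray, side: str) -> np.ndarray:
        g = self.growth_left if side == "left" else self.growth_right
        t = np.asarray(t, dtype=float)
        return self.halfwidth0_um * (1.0 + (g - 1.0) * (1.0 - np.exp(-t / self.tau_a_s)))

    def true_area_um2(self, t: float | np.ndarray) -> np.ndarray:
        return (self.side_halfwidth(t, "left") + self.side_halfwidth(t, "right")) * (
            2 * self.halfheight_um
        )

    def true_mask(self, t: float) -> np.ndarray:
        """Pixelated truth mask at time ``t`` (rows = y, cols = x)."""
        x = (np.arange(self.nx) + 0.5) * self.pixel_size_um - self.nx * self.pixel_size_um / 2
        y = (np.arange(self.ny) + 0.5) * self.pixel_size_um - self.ny * self.pixel_size_um / 2
        wl = float(self.side_halfwidth(t, "left"))
        wr = float(self.side_halfwidth(t, "right"))
        in_x = (x[None, :] >= -wl) & (x[None, :] <= wr)
        in_y = np.abs(y[:, None]) <= self.halfheight_um
        return in_x & in_y

    def check_containment(self) -> None:
        half_x = self.nx * self.pixel_size_um / 2
        for t in self.frame_times:
            wl = float(self.side_halfwidth(t, "left"))
            wr = float(self.side_halfwidth(t, "right"))
            if wl > half_x or wr > half_x or self.halfheight_um > self.ny * self.pixel_size_um / 2:
                raise ValueError(
                    f"strip leaves the frame at t = {t:g} s "
                    f"(half-widths {wl:.0f}/{wr:.0f} μm)"
                )


def generate_area_lapse(spec: Phantom2DSpec) -> FrameSeries2D:
    """Render the 2D swelling phantom as a :class:`FrameSeries2D`."""
    spec.check_containment()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for t in spec.frame_times:
        mask = spec.true_mask(float(t))
        img = np.where(mask, spec.fg_intensity, spec.bg_intensity).astype(np.float64)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames.append(np.clip(img, 0.0, None).astype(np.float32))
    return FrameSeries2D(
        frames=frames,
        timestamps_s=spec.frame_times.tolist(),
        pixel_size_um=spec.pixel_size_um,
    )
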