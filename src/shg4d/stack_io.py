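"""Reading and writing of two-channel z-stack time series and feature tables.

On-disk conventions
-------------------
Each time point is stored as one multi-page TIFF per detection channel
(pages = z-slices, rows = y, columns = x), referenced by a plain-text
manifest (CSV or JSON) carrying acquisition timestamps (minutes since drug
addition) and voxel spacings in micrometres.  Timestamps live in the
manifest, never in microscope metadata; the reader sorts by timestamp, so
manifest row order is irrelevant.

Feature tables are tidy CSV (one row per timestamp/feature/channel) with a
``# key: value`` metadata header recording provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelStack",
    "StackSeries",
    "read_series",
    "write_series",
    "write_features",
    "read_features",
]


@dataclass
class VoxelStack:
    """One time point of a two-channel 3D SHG acquisition.

    Arrays are indexed ``(z, y, x)``; ``spacing`` is ``(dx, dy, dz)`` in
    micrometres; ``timestamp_min`` is minutes since drug addition (t = 0 at
    addition).
    """

    forward: np.ndarray
    epi: np.ndarray
    spacing: tuple[float, float, float]
    timestamp_min: float

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward)
        self.epi = np.asarray(self.epi)
        if self.forward.ndim != 3:
            raise ValueError("channel arrays must be 3D (z, y, x)")
        if self.forward.shape != self.epi.shape:
            raise ValueError(
                f"channel shape mismatch: forward {self.forward.shape} "
                f"vs epi {self.epi.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if self.forward.size and (
            float(self.forward.min()) < 0 or float(self.epi.min()) < 0
        ):
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.forward.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class StackSeries:
    """Time-ordered sequence of :class:`VoxelStack` sharing one geometry."""

    stacks: list[VoxelStack]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stacks:
            raise ValueError("StackSeries requires at least one stack")
        t = self.timestamps
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"timestamps must be strictly increasing, got {list(t)}")
        shapes = {s.shape for s in self.stacks}
        if len(shapes) > 1:
            raise ValueError(
                "all stacks in a series must share one grid shape; found "
                + ", ".join(map(str, sorted(shapes)))
            )
        spacings = {s.spacing for s in self.stacks}
        if len(spacings) > 1:
            raise ValueError(
                "all stacks in a series must share one voxel spacing; found "
                + ", ".join(map(str, sorted(spacings)))
            )

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([s.timestamp_min for s in self.stacks], dtype=float)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.stacks[0].spacing

    def __len__(self) -> int:
        return len(self.stacks)

    def __iter__(self) -> Iterator[VoxelStack]:
        return iter(self.stacks)

    def __getitem__(self, i: int) -> VoxelStack:
        return self.stacks[i]


_MANIFEST_COLUMNS = ["path_f", "path_epi", "timestamp_min", "dx_um", "dy_um", "dz_um"]


def write_series(series: StackSeries, outdir: str | Path, prefix: str = "stack") -> Path:
    """Write a series as per-channel multi-page TIFFs plus a CSV manifest.

    Returns the manifest path.  Voxel dtype is preserved (integer stacks
    round-trip bit-exactly).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, stack in enumerate(series):
        dx, dy, dz = stack.spacing
        pf = outdir / f"{prefix}_t{i:03d}_f.tif"
        pe = outdir / f"{prefix}_t{i:03d}_epi.tif"
        tifffile.imwrite(pf, stack.forward)
        tifffile.imwrite(pe, stack.epi)
        rows.append(
            {
                "path_f": pf.name,
                "path_epi": pe.name,
                "timestamp_min": stack.timestamp_min,
                "dx_um": dx,
                "dy_um": dy,
                "dz_um": dz,
            }
        )
    manifest = outdir / f"{prefix}_manifest.csv"
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def _load_manifest(manifest_path: Path) -> pd.DataFrame:
    if manifest_path.suffix.lower() == ".json":
        with open(manifest_path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(manifest_path)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {manifest_path} lacks columns {missing}")
    return df


def read_series(manifest_path: str | Path) -> StackSeries:
    """Read a stack series from a manifest (CSV or JSON).

    Rows are sorted by ``timestamp_min``; TIFF paths are resolved relative to
    the manifest.  A shape or spacing mismatch across time points is a hard
    failure naming the offending files — one geometry per series.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = _load_manifest(manifest_path).sort_values("timestamp_min")
    base = manifest_path.parent

    stacks: list[VoxelStack] = []
    shapes: dict[tuple, list[str]] = {}
    for row in df.itertuples(index=False):
        pf, pe = base / str(row.path_f), base / str(row.path_epi)
        for p in (pf, pe):
            if not p.exists():
                raise FileNotFoundError(f"stack file referenced by manifest missing: {p}")
        fwd = tifffile.imread(pf)
        epi = tifffile.imread(pe)
        shapes.setdefault(fwd.shape, []).append(str(row.path_f))
        stacks.append(
            VoxelStack(
                forward=fwd,
                epi=epi,
                spacing=(float(row.dx_um), float(row.dy_um), float(row.dz_um)),
                timestamp_min=float(row.timestamp_min),
            )
        )
    if len(shapes) > 1:
        detail = "; ".join(f"{shape}: {names}" for shape, names in shapes.items())
        raise ValueError(
            f"stacks in series differ in grid shape ({detail}); "
            "the pipeline requires one geometry per series"
        )
    return StackSeries(stacks=stacks, metadata={"manifest": str(manifest_path)})


def write_features(
    trajectory: "pd.DataFrame | object",
    path: str | Path,
    metadata: dict | None = None,
) -> Path:
    """Write a feature trajectory as a tidy CSV with a metadata header.

    Accepts either a :class:`~shg4d.trajectory.FeatureTrajectory` (its tidy
    form is used) or a tidy DataFrame with columns
    ``timestamp_min, feature, channel, value``.
    """
    tidy = trajectory.to_tidy() if hasattr(trajectory, "to_tidy") else trajectory
    if not isinstance(tidy, pd.DataFrame):
        raise TypeError("expected FeatureTrajectory or tidy DataFrame")
    if tidy.empty:
        raise ValueError("refusing to write an empty feature trajectory")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = dict(metadata or {})
    meta.setdefault("format", "shg4d-features-v1")
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        tidy.to_csv(fh, index=False)
    return path


def read_features(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a feature table written by :func:`write_features`.

    Returns ``(tidy DataFrame, metadata dict)``; values round-trip exactly
    (full ``repr`` precision is written).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    if "channel" in df.columns:
        df["channel"] = df["channel"].fillna("")
    return df, meta
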