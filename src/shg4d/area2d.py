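"""Frame-wise area swelling analysis of 2D light-microscopy time lapses.

Very fast swelling (seconds) outruns a volumetric time series, whose stacks
take minutes each; a plain camera at 1 frame s⁻¹ captures it instead.  Each
frame is classified into sample/background, the classified area is tracked
as a ratio to the first frame, and lateral inhomogeneity is quantified by
splitting the growth left/right of the original sample margin.

The pixel classifier is the 2D sibling of the volumetric segmentation
policy (smoothed Otsu + largest component + hole fill); a seeded mode
trains a transparent logistic model on intensity and local-variance
features from user scribbles for textured real images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "FrameSeries2D",
    "Area2DParams",
    "AreaTrajectory",
    "PixelClassifier",
    "classify_frame",
    "area_trajectory",
    "interval_maps",
    "write_frames",
    "read_frames",
]


@dataclass
class FrameSeries2D:
    """Ordered 2D frames (rows = y, cols = x) with timestamps in seconds."""

    frames: list[np.ndarray]
    timestamps_s: list[float]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("FrameSeries2D requires at least one frame")
        if len(self.frames) != len(self.timestamps_s):
            raise ValueError("one timestamp per frame required")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames must share one shape, found {sorted(shapes)}")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class Area2DParams:
    smoothing_sigma_px: float = 1.0
    polarity: str = "auto"  # "bright" | "dark" | "auto"
    min_pixels: int = 64
    fill_holes: bool = True
    max_flagged_fraction: float = 0.2


class FlaggedFrameError(RuntimeError):
    """A frame produced no usable sample mask."""


def _postprocess(raw: np.ndarray, params: Area2DParams) -> np.ndarray:
    labels, n = ndimage.label(raw, structure=np.ones((3, 3), dtype=bool))  # 8-connectivity
    if n == 0:
        raise FlaggedFrameError("no sample pixels found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    if params.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if int(mask.sum()) < params.min_pixels:
        raise FlaggedFrameError("sample mask below minimum size")
    return mask


def _border_fraction(mask: np.ndarray) -> float:
    border = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    return float(border.mean())


def classify_frame(frame: np.ndarray, params: Area2DParams | None = None) -> np.ndarray:
    """Sample/background classification of one frame.

    Polarity "bright" takes the above-Otsu class as sample, "dark" the
    below-Otsu class, and "auto" the class occupying less of the frame
    border (background normally touches the border).  Inverting a frame's
    contrast and flipping the polarity flag yields the same mask.
    """
    params = params or Area2DParams()
    img = np.asarray(frame, dtype=np.float64)
    if float(img.max()) == float(img.min()):
        raise ValueError("constant frame; nothing to classify")
    smoothed = ndimage.gaussian_filter(img, sigma=params.smoothing_sigma_px)
    thr = float(threshold_otsu(smoothed))
    bright = smoothed > thr
    if params.polarity == "bright":
        raw = bright
    elif params.polarity == "dark":
        raw = ~bright
    elif params.polarity == "auto":
        raw = bright if _border_fraction(bright) <= _border_fraction(~bright) else ~bright
    else:
        raise ValueError(f"unknown polarity {params.polarity!r}")
    return _postprocess(raw, params)


class PixelClassifier:
    """Seeded per-pixel classifier for textured images (scribble-trained).

    Features per pixel: raw intensity, Gaussian-smoothed intensity and local
    standard deviation.  A logistic model keeps the decision transparent and
    reproducible.
    """

    def __init__(self, sigma_px: float = 2.0):
        from sklearn.linear_model import LogisticRegression

        self.sigma_px = sigma_px
        self._model = LogisticRegression(max_iter=1000)

    def _features(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=np.float64)
        smooth = ndimage.gaussian_filter(img, self.sigma_px)
        var = ndimage.gaussian_filter(img**2, self.sigma_px) - smooth**2
        local_sd = np.sqrt(np.clip(var, 0, None))
        return np.stack([img.ravel(), smooth.ravel(), local_sd.ravel()], axis=1)

    def fit(self, frames: Sequence[np.ndarray], fg_scribbles, bg_scribbles) -> "PixelClassifier":
        xs, ys = [], []
        for img, fg, bg in zip(frames, fg_scribbles, bg_scribbles):
            feats = self._features(img)
            fg = np.asarray(fg, dtype=bool).ravel()
            bg = np.asarray(bg, dtype=bool).ravel()
            xs.append(feats[fg])
            ys.append(np.ones(int(fg.sum())))
            xs.append(feats[bg])
            ys.append(np.zeros(int(bg.sum())))
        self._model.fit(np.concatenate(xs), np.concatenate(ys))
        return self

    def classify(self, frame: np.ndarray, params: Area2DParams | None = None) -> np.ndarray:
        params = params or Area2DParams()
        raw = self._model.predict(self._features(frame)).reshape(frame.shape).astype(bool)
        return _postprocess(raw, params)


@dataclass
class AreaTrajectory:
    """Per-frame classified areas, ratios to the first frame and per-side
    (left/right of the original margin) ratios."""

    table: pd.DataFrame  # t_s, area_um2, ratio, area_left_um2, area_right_um2, ratio_left, ratio_right
    masks: list[np.ndarray | None]
    margin_mask: np.ndarray  # outline of the first-frame mask
    split_axis: np.ndarray  # unit vector (x, y) of the width (split) direction
    split_origin: np.ndarray  # centroid (x, y) of the first-frame mask, px
    flagged: list[int] = field(default_factory=list)


def _first_mask_frame_geometry(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and width-axis unit vector (both in (x, y) pixel coords) of
    the first-frame mask: the split runs along the mask's principal (long)
    axis, so sides lie along the perpendicular width axis."""
    idx = np.argwhere(mask)  # (y, x)
    coords = idx[:, ::-1].astype(float)  # (x, y)
    centroid = coords.mean(axis=0)
    c = coords - centroid
    cov = (c.T @ c) / c.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    width_axis = eigvecs[:, 0]  # smaller-extent direction
    if width_axis[0] < 0 or (width_axis[0] == 0 and width_axis[1] < 0):
        width_axis = -width_axis  # sign toward +x so "left" means smaller x
    return centroid, width_axis


def _side_areas(mask: np.ndarray, origin: np.ndarray, axis: np.ndarray, px_area: float):
    idx = np.argwhere(mask)
    coords = idx[:, ::-1].astype(float) - origin
    proj = coords @ axis
    left = int((proj < 0).sum())
    right = int((proj >= 0).sum())
    return left * px_area, right * px_area


def area_trajectory(
    frames: FrameSeries2D,
    params: Area2DParams | None = None,
    classifier: PixelClassifier | None = None,
) -> AreaTrajectory:
    """Classify every frame and assemble the area trajectory.

    Flagged frames (no usable mask) are dropped from the table; more than
    ``max_flagged_fraction`` of them is a failure.  The first frame must be
    classifiable — it defines the original margin and the per-side split.
    """
    params = params or Area2DParams()
    if len(frames) < 2:
        raise ValueError("area trajectory requires >= 2 frames")
    px_area = frames.pixel_size_um**2
    masks: list[np.ndarray | None] = []
    flagged: list[int] = []
    for i, frame in enumerate(frames.frames):
        try:
            mask = (
                classifier.classify(frame, params)
                if classifier is not None
                else classify_frame(frame, params)
            )
        except FlaggedFrameError:
            mask = None
            flagged.append(i)
        masks.append(mask)
    if len(flagged) > params.max_flagged_fraction * len(frames):
        raise RuntimeError(
            f"{len(flagged)}/{len(frames)} frames flagged "
            f"(> {params.max_flagged_fraction:.0%}); classification failed"
        )
    if masks[0] is None:
        raise RuntimeError("first frame unclassifiable; margin undefined")

    origin, width_axis = _first_mask_frame_geometry(masks[0])
    eroded = ndimage.binary_erosion(masks[0])
    margin = masks[0] & ~eroded

    rows = []
    base_area = base_left = base_right = None
    for i, (t, mask) in enumerate(zip(frames.timestamps_s, masks)):
        if mask is None:
            continue
        area = float(mask.sum()) * px_area
        left, right = _side_areas(mask, origin, width_axis, px_area)
        if base_area is None:
            base_area, base_left, base_right = area, left, right
        rows.append(
            {
                "t_s": t,
                "area_um2": area,
                "ratio": area / base_area,
                "area_left_um2": left,
                "area_right_um2": right,
                "ratio_left": left / base_left if base_left else float("nan"),
                "ratio_right": right / base_right if base_right else float("nan"),
            }
        )
    return AreaTrajectory(
        table=pd.DataFrame(rows),
        masks=masks,
        margin_mask=margin,
        split_axis=width_axis,
        split_origin=origin,
        flagged=flagged,
    )


def interval_maps(traj: AreaTrajectory, frames: FrameSeries2D, interval_s: float = 10.0):
    """Newly covered area per time interval (default 10 s).

    Returns ``(label_image, intervals)``: pixels get the 1-based index of
    the interval in which they first joined the mask (0 = covered at start
    or never).  For monotonically growing samples the interval maps tile
    final-minus-first exactly.
    """
    t = np.asarray(frames.timestamps_s, dtype=float)
    picks = []
    for k, target in enumerate(np.arange(t[0], t[-1] + 1e-9, interval_s)):
        i = int(np.argmin(np.abs(t - target)))
        if traj.masks[i] is None or (picks and i <= picks[-1]):
            continue
        picks.append(i)
    if len(picks) < 2:
        raise ValueError("need at least two classifiable frames an interval apart")
    label = np.zeros(frames.frames[0].shape, dtype=np.int32)
    intervals = []
    covered = traj.masks[picks[0]].copy()
    for k in range(1, len(picks)):
        new = traj.masks[picks[k]] & ~covered
        label[new] = k
        covered |= traj.masks[picks[k]]
        intervals.append((float(t[picks[k - 1]]), float(t[picks[k]])))
    return label, intervals


# ---------------------------------------------------------------------------
# frame IO
# ---------------------------------------------------------------------------

_MANIFEST2D_COLUMNS = ["path", "timestamp_s", "pixel_size_um"]


def write_frames(series: FrameSeries2D, outdir: str | Path, prefix: str = "frame") -> Path:
    """Write frames as numbered TIFFs plus a CSV manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (frame, t) in enumerate(zip(series.frames, series.timestamps_s)):
        p = outdir / f"{prefix}_{i:04d}.tif"
        tifffile.imwrite(p, frame)
        rows.append({"path": p.name, "timestamp_s": t, "pixel_size_um": series.pixel_size_um})
    manifest = outdir / f"{prefix}_manifest.csv"
    pd.DataFrame(rows, columns=_MANIFEST2D_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_frames(manifest_path: str | Path) -> FrameSeries2D:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path).sort_values("timestamp_s")
    missing = [c for c in _MANIFEST2D_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {manifest_path} lacks columns {missing}")
    px = df["pixel_size_um"].unique()
    if len(px) != 1:
        raise ValueError(f"frames disagree on pixel size: {px}")
    frames = [tifffile.imread(manifest_path.parent / p) for p in df["path"]]
    return FrameSeries2D(
        frames=frames,
        timestamps_s=[float(t) for t in df["timestamp_s"]],
        pixel_size_um=float(px[0]),
    )
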