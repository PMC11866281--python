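"""Feature trajectories, 2D feature correlations and damage-mode calls.

The per-time-point features (V, w, h, Ī, ∑I) only become interpretable as
baseline-normalised percent changes: the first retained record (in real
acquisitions 2–5 min after drug addition) anchors every trajectory at 0 and
series are cropped to 50 min for cross-sample consistency.

The mode-of-action call rests on an intensity-conservation argument.  If
swelling comes from fiber bundles drifting apart, emitting material is
conserved: the mean signal per volume Ī drops as 1/(1+Δw) while the
cumulative signal ∑I over the (cavity-filled) sample volume stays flat.  If
instead the collagen's molecular order degrades, Ī and ∑I fall together.
Two statistics formalise this: the cumulative retention R (median of
∑I(t)/∑I(t₀) after baseline) and the width gain W (max Δw%):

    R < 1 − τ_R                  → intrinsic_destruction
    R ≥ 1 − τ_R and W ≥ τ_W      → bundle_drifting
    R ≥ 1 − τ_R and W < τ_W      → inert
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import GeometryFeatures, IntensityFeatures, measure_geometry, measure_intensity
from .segmentation import EmptyMaskError, SegmentationParams, TissueMask, mask_overlap, segment_tissue
from .stack_io import StackSeries

__all__ = [
    "FeatureRecord",
    "FeatureTrajectory",
    "CorrelationResult",
    "ModeOfActionResult",
    "build_trajectory",
    "correlate",
    "classify_mode",
]

DEFAULT_CROP_MIN = 50.0

#: wide-table columns holding raw features (percent-change columns add a d…_pct twin)
_PCT_FEATURES = {
    "V_um3": "dV_pct",
    "w_um": "dw_pct",
    "h_um": "dh_pct",
    "imean_f": "dimean_f_pct",
    "imean_epi": "dimean_epi_pct",
    "isum_f": "disum_f_pct",
    "isum_epi": "disum_epi_pct",
}


@dataclass
class FeatureRecord:
    timestamp_min: float
    geometry: Optional[GeometryFeatures] = None
    intensity: Optional[IntensityFeatures] = None
    overlap_prev: float = float("nan")
    flagged: bool = False
    reason: Optional[str] = None


@dataclass
class FeatureTrajectory:
    """Baseline-normalised, cropped feature table.

    ``table`` is wide (one row per retained time point); percent changes are
    100·(x(t) − x(t₀))/x(t₀) against the first retained record.
    ``records`` keeps every time point, including flagged/cropped ones with
    their reasons.
    """

    records: list[FeatureRecord]
    table: pd.DataFrame
    crop_min: float
    provenance: dict = field(default_factory=dict)

    @property
    def baseline_t(self) -> float:
        return float(self.table["t_min"].iloc[0])

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for _, r in self.table.iterrows():
            for col in self.table.columns:
                if col == "t_min":
                    continue
                channel = ""
                if col.endswith("_f") or "_f_" in col:
                    channel = "f"
                elif col.endswith("_epi") or "_epi_" in col:
                    channel = "epi"
                rows.append(
                    {
                        "timestamp_min": r["t_min"],
                        "feature": col,
                        "channel": channel,
                        "value": r[col],
                    }
                )
        return pd.DataFrame(rows, columns=["timestamp_min", "feature", "channel", "value"])


def build_trajectory(
    series: StackSeries,
    seg_params: SegmentationParams | None = None,
    crop_min: float = DEFAULT_CROP_MIN,
) -> FeatureTrajectory:
    """Segment and measure every time point, then assemble the trajectory.

    Records later than ``crop_min`` (exclusive: a record at exactly the crop
    limit is retained) or with an empty segmentation are dropped from the
    table but kept in ``records`` with a reason.  Fewer than two usable
    records make a trajectory undefined.
    """
    seg_params = seg_params or SegmentationParams()
    records: list[FeatureRecord] = []
    prev_mask: TissueMask | None = None
    for stack in series:
        t = stack.timestamp_min
        if t > crop_min:
            records.append(FeatureRecord(t, flagged=True, reason=f"beyond crop limit {crop_min} min"))
            continue
        try:
            mask = segment_tissue(stack, seg_params)
        except EmptyMaskError as exc:
            records.append(FeatureRecord(t, flagged=True, reason=str(exc)))
            prev_mask = None
            continue
        geom = measure_geometry(mask)
        inten = measure_intensity(stack, mask)
        overlap = mask_overlap(prev_mask, mask) if prev_mask is not None else float("nan")
        records.append(FeatureRecord(t, geom, inten, overlap))
        prev_mask = mask

    usable = [r for r in records if not r.flagged]
    if len(usable) < 2:
        raise ValueError(
            f"trajectory undefined: {len(usable)} usable time point(s) "
            f"(need >= 2) within the {crop_min} min crop"
        )

    rows = []
    for r in usable:
        g, i = r.geometry, r.intensity
        rows.append(
            {
                "t_min": r.timestamp_min,
                "V_um3": g.volume_um3,
                "w_um": g.width_um,
                "h_um": g.height_um,
                "imean_f": i.imean_f,
                "imean_epi": i.imean_epi,
                "isum_f": i.isum_f,
                "isum_epi": i.isum_epi,
                "tilt_length_deg": g.tilt_deg[0],
                "tilt_width_deg": g.tilt_deg[1],
                "tilt_height_deg": g.tilt_deg[2],
                "overlap_prev": r.overlap_prev,
            }
        )
    table = pd.DataFrame(rows)
    for raw, pct in _PCT_FEATURES.items():
        x0 = table[raw].iloc[0]
        table[pct] = 100.0 * (table[raw] - x0) / x0
    prov = {
        "crop_min": crop_min,
        "n_total": len(records),
        "n_retained": len(usable),
        "seg_params": vars(seg_params).copy(),
    }
    return FeatureTrajectory(records=records, table=table, crop_min=crop_min, provenance=prov)


@dataclass
class CorrelationResult:
    """A time-ordered 2D feature path with summary statistics.

    ``slope_origin`` is the least-squares slope through the origin (both
    percent-change coordinates are anchored at 0 at baseline by
    construction); ``pearson_r`` the ordinary correlation coefficient.
    """

    x_name: str
    y_name: str
    x: np.ndarray
    y: np.ndarray
    slope_origin: float
    pearson_r: float

    @property
    def n(self) -> int:
        return len(self.x)


def correlate(trajectory: FeatureTrajectory, x_feature: str, y_feature: str) -> CorrelationResult:
    """Correlate two trajectory features, e.g. ('dw_pct', 'dimean_f_pct') or
    ('imean_f', 'imean_epi').  Requires >= 3 retained points and nonconstant x."""
    table = trajectory.table
    for name in (x_feature, y_feature):
        if name not in table.columns:
            raise KeyError(f"unknown feature {name!r}; available: {list(table.columns)}")
    x = table[x_feature].to_numpy(dtype=float)
    y = table[y_feature].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("correlation requires >= 3 retained time points")
    sxx = float(np.dot(x, x))
    if sxx == 0 or float(np.var(x)) == 0:
        raise ValueError(f"zero-variance x feature {x_feature!r}")
    slope = float(np.dot(x, y) / sxx)
    # a flat y (e.g. conserved cumulative signal measured noiselessly) has no
    # defined correlation coefficient; report NaN rather than warn
    pearson = float(np.corrcoef(x, y)[0, 1]) if float(np.var(y)) > 0 else float("nan")
    return CorrelationResult(x_feature, y_feature, x, y, slope, pearson)


@dataclass
class ModeOfActionResult:
    label: str  # inert | bundle_drifting | intrinsic_destruction
    retention_R: float
    width_gain_W_pct: float
    slope_imean_vs_width: float
    tau_R: float
    tau_W_pct: float
    retention_R_epi: float = float("nan")


def classify_mode(
    trajectory: FeatureTrajectory,
    tau_R: float = 0.15,
    tau_W_pct: float = 10.0,
) -> ModeOfActionResult:
    """Call the damage mode from cumulative retention and width gain.

    R uses the forward channel (the geometry channel); the epi retention is
    reported alongside.  The label is a pure function of (R, W, thresholds).
    """
    table = trajectory.table
    isum0 = float(table["isum_f"].iloc[0])
    ratios = table["isum_f"].to_numpy(dtype=float)[1:] / isum0
    r_stat = float(np.median(ratios))
    isum0_epi = float(table["isum_epi"].iloc[0])
    r_epi = float(np.median(table["isum_epi"].to_numpy(dtype=float)[1:] / isum0_epi))
    w_stat = float(table["dw_pct"].max())
    try:
        slope = correlate(trajectory, "dw_pct", "dimean_f_pct").slope_origin
    except ValueError:
        slope = float("nan")

    if r_stat < 1.0 - tau_R:
        label = "intrinsic_destruction"
    elif w_stat >= tau_W_pct:
        label = "bundle_drifting"
    else:
        label = "inert"
    return ModeOfActionResult(
        label=label,
        retention_R=r_stat,
        width_gain_W_pct=w_stat,
        slope_imean_vs_width=slope,
        tau_R=tau_R,
        tau_W_pct=tau_W_pct,
        retention_R_epi=r_epi,
    )
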