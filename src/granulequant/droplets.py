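"""In vitro phase-separated droplet quantification.

Covers droplet segmentation, the condensation metric (summed
background-subtracted mean intensity x area per field, normalized to a
reference condition), linear intensity-vs-concentration calibration fitted
on homogeneous solutions, per-droplet protein concentrations, the
Dhh1:Pat1 stoichiometric ratio and droplet size distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from scipy import stats
from skimage.filters import threshold_otsu

from .errors import InputError
from .io import AnalysisConfig, DropletParams, ImageStack


@dataclass
class DropletRecord:
    """One segmented droplet with per-channel measurements.

    ``mean_intensity`` (background-subtracted, used by the condensation
    metric), ``mean_intensity_raw`` (as measured, on the same scale as the
    homogeneous calibration solutions) and ``concentration_uM`` are keyed
    by channel name.
    """

    label: int
    area_px: int
    area_um2: float
    equivalent_diameter_um: float
    mean_intensity: dict[str, float] = field(default_factory=dict)
    mean_intensity_raw: dict[str, float] = field(default_factory=dict)
    concentration_uM: dict[str, float] = field(default_factory=dict)


@dataclass
class CalibrationCurve:
    """Linear intensity = slope * concentration + intercept fit."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    concentration_range: tuple[float, float]

    def predict(self, concentration_uM: float) -> float:
        return self.slope * concentration_uM + self.intercept


def _resolve_threshold(frame: np.ndarray, method: str) -> float:
    if method == "otsu":
        return float(threshold_otsu(frame))
    if method.startswith("fixed:"):
        return float(method.split(":", 1)[1])
    raise InputError(f"unknown threshold method {method!r}")


def segment_droplets(
    stack: ImageStack,
    params: DropletParams | AnalysisConfig | None = None,
    seg_channel: int | str = 0,
    timepoint: int = 0,
) -> tuple[np.ndarray, list[DropletRecord]]:
    """Threshold-segment droplets and measure them on every channel.

    Foreground = pixels of the segmentation channel above the threshold;
    8-connected components below the minimum area are removed. The
    per-channel background (median of non-foreground pixels) is subtracted
    from every droplet's mean intensity. Means are taken on a slightly
    eroded component (``measure_erosion_px``) to avoid partial-volume edge
    pixels; erosion never empties a component — the full component is used
    as fallback.
    """
    if params is None:
        params = DropletParams()
    p = params.droplet if isinstance(params, AnalysisConfig) else params
    frame = stack.frame(seg_channel, timepoint)
    if frame.max() == frame.min():
        return np.zeros(frame.shape, dtype=np.int32), []
    threshold = _resolve_threshold(frame, p.threshold_method)
    foreground = frame > threshold
    labels, n = ndi.label(foreground, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels.astype(np.int32), []

    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.nonzero(areas >= p.min_droplet_area_px)[0] + 1
    out = np.zeros(frame.shape, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new

    backgrounds = {
        name: float(np.median(stack.frame(name, timepoint)[~foreground]))
        for name in stack.channel_names
    }
    px = stack.pixel_size_um
    records = []
    for label in range(1, len(keep) + 1):
        mask = out == label
        if p.measure_erosion_px > 0:
            eroded = ndi.binary_erosion(mask, iterations=p.measure_erosion_px)
            measure_mask = eroded if eroded.any() else mask
        else:
            measure_mask = mask
        area_px = int(mask.sum())
        area_um2 = area_px * px**2
        rec = DropletRecord(
            label=label,
            area_px=area_px,
            area_um2=area_um2,
            equivalent_diameter_um=2.0 * math.sqrt(area_um2 / math.pi),
        )
        for name in stack.channel_names:
            channel_frame = stack.frame(name, timepoint)
            raw = float(channel_frame[measure_mask].mean())
            rec.mean_intensity_raw[name] = raw
            rec.mean_intensity[name] = raw - backgrounds[name]
        records.append(rec)
    return out, records


def droplet_metric(records: Sequence[DropletRecord], channel: str) -> float:
    """Condensation metric for one field: sum of mean intensity x area (px).

    Uses the background-subtracted mean, making the metric additive across
    disjoint fields and invariant to intensity offsets. An empty field
    scores 0.
    """
    return float(
        sum(rec.mean_intensity[channel] * rec.area_px for rec in records)
    )


def normalize_metric(values: Sequence[float], reference_value: float) -> list[float]:
    """Divide metric values by the reference condition's value."""
    if reference_value <= 0:
        raise InputError("reference_value must be > 0")
    return [v / reference_value for v in values]


def fit_calibration(pairs: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, intensity) pairs.

    Exact on noiseless collinear input; raises on a single distinct
    concentration (singular fit).
    """
    if len(pairs) < 2:
        raise InputError("need at least 2 calibration points")
    conc = np.asarray([p[0] for p in pairs], dtype=float)
    intensity = np.asarray([p[1] for p in pairs], dtype=float)
    if np.unique(conc).size < 2:
        raise InputError("calibration requires >= 2 distinct concentrations")
    fit = stats.linregress(conc, intensity)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(pairs),
        concentration_range=(float(conc.min()), float(conc.max())),
    )


def droplet_concentration(
    mean_intensity: float, curve: CalibrationCurve
) -> tuple[float, bool]:
    """Invert the calibration line: c = (intensity - intercept) / slope.

    Returns (concentration_uM, extrapolated), where ``extrapolated`` flags
    estimates outside the fitted concentration range.
    """
    if curve.slope <= 0:
        raise InputError("calibration slope must be > 0 to invert")
    c = (mean_intensity - curve.intercept) / curve.slope
    lo, hi = curve.concentration_range
    return c, bool(c < lo or c > hi)


@dataclass
class StoichiometrySummary:
    mean_ratio: float
    sd: float
    n: int
    n_excluded: int


def droplet_stoichiometry(
    records: Sequence[DropletRecord],
    curve_a: CalibrationCurve,
    curve_b: CalibrationCurve,
    channel_a: str,
    channel_b: str,
) -> StoichiometrySummary:
    """Per-droplet concentration ratio A:B, averaged over droplets.

    Each droplet's raw mean intensity (same scale as the homogeneous
    calibration solutions) is converted to a concentration via the two
    calibration curves; droplets with non-positive denominator
    concentration are excluded and counted.
    """
    ratios = []
    n_excluded = 0
    for rec in records:
        ca, _ = droplet_concentration(rec.mean_intensity_raw[channel_a], curve_a)
        cb, _ = droplet_concentration(rec.mean_intensity_raw[channel_b], curve_b)
        rec.concentration_uM[channel_a] = ca
        rec.concentration_uM[channel_b] = cb
        if cb <= 0:
            n_excluded += 1
            continue
        ratios.append(ca / cb)
    if not ratios:
        raise InputError("no droplets with a valid denominator concentration")
    arr = np.asarray(ratios)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return StoichiometrySummary(float(arr.mean()), sd, len(arr), n_excluded)


def size_distribution(
    records: Sequence[DropletRecord], bin_width_um: float
) -> dict[int, int]:
    """Histogram of equivalent diameters in half-open bins [i*w, (i+1)*w).

    Returns a mapping from bin index to count over non-empty bins only, so
    the counts always sum to the number of droplets.
    """
    if bin_width_um <= 0:
        raise InputError("bin_width_um must be > 0")
    hist: dict[int, int] = {}
    for rec in records:
        idx = int(math.floor(rec.equivalent_diameter_um / bin_width_um))
        hist[idx] = hist.get(idx, 0) + 1
    return dict(sorted(hist.items()))
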