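"""P-body focus detection, measurement, cross-channel matching.

Foci are diffraction-limited bright puncta. Candidates are strict local
intensity maxima; each is measured against its local background (median of a
surrounding annulus) and retained only if it clears both an absolute
intensity threshold and the 5% contrast threshold,
``(peak - background) / background >= 0.05``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage as ndi

from .errors import InputError
from .io import AnalysisConfig, FocusParams
from .segmentation import CellLabelMap


@dataclass
class Focus:
    """One measured punctum.

    ``row``/``col`` are the subpixel intensity-weighted centroid;
    intensities are raw counts; ``contrast`` is dimensionless
    (peak - background) / background. ``valid`` is False when the
    background annulus was clipped by the image border, which excludes the
    focus from any ranking.
    """

    row: float
    col: float
    peak_intensity: float
    background: float
    integrated_intensity: float
    contrast: float
    noise_sd: float = 0.0
    channel: str | int = 0
    timepoint: int = 0
    cell_label: int | None = None
    valid: bool = True


@dataclass(frozen=True)
class FocusMatch:
    focus_a: Focus
    focus_b: Focus
    distance_um: float


def _disc_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer offsets with Euclidean distance < radius from the origin."""
    r = int(math.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dr**2 + dc**2 < radius**2
    return dr[inside], dc[inside]


def detect_local_maxima(image: np.ndarray, maxima_radius_px: float) -> list[tuple[int, int]]:
    """Find pixels strictly brighter than everything within a radius.

    Plateau ties keep only the lexicographically smallest (row, col) of the
    plateau, and pixels at the image minimum are never candidates — so a
    constant image yields no maxima. Results are sorted by descending pixel
    value, ties by ascending (row, col).
    """
    if maxima_radius_px < 1:
        raise InputError("maxima_radius_px must be >= 1")
    image = np.asarray(image, dtype=float)
    r = int(math.ceil(maxima_radius_px))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    footprint = (dr**2 + dc**2 <= maxima_radius_px**2) & ((dr != 0) | (dc != 0))
    neighbour_max = ndi.maximum_filter(
        image, footprint=footprint, mode="constant", cval=-np.inf
    )
    lo = image.min()
    cand = np.nonzero((image >= neighbour_max) & (image > lo))
    offsets = np.stack(np.nonzero(footprint), axis=1) - r
    keep: list[tuple[int, int]] = []
    for row, col in zip(*cand):
        value = image[row, col]
        smallest = True
        for orow, ocol in offsets:
            nr, nc = row + orow, col + ocol
            if 0 <= nr < image.shape[0] and 0 <= nc < image.shape[1]:
                if image[nr, nc] == value and (nr, nc) < (row, col):
                    smallest = False
                    break
        if smallest:
            keep.append((int(row), int(col)))
    keep.sort(key=lambda rc: (-image[rc], rc))
    return keep


def measure_focus(
    image: np.ndarray,
    point: tuple[int, int],
    r_int_px: float,
    r_bg_in_px: float,
    r_bg_out_px: float,
    channel: str | int = 0,
    timepoint: int = 0,
) -> Focus:
    """Measure one candidate punctum.

    background = median of the annulus [r_bg_in, r_bg_out); peak = max over
    the disc of radius r_int; integrated = sum over the disc of
    (pixel - background); contrast = (peak - background)/background;
    centroid = background-subtracted intensity-weighted centre of mass of
    the disc. A focus whose annulus is clipped by the border is returned
    with ``valid=False`` and is excluded from ranking downstream.
    """
    if not (r_bg_out_px > r_bg_in_px >= r_int_px > 0):
        raise InputError("requires r_bg_out > r_bg_in >= r_int > 0")
    image = np.asarray(image, dtype=float)
    row, col = int(point[0]), int(point[1])
    reach = int(math.ceil(r_bg_out_px)) - 1
    clipped = (
        row - reach < 0
        or col - reach < 0
        or row + reach >= image.shape[0]
        or col + reach >= image.shape[1]
    )
    if clipped:
        return Focus(row, col, image[row, col], np.nan, np.nan, np.nan, np.nan,
                     channel=channel, timepoint=timepoint, valid=False)

    ann_dr, ann_dc = _disc_offsets(r_bg_out_px)
    dist2 = ann_dr**2 + ann_dc**2
    in_annulus = dist2 >= r_bg_in_px**2
    annulus = image[row + ann_dr[in_annulus], col + ann_dc[in_annulus]]
    background = float(np.median(annulus))
    noise_sd = float(1.4826 * np.median(np.abs(annulus - background)))

    disc_dr, disc_dc = _disc_offsets(r_int_px)
    disc = image[row + disc_dr, col + disc_dc]
    peak = float(disc.max())
    integrated = float(np.sum(disc - background))
    contrast = (peak - background) / background if background > 0 else np.inf

    weights = np.clip(disc - background, 0, None)
    total = weights.sum()
    if total > 0:
        crow = row + float(np.sum(weights * disc_dr) / total)
        ccol = col + float(np.sum(weights * disc_dc) / total)
    else:
        crow, ccol = float(row), float(col)
    return Focus(crow, ccol, peak, background, integrated, contrast, noise_sd,
                 channel=channel, timepoint=timepoint)


def robust_intensity_floor(image: np.ndarray, n_sigma: float = 3.0) -> float:
    """Default absolute intensity threshold: median + n_sigma * MAD-based sd.

    The original analysis used an instrument-specific absolute threshold;
    a robust noise estimate generalises it across acquisitions.
    """
    image = np.asarray(image, dtype=float)
    med = np.median(image)
    sd = 1.4826 * np.median(np.abs(image - med))
    return float(med + n_sigma * sd)


def filter_foci(
    candidates: list[tuple[int, int]],
    image: np.ndarray,
    params: FocusParams | AnalysisConfig,
    channel: str | int = 0,
    timepoint: int = 0,
) -> list[Focus]:
    """Measure candidates and retain those passing both thresholds.

    A focus is kept when peak_intensity >= intensity_min AND
    contrast >= contrast_min (the 5% cutoff is inclusive: contrast exactly
    0.05 is retained). Output is sorted by descending integrated intensity.
    """
    p = params.focus if isinstance(params, AnalysisConfig) else params
    # global robust noise floor guards against annuli that underestimate
    # their own noise by chance (many background candidates are tested)
    global_sd = 0.0
    if p.intensity_min is None:
        med = float(np.median(image))
        global_sd = float(1.4826 * np.median(np.abs(np.asarray(image, float) - med)))
    retained = []
    for point in candidates:
        focus = measure_focus(
            image, point, p.r_int_px, p.r_bg_in_px, p.r_bg_out_px, channel, timepoint
        )
        if not focus.valid:
            continue
        if p.intensity_min is not None:
            intensity_min = p.intensity_min
        else:
            # local significance: the focus's own annulus background plus
            # n robust noise sd of that annulus (absolute thresholds are
            # instrument-specific; this generalises across acquisitions)
            noise_sd = max(focus.noise_sd, global_sd)
            intensity_min = focus.background + p.local_significance * noise_sd
        if focus.peak_intensity >= intensity_min and focus.contrast >= p.contrast_min:
            retained.append(focus)
    retained.sort(key=lambda f: (-f.integrated_intensity, f.row, f.col))
    return retained


def detect_foci(
    image: np.ndarray,
    params: FocusParams | AnalysisConfig,
    channel: str | int = 0,
    timepoint: int = 0,
) -> list[Focus]:
    """Local-maxima detection followed by intensity/contrast filtering.

    The frame is first smoothed with a small Gaussian (``detection_sigma_px``,
    a matched filter for diffraction-limited puncta); candidates and all
    measurements are taken on the smoothed frame. Smoothing preserves the
    background-corrected integrated intensity of a punctum up to disc
    truncation, and leaves intensity *ratios* between channels untouched,
    while suppressing single-pixel noise that would otherwise defeat the
    contrast threshold.
    """
    p = params.focus if isinstance(params, AnalysisConfig) else params
    if p.detection_sigma_px > 0:
        image = ndi.gaussian_filter(np.asarray(image, dtype=float), p.detection_sigma_px)
    candidates = detect_local_maxima(image, p.maxima_radius_px)
    return filter_foci(candidates, image, p, channel, timepoint)


def match_foci_channels(
    set_a: list[Focus],
    set_b: list[Focus],
    d_max_um: float,
    pixel_size_um: float,
) -> list[FocusMatch]:
    """Greedy one-to-one nearest-neighbour matching across channels.

    All cross-channel pairs are sorted by ascending centroid distance (ties
    by (row, col) of the first-channel focus); a pair is accepted when both
    foci are still unmatched and the distance is within ``d_max_um``.
    """
    if not set_a or not set_b:
        return []
    pairs = []
    for i, fa in enumerate(set_a):
        for j, fb in enumerate(set_b):
            d_px = math.hypot(fa.row - fb.row, fa.col - fb.col)
            d_um = d_px * pixel_size_um
            if d_um <= d_max_um:
                pairs.append((d_um, fa.row, fa.col, fb.row, fb.col, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for d_um, _, _, _, _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(FocusMatch(set_a[i], set_b[j], d_um))
    return matches


def assign_foci_to_cells(foci: list[Focus], label_map: CellLabelMap) -> list[Focus]:
    """Attach the cell label at each focus's rounded centroid (0 -> None)."""
    out = []
    labels = label_map.labels
    for focus in foci:
        r = int(round(focus.row))
        c = int(round(focus.col))
        r = min(max(r, 0), labels.shape[0] - 1)
        c = min(max(c, 0), labels.shape[1] - 1)
        label = int(labels[r, c])
        out.append(replace(focus, cell_label=label if label > 0 else None))
    return out


def foci_per_cell(n_foci: int, n_cells: int) -> float:
    """PBs per cell for one image: the focus count divided by the cell count."""
    if n_cells <= 0:
        raise InputError("foci_per_cell undefined for an image with no cells")
    return n_foci / n_cells
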