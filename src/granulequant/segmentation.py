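"""Yeast cell segmentation by edge-normal voting.

Cytoplasmic fluorescence makes yeast cell interiors bright on a dark
background. The segmenter detects intensity boundaries as zero-crossings of
a Laplacian-of-Gaussian response, then casts votes from every edge pixel
along its dark-to-bright gradient normal at distances between the smallest
and largest expected cell radius. Normals of a roughly convex bright cell
converge near its centre, so vote-density maxima serve as cell seeds, from
which cells are reconstructed by thresholded region growing halted at edges.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import flood

from .errors import InputError
from .io import AnalysisConfig, SegmentationParams


@dataclass
class EdgeMap:
    """Edge pixels with dark-to-bright gradient directions.

    ``coords`` is an (n, 2) integer array of (row, col) positions,
    ``directions`` the matching (n, 2) unit vectors pointing from dark to
    bright, ``magnitudes`` the gradient magnitude at each edge pixel.
    """

    coords: np.ndarray
    directions: np.ndarray
    magnitudes: np.ndarray
    shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class CellRecord:
    label: int
    area_px: int
    centroid: tuple[float, float]
    touches_border: bool


@dataclass
class CellLabelMap:
    """Integer label image (0 = background) plus per-cell records."""

    labels: np.ndarray
    cells: list[CellRecord] = field(default_factory=list)
    exclude_border: bool = True

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def detect_edges(
    image: np.ndarray, edge_sigma_px: float, magnitude_quantile: float = 0.5
) -> EdgeMap:
    """Locate intensity boundaries as Laplacian-of-Gaussian zero-crossings.

    A pixel is an edge if its LoG response changes sign against a 4-neighbour
    and it is the closer of the two to zero. Only zero-crossings whose local
    gradient magnitude exceeds the given quantile of all zero-crossing
    magnitudes are kept. A constant image yields an empty map.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise InputError("empty image")
    if edge_sigma_px <= 0:
        raise InputError("edge_sigma_px must be > 0")
    if not (0 < magnitude_quantile < 1):
        raise InputError("magnitude_quantile must lie in (0, 1)")

    log = ndi.gaussian_laplace(image, sigma=edge_sigma_px)
    zc = np.zeros(image.shape, dtype=bool)
    for axis in (0, 1):
        a = np.swapaxes(log, 0, axis)
        z = np.swapaxes(zc, 0, axis)
        sign_change = a[:-1] * a[1:] < 0
        first_closer = np.abs(a[:-1]) <= np.abs(a[1:])
        z[:-1] |= sign_change & first_closer
        z[1:] |= sign_change & ~first_closer

    gr = ndi.gaussian_filter(image, sigma=edge_sigma_px, order=(1, 0))
    gc = ndi.gaussian_filter(image, sigma=edge_sigma_px, order=(0, 1))
    mag = np.hypot(gr, gc)

    rows, cols = np.nonzero(zc)
    if rows.size == 0:
        return EdgeMap(
            np.empty((0, 2), int), np.empty((0, 2)), np.empty(0), image.shape
        )
    m = mag[rows, cols]
    # the quantile rejects spurious weak crossings on noisy images; the cap
    # at a fraction of the strongest edge keeps genuine boundaries intact on
    # clean images where nearly all crossings are real
    cutoff = min(np.quantile(m, magnitude_quantile), 0.25 * m.max())
    keep = m > cutoff
    keep &= m > 0  # direction undefined at zero gradient
    rows, cols, m = rows[keep], cols[keep], m[keep]
    directions = np.stack([gr[rows, cols], gc[rows, cols]], axis=1) / m[:, None]
    coords = np.stack([rows, cols], axis=1)
    return EdgeMap(coords, directions, m, image.shape)


def vote_cell_centres(
    edges: EdgeMap,
    r_min_px: float,
    r_max_px: float,
    smoothing_sigma_px: float = 2.0,
) -> np.ndarray:
    """Accumulate votes along dark-to-bright edge normals.

    Every edge pixel casts one vote at each integer distance in
    ``[r_min_px, r_max_px]`` along its gradient direction; the accumulator
    is then smoothed with a small Gaussian so that near-coincident rays
    reinforce one peak.
    """
    if not (r_max_px > r_min_px > 0):
        raise InputError("requires r_max_px > r_min_px > 0")
    acc = np.zeros(edges.shape, dtype=float)
    if len(edges) == 0:
        return acc
    radii = np.arange(np.ceil(r_min_px), np.floor(r_max_px) + 1.0)
    # (n_edges, n_radii, 2) target positions, rounded to pixels
    targets = edges.coords[:, None, :] + edges.directions[:, None, :] * radii[None, :, None]
    targets = np.rint(targets).astype(int).reshape(-1, 2)
    inside = (
        (targets[:, 0] >= 0)
        & (targets[:, 0] < acc.shape[0])
        & (targets[:, 1] >= 0)
        & (targets[:, 1] < acc.shape[1])
    )
    targets = targets[inside]
    np.add.at(acc, (targets[:, 0], targets[:, 1]), 1.0)
    if smoothing_sigma_px > 0:
        acc = ndi.gaussian_filter(acc, smoothing_sigma_px)
    return acc


def find_seeds(
    accumulator: np.ndarray, min_votes: float, nms_radius_px: float
) -> list[tuple[int, int]]:
    """Pick vote-density maxima as cell seeds.

    Local maxima (8-neighbourhood) with at least ``min_votes`` are taken in
    descending vote order (ties broken by ascending (row, col)) and greedily
    accepted unless within ``nms_radius_px`` of an already accepted seed.
    """
    if min_votes <= 0:
        raise InputError("min_votes must be > 0")
    if nms_radius_px < 1:
        raise InputError("nms_radius_px must be >= 1")
    acc = np.asarray(accumulator, dtype=float)
    local_max = acc >= ndi.maximum_filter(acc, size=3, mode="constant", cval=-np.inf)
    rows, cols = np.nonzero(local_max & (acc >= min_votes))
    if rows.size == 0:
        return []
    order = np.lexsort((cols, rows, -acc[rows, cols]))
    seeds: list[tuple[int, int]] = []
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if all((r - sr) ** 2 + (c - sc) ** 2 > nms_radius_px**2 for sr, sc in seeds):
            seeds.append((r, c))
    return seeds


def _background_mode(image: np.ndarray) -> float:
    """Most common rounded intensity — the dark-background mode."""
    counts = np.bincount(np.rint(image).astype(int).ravel())
    return float(np.argmax(counts))


def _geodesic_resolve(
    region_masks: list[np.ndarray],
    seeds: list[tuple[int, int]],
    seed_ids: list[int],
    contested: np.ndarray,
    labels: np.ndarray,
) -> None:
    """Assign contested pixels to the geodesically nearest claiming seed.

    Multi-source Dijkstra restricted to each seed's own region mask;
    8-connected with Euclidean step costs. Ties go to the earlier seed.
    """
    h, w = labels.shape
    steps = [
        (dr, dc, float(np.hypot(dr, dc)))
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    ]
    best = np.full(labels.shape, np.inf)
    heap: list[tuple[float, int, int, int]] = []
    for idx, (r, c) in enumerate(seeds):
        heapq.heappush(heap, (0.0, idx, r, c))
    owner = np.zeros(labels.shape, dtype=int)
    while heap:
        d, idx, r, c = heapq.heappop(heap)
        if d >= best[r, c]:
            continue
        best[r, c] = d
        owner[r, c] = seed_ids[idx]
        for dr, dc, cost in steps:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and region_masks[idx][nr, nc]:
                if d + cost < best[nr, nc]:
                    heapq.heappush(heap, (d + cost, idx, nr, nc))
    labels[contested] = owner[contested]


def reconstruct_cells(
    image: np.ndarray,
    seeds: list[tuple[int, int]],
    edges: EdgeMap,
    config: AnalysisConfig | SegmentationParams,
    pixel_size_um: float | None = None,
) -> CellLabelMap:
    """Grow cells from seeds over bright pixels, halted at edge pixels.

    Each seed claims the connected set of pixels brighter than the midpoint
    of its own intensity and the image's background mode, with edge pixels
    acting as barriers. Pixels claimed by several seeds go to the
    geodesically nearest one. Regions outside the configured area range are
    discarded; cells touching the image border are flagged.
    """
    if isinstance(config, AnalysisConfig):
        seg = config.segmentation
        pixel_size_um = pixel_size_um or config.pixel_size_um
    else:
        seg = config
        if pixel_size_um is None:
            raise InputError("pixel_size_um required with bare SegmentationParams")

    image = np.asarray(image, dtype=float)
    labels = np.zeros(image.shape, dtype=np.int32)
    if not seeds:
        return CellLabelMap(labels, [], seg.exclude_border)
    for r, c in seeds:
        if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
            raise InputError(f"seed {(r, c)} outside image bounds")

    barrier = np.zeros(image.shape, dtype=bool)
    if len(edges):
        barrier[edges.coords[:, 0], edges.coords[:, 1]] = True
    bg = _background_mode(image)

    region_masks: list[np.ndarray] = []
    for r, c in seeds:
        threshold = 0.5 * (image[r, c] + bg)
        mask = (image > threshold) & ~barrier
        mask[r, c] = True  # the seed always belongs to its own region
        region_masks.append(flood(mask, (r, c), connectivity=2))

    claims = np.zeros(image.shape, dtype=np.int16)
    for mask in region_masks:
        claims += mask
    for idx, mask in enumerate(region_masks):
        sole = mask & (claims == 1)
        labels[sole] = idx + 1
    contested = claims > 1
    if np.any(contested):
        claiming = [i for i, m in enumerate(region_masks) if np.any(m & contested)]
        _geodesic_resolve(
            [region_masks[i] for i in claiming],
            [seeds[i] for i in claiming],
            [i + 1 for i in claiming],
            contested,
            labels,
        )

    # area filter in physical units, then consecutive relabelling
    min_area_px = seg.min_cell_area_um2 / pixel_size_um**2
    max_area_px = seg.max_cell_area_um2 / pixel_size_um**2
    out = np.zeros(image.shape, dtype=np.int32)
    cells: list[CellRecord] = []
    next_label = 1
    for idx in range(len(seeds)):
        mask = labels == idx + 1
        area = int(mask.sum())
        if area == 0 or not (min_area_px <= area <= max_area_px):
            continue
        rows, cols = np.nonzero(mask)
        touches = bool(
            rows.min() == 0
            or cols.min() == 0
            or rows.max() == image.shape[0] - 1
            or cols.max() == image.shape[1] - 1
        )
        out[mask] = next_label
        cells.append(
            CellRecord(next_label, area, (float(rows.mean()), float(cols.mean())), touches)
        )
        next_label += 1
    return CellLabelMap(out, cells, seg.exclude_border)


def count_cells(label_map: CellLabelMap) -> int:
    """Number of retained cells, respecting the border-exclusion flag."""
    if label_map.exclude_border:
        return sum(not cell.touches_border for cell in label_map.cells)
    return label_map.n_cells


def segment_cells(
    image: np.ndarray,
    config: AnalysisConfig,
    pixel_size_um: float | None = None,
) -> CellLabelMap:
    """Full segmentation: edges -> votes -> seeds -> reconstruction."""
    seg = config.segmentation
    px = pixel_size_um or config.pixel_size_um
    r_min_px = seg.r_min_um / px
    r_max_px = seg.r_max_um / px
    edges = detect_edges(image, seg.edge_sigma_px, seg.magnitude_quantile)
    acc = vote_cell_centres(edges, r_min_px, r_max_px, seg.accumulator_sigma_px)
    min_votes = seg.min_votes if seg.min_votes is not None else 0.05 * 2 * np.pi * r_min_px
    nms = seg.nms_radius_px if seg.nms_radius_px is not None else r_max_px
    seeds = find_seeds(acc, min_votes, nms) if acc.max() > 0 else []
    return reconstruct_cells(image, seeds, edges, seg, px)
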