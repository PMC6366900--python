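"""Seeded synthetic microscopy scenes with complete ground truth.

The generator emulates the statistical structure the analysis assumes:

* dark-background fields of bright elliptical yeast cells (~4-6 um
  diameter) containing diffraction-limited Gaussian foci, two channels with
  a planted intensity ratio and a planted colocalized fraction;
* confocal fields of circular liquid droplets whose interior intensity
  follows a planted linear intensity/concentration calibration;
* homogeneous calibration images at known concentrations;
* time-lapses with a scheduled expected foci-per-cell per frame.

All randomness flows through one ``numpy`` Generator per call, so the same
seed and parameters reproduce pixel-identical images and identical ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi

from .errors import InputError, PlacementError
from .io import CONFOCAL_PIXEL_SIZE_UM, WIDEFIELD_PIXEL_SIZE_UM, ImageStack

DEFAULT_CHANNEL_NAMES = ("GFP", "mCherry")


@dataclass
class NoiseSpec:
    """Camera noise model: Poisson shot noise on expected counts, then
    additive Gaussian read noise. Both are optional."""

    background_level: float = 200.0
    read_noise_sd: float = 10.0
    shot_noise: bool = True


@dataclass
class CellTruth:
    centre: tuple[float, float]          # (row, col) px
    radii: tuple[float, float]           # semi-axes (a, b) px
    orientation: float                   # radians
    interior_level: float                # counts


@dataclass
class FocusTruth:
    row: float
    col: float
    channel: int
    amplitude: float                     # peak counts above local scene
    psf_sigma_px: float
    cell_index: int | None = None
    pair_id: int | None = None           # shared by colocalized partners


@dataclass
class DropletTruth:
    centre: tuple[float, float]
    radius_px: float
    concentrations: tuple[float, ...]    # uM per channel


@dataclass
class GroundTruth:
    """Planted parameters of one synthetic scene."""

    seed: int
    shape: tuple[int, int]
    pixel_size_um: float
    noise: NoiseSpec
    psf_sigma_px: float = 1.3
    cells: list[CellTruth] = field(default_factory=list)
    foci: list[FocusTruth] = field(default_factory=list)
    droplets: list[DropletTruth] = field(default_factory=list)
    calibration: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _place_centres_grid(
    rng: np.random.Generator,
    n: int,
    min_spacing_px: float,
    margin_px: float,
    shape: tuple[int, int] | None,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Place n centres with a guaranteed minimum pairwise spacing.

    Centres sit on a randomly subsampled jittered grid whose pitch exceeds
    the spacing by the jitter budget, so the constraint holds by
    construction at any requested density; a post-check enforces it.
    """
    if n == 0:
        return np.empty((0, 2)), shape or (256, 256)
    pitch = min_spacing_px * 1.15
    jitter = (pitch - min_spacing_px) / 2.0 * 0.98
    if shape is None:
        ncols = int(math.ceil(math.sqrt(n)))
        nrows = int(math.ceil(n / ncols))
        shape = (
            int(math.ceil(nrows * pitch + 2 * margin_px)),
            int(math.ceil(ncols * pitch + 2 * margin_px)),
        )
    else:
        nrows = int((shape[0] - 2 * margin_px) // pitch)
        ncols = int((shape[1] - 2 * margin_px) // pitch)
        if nrows * ncols < n:
            raise PlacementError(
                f"field {shape} too small for {n} cells at spacing "
                f"{min_spacing_px:.0f} px"
            )
    sites = [(i, j) for i in range(nrows) for j in range(ncols)]
    chosen = rng.choice(len(sites), size=n, replace=False)
    centres = np.empty((n, 2))
    for k, s in enumerate(chosen):
        i, j = sites[s]
        centres[k, 0] = margin_px + (i + 0.5) * pitch + rng.uniform(-jitter, jitter)
        centres[k, 1] = margin_px + (j + 0.5) * pitch + rng.uniform(-jitter, jitter)
    if n > 1:
        d = np.linalg.norm(centres[:, None] - centres[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < min_spacing_px:
            raise PlacementError("jittered grid violated the spacing constraint")
    return centres, shape


def _inside_ellipse(cell: CellTruth, row: float, col: float, scale: float = 1.0) -> bool:
    dr, dc = row - cell.centre[0], col - cell.centre[1]
    ct, st = math.cos(cell.orientation), math.sin(cell.orientation)
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    a, b = cell.radii[0] * scale, cell.radii[1] * scale
    return (u / a) ** 2 + (v / b) ** 2 < 1.0


def _sample_point_in_ellipse(
    rng: np.random.Generator, cell: CellTruth, scale: float
) -> tuple[float, float]:
    ct, st = math.cos(cell.orientation), math.sin(cell.orientation)
    while True:
        u = rng.uniform(-1, 1)
        v = rng.uniform(-1, 1)
        if u * u + v * v < 1.0:
            du = u * cell.radii[0] * scale
            dv = v * cell.radii[1] * scale
            return (
                cell.centre[0] + du * ct - dv * st,
                cell.centre[1] + du * st + dv * ct,
            )


def _sample_radius(rng: np.random.Generator, spec) -> float:
    """Radius spec: scalar, ("uniform", lo, hi) or ("lognormal", median, sigma)."""
    if np.isscalar(spec):
        return float(spec)
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "lognormal":
        return float(spec[1] * math.exp(rng.normal(0.0, spec[2])))
    raise InputError(f"unknown distribution spec {spec!r}")


def _foci_count(rng: np.random.Generator, spec) -> int:
    """Foci-per-cell spec: int (fixed), float (Poisson mean) or tagged tuple."""
    if isinstance(spec, (tuple, list)):
        if spec[0] == "fixed":
            return int(spec[1])
        if spec[0] == "poisson":
            return int(rng.poisson(spec[1]))
        raise InputError(f"unknown foci_per_cell spec {spec!r}")
    if isinstance(spec, (int, np.integer)):
        return int(spec)
    return int(rng.poisson(float(spec)))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_scene(
    truth: GroundTruth,
    n_channels: int,
    blur: bool = True,
) -> np.ndarray:
    """Noiseless expected image per channel: background + cell interiors
    (PSF-blurred when ``blur``) + analytic Gaussian foci."""
    h, w = truth.shape
    bg = truth.noise.background_level
    scene = np.full((n_channels, h, w), bg, dtype=float)
    for cell in truth.cells:
        r0, c0 = cell.centre
        rad = max(cell.radii) + 2
        rlo, rhi = max(0, int(r0 - rad)), min(h, int(r0 + rad) + 1)
        clo, chi = max(0, int(c0 - rad)), min(w, int(c0 + rad) + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        dr, dc = rr - r0, cc - c0
        ct, st = math.cos(cell.orientation), math.sin(cell.orientation)
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        inside = (u / cell.radii[0]) ** 2 + (v / cell.radii[1]) ** 2 <= 1.0
        for ch in range(n_channels):
            win = scene[ch, rlo:rhi, clo:chi]
            win[inside] = cell.interior_level
    if blur and truth.psf_sigma_px > 0:
        for ch in range(n_channels):
            scene[ch] = ndi.gaussian_filter(scene[ch], truth.psf_sigma_px, mode="nearest")
    for focus in truth.foci:
        sigma = focus.psf_sigma_px
        rad = int(math.ceil(6 * sigma))
        r0, c0 = focus.row, focus.col
        rlo, rhi = max(0, int(r0 - rad)), min(h, int(r0 + rad) + 1)
        clo, chi = max(0, int(c0 - rad)), min(w, int(c0 + rad) + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        spot = focus.amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
        )
        scene[focus.channel, rlo:rhi, clo:chi] += spot
    return scene


def _apply_noise(
    scene: np.ndarray, noise: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    out = scene
    if noise.shot_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, size=out.shape)
    return np.clip(out, 0, None)


# ---------------------------------------------------------------------------
# cell fields
# ---------------------------------------------------------------------------

def _plant_cells(
    rng: np.random.Generator,
    n_cells: int,
    shape: tuple[int, int] | None,
    pixel_size_um: float,
    cell_radius_um: tuple[float, float],
    interior_levels: tuple[float, float],
    axis_ratio_max: float,
    min_spacing_um: float,
) -> tuple[list[CellTruth], tuple[int, int]]:
    r_max_px = cell_radius_um[1] / pixel_size_um
    margin = r_max_px + 8
    spacing_px = min_spacing_um / pixel_size_um
    centres, shape = _place_centres_grid(rng, n_cells, spacing_px, margin, shape)
    cells = []
    for centre in centres:
        mean_radius = rng.uniform(*cell_radius_um) / pixel_size_um
        ratio = rng.uniform(1.0, axis_ratio_max)
        a = mean_radius * math.sqrt(ratio)
        b = mean_radius / math.sqrt(ratio)
        cells.append(
            CellTruth(
                centre=(float(centre[0]), float(centre[1])),
                radii=(a, b),
                orientation=float(rng.uniform(0, math.pi)),
                interior_level=float(rng.uniform(*interior_levels)),
            )
        )
    return cells, shape


def _plant_focus_positions(
    rng: np.random.Generator,
    cell: CellTruth,
    n: int,
    existing: list[tuple[float, float]],
    min_sep_px: float,
    max_tries: int = 200,
) -> list[tuple[float, float]]:
    points: list[tuple[float, float]] = []
    for _ in range(n):
        for _ in range(max_tries):
            p = _sample_point_in_ellipse(rng, cell, scale=0.6)
            if all(
                math.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep_px
                for q in points + existing
            ):
                points.append(p)
                break
        else:
            raise PlacementError(
                f"could not place {n} foci at separation {min_sep_px} px"
            )
    return points


def generate_cell_field(
    n_cells: int = 20,
    foci_per_cell=2.0,
    channel_ratio: float = 2.0,
    coloc_fraction: float = 1.0,
    noise: NoiseSpec | None = None,
    shape: tuple[int, int] | None = None,
    seed: int = 0,
    *,
    n_channels: int = 2,
    pixel_size_um: float = WIDEFIELD_PIXEL_SIZE_UM,
    cell_radius_um: tuple[float, float] = (2.0, 3.0),
    interior_levels: tuple[float, float] | None = None,
    axis_ratio_max: float = 1.3,
    min_spacing_um: float = 7.0,
    focus_amplitude: float = 300.0,
    focus_amp_sigma_log: float = 0.3,
    psf_sigma_px: float = 1.3,
    focus_min_sep_px: float = 4.0,
    jitter_sd_px: float = 0.5,
    decoys_per_channel: int = 0,
    channel_names: Sequence[str] = DEFAULT_CHANNEL_NAMES,
) -> tuple[ImageStack, GroundTruth]:
    """Synthesize one field of yeast cells with planted fluorescent foci.

    Channel-0 foci have lognormally distributed amplitudes (median
    ``focus_amplitude``); for the colocalized fraction a channel-1 partner
    is planted at the channel-0 position plus sub-resolution Gaussian
    jitter, with amplitude divided by ``channel_ratio`` (the planted A:B
    intensity ratio). ``decoys_per_channel`` adds unpaired foci per channel.
    Cell interiors default to 3.0-3.5x the background level.
    """
    if not (0.0 <= coloc_fraction <= 1.0):
        raise InputError("coloc_fraction must lie in [0, 1]")
    if n_cells < 0:
        raise InputError("n_cells must be >= 0")
    noise = noise or NoiseSpec()
    if interior_levels is None:
        interior_levels = (3.0 * noise.background_level, 3.5 * noise.background_level)
    rng = np.random.default_rng(seed)
    cells, shape = _plant_cells(
        rng, n_cells, shape, pixel_size_um, cell_radius_um,
        interior_levels, axis_ratio_max, min_spacing_um,
    )
    truth = GroundTruth(
        seed=seed, shape=shape, pixel_size_um=pixel_size_um,
        noise=noise, psf_sigma_px=psf_sigma_px, cells=cells,
    )

    pair_id = 0
    for idx, cell in enumerate(cells):
        n_foci = _foci_count(rng, foci_per_cell)
        positions = _plant_focus_positions(rng, cell, n_foci, [], focus_min_sep_px)
        for row, col in positions:
            amp = focus_amplitude * math.exp(rng.normal(0.0, focus_amp_sigma_log))
            paired = n_channels > 1 and rng.uniform() < coloc_fraction
            this_pair = pair_id if paired else None
            truth.foci.append(
                FocusTruth(row, col, 0, amp, psf_sigma_px, idx, this_pair)
            )
            if paired:
                for _ in range(100):
                    prow = row + rng.normal(0.0, jitter_sd_px)
                    pcol = col + rng.normal(0.0, jitter_sd_px)
                    if _inside_ellipse(cell, prow, pcol, scale=0.8):
                        break
                truth.foci.append(
                    FocusTruth(
                        prow, pcol, 1, amp / channel_ratio, psf_sigma_px, idx, this_pair
                    )
                )
                pair_id += 1
    if decoys_per_channel and cells:
        occupied = [(f.row, f.col) for f in truth.foci]
        for ch in range(min(n_channels, 2)):
            for _ in range(decoys_per_channel):
                cell_idx = int(rng.integers(len(cells)))
                pos = _plant_focus_positions(
                    rng, cells[cell_idx], 1, occupied, focus_min_sep_px
                )[0]
                occupied.append(pos)
                amp = focus_amplitude * math.exp(rng.normal(0.0, focus_amp_sigma_log))
                if ch == 1:
                    amp /= channel_ratio
                truth.foci.append(
                    FocusTruth(pos[0], pos[1], ch, amp, psf_sigma_px, cell_idx, None)
                )

    scene = render_scene(truth, n_channels)
    data = _apply_noise(scene, noise, rng)[:, None]  # add timepoint axis
    stack = ImageStack(data, tuple(channel_names)[:n_channels], pixel_size_um)
    return stack, truth


# ---------------------------------------------------------------------------
# droplet fields and calibration series
# ---------------------------------------------------------------------------

def generate_droplet_image(
    n_droplets: int = 50,
    radius_um=("lognormal", 1.5, 0.25),
    concentrations=(2.0, 1.0),
    ratio_ab: float | None = None,
    slopes: tuple[float, ...] = (100.0, 100.0),
    intercepts: tuple[float, ...] = (50.0, 50.0),
    noise: NoiseSpec | None = None,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    *,
    pixel_size_um: float = CONFOCAL_PIXEL_SIZE_UM,
    psf_sigma_px: float = 0.8,
    channel_names: Sequence[str] = ("mCherry", "GFP"),
) -> tuple[ImageStack, GroundTruth]:
    """Synthesize a confocal field of non-overlapping liquid droplets.

    Before blur and noise, the interior intensity of droplet d in channel c
    is ``slopes[c] * conc[d, c] + intercepts[c]`` and the background equals
    ``intercepts[c]``. Per-channel concentration entries may be scalars or
    ``("uniform", lo, hi)`` specs; when ``ratio_ab`` is set, every droplet's
    channel-0 concentration is ``ratio_ab`` times its channel-1 value.
    """
    n_channels = len(slopes)
    if len(intercepts) != n_channels:
        raise InputError("slopes and intercepts must have the same length")
    noise = noise or NoiseSpec(background_level=0.0, read_noise_sd=0.0, shot_noise=False)
    rng = np.random.default_rng(seed)
    h, w = shape

    droplets: list[DropletTruth] = []
    for _ in range(n_droplets):
        radius = _sample_radius(rng, radius_um) / pixel_size_um
        for _ in range(500):
            r0 = rng.uniform(radius + 3, h - radius - 3)
            c0 = rng.uniform(radius + 3, w - radius - 3)
            if all(
                math.hypot(r0 - d.centre[0], c0 - d.centre[1])
                > radius + d.radius_px + 2
                for d in droplets
            ):
                break
        else:
            raise PlacementError(f"could not place {n_droplets} droplets in {shape}")
        conc = []
        for c in range(n_channels):
            spec = concentrations[c] if c < len(concentrations) else concentrations[-1]
            value = _sample_radius(rng, spec)  # same scalar/spec convention
            conc.append(value)
        if ratio_ab is not None and n_channels >= 2:
            conc[0] = ratio_ab * conc[1]
        if any(v < 0 for v in conc):
            raise InputError("concentrations must be >= 0")
        droplets.append(DropletTruth((r0, c0), radius, tuple(conc)))

    scene = np.empty((n_channels, h, w), dtype=float)
    for ch in range(n_channels):
        frame = np.full((h, w), intercepts[ch], dtype=float)
        for d in droplets:
            rad = int(math.ceil(d.radius_px)) + 1
            r0, c0 = d.centre
            rlo, rhi = max(0, int(r0 - rad)), min(h, int(r0 + rad) + 1)
            clo, chi = max(0, int(c0 - rad)), min(w, int(c0 + rad) + 1)
            rr, cc = np.mgrid[rlo:rhi, clo:chi]
            inside = (rr - r0) ** 2 + (cc - c0) ** 2 < d.radius_px**2
            frame[rlo:rhi, clo:chi][inside] = (
                slopes[ch] * d.concentrations[ch] + intercepts[ch]
            )
        if psf_sigma_px > 0:
            frame = ndi.gaussian_filter(frame, psf_sigma_px, mode="nearest")
        scene[ch] = frame
    data = _apply_noise(scene, noise, rng)[:, None]
    truth = GroundTruth(
        seed=seed, shape=shape, pixel_size_um=pixel_size_um, noise=noise,
        psf_sigma_px=psf_sigma_px, droplets=droplets,
    )
    stack = ImageStack(data, tuple(channel_names)[:n_channels], pixel_size_um)
    return stack, truth


def generate_calibration_series(
    concentrations: Sequence[float],
    slope: float,
    intercept: float,
    noise: NoiseSpec | None = None,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    *,
    pixel_size_um: float = CONFOCAL_PIXEL_SIZE_UM,
    channel_name: str = "calibration",
) -> list[tuple[ImageStack, float]]:
    """Homogeneous solutions at known concentrations, one image each.

    Every image is uniform at ``slope * c + intercept`` plus the requested
    noise — the input for fitting an intensity-vs-concentration line.
    """
    if any(c < 0 for c in concentrations):
        raise InputError("concentrations must be non-negative")
    if len(set(concentrations)) < 2:
        raise InputError("need at least 2 distinct concentrations")
    noise = noise or NoiseSpec(background_level=0.0, read_noise_sd=0.0, shot_noise=False)
    rng = np.random.default_rng(seed)
    series = []
    for c in concentrations:
        scene = np.full((1, *shape), slope * c + intercept, dtype=float)
        data = _apply_noise(scene, noise, rng)[:, None]
        series.append((ImageStack(data, (channel_name,), pixel_size_um), float(c)))
    return series


# ---------------------------------------------------------------------------
# time-lapses
# ---------------------------------------------------------------------------

def generate_timelapse(
    schedule: Sequence[float],
    n_cells: int = 50,
    seed: int = 0,
    *,
    n_channels: int = 2,
    channel_ratio: float = 2.0,
    coloc_fraction: float = 1.0,
    noise: NoiseSpec | None = None,
    shape: tuple[int, int] | None = None,
    pixel_size_um: float = WIDEFIELD_PIXEL_SIZE_UM,
    time_interval_s: float = 60.0,
    focus_amplitude: float = 300.0,
    psf_sigma_px: float = 1.3,
    channel_names: Sequence[str] = DEFAULT_CHANNEL_NAMES,
    **cell_kwargs,
) -> tuple[ImageStack, list[GroundTruth]]:
    """Static cells imaged over time with scheduled expected foci per cell.

    Per frame t each cell's focus count is Poisson with mean
    ``schedule[t]``, emulating stress-induced P-body formation/dissolution
    kinetics; cells do not move or grow between frames.
    """
    if any(s < 0 for s in schedule):
        raise InputError("schedule values must be >= 0")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    interior = (3.0 * noise.background_level, 3.5 * noise.background_level)
    cells, shape = _plant_cells(
        rng, n_cells, shape, pixel_size_um,
        cell_kwargs.pop("cell_radius_um", (2.0, 3.0)), interior,
        cell_kwargs.pop("axis_ratio_max", 1.3),
        cell_kwargs.pop("min_spacing_um", 7.0),
    )
    frames = []
    truths = []
    for t, mean_foci in enumerate(schedule):
        truth = GroundTruth(
            seed=seed, shape=shape, pixel_size_um=pixel_size_um,
            noise=noise, psf_sigma_px=psf_sigma_px, cells=cells,
        )
        pair_id = 0
        for idx, cell in enumerate(cells):
            n_foci = int(rng.poisson(mean_foci))
            positions = _plant_focus_positions(rng, cell, n_foci, [], 4.0)
            for row, col in positions:
                amp = focus_amplitude * math.exp(rng.normal(0.0, 0.3))
                paired = n_channels > 1 and rng.uniform() < coloc_fraction
                truth.foci.append(
                    FocusTruth(row, col, 0, amp, psf_sigma_px, idx,
                               pair_id if paired else None)
                )
                if paired:
                    prow = row + rng.normal(0.0, 0.5)
                    pcol = col + rng.normal(0.0, 0.5)
                    truth.foci.append(
                        FocusTruth(prow, pcol, 1, amp / channel_ratio,
                                   psf_sigma_px, idx, pair_id)
                    )
                    pair_id += 1
        scene = render_scene(truth, n_channels)
        frames.append(_apply_noise(scene, noise, rng))
        truths.append(truth)
    data = np.stack(frames, axis=1)  # (C, T, H, W)
    stack = ImageStack(
        data, tuple(channel_names)[:n_channels], pixel_size_um,
        time_interval_s=time_interval_s,
    )
    return stack, truths
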