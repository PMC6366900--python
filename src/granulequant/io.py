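"""Image stacks, result tables and the shared analysis configuration.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``;
* disc/annulus membership is Euclidean distance from the centre with the
  half-open ``distance < radius`` convention;
* intensities are handled as real numbers in raw camera counts — no
  rescaling is ever applied, because calibration arithmetic needs counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError, InputError

#: micrometres per pixel for the widefield profile (100x objective, sCMOS)
WIDEFIELD_PIXEL_SIZE_UM = 0.065
#: micrometres per pixel for the confocal profile (63x oil objective)
CONFOCAL_PIXEL_SIZE_UM = 0.180


# ---------------------------------------------------------------------------
# ImageStack
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """Multi-channel, multi-timepoint grayscale image data.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_timepoints, height, width)`` with
        non-negative intensities in camera counts.
    channel_names:
        Ordered unique channel labels, e.g. ``("GFP", "mCherry")``.
    pixel_size_um:
        Physical edge length of one pixel in micrometres.
    time_interval_s:
        Seconds between consecutive frames, or ``None`` for single frames.
    bit_depth:
        Bit depth of the acquisition (8 or 16); informational only, data are
        kept as floats.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float
    time_interval_s: float | None = None
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None, None]
        elif self.data.ndim == 3:
            self.data = self.data[:, None]
        if self.data.ndim != 4:
            raise InputError(f"expected 2-4D pixel data, got {self.data.ndim}D")
        self.channel_names = tuple(self.channel_names)
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InputError("channel_names must be unique")
        if len(self.channel_names) != self.data.shape[0]:
            raise InputError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels of pixel data"
            )
        if self.pixel_size_um <= 0:
            raise InputError("pixel_size_um must be positive")
        if np.any(self.data < 0):
            raise InputError("intensities must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.data.shape[2], self.data.shape[3]

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise InputError(f"unknown channel {channel!r}") from None
        return int(channel)

    def frame(self, channel: int | str = 0, timepoint: int = 0) -> np.ndarray:
        """Return one (height, width) frame."""
        return self.data[self.channel_index(channel), timepoint]


@dataclass(frozen=True)
class StackLayout:
    """How TIFF pages map onto (channel, timepoint).

    ``order="ct"`` means channel-fastest: page index = t * n_channels + c.
    ``order="tc"`` means timepoint-fastest: page index = c * n_timepoints + t.
    """

    n_channels: int = 1
    n_timepoints: int = 1
    order: str = "ct"
    channel_names: tuple[str, ...] | None = None

    def page_index(self, channel: int, timepoint: int) -> int:
        if self.order == "ct":
            return timepoint * self.n_channels + channel
        if self.order == "tc":
            return channel * self.n_timepoints + timepoint
        raise InputError(f"unknown page order {self.order!r}")


def read_image_stack(
    path: str | Path,
    layout: StackLayout | None = None,
    pixel_size_um: float = WIDEFIELD_PIXEL_SIZE_UM,
    time_interval_s: float | None = None,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into an :class:`ImageStack`.

    Raises :class:`InputError` if the file is missing, the page count does
    not match the layout, or pages are not single-plane grayscale.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise InputError(f"{path}: expected grayscale pages, got shape {pages.shape}")
    layout = layout or StackLayout(n_channels=1, n_timepoints=pages.shape[0])
    expected = layout.n_channels * layout.n_timepoints
    if pages.shape[0] != expected:
        raise InputError(
            f"{path}: {pages.shape[0]} pages, but layout declares "
            f"{layout.n_channels} channels x {layout.n_timepoints} timepoints"
        )
    h, w = pages.shape[1:]
    data = np.empty((layout.n_channels, layout.n_timepoints, h, w), dtype=float)
    for c in range(layout.n_channels):
        for t in range(layout.n_timepoints):
            data[c, t] = pages[layout.page_index(c, t)]
    names = layout.channel_names or tuple(
        f"ch{c}" for c in range(layout.n_channels)
    )
    bit_depth = 8 if pages.dtype == np.uint8 else 16
    return ImageStack(data, names, pixel_size_um, time_interval_s, bit_depth)


def write_image_stack(stack: ImageStack, path: str | Path, layout_order: str = "ct") -> None:
    """Write a stack as a multi-page TIFF (8/16-bit unsigned, rounded).

    Page order mirrors :class:`StackLayout` with the given ``order`` so that
    write -> read is the identity on integral pixel data.
    """
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    layout = StackLayout(stack.n_channels, stack.n_timepoints, layout_order)
    n_pages = stack.n_channels * stack.n_timepoints
    pages = np.empty((n_pages, *stack.shape), dtype=dtype)
    limit = float(np.iinfo(dtype).max)
    for c in range(stack.n_channels):
        for t in range(stack.n_timepoints):
            pages[layout.page_index(c, t)] = np.clip(
                np.rint(stack.data[c, t]), 0, limit
            ).astype(dtype)
    tifffile.imwrite(Path(path), pages)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results_table(records: Sequence[Mapping], path: str | Path) -> None:
    """Persist uniform keyed records as a tab-separated UTF-8 table.

    Numeric fields are rendered with full (round-trippable) precision.
    """
    if not records:
        raise InputError("cannot write an empty results table")
    keys = list(records[0].keys())
    for i, rec in enumerate(records):
        if list(rec.keys()) != keys:
            raise InputError(f"record {i} keys differ from record 0")
    df = pd.DataFrame.from_records(list(records), columns=keys)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such table: {path}")
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class SegmentationParams:
    """Cell segmentation by Laplacian edges + inward normal voting."""

    edge_sigma_px: float = 2.0          # LoG smoothing scale
    magnitude_quantile: float = 0.9     # keep edges above this gradient quantile
    r_min_um: float = 1.5               # smallest expected cell radius
    r_max_um: float = 3.5               # largest expected cell radius
    min_votes: float | None = None      # default: 0.05 * 2*pi*r_min_px at use time
    nms_radius_px: float | None = None  # default: r_max_px at use time
    accumulator_sigma_px: float = 4.0
    min_cell_area_um2: float = 6.0
    max_cell_area_um2: float = 60.0
    exclude_border: bool = True


@dataclass
class FocusParams:
    """Focus detection: local maxima + intensity/contrast thresholds."""

    maxima_radius_px: float = 3.0
    detection_sigma_px: float = 1.0     # matched-filter smoothing before detection
    intensity_min: float | None = None  # absolute; default = local significance
    local_significance: float = 6.0     # peak >= annulus median + n*MAD-sd
    contrast_min: float = 0.05          # retention cutoff on (peak-bg)/bg
    r_int_px: float = 3.0               # measurement disc radius
    r_bg_in_px: float = 4.0             # background annulus inner radius
    r_bg_out_px: float = 7.0            # background annulus outer radius


@dataclass
class ColocParams:
    d_max_um: float = 0.25  # max centroid distance for cross-channel matching


@dataclass
class StoichParams:
    k_brightest: int = 10
    pool_first: bool = False  # pool foci across images before ranking


@dataclass
class DropletParams:
    threshold_method: str = "otsu"  # or "fixed:<value>"
    min_droplet_area_px: int = 9
    background_mode: str = "median"
    measure_erosion_px: int = 1  # erode components before measuring means


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline, grouped by stage."""

    pixel_size_um: float = WIDEFIELD_PIXEL_SIZE_UM
    rng_seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    focus: FocusParams = field(default_factory=FocusParams)
    coloc: ColocParams = field(default_factory=ColocParams)
    stoichiometry: StoichParams = field(default_factory=StoichParams)
    droplet: DropletParams = field(default_factory=DropletParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seg, foc = self.segmentation, self.focus
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if not (seg.r_max_um > seg.r_min_um > 0):
            raise ConfigError("segmentation: requires r_max_um > r_min_um > 0")
        if seg.edge_sigma_px <= 0:
            raise ConfigError("segmentation.edge_sigma_px must be > 0")
        if not (0 < seg.magnitude_quantile < 1):
            raise ConfigError("segmentation.magnitude_quantile must lie in (0, 1)")
        if seg.min_cell_area_um2 >= seg.max_cell_area_um2:
            raise ConfigError("segmentation: min_cell_area_um2 must be < max_cell_area_um2")
        if foc.contrast_min < 0:
            raise ConfigError("focus.contrast_min must be >= 0")
        if not (foc.r_bg_out_px > foc.r_bg_in_px >= foc.r_int_px > 0):
            raise ConfigError("focus: requires r_bg_out_px > r_bg_in_px >= r_int_px > 0")
        if foc.maxima_radius_px < 1:
            raise ConfigError("focus.maxima_radius_px must be >= 1")
        if self.coloc.d_max_um <= 0:
            raise ConfigError("coloc.d_max_um must be > 0")
        if self.stoichiometry.k_brightest < 1:
            raise ConfigError("stoichiometry.k_brightest must be >= 1")
        if self.droplet.min_droplet_area_px < 1:
            raise ConfigError("droplet.min_droplet_area_px must be >= 1")
        method = self.droplet.threshold_method
        if method != "otsu" and not method.startswith("fixed:"):
            raise ConfigError(
                "droplet.threshold_method must be 'otsu' or 'fixed:<value>'"
            )

    @classmethod
    def widefield(cls, **overrides) -> "AnalysisConfig":
        return cls(pixel_size_um=WIDEFIELD_PIXEL_SIZE_UM, **overrides)

    @classmethod
    def confocal(cls, **overrides) -> "AnalysisConfig":
        return cls(pixel_size_um=CONFOCAL_PIXEL_SIZE_UM, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_BLOCKS = {
    "segmentation": SegmentationParams,
    "focus": FocusParams,
    "coloc": ColocParams,
    "stoichiometry": StoichParams,
    "droplet": DropletParams,
}
_SCALARS = {"pixel_size_um", "rng_seed"}


def config_from_dict(raw: Mapping) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from nested plain dictionaries.

    Unknown keys (at either level) are rejected so typos never silently
    fall back to defaults; missing keys take the documented defaults.
    """
    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SCALARS:
            kwargs[key] = value
        elif key in _BLOCKS:
            cls = _BLOCKS[key]
            valid = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - valid
            if unknown:
                raise ConfigError(
                    f"unknown key(s) in block '{key}': {sorted(unknown)}"
                )
            kwargs[key] = cls(**value)
        else:
            raise ConfigError(f"unknown config key: {key!r}")
    return AnalysisConfig(**kwargs)


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a YAML configuration file; see :func:`config_from_dict`."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: config must be a mapping of blocks")
    return config_from_dict(raw)


def dump_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write a config as YAML such that :func:`load_config` reproduces it."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
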