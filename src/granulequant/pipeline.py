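"""End-to-end orchestration of the quantification stages.

Composes segmentation, focus detection, colocalization and the
stoichiometry/droplet statistics into the per-image and per-timepoint
tables the downstream figures need, and provides a seeded self-test that
exercises every stage against planted ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .errors import InputError
from .droplets import (
    CalibrationCurve,
    droplet_metric,
    droplet_stoichiometry,
    fit_calibration,
    normalize_metric,
    segment_droplets,
)
from .foci import assign_foci_to_cells, detect_foci, match_foci_channels
from .io import AnalysisConfig, ImageStack
from .segmentation import count_cells, segment_cells
from .stoichiometry import ratio_timecourse


def subseed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the manifest seed.

    Hash-based so that rerunning one stage alone reproduces its stream.
    Kept below 2**31 for portability.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunManifest:
    """Reproducibility record attached to every pipeline run."""

    config: dict
    rng_seed: int
    tool_version: str = __version__
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_input(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.inputs[str(path)] = digest

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def quantify_image(
    stack: ImageStack,
    config: AnalysisConfig,
    name: str = "image",
    timepoint: int = 0,
) -> dict:
    """All per-image quantities for one timepoint of one stack.

    Cells are segmented on channel 0 (cytoplasmic fluorescence); foci are
    detected per channel; with two channels, foci are matched and the
    colocalized count is the headline "PB" count divided by the cell count.
    With one channel the channel-0 focus count is used instead.
    """
    frame0 = stack.frame(0, timepoint)
    label_map = segment_cells(frame0, config)
    n_cells = count_cells(label_map)
    record: dict = {"image": name, "timepoint": timepoint, "n_cells": n_cells}

    foci_by_channel = {}
    for ch_name in stack.channel_names:
        foci = detect_foci(stack.frame(ch_name, timepoint), config, ch_name, timepoint)
        foci = assign_foci_to_cells(foci, label_map)
        foci_by_channel[ch_name] = foci
        record[f"n_foci_{ch_name}"] = len(foci)

    if stack.n_channels >= 2:
        a, b = stack.channel_names[:2]
        matches = match_foci_channels(
            foci_by_channel[a], foci_by_channel[b],
            config.coloc.d_max_um, stack.pixel_size_um,
        )
        record["n_colocalized"] = len(matches)
        pb_count = len(matches)
    else:
        record["n_colocalized"] = record[f"n_foci_{stack.channel_names[0]}"]
        pb_count = record["n_colocalized"]

    if n_cells > 0:
        record["pbs_per_cell"] = pb_count / n_cells
        record["excluded"] = False
        record["exclusion_reason"] = ""
    else:
        record["pbs_per_cell"] = math.nan
        record["excluded"] = True
        record["exclusion_reason"] = "no cells segmented"
    record["_foci"] = foci_by_channel  # stripped before table output
    return record


def run_pb_quantification(
    stacks: Mapping[str, ImageStack] | Sequence[ImageStack],
    config: AnalysisConfig,
    manifest: RunManifest | None = None,
) -> tuple[list[dict], list[dict]]:
    """P-body quantification over a dataset of image stacks.

    Returns (per_image_records, per_timepoint_records). Every timepoint of
    every stack yields one per-image record; the per-timepoint summary is
    the mean +/- SEM of PBs-per-cell across images, skipping images
    excluded for having no cells (recorded as warnings).
    """
    if not stacks:
        raise InputError("empty dataset")
    if not isinstance(stacks, Mapping):
        stacks = {f"image_{i:03d}": s for i, s in enumerate(stacks)}
    t0 = time.perf_counter()
    per_image: list[dict] = []
    for name, stack in stacks.items():
        for t in range(stack.n_timepoints):
            rec = quantify_image(stack, config, name, t)
            rec.pop("_foci")
            per_image.append(rec)
            if rec["excluded"] and manifest is not None:
                manifest.warnings.append(
                    f"{name} t={t}: excluded ({rec['exclusion_reason']})"
                )
    per_timepoint: list[dict] = []
    for t in sorted({r["timepoint"] for r in per_image}):
        values = [
            r["pbs_per_cell"] for r in per_image
            if r["timepoint"] == t and not r["excluded"]
        ]
        n = len(values)
        mean = float(np.mean(values)) if n else math.nan
        sem = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        per_timepoint.append(
            {
                "timepoint": t,
                "n_images": n,
                "pbs_per_cell_mean": mean,
                "pbs_per_cell_sem": sem,
                "n_excluded": sum(
                    r["timepoint"] == t and r["excluded"] for r in per_image
                ),
            }
        )
    if manifest is not None:
        manifest.timings_s["pb_quantification"] = time.perf_counter() - t0
    return per_image, per_timepoint


def run_droplet_quantification(
    conditions: Mapping[str, Sequence[ImageStack]],
    config: AnalysisConfig,
    calibrations: Mapping[str, CalibrationCurve] | None = None,
    reference_condition: str | None = None,
    manifest: RunManifest | None = None,
) -> tuple[list[dict], list[dict], dict]:
    """Droplet quantification over named conditions.

    Returns (per_droplet_records, per_condition_metric_records,
    stoichiometry_by_condition). The condensation metric (sum of
    background-subtracted mean intensity x area) is computed per field and
    channel; with a reference condition it is normalized per channel to
    that condition's mean. Concentrations and A:B ratios are computed when
    calibration curves for the first two channels are supplied.
    """
    if not conditions:
        raise InputError("no conditions supplied")
    if reference_condition is not None and reference_condition not in conditions:
        raise InputError(f"reference condition {reference_condition!r} absent")
    t0 = time.perf_counter()
    per_droplet: list[dict] = []
    metric_rows: list[dict] = []
    records_by_condition: dict[str, list] = {}
    for cond, stacks in conditions.items():
        all_records = []
        for i, stack in enumerate(stacks):
            _, records = segment_droplets(stack, config)
            all_records.extend(records)
            for rec in records:
                row = {
                    "condition": cond,
                    "field": i,
                    "label": rec.label,
                    "area_px": rec.area_px,
                    "area_um2": rec.area_um2,
                    "equivalent_diameter_um": rec.equivalent_diameter_um,
                }
                for name in stack.channel_names:
                    row[f"mean_intensity_{name}"] = rec.mean_intensity[name]
                per_droplet.append(row)
            for name in stack.channel_names:
                metric_rows.append(
                    {
                        "condition": cond,
                        "field": i,
                        "channel": name,
                        "metric": droplet_metric(records, name),
                    }
                )
        records_by_condition[cond] = all_records

    per_condition: list[dict] = []
    channels = sorted({m["channel"] for m in metric_rows})
    reference_means = {}
    if reference_condition is not None:
        for ch in channels:
            values = [
                m["metric"] for m in metric_rows
                if m["condition"] == reference_condition and m["channel"] == ch
            ]
            ref = float(np.mean(values))
            if ref <= 0:
                raise InputError(
                    f"reference condition metric must be > 0 (channel {ch})"
                )
            reference_means[ch] = ref
    for cond in conditions:
        for ch in channels:
            values = [
                m["metric"] for m in metric_rows
                if m["condition"] == cond and m["channel"] == ch
            ]
            row = {
                "condition": cond,
                "channel": ch,
                "metric_mean": float(np.mean(values)),
                "metric_sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
                "n_fields": len(values),
            }
            if reference_means:
                row["normalized_mean"] = float(
                    np.mean(normalize_metric(values, reference_means[ch]))
                )
            per_condition.append(row)

    stoich: dict = {}
    if calibrations and len(channels) >= 2:
        ch_a, ch_b = list(calibrations)[:2]
        for cond, records in records_by_condition.items():
            if not records:
                continue
            summary = droplet_stoichiometry(
                records, calibrations[ch_a], calibrations[ch_b], ch_a, ch_b
            )
            stoich[cond] = summary
    if manifest is not None:
        manifest.timings_s["droplet_quantification"] = time.perf_counter() - t0
    return per_droplet, per_condition, stoich


# ---------------------------------------------------------------------------
# self-test
# ---------------------------------------------------------------------------

def run_end_to_end_selftest(seed: int = 0, config: AnalysisConfig | None = None) -> dict:
    """Generate small ground-truthed scenes and check every stage.

    Returns {check_name: {"passed": bool, "value": float}}; failures are
    reported, never raised, and the report is deterministic under the seed.
    """
    from .simulate import (
        NoiseSpec,
        generate_calibration_series,
        generate_cell_field,
        generate_droplet_image,
    )

    config = config or AnalysisConfig()
    report: dict[str, dict] = {}

    def check(name: str, passed: bool, value: float) -> None:
        report[name] = {"passed": bool(passed), "value": float(value)}

    def guarded(names: Sequence[str], fn) -> None:
        """A stage error marks its checks failed instead of aborting."""
        try:
            fn()
        except Exception:
            for name in names:
                if name not in report:
                    check(name, False, math.nan)

    def _cells() -> None:
        hits = trials = 0
        for i in range(3):
            stack, _ = generate_cell_field(
                n_cells=5, foci_per_cell=2.0, seed=subseed(seed, f"cells{i}")
            )
            hits += count_cells(segment_cells(stack.frame(0), config)) == 5
            trials += 1
        check("cell_count_recovery", hits == trials, hits / trials)

    guarded(["cell_count_recovery"], _cells)

    def _foci() -> None:
        # focus precision/recall on one field
        stack, truth = generate_cell_field(
            n_cells=8, foci_per_cell=3, n_channels=1, coloc_fraction=0.0,
            seed=subseed(seed, "foci"), focus_amplitude=300.0,
        )
        found = detect_foci(stack.frame(0), config)
        planted = [(f.row, f.col) for f in truth.foci]
        matched = set()
        n_fp = 0
        for f in found:
            ds = [
                (math.hypot(f.row - r, f.col - c), i)
                for i, (r, c) in enumerate(planted) if i not in matched
            ]
            d, i = min(ds) if ds else (math.inf, None)
            if d <= 2:
                matched.add(i)
            else:
                n_fp += 1
        precision = len(matched) / max(len(matched) + n_fp, 1)
        recall = len(matched) / max(len(planted), 1)
        check("focus_precision", precision >= 0.95, precision)
        check("focus_recall", recall >= 0.95, recall)

    guarded(["focus_precision", "focus_recall"], _foci)

    def _coloc() -> None:
        # colocalization on a paired field with decoys
        stack, truth = generate_cell_field(
            n_cells=10, foci_per_cell=2, coloc_fraction=1.0, decoys_per_channel=5,
            seed=subseed(seed, "coloc"), focus_amplitude=600.0,
            focus_amp_sigma_log=0.15, focus_min_sep_px=6.0,
        )
        fa = detect_foci(stack.frame(0), config, channel=0)
        fb = detect_foci(stack.frame(1), config, channel=1)
        matches = match_foci_channels(
            fa, fb, config.coloc.d_max_um, stack.pixel_size_um
        )
        n_pairs = len({f.pair_id for f in truth.foci if f.pair_id is not None})
        check(
            "colocalization_pairs",
            len(matches) == n_pairs,
            len(matches) / max(n_pairs, 1),
        )

    guarded(["colocalization_pairs"], _coloc)

    def _ratio() -> None:
        # in vivo ratio recovery at planted ratio 2
        rho = 2.0
        imgs_a, imgs_b = [], []
        for i in range(4):
            sa, _ = generate_cell_field(
                n_cells=5, foci_per_cell=3, n_channels=1,
                seed=subseed(seed, f"ratioA{i}"), focus_amplitude=300.0 * rho,
            )
            sb, _ = generate_cell_field(
                n_cells=5, foci_per_cell=3, n_channels=1,
                seed=subseed(seed, f"ratioB{i}"), focus_amplitude=300.0,
            )
            imgs_a.append(detect_foci(sa.frame(0), config))
            imgs_b.append(detect_foci(sb.frame(0), config))
        result = ratio_timecourse(
            {0.0: imgs_a}, {0.0: imgs_b}, k=config.stoichiometry.k_brightest
        )
        ratio = result[0].ratio
        check("invivo_ratio_recovery", abs(ratio / rho - 1) <= 0.10, ratio)

    guarded(["invivo_ratio_recovery"], _ratio)

    def _droplets() -> None:
        # calibration + droplet stoichiometry round trip
        series = generate_calibration_series(
            [0, 1, 2, 3, 4, 5], slope=100.0, intercept=50.0,
            noise=NoiseSpec(0.0, 1.0, False), seed=subseed(seed, "calib"),
        )
        curve = fit_calibration([(c, float(s.frame(0).mean())) for s, c in series])
        check("calibration_slope", abs(curve.slope / 100.0 - 1) <= 0.03, curve.slope)
        stack, _ = generate_droplet_image(
            n_droplets=30, ratio_ab=2.7, concentrations=(2.0, ("uniform", 0.8, 1.5)),
            noise=NoiseSpec(0.0, 5.0, False), seed=subseed(seed, "droplets"),
        )
        _, records = segment_droplets(stack, config)
        summary = droplet_stoichiometry(records, curve, curve, "mCherry", "GFP")
        check(
            "invitro_ratio_recovery",
            abs(summary.mean_ratio / 2.7 - 1) <= 0.10,
            summary.mean_ratio,
        )

    guarded(["calibration_slope", "invitro_ratio_recovery"], _droplets)

    def _metric() -> None:
        # metric doubling: twice the droplets -> about twice the metric;
        # fixed radius so the only variability is measurement noise
        s1, _ = generate_droplet_image(
            n_droplets=20, radius_um=1.5, concentrations=(2.0, 1.0),
            noise=NoiseSpec(0.0, 5.0, False), seed=subseed(seed, "metric1"),
        )
        s2, _ = generate_droplet_image(
            n_droplets=40, radius_um=1.5, concentrations=(2.0, 1.0),
            noise=NoiseSpec(0.0, 5.0, False), seed=subseed(seed, "metric2"),
        )
        m1 = droplet_metric(segment_droplets(s1, config)[1], "mCherry")
        m2 = droplet_metric(segment_droplets(s2, config)[1], "mCherry")
        check("metric_doubling", abs(m2 / m1 / 2.0 - 1) <= 0.10, m2 / m1)

    guarded(["metric_doubling"], _metric)

    def _determinism() -> None:
        def one_run():
            stack, _ = generate_cell_field(
                n_cells=5, foci_per_cell=2, seed=subseed(seed, "determinism")
            )
            per_image, _ = run_pb_quantification([stack], config)
            return per_image
        check("determinism", one_run() == one_run(), 1.0)

    guarded(["determinism"], _determinism)

    return report
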