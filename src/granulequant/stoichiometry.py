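"""In vivo stoichiometry from focus intensities.

Two strains carrying the same fluorophore on different P-body components are
imaged under identical conditions, so intensity ratios read out abundance
ratios directly, with no spectral correction. Per image the k brightest
foci (default k = 10) are ranked by background-corrected integrated
intensity; the median of the pooled top-k intensities represents the
condition, and the ratio of the two condition medians is reported per
timepoint of the starvation time course.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError
from .foci import Focus


def _intensities(foci: Iterable[Focus | float]) -> np.ndarray:
    values = [
        f.integrated_intensity if isinstance(f, Focus) else float(f) for f in foci
    ]
    return np.asarray(values, dtype=float)


def top_k_median(
    foci: Sequence[Focus | float], k: int, allow_fewer: bool = False
) -> float:
    """Median intensity of the k brightest foci.

    Foci are ranked by background-corrected integrated intensity, the top k
    taken, and their median returned (mean of the central pair for even k).
    Fewer than k foci is an error unless ``allow_fewer`` is explicitly set,
    in which case all foci are used — callers must flag that in output.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    values = _intensities(foci)
    if len(values) < k:
        if not allow_fewer:
            raise InputError(
                f"need at least k={k} foci, got {len(values)} "
                f"(short by {k - len(values)})"
            )
        if len(values) == 0:
            raise InputError("no foci at all")
        k = len(values)
    top = np.sort(values)[::-1][:k]
    return float(np.median(top))


@dataclass
class StoichiometryResult:
    """Per-timepoint ratio of top-k median intensities between two strains."""

    timepoint: float
    value_a: float
    value_b: float
    ratio: float
    dispersion: float | None
    k_used: int
    n_foci_a: int
    n_foci_b: int
    used_fewer: bool = False


def _condition_median(
    images: Sequence[Sequence[Focus | float]],
    k: int,
    pool_first: bool,
    allow_fewer: bool,
) -> tuple[float, int, bool]:
    """Pool the per-image top-k intensities, return their median.

    With ``pool_first`` all foci are pooled across images before a single
    top-k ranking — the alternative reading of "the 10 brightest PBs".
    """
    if not images:
        raise InputError("no images for this timepoint")
    used_fewer = False
    if pool_first:
        pooled = np.concatenate([_intensities(img) for img in images]) if images else np.array([])
        n = len(pooled)
        if n < k:
            if not allow_fewer:
                raise InputError(f"pooled foci ({n}) fewer than k={k}")
            used_fewer = True
        top = np.sort(pooled)[::-1][: min(k, n)]
        return float(np.median(top)), n, used_fewer
    tops = []
    n_total = 0
    for img in images:
        values = _intensities(img)
        n_total += len(values)
        if len(values) < k:
            if not allow_fewer:
                raise InputError(
                    f"an image has {len(values)} foci, fewer than k={k}"
                )
            used_fewer = True
        tops.append(np.sort(values)[::-1][: min(k, len(values))])
    pooled_tops = np.concatenate(tops)
    return float(np.median(pooled_tops)), n_total, used_fewer


def ratio_timecourse(
    series_a: Mapping[float, Sequence[Sequence[Focus | float]]],
    series_b: Mapping[float, Sequence[Sequence[Focus | float]]],
    k: int = 10,
    pool_first: bool = False,
    allow_fewer: bool = False,
    replicates_a: Mapping[float, Sequence] | None = None,
    replicates_b: Mapping[float, Sequence] | None = None,
) -> list[StoichiometryResult]:
    """Ratio of top-k median intensities per timepoint, strain A over B.

    ``series_*`` map timepoint -> list of images, each a list of foci (or
    plain intensities). Both series must cover the same timepoint grid.
    When replicate labels are given (one per image, aligned), the dispersion
    is the standard error over replicate-level ratios.
    """
    if set(series_a) != set(series_b):
        missing = set(series_a) ^ set(series_b)
        raise InputError(f"timepoint grids differ (unmatched: {sorted(missing)})")
    results = []
    for t in sorted(series_a):
        med_a, n_a, few_a = _condition_median(series_a[t], k, pool_first, allow_fewer)
        med_b, n_b, few_b = _condition_median(series_b[t], k, pool_first, allow_fewer)
        if med_b == 0:
            raise InputError(f"timepoint {t}: zero median intensity in series B")
        dispersion = None
        if replicates_a is not None and replicates_b is not None:
            dispersion = _replicate_sem(
                series_a[t], replicates_a[t], series_b[t], replicates_b[t],
                k, pool_first, allow_fewer,
            )
        results.append(
            StoichiometryResult(
                timepoint=t,
                value_a=med_a,
                value_b=med_b,
                ratio=med_a / med_b,
                dispersion=dispersion,
                k_used=k,
                n_foci_a=n_a,
                n_foci_b=n_b,
                used_fewer=few_a or few_b,
            )
        )
    return results


def _replicate_sem(images_a, labels_a, images_b, labels_b, k, pool_first, allow_fewer):
    """SEM across replicate-level ratios (replicates shared between strains)."""
    groups_a: dict = {}
    groups_b: dict = {}
    for img, lab in zip(images_a, labels_a):
        groups_a.setdefault(lab, []).append(img)
    for img, lab in zip(images_b, labels_b):
        groups_b.setdefault(lab, []).append(img)
    common = sorted(set(groups_a) & set(groups_b))
    if len(common) < 2:
        return None
    ratios = []
    for lab in common:
        ma, _, _ = _condition_median(groups_a[lab], k, pool_first, allow_fewer)
        mb, _, _ = _condition_median(groups_b[lab], k, pool_first, allow_fewer)
        ratios.append(ma / mb)
    return float(np.std(ratios, ddof=1) / np.sqrt(len(ratios)))


@dataclass
class IntensitySummary:
    n: int
    mean: float
    median: float
    q25: float
    q75: float


def intensity_distribution(foci: Sequence[Focus | float]) -> IntensitySummary:
    """Summary statistics of integrated focus intensities."""
    values = _intensities(foci)
    if len(values) == 0:
        raise InputError("cannot summarise an empty focus list")
    return IntensitySummary(
        n=len(values),
        mean=float(np.mean(values)),
        median=float(np.median(values)),
        q25=float(np.percentile(values, 25)),
        q75=float(np.percentile(values, 75)),
    )


def fold_change(summary_a: IntensitySummary, summary_b: IntensitySummary) -> float:
    """Median fold change between two intensity distributions (A over B)."""
    if summary_b.median == 0:
        raise InputError("zero median in denominator distribution")
    return summary_a.median / summary_b.median
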