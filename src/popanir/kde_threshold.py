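"""KDE-based selection of the target-population identity threshold.

The distribution of per-read percent identities against a reference genome
is frequently multimodal: the peak nearest 100% identity corresponds to the
sequence-discrete target population, while lower-identity peaks betray
co-occurring relatives recruiting reads by partial similarity. A Gaussian
kernel density estimate is fitted to the identities and the local minima of
the density (the "valleys" separating peaks) are located as peaks of the
negated curve. The valley closest to 100% identity, plus a conservative
valley modifier (default +3 percentage points, compensating for the lag the
kernel smoothing introduces), becomes the read-selection threshold: reads at
or above it are attributed to the target population.

When the distribution is unimodal (a clonal population with no detectable
relatives) there is no valley; a configurable static cutoff (default 95%
nucleotide identity, the conventional species-level value) is used instead
and flagged via ``fallback_used``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
from scipy import signal, stats

from .alignment_io import AlignmentRecord

__all__ = [
    "IdentitySample",
    "KdeCurve",
    "ThresholdResult",
    "DegenerateSampleError",
    "fit_identity_kde",
    "locate_minima",
    "select_population_threshold",
    "filter_target_reads",
    "derive_threshold",
    "write_threshold_report",
    "DEFAULT_BANDWIDTH",
    "DEFAULT_VALLEY_MODIFIER",
    "DEFAULT_FALLBACK_THRESHOLD",
]

#: Default KDE bandwidth, as a scaling factor on the sample standard
#: deviation (the scipy ``gaussian_kde`` convention). 0.25 works well for
#: blastn identities spanning the typical 70–100% range.
DEFAULT_BANDWIDTH = 0.25
#: Percentage points added to the chosen valley; the KDE valley lags the
#: histogram, so the shift gives a more conservative read selection.
DEFAULT_VALLEY_MODIFIER = 3.0
#: Static cutoff used when the density has no interior valley (clonal case).
DEFAULT_FALLBACK_THRESHOLD = 95.0
DEFAULT_GRID_STEP = 0.01


class DegenerateSampleError(ValueError):
    """Fewer than two distinct identity values: no density can be fitted."""


@dataclass(frozen=True)
class IdentitySample:
    """Per-read identities of one (genome, sample) pair."""

    identities: np.ndarray
    genome_id: str = ""
    sample_id: str = ""

    def __len__(self) -> int:
        return len(self.identities)


@dataclass(frozen=True)
class KdeCurve:
    """A fitted identity density on a regular grid.

    ``bandwidth`` is the smoothing factor as supplied; ``kernel_width`` is
    the resulting absolute kernel standard deviation in percentage points
    (factor × sample standard deviation), recorded so users can fix either.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    kernel_width: float


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of valley detection and threshold selection."""

    minima: tuple[float, ...]
    chosen_minimum: float | None
    valley_modifier: float
    threshold: float
    fallback_used: bool


def fit_identity_kde(
    sample: IdentitySample | np.ndarray | Sequence[float],
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_step: float = DEFAULT_GRID_STEP,
    floor: float = 70.0,
) -> KdeCurve:
    """Fit a Gaussian KDE to read identities on the regular [floor, 100] grid.

    The density is renormalized to unit trapezoid integral over the grid
    (the kernel leaks a little mass past the 100% boundary for reads pinned
    against it; renormalization is a uniform scale and cannot move extrema).
    """
    values = np.asarray(
        sample.identities if isinstance(sample, IdentitySample) else sample, dtype=float
    )
    if values.size < 2 or np.unique(values).size < 2:
        raise DegenerateSampleError(
            "need at least two distinct identity values to fit a density"
        )
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    kde = stats.gaussian_kde(values, bw_method=bandwidth)
    n_points = int(round((100.0 - floor) / grid_step)) + 1
    grid = np.linspace(floor, 100.0, n_points)
    density = kde(grid)
    area = np.trapezoid(density, grid)
    if area > 0:
        density = density / area
    kernel_width = float(kde.factor * values.std(ddof=1))
    return KdeCurve(grid=grid, density=density, bandwidth=float(bandwidth),
                    kernel_width=kernel_width)


def locate_minima(curve: KdeCurve) -> np.ndarray:
    """Identity values of the interior local minima of the density.

    Found as local maxima of the negated density (plateaus resolve to the
    plateau midpoint); grid endpoints are never reported.
    """
    idx, _ = signal.find_peaks(-curve.density)
    return curve.grid[idx]


def select_population_threshold(
    minima: Sequence[float] | np.ndarray,
    valley_modifier: float = DEFAULT_VALLEY_MODIFIER,
    fallback: float = DEFAULT_FALLBACK_THRESHOLD,
) -> ThresholdResult:
    """Turn detected valleys into the target-population identity cutoff.

    The valley closest to 100% identity is chosen and the valley modifier is
    added (capped at 100). With no valley at all, the static ``fallback``
    cutoff is used and flagged.
    """
    minima = tuple(float(m) for m in minima)
    if minima:
        chosen = max(minima)
        threshold = min(100.0, chosen + valley_modifier)
        return ThresholdResult(
            minima=minima,
            chosen_minimum=chosen,
            valley_modifier=valley_modifier,
            threshold=threshold,
            fallback_used=False,
        )
    return ThresholdResult(
        minima=(),
        chosen_minimum=None,
        valley_modifier=valley_modifier,
        threshold=float(fallback),
        fallback_used=True,
    )


def filter_target_reads(
    records: Iterable[AlignmentRecord], threshold: float
) -> list[AlignmentRecord]:
    """Retain records with identity >= threshold (order preserved)."""
    return [r for r in records if r.identity >= threshold]


def derive_threshold(
    sample: IdentitySample | np.ndarray | Sequence[float],
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_step: float = DEFAULT_GRID_STEP,
    valley_modifier: float = DEFAULT_VALLEY_MODIFIER,
    fallback: float = DEFAULT_FALLBACK_THRESHOLD,
    floor: float = 70.0,
) -> tuple[KdeCurve | None, ThresholdResult]:
    """Fit, locate valleys and select the threshold in one call.

    A degenerate sample (all identities equal) has no density to fit and
    drops straight to the fallback cutoff.
    """
    try:
        curve = fit_identity_kde(sample, bandwidth=bandwidth, grid_step=grid_step,
                                 floor=floor)
    except DegenerateSampleError:
        return None, select_population_threshold(
            (), valley_modifier=valley_modifier, fallback=fallback
        )
    minima = locate_minima(curve)
    return curve, select_population_threshold(
        minima, valley_modifier=valley_modifier, fallback=fallback
    )


def write_threshold_report(
    rows: Iterable[tuple[str, str, int, ThresholdResult]],
    dest: Union[str, Path, TextIO],
    header_lines: Sequence[str] = (),
) -> None:
    """Write a TSV threshold report; rows are (genome, sample, n_reads, result)."""
    if isinstance(dest, (str, Path)):
        handle: TextIO = open(dest, "w")
        close = True
    else:
        handle, close = dest, False
    try:
        for line in header_lines:
            handle.write(f"# {line}\n")
        handle.write(
            "genome_id\tsample_id\tn_reads\tminima\tchosen_minimum\t"
            "modifier\tthreshold\tfallback_used\n"
        )
        for genome_id, sample_id, n_reads, result in rows:
            minima = ",".join(f"{m:.2f}" for m in result.minima)
            chosen = "" if result.chosen_minimum is None else f"{result.chosen_minimum:.2f}"
            handle.write(
                f"{genome_id}\t{sample_id}\t{n_reads}\t{minima}\t{chosen}\t"
                f"{result.valley_modifier:g}\t{result.threshold:.2f}\t"
                f"{result.fallback_used}\n"
            )
    finally:
        if close:
            handle.close()
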