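"""Coverage and identity metrics of a target population in one sample.

Metrics computed from the reads attributed to the target population (those
at or above the KDE-derived identity threshold):

- **ANIr** — mean percent identity of the target reads; **mANIr** — their
  median, more robust to the long low-identity tails short reads produce.
- **depth** — mean per-base sequencing depth (total aligned reference bases
  over genome length).
- **breadth** — fraction of nonredundant reference bases covered by at
  least one target read; a population is considered robustly detected when
  breadth >= 10%.
- **EMR** (exact match ratio) — reads at >=99% identity over reads between
  the threshold and 99%; higher means more clonal relative to the reference.

Below-detection metrics are computed and flagged rather than withheld, so
downstream significance tests can refuse them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np

from .alignment_io import AlignmentRecord, ReferenceIndex
from .kde_threshold import filter_target_reads

__all__ = [
    "PopulationMetrics",
    "UndefinedMetricError",
    "compute_anir_manir",
    "compute_breadth",
    "compute_depth",
    "compute_emr",
    "assess_detection",
    "summarize_population",
    "write_metrics_report",
    "DETECTION_BREADTH",
]

#: Minimum sequencing breadth for robust detection of a reference genome.
DETECTION_BREADTH = 0.10


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested for an empty read set."""


@dataclass(frozen=True)
class PopulationMetrics:
    """All per-(genome, sample) population metrics in one record.

    ``anir``/``manir`` are ``None`` when no target reads exist; ``emr`` is
    ``None`` whenever its denominator (reads below 99% identity) is zero.
    """

    genome_id: str
    sample_id: str
    n_target_reads: int
    anir: float | None
    manir: float | None
    depth: float
    breadth: float
    emr: float | None
    detected: bool
    threshold_used: float
    fallback_used: bool = False


def compute_anir_manir(identities: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Mean (ANIr) and median (mANIr) of target-read identities."""
    values = np.asarray(identities, dtype=float)
    if values.size == 0:
        raise UndefinedMetricError("ANIr/mANIr undefined for an empty read set")
    return float(values.mean()), float(np.median(values))


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total length of the union of half-open intervals (vectorized sweep)."""
    order = np.argsort(starts, kind="stable")
    s = starts[order]
    e = ends[order]
    running = np.empty_like(e)
    running[0] = s[0]  # nothing covered before the first interval
    np.maximum.accumulate(e[:-1], out=running[1:])
    covered = np.clip(e - np.maximum(s, running), 0, None)
    return int(covered.sum())


def compute_breadth(
    records: Sequence[AlignmentRecord], reference: ReferenceIndex
) -> float:
    """Fraction of unique (nonredundant) reference bases covered by reads."""
    if not records:
        return 0.0
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        by_contig.setdefault(r.contig_id, []).append((r.ref_start, r.ref_end))
    covered = 0
    for intervals in by_contig.values():
        arr = np.asarray(intervals, dtype=np.int64)
        covered += _union_length(arr[:, 0], arr[:, 1])
    return covered / reference.total_length


def compute_depth(
    records: Sequence[AlignmentRecord], reference: ReferenceIndex
) -> float:
    """Mean per-base sequencing depth: aligned reference bases / genome length."""
    aligned = sum(r.ref_end - r.ref_start for r in records)
    return aligned / reference.total_length


def compute_emr(
    identities: Sequence[float] | np.ndarray, threshold: float
) -> float | None:
    """Exact match ratio: reads >=99% identity over reads in [threshold, 99).

    ``None`` when the denominator is zero (every target read is an exact or
    near-exact match) — reported as undefined, not as a number.
    """
    values = np.asarray(identities, dtype=float)
    numerator = int((values >= 99.0).sum())
    denominator = int(((values >= threshold) & (values < 99.0)).sum())
    if denominator == 0:
        return None
    return numerator / denominator


def assess_detection(breadth: float, min_breadth: float = DETECTION_BREADTH) -> bool:
    """Detection rule: breadth at or above the 10% floor (boundary inclusive)."""
    return breadth >= min_breadth


def summarize_population(
    records: Sequence[AlignmentRecord],
    threshold: float,
    reference: ReferenceIndex,
    sample_id: str = "",
    min_breadth: float = DETECTION_BREADTH,
    fallback_used: bool = False,
) -> PopulationMetrics:
    """Filter target reads and populate every metric for one sample."""
    target = filter_target_reads(records, threshold)
    identities = np.asarray([r.identity for r in target], dtype=float)
    breadth = compute_breadth(target, reference)
    depth = compute_depth(target, reference)
    if identities.size:
        anir, manir = compute_anir_manir(identities)
        emr = compute_emr(identities, threshold)
    else:
        anir = manir = emr = None
    return PopulationMetrics(
        genome_id=reference.genome_id,
        sample_id=sample_id,
        n_target_reads=len(target),
        anir=anir,
        manir=manir,
        depth=depth,
        breadth=breadth,
        emr=emr,
        detected=assess_detection(breadth, min_breadth),
        threshold_used=float(threshold),
        fallback_used=fallback_used,
    )


def _fmt(value: float | None, spec: str = ".4f") -> str:
    return "NA" if value is None else format(value, spec)


def write_metrics_report(
    rows: Iterable[PopulationMetrics],
    dest: Union[str, Path, TextIO],
    header_lines: Sequence[str] = (),
) -> None:
    """Write per-(genome, sample) metrics as TSV (missing values as NA)."""
    if isinstance(dest, (str, Path)):
        handle: TextIO = open(dest, "w")
        close = True
    else:
        handle, close = dest, False
    try:
        for line in header_lines:
            handle.write(f"# {line}\n")
        handle.write(
            "genome_id\tsample_id\tn_target_reads\tanir\tmanir\tdepth\tbreadth\t"
            "emr\tdetected\tthreshold_used\tfallback_used\n"
        )
        for m in rows:
            handle.write(
                f"{m.genome_id}\t{m.sample_id}\t{m.n_target_reads}\t"
                f"{_fmt(m.anir)}\t{_fmt(m.manir)}\t{m.depth:.4f}\t{m.breadth:.4f}\t"
                f"{_fmt(m.emr)}\t{m.detected}\t{m.threshold_used:.2f}\t"
                f"{m.fallback_used}\n"
            )
    finally:
        if close:
            handle.close()
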