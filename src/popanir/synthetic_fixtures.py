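"""Synthetic read-recruitment fixtures with known ground truth.

Real recruitment data mixes a target population (identities piled up near
100%) with co-occurring relatives (a second mode near, say, 80%). The
simulators here emulate exactly that: per-read identities are drawn from a
truncated-Gaussian mixture on [floor, 100], reads are placed along a
multi-contig genome (uniformly, in hotspots, or with per-gene frequency
multipliers), and everything is emitted in the same 12-column tabular
dialect the parsers consume, alongside a truth sidecar naming each read's
mixture component and coordinates. Paired samples with a known ANIr shift
and known gene-frequency changes provide controlled inputs for the
resampling and differential-gene machinery.

All simulators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .alignment_io import AlignmentRecord, ReferenceIndex, write_blast_tabular
from .gene_content import GeneInterval
from .kde_threshold import IdentitySample

__all__ = [
    "MixtureSpec",
    "PairedSamples",
    "simulate_identity_sample",
    "simulate_alignment_records",
    "simulate_alignment_file",
    "simulate_paired_samples",
    "write_reference_fasta",
    "make_reference",
]


@dataclass(frozen=True)
class MixtureSpec:
    """A truncated-Gaussian identity mixture and its read geometry.

    ``components`` is a sequence of (mean identity, sd, weight) triples;
    weights must be positive and sum to 1, and means must lie inside the
    truncation range [floor, 100].
    """

    components: tuple[tuple[float, float, float], ...]
    n_reads: int
    read_length: int
    genome: ReferenceIndex
    seed: int
    floor: float = 70.0

    def __post_init__(self) -> None:
        weights = [w for _, _, w in self.components]
        if any(w <= 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("component weights must be positive and sum to 1")
        for mean, sd, _ in self.components:
            if not (self.floor <= mean <= 100.0):
                raise ValueError(f"component mean {mean} outside [{self.floor}, 100]")
            if sd <= 0:
                raise ValueError("component sd must be positive")


@dataclass(frozen=True)
class PairedSamples:
    """Two simulated samples plus the ground truth linking them."""

    records_a: list[AlignmentRecord]
    records_b: list[AlignmentRecord]
    truth: dict


def make_reference(
    contig_lengths: Mapping[str, int] | Sequence[int],
    genome_id: str = "sim_genome",
) -> ReferenceIndex:
    """Convenience constructor for a simulated multi-contig reference."""
    if not isinstance(contig_lengths, Mapping):
        contig_lengths = {f"contig_{i + 1}": int(n) for i, n in enumerate(contig_lengths)}
    return ReferenceIndex(genome_id=genome_id, contig_lengths=dict(contig_lengths))


def simulate_identity_sample(
    spec: MixtureSpec,
    rng: np.random.Generator | None = None,
    sample_id: str = "sim",
) -> tuple[IdentitySample, np.ndarray]:
    """Draw per-read identities; returns the sample and component labels."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    weights = np.array([w for _, _, w in spec.components])
    assignment = rng.choice(len(spec.components), size=spec.n_reads, p=weights)
    identities = np.empty(spec.n_reads)
    for i, (mean, sd, _) in enumerate(spec.components):
        mask = assignment == i
        k = int(mask.sum())
        if k == 0:
            continue
        a = (spec.floor - mean) / sd
        b = (100.0 - mean) / sd
        identities[mask] = stats.truncnorm.rvs(
            a, b, loc=mean, scale=sd, size=k, random_state=rng
        )
    sample = IdentitySample(
        identities=identities, genome_id=spec.genome.genome_id, sample_id=sample_id
    )
    return sample, assignment


def _position_segments(
    genome: ReferenceIndex,
    read_length: int,
    weighted_intervals: Sequence[tuple[str, int, int, float]],
    base_weight: float,
) -> tuple[list[tuple[str, int]], np.ndarray, np.ndarray]:
    """Segment the valid read-start space into constant-weight pieces.

    Returns (segment (contig, start) anchors, segment lengths, weights). A
    read starting inside a weighted interval gets that interval's weight;
    weights may be ``inf`` to confine all placement to those intervals.
    """
    anchors: list[tuple[str, int]] = []
    lengths: list[int] = []
    weights: list[float] = []
    by_contig: dict[str, list[tuple[int, int, float]]] = {}
    for contig, start, end, weight in weighted_intervals:
        by_contig.setdefault(contig, []).append((start, end, weight))
    for contig, contig_len in genome.contig_lengths.items():
        span = contig_len - read_length + 1  # valid read starts
        if span <= 0:
            continue
        cuts = {0, span}
        for start, end, _ in by_contig.get(contig, ()):
            cuts.add(min(max(start, 0), span))
            cuts.add(min(max(end, 0), span))
        edges = sorted(cuts)
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi <= lo:
                continue
            weight = base_weight
            for start, end, w in by_contig.get(contig, ()):
                if start <= lo and hi <= end:
                    weight = w
                    break
            anchors.append((contig, lo))
            lengths.append(hi - lo)
            weights.append(weight)
    return anchors, np.asarray(lengths, dtype=float), np.asarray(weights, dtype=float)


def _sample_positions(
    genome: ReferenceIndex,
    n: int,
    read_length: int,
    rng: np.random.Generator,
    weighted_intervals: Sequence[tuple[str, int, int, float]] = (),
    base_weight: float = 1.0,
) -> list[tuple[str, int]]:
    anchors, lengths, weights = _position_segments(
        genome, read_length, weighted_intervals, base_weight
    )
    if not anchors:
        raise ValueError("read_length exceeds every contig length")
    if np.isinf(weights).any():
        weights = np.where(np.isinf(weights), 1.0, 0.0)
    mass = lengths * weights
    total = mass.sum()
    if total <= 0:
        raise ValueError("placement weights leave no valid read-start positions")
    seg = rng.choice(len(anchors), size=n, p=mass / total)
    offsets = np.floor(rng.random(n) * lengths[seg]).astype(int)
    return [(anchors[s][0], anchors[s][1] + o) for s, o in zip(seg, offsets)]


def _records_from_draws(
    spec: MixtureSpec,
    identities: np.ndarray,
    positions: list[tuple[str, int]],
    read_prefix: str,
) -> list[AlignmentRecord]:
    """Turn drawn identities and placements into internally consistent rows.

    The emitted mismatch count is the nearest integer consistent with the
    read length, and the recorded identity is recomputed from that integer,
    so a round trip through the tabular parser preserves identities exactly.
    """
    rl = spec.read_length
    records = []
    for i, (identity, (contig, start)) in enumerate(zip(identities, positions)):
        mismatches = int(round((1.0 - identity / 100.0) * rl))
        consistent = round(100.0 * (rl - mismatches) / rl, 2)
        records.append(
            AlignmentRecord(
                read_id=f"{read_prefix}{i:07d}",
                contig_id=contig,
                identity=consistent,
                aln_length=rl,
                ref_start=start,
                ref_end=start + rl,
                bitscore=2.0 * (rl - mismatches),
            )
        )
    return records


def simulate_alignment_records(
    spec: MixtureSpec,
    placement: str = "uniform",
    hotspots: Sequence[tuple[str, int, int]] = (),
    enrichment: float = np.inf,
    rng: np.random.Generator | None = None,
    read_prefix: str = "read_",
    weighted_intervals: Sequence[tuple[str, int, int, float]] = (),
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Simulate one sample's alignment records plus the truth table.

    ``placement`` is ``uniform``, or ``hotspot`` with enrichment-weighted
    intervals (``enrichment=inf`` confines all reads to the hotspots,
    emulating conserved-region false-positive signal). ``weighted_intervals``
    allows arbitrary per-interval weights (used for gene multipliers).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    sample, assignment = simulate_identity_sample(spec, rng=rng)
    if placement == "hotspot":
        # confine read starts so the whole read lies inside the hotspot
        intervals = [
            (c, s, e - spec.read_length, float(enrichment))
            for c, s, e in hotspots
            if e - spec.read_length > s
        ]
        if not intervals:
            raise ValueError("every hotspot is shorter than the read length")
    elif placement == "uniform":
        intervals = list(weighted_intervals)
    else:
        raise ValueError(f"unknown placement mode {placement!r}")
    positions = _sample_positions(
        spec.genome, spec.n_reads, spec.read_length, rng, intervals
    )
    records = _records_from_draws(spec, sample.identities, positions, read_prefix)
    truth = pd.DataFrame(
        {
            "read_id": [r.read_id for r in records],
            "component": assignment,
            "drawn_identity": sample.identities,
            "emitted_identity": [r.identity for r in records],
            "contig_id": [r.contig_id for r in records],
            "ref_start": [r.ref_start for r in records],
            "ref_end": [r.ref_end for r in records],
        }
    )
    return records, truth


def simulate_alignment_file(
    spec: MixtureSpec,
    alignment_path: Union[str, Path],
    truth_path: Union[str, Path] | None = None,
    **kwargs,
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Simulate a sample and write the tabular alignment + truth sidecar."""
    records, truth = simulate_alignment_records(spec, **kwargs)
    write_blast_tabular(records, alignment_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return records, truth


def simulate_paired_samples(
    spec: MixtureSpec,
    gene_multipliers: Mapping[GeneInterval, float] | None = None,
    anir_shift: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PairedSamples:
    """Simulate samples A and B with a known ANIr shift and gene-scale truth.

    Sample B's component means are shifted down by ``anir_shift`` (so the
    true signed difference ANIr(A) - ANIr(B) is ~ +anir_shift) and its read
    placement density is scaled inside each gene by the given multiplier.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    gene_multipliers = dict(gene_multipliers or {})
    for mult in gene_multipliers.values():
        if mult < 0:
            raise ValueError("gene multipliers must be >= 0")
    records_a, truth_a = simulate_alignment_records(
        spec, rng=rng, read_prefix="A_read_"
    )
    shifted = tuple(
        (mean - anir_shift, sd, w) for mean, sd, w in spec.components
    )
    spec_b = replace(spec, components=shifted)
    weighted = [
        (g.contig_id, g.start, g.end, float(m)) for g, m in gene_multipliers.items()
    ]
    records_b, truth_b = simulate_alignment_records(
        spec_b, rng=rng, read_prefix="B_read_", weighted_intervals=weighted
    )
    truth = {
        "anir_shift": float(anir_shift),
        "scaled_genes": {g.gene_id: float(m) for g, m in gene_multipliers.items()
                         if m != 1.0},
        "realized_mean_a": float(truth_a["emitted_identity"].mean()),
        "realized_mean_b": float(truth_b["emitted_identity"].mean()),
        "per_read_a": truth_a,
        "per_read_b": truth_b,
    }
    return PairedSamples(records_a=records_a, records_b=records_b, truth=truth)


def write_reference_fasta(
    reference: ReferenceIndex,
    path: Union[str, Path],
    seed: int = 0,
    line_width: int = 70,
) -> None:
    """Write a random-sequence FASTA matching the reference contig lengths."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    with open(path, "w") as handle:
        for contig, length in reference.contig_lengths.items():
            seq = "".join(rng.choice(bases, size=length))
            handle.write(f">{contig}\n")
            for i in range(0, length, line_width):
                handle.write(seq[i : i + line_width] + "\n")


def write_truth_yaml(truth: dict, path: Union[str, Path]) -> None:
    """Serialize a paired-sample truth dict (per-read tables as TSV refs)."""
    scalar = {k: v for k, v in truth.items() if not isinstance(v, pd.DataFrame)}
    with open(path, "w") as handle:
        yaml.safe_dump(scalar, handle, sort_keys=True)
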