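"""Genome-normalized gene abundance and differential-gene flagging.

Per-gene sequencing depth is divided by the genome-wide depth of the target
population in the same sample, so the genome's own relative abundance is the
reference frame: a core gene tracking the genome sits near 1 in every
sample, regardless of how abundant the genome is. The per-gene difference of
these normalized abundances between two samples then forms an empirical
distribution whose central mass is core genes (difference ~ 0); genes in the
extreme tails — below the 2.5% or above the 97.5% quantile — are flagged as
changing in frequency within the population between the samples.

The flagging is an empirical-tail rule, not a parametric test: the flagged
genes are by construction roughly the most extreme 5% of the distribution.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import gffutils
import numpy as np
import pandas as pd

from .alignment_io import AlignmentRecord, ReferenceIndex

__all__ = [
    "GeneInterval",
    "GeneAbundanceProfile",
    "GeneDifferenceResult",
    "read_gene_intervals",
    "read_gene_intervals_gff3",
    "read_gene_intervals_tsv",
    "compute_gene_depths",
    "normalize_gene_abundance",
    "flag_differential_genes",
    "write_gene_difference_report",
]


@dataclass(frozen=True)
class GeneInterval:
    """One coding sequence on a contig (0-based, half-open)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty gene interval for {self.gene_id!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAbundanceProfile:
    """Per-gene normalized abundance of one (genome, sample) pair."""

    sample_id: str
    genome_id: str
    genome_depth: float
    abundances: dict[str, float]


@dataclass(frozen=True)
class GeneDifferenceResult:
    """Pairwise differences (A - B) and the tail-flagged gene sets."""

    differences: dict[str, float]
    q_low_value: float
    q_high_value: float
    higher_in_a: frozenset[str]
    higher_in_b: frozenset[str]


def read_gene_intervals_gff3(path: Union[str, Path]) -> list[GeneInterval]:
    """Extract CDS features from a GFF3 file (1-based inclusive on entry)."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneInterval] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [None])[0] or feat.attributes.get(
            "locus_tag", [None]
        )[0] or f"{feat.seqid}:{feat.start}-{feat.end}"
        annotation = feat.attributes.get("product", [None])[0]
        genes.append(
            GeneInterval(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                annotation=annotation,
            )
        )
    return genes


def read_gene_intervals_tsv(path: Union[str, Path]) -> list[GeneInterval]:
    """Read a 4/5-column TSV: gene_id, contig, start, end[, annotation].

    Coordinates are 1-based inclusive (Prodigal-style) and converted on
    entry.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", header=None)
    if frame.shape[1] < 4:
        raise ValueError("gene coordinate TSV needs >=4 columns")
    genes = []
    for row in frame.itertuples(index=False):
        annotation = str(row[4]) if frame.shape[1] > 4 and pd.notna(row[4]) else None
        genes.append(
            GeneInterval(
                gene_id=str(row[0]),
                contig_id=str(row[1]),
                start=int(row[2]) - 1,
                end=int(row[3]),
                annotation=annotation,
            )
        )
    return genes


def read_gene_intervals(path: Union[str, Path]) -> list[GeneInterval]:
    """Dispatch on extension: .gff/.gff3 -> GFF3, otherwise coordinate TSV."""
    suffix = Path(path).suffix.lower()
    if suffix in {".gff", ".gff3"}:
        return read_gene_intervals_gff3(path)
    return read_gene_intervals_tsv(path)


def compute_gene_depths(
    records: Sequence[AlignmentRecord],
    genes: Sequence[GeneInterval],
    reference: ReferenceIndex,
) -> dict[str, float]:
    """Mean per-base depth of each gene from base-level read overlap.

    Depth is accumulated on a per-contig coverage array (difference-array
    trick + prefix sums), then averaged over each gene interval, so a read
    overlapping a gene contributes exactly its overlapping bases.
    """
    for gene in genes:
        if gene.contig_id not in reference:
            raise KeyError(
                f"gene {gene.gene_id!r} lies on unknown contig {gene.contig_id!r}"
            )
        if gene.end > reference.contig_lengths[gene.contig_id]:
            raise ValueError(
                f"gene {gene.gene_id!r} extends past contig {gene.contig_id!r}"
            )
    prefix: dict[str, np.ndarray] = {}
    needed = {g.contig_id for g in genes}
    for contig in needed:
        length = reference.contig_lengths[contig]
        diff = np.zeros(length + 1, dtype=np.int64)
        prefix[contig] = diff
    for r in records:
        diff = prefix.get(r.contig_id)
        if diff is None:
            continue
        diff[r.ref_start] += 1
        diff[r.ref_end] -= 1
    for contig, diff in prefix.items():
        coverage = np.cumsum(diff[:-1])
        # prefix sums of coverage: overlap over [s, e) = csum[e] - csum[s]
        prefix[contig] = np.concatenate(([0], np.cumsum(coverage)))
    depths: dict[str, float] = {}
    for gene in genes:
        csum = prefix[gene.contig_id]
        overlap = csum[gene.end] - csum[gene.start]
        depths[gene.gene_id] = overlap / gene.length
    return depths


def normalize_gene_abundance(
    gene_depths: Mapping[str, float],
    genome_depth: float,
    sample_id: str = "",
    genome_id: str = "",
) -> GeneAbundanceProfile:
    """Divide each gene depth by the genome depth of the same sample.

    The genome-wide mean depth of the target population is the relative
    abundance reference frame; a zero genome depth means the population was
    not detected and normalization is refused.
    """
    if genome_depth <= 0:
        raise ValueError(
            "genome depth is zero: population undetected, cannot normalize"
        )
    return GeneAbundanceProfile(
        sample_id=sample_id,
        genome_id=genome_id,
        genome_depth=float(genome_depth),
        abundances={g: d / genome_depth for g, d in gene_depths.items()},
    )


def flag_differential_genes(
    profile_a: GeneAbundanceProfile,
    profile_b: GeneAbundanceProfile,
    q_low: float = 0.025,
    q_high: float = 0.975,
) -> GeneDifferenceResult:
    """Flag genes whose normalized-abundance difference sits in the tails.

    Differences are A - B over the shared gene universe; quantiles use
    linear interpolation between order statistics, and flagging is by strict
    inequality, so a fully degenerate (all-equal) difference distribution
    flags nothing.
    """
    genes_a = set(profile_a.abundances)
    genes_b = set(profile_b.abundances)
    if genes_a != genes_b:
        missing = sorted(genes_a.symmetric_difference(genes_b))
        raise ValueError(f"profiles disagree on the gene universe: {missing}")
    gene_ids = sorted(genes_a)
    diffs = np.array(
        [profile_a.abundances[g] - profile_b.abundances[g] for g in gene_ids]
    )
    lo, hi = np.quantile(diffs, [q_low, q_high])
    higher_in_a = frozenset(g for g, d in zip(gene_ids, diffs) if d > hi)
    higher_in_b = frozenset(g for g, d in zip(gene_ids, diffs) if d < lo)
    return GeneDifferenceResult(
        differences=dict(zip(gene_ids, (float(d) for d in diffs))),
        q_low_value=float(lo),
        q_high_value=float(hi),
        higher_in_a=higher_in_a,
        higher_in_b=higher_in_b,
    )


def write_gene_difference_report(
    result: GeneDifferenceResult,
    profile_a: GeneAbundanceProfile,
    profile_b: GeneAbundanceProfile,
    dest: Union[str, Path, TextIO],
    annotations: Mapping[str, str] | None = None,
    header_lines: Sequence[str] = (),
) -> None:
    """Write the per-gene difference table with tail flags as TSV."""
    if isinstance(dest, (str, Path)):
        handle: TextIO = open(dest, "w")
        close = True
    else:
        handle, close = dest, False
    annotations = annotations or {}
    try:
        for line in header_lines:
            handle.write(f"# {line}\n")
        handle.write(
            "gene_id\tannotation\tnorm_abund_a\tnorm_abund_b\tdifference\tflag\n"
        )
        for gene_id in sorted(result.differences):
            if gene_id in result.higher_in_a:
                flag = "higher_in_A"
            elif gene_id in result.higher_in_b:
                flag = "higher_in_B"
            else:
                flag = "none"
            handle.write(
                f"{gene_id}\t{annotations.get(gene_id, '')}\t"
                f"{profile_a.abundances[gene_id]:.4f}\t"
                f"{profile_b.abundances[gene_id]:.4f}\t"
                f"{result.differences[gene_id]:.4f}\t{flag}\n"
            )
    finally:
        if close:
            handle.close()
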