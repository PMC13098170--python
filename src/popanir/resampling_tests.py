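"""Bootstrap and permutation tests for ANIr differences between samples.

Metagenomic surveys rarely provide biological replicates, so parametric
tests are replaced by two resampling schemes that ask whether two target
populations, recruited with the same reference genome from samples A and B,
are plausibly the same population:

- **Bootstrap** — build a null ANIr distribution for sample A by repeatedly
  (default 10,000 times) resampling, with replacement, 2% of A's target-read
  identities and recording the mean. Sample B's ANIr is then compared to
  that distribution.
- **Permutation** — pool the identities of A and B, repeatedly split the
  pool at random into sets of the original sizes, and record the difference
  of the two means; the observed ANIr difference is compared to that null.

Either way the null hypothesis (same population) is rejected when the
observed value falls outside three standard deviations of the null mean, or
outside the null's central 95% (below the 2.5th or above the 97.5th
percentile). Both verdicts are reported separately; the combined verdict
(``significant``) is their OR. p-values are empirical and two-sided with the add-one
correction, so they are never exactly zero (floor 1/(n_iterations+1)).

No multiple-testing correction is applied across genome/sample pairs; with
many comparisons the user should correct downstream.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence, TextIO, Union

import numpy as np

__all__ = [
    "ResamplingResult",
    "BelowDetectionError",
    "bootstrap_anir_distribution",
    "bootstrap_identity_test",
    "permutation_anir_difference_test",
    "write_test_report",
    "DEFAULT_ITERATIONS",
    "DEFAULT_RESAMPLE_FRACTION",
]

DEFAULT_ITERATIONS = 10_000
DEFAULT_RESAMPLE_FRACTION = 0.02
_CHUNK_ELEMENTS = 4_000_000  # cap transient permutation matrices at ~32 MB


class BelowDetectionError(ValueError):
    """A sample below the detection breadth was passed without force=True."""


@dataclass(frozen=True)
class ResamplingResult:
    """Observed statistic, null summary and significance verdicts."""

    method: str  # "bootstrap" | "permutation"
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_iterations: int
    significant_3sd: bool
    significant_percentile: bool
    seed: int | None

    @property
    def significant(self) -> bool:
        """Combined verdict: either decision rule rejects."""
        return self.significant_3sd or self.significant_percentile


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _verdicts(
    null: np.ndarray, observed: float, center: float
) -> tuple[float, bool, bool, float, float]:
    """p-value (two-sided, add-one) and both significance rules."""
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    n = null.size
    # tie tolerance: means of the same multiset summed in different orders
    # differ in the last bits; exact ties must count as "at least as extreme"
    tie_eps = 1e-9 * max(1.0, abs(observed))
    extreme = int((np.abs(null - center) >= abs(observed - center) - tie_eps).sum())
    p_value = (1 + extreme) / (n + 1)
    if null_sd == 0.0:
        significant_3sd = observed != null_mean
    else:
        significant_3sd = abs(observed - null_mean) > 3.0 * null_sd
    q_low, q_high = np.percentile(null, [2.5, 97.5])
    significant_percentile = bool(observed < q_low or observed > q_high)
    return p_value, significant_3sd, significant_percentile, null_mean, null_sd


def bootstrap_anir_distribution(
    identities_a: Sequence[float] | np.ndarray,
    n_iterations: int = DEFAULT_ITERATIONS,
    resample_fraction: float = DEFAULT_RESAMPLE_FRACTION,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Null ANIr distribution from with-replacement 2%-size resamples of A.

    Resample size is ``max(1, round(fraction * n))``. Reproducible given a
    seed (or an explicit generator).
    """
    values = np.asarray(identities_a, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty identity set")
    rng = _as_rng(seed)
    k = max(1, int(np.floor(resample_fraction * values.size + 0.5)))
    idx = rng.integers(0, values.size, size=(n_iterations, k))
    return values[idx].mean(axis=1)


def bootstrap_identity_test(
    identities_a: Sequence[float] | np.ndarray,
    anir_b: float,
    n_iterations: int = DEFAULT_ITERATIONS,
    resample_fraction: float = DEFAULT_RESAMPLE_FRACTION,
    seed: int | None = None,
) -> ResamplingResult:
    """Compare sample B's ANIr to the bootstrapped ANIr null of sample A."""
    null = bootstrap_anir_distribution(
        identities_a, n_iterations=n_iterations,
        resample_fraction=resample_fraction, seed=seed,
    )
    p, sig3, sigp, null_mean, null_sd = _verdicts(null, anir_b, center=float(null.mean()))
    return ResamplingResult(
        method="bootstrap",
        observed=float(anir_b),
        null_mean=null_mean,
        null_sd=null_sd,
        p_value=p,
        n_iterations=n_iterations,
        significant_3sd=sig3,
        significant_percentile=sigp,
        seed=seed if isinstance(seed, int) else None,
    )


def permutation_anir_difference_test(
    identities_a: Sequence[float] | np.ndarray,
    identities_b: Sequence[float] | np.ndarray,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.Generator | None = None,
) -> ResamplingResult:
    """Permutation null of the signed ANIr difference between two samples.

    Each iteration shuffles the pooled identities without replacement into
    two sets of the original sizes and records the difference of means. The
    pool is sorted first so the null depends only on the pooled multiset;
    for equally sized samples, swapping A and B then exactly negates the
    null draws and leaves the two-sided p-value unchanged.
    """
    a = np.asarray(identities_a, dtype=float)
    b = np.asarray(identities_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both identity sets must be non-empty")
    rng = _as_rng(seed)
    observed = float(a.mean() - b.mean())
    pool = np.sort(np.concatenate([a, b]))
    n_a, n = a.size, pool.size
    null = np.empty(n_iterations)
    chunk = max(1, min(n_iterations, _CHUNK_ELEMENTS // n))
    done = 0
    while done < n_iterations:
        m = min(chunk, n_iterations - done)
        mat = np.tile(pool, (m, 1))
        rng.permuted(mat, axis=1, out=mat)
        null[done : done + m] = mat[:, :n_a].mean(axis=1) - mat[:, n_a:].mean(axis=1)
        done += m
    p, sig3, sigp, null_mean, null_sd = _verdicts(null, observed, center=0.0)
    return ResamplingResult(
        method="permutation",
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        p_value=p,
        n_iterations=n_iterations,
        significant_3sd=sig3,
        significant_percentile=sigp,
        seed=seed if isinstance(seed, int) else None,
    )


def write_test_report(
    results: Sequence[tuple[str, str, str, ResamplingResult]],
    dest: Union[str, Path, TextIO],
    fmt: str = "tsv",
    header_lines: Sequence[str] = (),
) -> None:
    """Write (genome, sample_A, sample_B, result) rows as TSV or JSON."""
    if isinstance(dest, (str, Path)):
        handle: TextIO = open(dest, "w")
        close = True
    else:
        handle, close = dest, False
    try:
        if fmt == "json":
            payload = [
                {"genome_id": g, "sample_a": sa, "sample_b": sb, **asdict(r)}
                for g, sa, sb, r in results
            ]
            json.dump(payload, handle, indent=2)
            handle.write("\n")
            return
        for line in header_lines:
            handle.write(f"# {line}\n")
        handle.write(
            "genome_id\tsample_a\tsample_b\tmethod\tobserved\tnull_mean\tnull_sd\t"
            "p_value\tsignificant_3sd\tsignificant_percentile\tn_iterations\tseed\n"
        )
        for g, sa, sb, r in results:
            handle.write(
                f"{g}\t{sa}\t{sb}\t{r.method}\t{r.observed:.6f}\t{r.null_mean:.6f}\t"
                f"{r.null_sd:.6g}\t{r.p_value:.6g}\t{r.significant_3sd}\t"
                f"{r.significant_percentile}\t{r.n_iterations}\t{r.seed}\n"
            )
    finally:
        if close:
            handle.close()
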