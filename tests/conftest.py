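"""Shared fixtures: small references, simulated samples, analytic oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy import stats

from popanir import MixtureSpec, make_reference, simulate_identity_sample

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

# The study-condition mixtures: a clonal population piled up near 99%
# identity, and a heterogeneous one whose co-occurring relative forms a
# second mode near 80%.
CLONAL_COMPONENTS = ((99.0, 2.0, 1.0),)
BIMODAL_COMPONENTS = ((98.5, 0.8, 0.7), (80.0, 2.0, 0.3))


@pytest.fixture
def reference():
    return make_reference({"c1": 600, "c2": 400}, genome_id="toy")


@pytest.fixture
def sim_genome():
    return make_reference({"contig_1": 120_000, "contig_2": 80_000},
                          genome_id="sim_genome")


@pytest.fixture
def bimodal_sample(sim_genome):
    spec = MixtureSpec(components=BIMODAL_COMPONENTS, n_reads=20_000,
                       read_length=150, genome=sim_genome, seed=11)
    sample, assignment = simulate_identity_sample(spec)
    return spec, sample, assignment


def truncnorm_pdf(x, mean, sd, low=70.0, high=100.0):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.pdf(x, a, b, loc=mean, scale=sd)


def mixture_pdf(x, components, low=70.0, high=100.0):
    """Closed-form truncated-Gaussian mixture density."""
    x = np.asarray(x, dtype=float)
    dens = np.zeros_like(x)
    for mean, sd, weight in components:
        dens += weight * truncnorm_pdf(x, mean, sd, low, high)
    return dens


def smoothed_mixture_pdf(x, components, kernel_sd, low=70.0, high=100.0):
    """Truncated-Gaussian mixture convolved with a Gaussian kernel.

    Closed form via the Gaussian product identity: the convolution of a
    [low, high]-truncated N(m, sd^2) with N(0, h^2) evaluated at x is
    N(x; m, sd^2 + h^2) * (Phi((high - mu*) / s*) - Phi((low - mu*) / s*)) / Z
    with mu* = (m h^2 + x sd^2) / (sd^2 + h^2), s*^2 = sd^2 h^2 / (sd^2 + h^2)
    and Z the truncation mass. This is the estimand of a Gaussian KDE with
    kernel sd ``kernel_sd`` fitted to draws from the mixture.
    """
    x = np.asarray(x, dtype=float)
    h2 = kernel_sd**2
    dens = np.zeros_like(x)
    for mean, sd, weight in components:
        s2 = sd**2
        z = stats.norm.cdf((high - mean) / sd) - stats.norm.cdf((low - mean) / sd)
        mu_star = (mean * h2 + x * s2) / (s2 + h2)
        s_star = np.sqrt(s2 * h2 / (s2 + h2))
        envelope = stats.norm.pdf(x, loc=mean, scale=np.sqrt(s2 + h2))
        window = stats.norm.cdf((high - mu_star) / s_star) - stats.norm.cdf(
            (low - mu_star) / s_star
        )
        dens += weight * envelope * window / z
    return dens


def interior_minimum(grid, density):
    """Brute-force scan for interior local minima of a sampled curve."""
    d = np.asarray(density)
    mins = [
        i
        for i in range(1, len(d) - 1)
        if d[i] < d[i - 1] and d[i] < d[i + 1]
    ]
    return np.asarray(grid)[mins]
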