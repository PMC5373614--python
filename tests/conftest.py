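"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import integrate, stats

from elnnpaired import FitConfig, PairedDiffMatrix, simulate_elnn


def quad_log_marginal_de(d, mu, k, alpha, beta):
    """Brute-force log marginal of the DE hierarchy by nested quadrature.

    Integrates the joint N(d | m, 1/t) * N(m | mu, k/t) * Gamma(t | alpha,
    rate beta) over the gene mean m and precision t; independent of the
    closed form under test.
    """
    d = np.asarray(d, dtype=float)

    def inner(t):
        def joint(m):
            return np.exp(
                stats.norm.logpdf(d, m, 1.0 / np.sqrt(t)).sum()
                + stats.norm.logpdf(m, mu, np.sqrt(k / t))
            )
        lo = mu - 12 * np.sqrt(k / t) - 3
        hi = mu + 12 * np.sqrt(k / t) + 3
        return integrate.quad(joint, lo, hi, limit=200)[0]

    def outer(t):
        return inner(t) * stats.gamma.pdf(t, alpha, scale=1.0 / beta)

    t_lo = stats.gamma.ppf(1e-12, alpha, scale=1.0 / beta)
    t_hi = stats.gamma.ppf(1.0 - 1e-12, alpha, scale=1.0 / beta)
    val = integrate.quad(outer, t_lo, t_hi, limit=400)[0]
    return np.log(val)


def quad_log_marginal_ne(d, alpha, beta):
    """Brute-force log marginal of the NE hierarchy (gene mean fixed at 0)."""
    d = np.asarray(d, dtype=float)

    def outer(t):
        return np.exp(
            stats.norm.logpdf(d, 0.0, 1.0 / np.sqrt(t)).sum()
            + stats.gamma.logpdf(t, alpha, scale=1.0 / beta)
        )

    t_lo = stats.gamma.ppf(1e-12, alpha, scale=1.0 / beta)
    t_hi = stats.gamma.ppf(1.0 - 1e-12, alpha, scale=1.0 / beta)
    val = integrate.quad(outer, t_lo, t_hi, limit=400)[0]
    return np.log(val)


def random_de_params(rng):
    """Draw one plausible (mu, k, alpha, beta) for a DE cluster."""
    return (
        float(rng.uniform(0.2, 2.0)),
        float(rng.uniform(0.05, 0.9)),
        float(rng.uniform(0.6, 5.0)),
        float(rng.uniform(0.05, 2.0)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20170330)


@pytest.fixture(scope="session")
def g30_small():
    """One modest dataset from the hierarchical-mixture generator."""
    return simulate_elnn(400, 30, seed=11)


@pytest.fixture
def tiny_matrix(rng):
    return PairedDiffMatrix(values=rng.normal(size=(5, 3)))


@pytest.fixture
def quick_config():
    return FitConfig(max_iter=40, seed=0)
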