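"""Core of the eLNNpaired model.

Each gene probe's within-pair log2 expression differences ``d_gl`` are
modelled as draws from one of three conjugate normal--gamma hierarchies:

* cluster 1 (over-expressed, OE)::

      d_gl | mu_g, tau_g ~ N(mu_g, 1/tau_g)
      mu_g | tau_g       ~ N(mu_1, k_1/tau_g),   mu_1 > 0, 0 < k_1 < 1
      tau_g              ~ Gamma(alpha_1, rate=beta_1)

* cluster 2 (under-expressed, UE): same with mu_2 < 0, k_2, alpha_2, beta_2;
* cluster 3 (non-differentially expressed, NE): mu_g = 0, k = 0, i.e.
  ``d_gl | tau_g ~ N(0, 1/tau_g)``, ``tau_g ~ Gamma(alpha_3, rate=beta_3)``.

Conjugacy yields closed-form marginal densities (multivariate-t type); all
density work is done in log space.  To keep OE genes genuinely positive the
hyper-parameters of clusters 1 and 2 obey mode-of-precision constraints

    alpha_1 > 1 + beta_1 * ((c_1 - sqrt(k_1) * z_lo) / mu_1)**2
    alpha_2 > 1 + beta_2 * ((c_2 - sqrt(k_2) * z_hi) / mu_2)**2

with ``c_1 = z_hi = Phi^{-1}(p_hi)`` and ``c_2 = z_lo = Phi^{-1}(p_lo)``
(defaults 0.95 / 0.05).  Estimation works on an unconstrained 10-vector
``theta`` whose image automatically satisfies every constraint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, ndtr, ndtri

logger = logging.getLogger("elnnpaired")

__all__ = [
    "ELNNError",
    "InputError",
    "ConstraintViolationError",
    "NonFiniteParameterError",
    "DegeneracyError",
    "PairedDiffMatrix",
    "HyperParams",
    "RawParams",
    "MixtureModel",
    "raw_to_natural",
    "natural_to_raw",
    "constraint_gap",
    "log_marginal_de",
    "log_marginal_ne",
    "log_marginals",
]


class ELNNError(Exception):
    """Base class for model errors."""


class InputError(ELNNError):
    """Malformed or non-finite input data."""


class ConstraintViolationError(ELNNError):
    """Hyper-parameters violate a model constraint; the message names it."""


class NonFiniteParameterError(ELNNError):
    """A transformed parameter overflowed to a non-finite value."""


class DegeneracyError(ELNNError):
    """A numerically degenerate state (e.g. all component densities zero)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedDiffMatrix:
    """G x n matrix of within-pair log2 differences d_gl = log2 y_gl - log2 x_gl."""

    values: np.ndarray
    gene_ids: tuple[str, ...] = ()
    pair_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InputError(f"expected a 2-D matrix, got ndim={values.ndim}")
        G, n = values.shape
        if G < 1:
            raise InputError("need at least one gene")
        if n < 2:
            raise InputError(
                f"need at least 2 sample pairs (got n={n}); a single pair has no "
                "within-gene variance"
            )
        if not np.all(np.isfinite(values)):
            raise InputError("matrix contains non-finite entries")
        gene_ids = tuple(self.gene_ids) or tuple(f"g{i + 1}" for i in range(G))
        pair_ids = tuple(self.pair_ids) or tuple(f"p{j + 1}" for j in range(n))
        if len(gene_ids) != G:
            raise InputError(f"{len(gene_ids)} gene ids for {G} genes")
        if len(pair_ids) != n:
            raise InputError(f"{len(pair_ids)} pair ids for {n} pairs")
        if len(set(gene_ids)) != G:
            raise InputError("gene ids are not unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "pair_ids", pair_ids)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class HyperParams:
    """Natural-scale hyper-parameters psi plus the constraint percentiles."""

    mu1: float
    k1: float
    alpha1: float
    beta1: float
    mu2: float
    k2: float
    alpha2: float
    beta2: float
    alpha3: float
    beta3: float
    p_hi: float = 0.95
    p_lo: float = 0.05

    @property
    def c1(self) -> float:
        """Upper standard-normal percentile Phi^{-1}(p_hi)."""
        return float(ndtri(self.p_hi))

    @property
    def c2(self) -> float:
        """Lower standard-normal percentile Phi^{-1}(p_lo)."""
        return float(ndtri(self.p_lo))

    def validate(self, check_constraints: bool = True) -> None:
        """Raise ConstraintViolationError on the first violated invariant."""
        if not self.mu1 > 0:
            raise ConstraintViolationError(f"mu1 must be > 0 (got {self.mu1})")
        if not self.mu2 < 0:
            raise ConstraintViolationError(f"mu2 must be < 0 (got {self.mu2})")
        for name in ("k1", "k2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConstraintViolationError(f"{name} must lie in (0,1) (got {v})")
        for name in ("alpha1", "beta1", "alpha2", "beta2", "alpha3", "beta3"):
            v = getattr(self, name)
            if not v > 0:
                raise ConstraintViolationError(f"{name} must be > 0 (got {v})")
        if check_constraints:
            gap1, gap2 = constraint_gap(self)
            if not gap1 > 0:
                raise ConstraintViolationError(
                    f"alpha1 constraint violated: alpha1 - 1 - beta1*A1 = {gap1:.6g} <= 0"
                )
            if not gap2 > 0:
                raise ConstraintViolationError(
                    f"alpha2 constraint violated: alpha2 - 1 - beta2*A2 = {gap2:.6g} <= 0"
                )


@dataclass(frozen=True)
class RawParams:
    """Unconstrained optimizer vector theta = (delta1, xi1, lambda1, nu1, ...)."""

    delta1: float
    xi1: float
    lambda1: float
    nu1: float
    delta2: float
    xi2: float
    lambda2: float
    nu2: float
    lambda3: float
    nu3: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.delta1, self.xi1, self.lambda1, self.nu1,
                self.delta2, self.xi2, self.lambda2, self.nu2,
                self.lambda3, self.nu3,
            ]
        )

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "RawParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (10,):
            raise InputError(f"raw parameter vector must have length 10, got {theta.shape}")
        return cls(*theta.tolist())


@dataclass(frozen=True)
class MixtureModel:
    """Hyper-parameters plus mixing proportions pi under a symmetric Dirichlet(b)."""

    hyper: HyperParams
    pi: tuple[float, float, float]
    b: float = 2.0

    def __post_init__(self) -> None:
        pi = tuple(float(p) for p in self.pi)
        if len(pi) != 3 or any(p < 0 for p in pi):
            raise InputError(f"pi must be 3 non-negative probabilities, got {pi}")
        if abs(sum(pi) - 1.0) > 1e-12:
            raise InputError(f"pi must sum to 1 within 1e-12, got sum={sum(pi)!r}")
        if not self.b > 1:
            raise InputError(f"Dirichlet concentration b must be > 1, got {self.b}")
        object.__setattr__(self, "pi", pi)

    # flat text serialization, 15 significant digits
    _FIELDS = (
        "mu1", "k1", "alpha1", "beta1", "mu2", "k2", "alpha2", "beta2",
        "alpha3", "beta3", "p_hi", "p_lo",
    )

    def to_text(self) -> str:
        lines = [f"{name}\t{getattr(self.hyper, name):.15g}" for name in self._FIELDS]
        for c, p in enumerate(self.pi, start=1):
            lines.append(f"pi{c}\t{p:.15g}")
        lines.append(f"b\t{self.b:.15g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "MixtureModel":
        kv: dict[str, float] = {}
        for line in text.strip().splitlines():
            key, _, val = line.partition("\t")
            kv[key.strip()] = float(val)
        hyper = HyperParams(**{name: kv[name] for name in cls._FIELDS})
        pi_raw = (kv["pi1"], kv["pi2"], kv["pi3"])
        s = sum(pi_raw)  # renormalize text round-off
        return cls(hyper=hyper, pi=tuple(p / s for p in pi_raw), b=kv.get("b", 2.0))


# ---------------------------------------------------------------------------
# constraints and reparameterization
# ---------------------------------------------------------------------------


def _bound_terms(mu1: float, k1: float, mu2: float, k2: float,
                 p_hi: float, p_lo: float) -> tuple[float, float]:
    """A1, A2 such that the constraints read alpha_c > 1 + beta_c * A_c."""
    c1 = ndtri(p_hi)
    c2 = ndtri(p_lo)
    with np.errstate(divide="ignore"):  # mu -> 0 gives an infinite bound, caught upstream
        a1 = ((c1 - np.sqrt(k1) * ndtri(p_lo)) / mu1) ** 2
        a2 = ((c2 - np.sqrt(k2) * ndtri(p_hi)) / mu2) ** 2
    return float(a1), float(a2)


def constraint_gap(psi: HyperParams) -> tuple[float, float]:
    """Slack (alpha1 - 1 - beta1*A1, alpha2 - 1 - beta2*A2); both must be > 0."""
    a1, a2 = _bound_terms(psi.mu1, psi.k1, psi.mu2, psi.k2, psi.p_hi, psi.p_lo)
    return psi.alpha1 - 1.0 - psi.beta1 * a1, psi.alpha2 - 1.0 - psi.beta2 * a2


def raw_to_natural(theta: RawParams | Sequence[float],
                   p_hi: float = 0.95, p_lo: float = 0.05) -> HyperParams:
    """Map the unconstrained 10-vector onto the natural scale.

    mu1 = exp(delta1), k1 = Phi(xi1), beta1 = exp(nu1) and
    alpha1 = exp(lambda1) + 1 + beta1*A1 (the constrained form, strictly
    feasible for every real lambda1); mirrored for cluster 2 with
    mu2 = -exp(delta2); alpha3 = exp(lambda3), beta3 = exp(nu3).
    """
    if not isinstance(theta, RawParams):
        theta = RawParams.from_array(np.asarray(theta, dtype=float))
    arr = theta.as_array()
    if not np.all(np.isfinite(arr)):
        raise NonFiniteParameterError(f"raw parameter vector is non-finite: {arr}")
    with np.errstate(over="raise"):
        try:
            mu1 = float(np.exp(theta.delta1))
            k1 = float(ndtr(theta.xi1))
            beta1 = float(np.exp(theta.nu1))
            mu2 = -float(np.exp(theta.delta2))
            k2 = float(ndtr(theta.xi2))
            beta2 = float(np.exp(theta.nu2))
            alpha3 = float(np.exp(theta.lambda3))
            beta3 = float(np.exp(theta.nu3))
            a1, a2 = _bound_terms(mu1, k1, mu2, k2, p_hi, p_lo)
            alpha1 = float(np.exp(theta.lambda1)) + 1.0 + beta1 * a1
            alpha2 = float(np.exp(theta.lambda2)) + 1.0 + beta2 * a2
        except FloatingPointError as exc:
            raise NonFiniteParameterError(f"overflow mapping theta={arr}: {exc}") from exc
    psi = HyperParams(mu1, k1, alpha1, beta1, mu2, k2, alpha2, beta2,
                      alpha3, beta3, p_hi=p_hi, p_lo=p_lo)
    for name in ("mu1", "beta1", "alpha1", "beta2", "alpha2", "alpha3", "beta3"):
        if not np.isfinite(getattr(psi, name)):
            raise NonFiniteParameterError(f"{name} is non-finite after transform")
    return psi


def natural_to_raw(psi: HyperParams) -> RawParams:
    """Exact inverse of :func:`raw_to_natural`; errors if psi is infeasible."""
    psi.validate(check_constraints=True)
    gap1, gap2 = constraint_gap(psi)
    # gap > 0 guaranteed by validate(); log of the slack recovers lambda
    return RawParams(
        delta1=float(np.log(psi.mu1)),
        xi1=float(ndtri(psi.k1)),
        lambda1=float(np.log(gap1)),
        nu1=float(np.log(psi.beta1)),
        delta2=float(np.log(-psi.mu2)),
        xi2=float(ndtri(psi.k2)),
        lambda2=float(np.log(gap2)),
        nu2=float(np.log(psi.beta2)),
        lambda3=float(np.log(psi.alpha3)),
        nu3=float(np.log(psi.beta3)),
    )


# ---------------------------------------------------------------------------
# marginal log-densities
# ---------------------------------------------------------------------------
#
# Integrating mu_g then tau_g out of the hierarchy gives, for c in {1, 2},
#
#   log f_c(d_g) = -(n/2) log(2 pi) - 1/2 log(1 + n k_c)
#                  + lgamma(alpha_c + n/2) - lgamma(alpha_c)
#                  + alpha_c log beta_c - (alpha_c + n/2) log(beta_c + Q_c/2)
#
#   Q_c = sum_l (d_gl - mu_c)^2 - k_c/(1 + n k_c) * (sum_l (d_gl - mu_c))^2
#
# and cluster 3 is the k = 0, mu = 0 special case.


def _log_marginal_vec(row_sum: np.ndarray, row_sq: np.ndarray, n: int,
                      mu: float, k: float, alpha: float, beta: float) -> np.ndarray:
    """Vectorized log marginal given per-gene sums of d and d^2."""
    s = row_sum - n * mu
    ss = row_sq - 2.0 * mu * row_sum + n * mu * mu
    q = ss - (k / (1.0 + n * k)) * s * s
    return (
        -0.5 * n * np.log(2.0 * np.pi)
        - 0.5 * np.log1p(n * k)
        + gammaln(alpha + 0.5 * n)
        - gammaln(alpha)
        + alpha * np.log(beta)
        - (alpha + 0.5 * n) * np.log(beta + 0.5 * q)
    )


def log_marginal_de(d_g: Sequence[float], psi: HyperParams, cluster: int) -> float:
    """Log marginal density of one gene's difference vector under cluster 1 or 2."""
    d = np.asarray(d_g, dtype=float).ravel()
    if not np.all(np.isfinite(d)):
        raise InputError("difference vector contains non-finite values")
    if cluster == 1:
        mu, k, alpha, beta = psi.mu1, psi.k1, psi.alpha1, psi.beta1
    elif cluster == 2:
        mu, k, alpha, beta = psi.mu2, psi.k2, psi.alpha2, psi.beta2
    else:
        raise InputError(f"cluster must be 1 or 2, got {cluster}")
    n = d.size
    return float(
        _log_marginal_vec(np.array([d.sum()]), np.array([(d * d).sum()]), n,
                          mu, k, alpha, beta)[0]
    )


def log_marginal_ne(d_g: Sequence[float], psi: HyperParams) -> float:
    """Log marginal density of one gene under the NE cluster (mu_g = 0)."""
    d = np.asarray(d_g, dtype=float).ravel()
    if not np.all(np.isfinite(d)):
        raise InputError("difference vector contains non-finite values")
    n = d.size
    return float(
        _log_marginal_vec(np.array([d.sum()]), np.array([(d * d).sum()]), n,
                          0.0, 0.0, psi.alpha3, psi.beta3)[0]
    )


def log_marginals(d: PairedDiffMatrix | np.ndarray | None, psi: HyperParams,
                  row_sum: np.ndarray | None = None,
                  row_sq: np.ndarray | None = None,
                  n_pairs: int | None = None) -> np.ndarray:
    """G x 3 matrix of per-gene log marginal densities (columns OE, UE, NE).

    ``row_sum``/``row_sq`` are optional precomputed per-gene sums of d and
    d^2 — the EM inner loop passes them (with ``n_pairs``) to avoid
    rescanning the matrix; ``d`` may then be None.
    """
    if d is None:
        if row_sum is None or row_sq is None or n_pairs is None:
            raise InputError("without d, row_sum, row_sq and n_pairs are required")
        n = int(n_pairs)
    else:
        values = d.values if isinstance(d, PairedDiffMatrix) else np.asarray(d, dtype=float)
        n = values.shape[1]
        if row_sum is None:
            row_sum = values.sum(axis=1)
        if row_sq is None:
            row_sq = (values * values).sum(axis=1)
    out = np.empty((row_sum.shape[0], 3))
    out[:, 0] = _log_marginal_vec(row_sum, row_sq, n, psi.mu1, psi.k1, psi.alpha1, psi.beta1)
    out[:, 1] = _log_marginal_vec(row_sum, row_sq, n, psi.mu2, psi.k2, psi.alpha2, psi.beta2)
    out[:, 2] = _log_marginal_vec(row_sum, row_sq, n, 0.0, 0.0, psi.alpha3, psi.beta3)
    return out
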