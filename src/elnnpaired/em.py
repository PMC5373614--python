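"""EM estimation of the three-component paired-difference mixture.

The E-step computes posterior responsibilities via Bayes' rule on the
closed-form cluster marginals; the M-step updates the mixing proportions in
closed form (Dirichlet-MAP, adding b-1 pseudo-counts per cluster) and
improves the hyper-parameters numerically on the unconstrained scale
(generalized EM: ascent is guaranteed, exact maximization is not).  Genes
are classified to the cluster with the largest responsibility; exact ties
resolve conservatively to NE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp, ndtri

from .model import (
    DegeneracyError,
    HyperParams,
    InputError,
    MixtureModel,
    NonFiniteParameterError,
    PairedDiffMatrix,
    RawParams,
    constraint_gap,
    log_marginals,
    logger,
    natural_to_raw,
    raw_to_natural,
)

__all__ = [
    "FitConfig",
    "Responsibilities",
    "FitResult",
    "e_step",
    "m_step_pi",
    "m_step_psi",
    "expected_complete_loglik",
    "observed_log_posterior",
    "initialize",
    "fit",
]

LABELS = np.array(["OE", "UE", "NE"])


@dataclass(frozen=True)
class FitConfig:
    """EM settings.

    tol: max-abs change in (theta, pi) between iterations that counts as
    converged, on the unconstrained scale.  b: symmetric Dirichlet
    concentration for pi (must be > 1).  p_hi/p_lo: constraint percentiles.
    """

    tol: float = 1e-3
    max_iter: int = 100
    b: float = 2.0
    p_hi: float = 0.95
    p_lo: float = 0.05
    seed: int | None = None
    verbose: bool = False


@dataclass(frozen=True)
class Responsibilities:
    """G x 3 posterior membership probabilities; rows sum to 1."""

    z_tilde: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z_tilde, dtype=float)
        if z.ndim != 2 or z.shape[1] != 3:
            raise InputError(f"responsibilities must be G x 3, got {z.shape}")
        if np.any(z < -1e-12) or np.any(z > 1 + 1e-12):
            raise InputError("responsibilities outside [0, 1]")
        if np.any(np.abs(z.sum(axis=1) - 1.0) > 1e-10):
            raise InputError("responsibility rows must sum to 1 within 1e-10")
        object.__setattr__(self, "z_tilde", z)


@dataclass(frozen=True)
class FitResult:
    model: MixtureModel
    resp: Responsibilities
    labels: np.ndarray  # per-gene "OE" / "UE" / "NE"
    trace: list[dict] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    @property
    def theta(self) -> RawParams:
        return natural_to_raw(self.model.hyper)


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------


def _resp_from_log(log_f: np.ndarray, pi: np.ndarray,
                   gene_ids: tuple[str, ...] | None = None) -> np.ndarray:
    with np.errstate(divide="ignore"):
        log_w = log_f + np.log(np.asarray(pi, dtype=float))
    bad = np.all(np.isneginf(log_w), axis=1)
    if np.any(bad):
        g = int(np.argmax(bad))
        name = gene_ids[g] if gene_ids else f"#{g}"
        raise DegeneracyError(f"all component densities vanished for gene {name}")
    z = np.exp(log_w - logsumexp(log_w, axis=1, keepdims=True))
    return z / z.sum(axis=1, keepdims=True)


def e_step(d: PairedDiffMatrix, model: MixtureModel) -> Responsibilities:
    """Posterior responsibilities z_gc = pi_c f_c(d_g) / sum_s pi_s f_s(d_g)."""
    log_f = log_marginals(d, model.hyper)
    return Responsibilities(_resp_from_log(log_f, np.array(model.pi), d.gene_ids))


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def m_step_pi(resp: Responsibilities, b: float = 2.0) -> np.ndarray:
    """Dirichlet-MAP update pi_c = (sum_g z_gc + b - 1) / (G + 3(b - 1))."""
    if not b > 1:
        raise InputError(f"Dirichlet concentration b must be > 1, got {b}")
    z = resp.z_tilde
    G = z.shape[0]
    return (z.sum(axis=0) + b - 1.0) / (G + 3.0 * (b - 1.0))


def _dirichlet_log_const(b: float) -> float:
    return float(gammaln(3.0 * b) - 3.0 * gammaln(b))


def expected_complete_loglik(d: PairedDiffMatrix, resp: Responsibilities,
                             model: MixtureModel) -> float:
    """Expected complete-data log posterior: density, pi and Dirichlet terms."""
    z = resp.z_tilde
    if z.shape[0] != d.n_genes:
        raise InputError("responsibility rows do not match gene count")
    pi = np.array(model.pi)
    zero = pi == 0.0
    if np.any(zero):
        if np.any(z[:, zero].sum(axis=0) > 0):
            raise DegeneracyError(
                "pi component is 0 while responsibilities put mass on it"
            )
        return -np.inf  # Dirichlet term (b-1) log pi_c diverges
    log_f = log_marginals(d, model.hyper)
    val = float(np.sum(z * log_f))
    val += float(np.sum(z.sum(axis=0) * np.log(pi)))
    val += _dirichlet_log_const(model.b) + (model.b - 1.0) * float(np.sum(np.log(pi)))
    return val


def _weighted_density_obj(theta_vec: np.ndarray, z: np.ndarray, row_sum: np.ndarray,
                          row_sq: np.ndarray, shape: tuple[int, int],
                          p_hi: float, p_lo: float) -> float:
    """Negative sum_g sum_c z_gc log f_c — the psi-dependent part of Eq-style Q."""
    try:
        psi = raw_to_natural(theta_vec, p_hi=p_hi, p_lo=p_lo)
    except NonFiniteParameterError:
        return 1e12
    with np.errstate(all="ignore"):
        log_f = log_marginals(None, psi, row_sum=row_sum, row_sq=row_sq,
                              n_pairs=shape[1])
    val = np.sum(z * log_f)
    if not np.isfinite(val):
        return 1e12
    return -float(val)


def m_step_psi(d: PairedDiffMatrix, resp: Responsibilities, theta0: RawParams,
               p_hi: float = 0.95, p_lo: float = 0.05,
               rng: np.random.Generator | None = None,
               maxiter: int = 80) -> RawParams:
    """Improve the hyper-parameters on the unconstrained scale (GEM ascent).

    Quasi-Newton with finite-difference gradients; if the line search fails
    to improve on theta0 a seeded random restart is tried once, and theta0
    is returned unchanged if neither attempt improves the objective.
    """
    z = resp.z_tilde
    values = d.values
    row_sum = values.sum(axis=1)
    row_sq = (values * values).sum(axis=1)
    args = (z, row_sum, row_sq, values.shape, p_hi, p_lo)
    x0 = theta0.as_array()
    f0 = _weighted_density_obj(x0, *args)

    res = minimize(_weighted_density_obj, x0, args=args, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    best_x, best_f = (res.x, res.fun) if res.fun < f0 else (x0, f0)

    if best_f >= f0 - 1e-12 and f0 < 1e11:
        # stuck: one seeded random restart near theta0
        rng = rng or np.random.default_rng(0)
        x1 = x0 + rng.normal(scale=0.1, size=10)
        res2 = minimize(_weighted_density_obj, x1, args=args, method="L-BFGS-B",
                        options={"maxiter": maxiter})
        if res2.fun < best_f:
            best_x, best_f = res2.x, res2.fun
    return RawParams.from_array(best_x)


def observed_log_posterior(d: PairedDiffMatrix, model: MixtureModel) -> float:
    """Observed-data log posterior sum_g log sum_c pi_c f_c(d_g) + Dirichlet term."""
    log_f = log_marginals(d, model.hyper)
    pi = np.array(model.pi)
    with np.errstate(divide="ignore"):
        per_gene = logsumexp(log_f + np.log(pi), axis=1)
    if np.any(pi == 0.0):
        return -np.inf
    return (
        float(per_gene.sum())
        + _dirichlet_log_const(model.b)
        + (model.b - 1.0) * float(np.sum(np.log(pi)))
    )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _moment_gamma(prec: np.ndarray) -> tuple[float, float]:
    """Gamma (shape, rate) matched to the first two moments of a precision proxy."""
    m = float(np.mean(prec))
    v = float(np.var(prec))
    if v <= 0 or not np.isfinite(v):
        return 2.0, 2.0 / max(m, 1e-8)
    return m * m / v, m / v


def initialize(d: PairedDiffMatrix, config: FitConfig = FitConfig()
               ) -> tuple[np.ndarray, RawParams]:
    """Deterministic moment-based starting point.

    Provisional labels come from per-gene one-sample t statistics cut at the
    5th/95th standard-normal percentiles; cluster-wise method-of-moments on
    the gene means and precision proxies 1/s_g^2 then yields natural-scale
    hyper-parameters, clipped into the feasible region before mapping to the
    unconstrained scale.
    """
    values = d.values
    G, n = values.shape
    m = values.mean(axis=1)
    s = values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(s > 0, m / (s / np.sqrt(n)), np.sign(m) * np.inf)
    z_hi = ndtri(0.95)
    oe = t > z_hi
    ue = t < -z_hi
    ne = ~(oe | ue)

    prec_all = 1.0 / np.clip(s, 1e-8, None) ** 2

    def cluster_stats(mask: np.ndarray, sign: float) -> tuple[float, float, float, float]:
        if mask.sum() < 3:
            logger.warning(
                "initialization: fewer than 3 genes in a provisional cluster; "
                "falling back to global moments with a fixed mean offset"
            )
            alpha, beta = _moment_gamma(prec_all)
            return sign * 0.5, 0.1, alpha, beta
        mu = float(np.mean(m[mask]))
        if mu * sign <= 0:
            mu = sign * 0.5
        k = float(np.clip(np.var(m[mask]) * np.median(prec_all[mask]), 1e-4, 0.99))
        alpha, beta = _moment_gamma(prec_all[mask])
        return mu, k, alpha, beta

    mu1, k1, a1, b1 = cluster_stats(oe, +1.0)
    mu2, k2, a2, b2 = cluster_stats(ue, -1.0)
    if ne.sum() >= 3:
        a3, b3 = _moment_gamma(prec_all[ne])
    else:
        logger.warning("initialization: fewer than 3 provisional NE genes; using global moments")
        a3, b3 = _moment_gamma(prec_all)

    # lift alphas strictly above the constraint bound before inverting
    def feasible_alpha(alpha: float, beta: float, mu: float, k: float,
                       which: int) -> float:
        probe = HyperParams(mu1=abs(mu), k1=k, alpha1=alpha, beta1=beta,
                            mu2=-abs(mu), k2=k, alpha2=alpha, beta2=beta,
                            alpha3=1.0, beta3=1.0, p_hi=config.p_hi, p_lo=config.p_lo)
        gap = constraint_gap(probe)[which]
        if gap < 0.05:
            return alpha + (0.05 - gap)
        return alpha

    a1 = feasible_alpha(a1, b1, mu1, k1, 0)
    a2 = feasible_alpha(a2, b2, mu2, k2, 1)

    psi0 = HyperParams(mu1, k1, a1, b1, mu2, k2, a2, b2, a3, b3,
                       p_hi=config.p_hi, p_lo=config.p_lo)
    theta0 = natural_to_raw(psi0)

    counts = np.array([oe.sum(), ue.sum(), ne.sum()], dtype=float)
    pi0 = np.maximum(counts / G, 0.01)
    pi0 = pi0 / pi0.sum()
    return pi0, theta0


# ---------------------------------------------------------------------------
# fit loop
# ---------------------------------------------------------------------------


def labels_from_resp(resp: Responsibilities) -> np.ndarray:
    """Maximum-posterior labels; exact ties fall back to NE."""
    z = resp.z_tilde
    idx = np.argmax(z, axis=1)
    top = z[np.arange(z.shape[0]), idx]
    tied = (z == top[:, None]).sum(axis=1) > 1
    idx[tied] = 2
    return LABELS[idx]


def fit(d: PairedDiffMatrix, config: FitConfig = FitConfig()) -> FitResult:
    """Alternate E-step and (pi, psi) M-steps until the parameters settle.

    Convergence: max-abs change in the stacked (theta, pi) vector below
    ``config.tol``, or ``config.max_iter`` sweeps.  The trace records the
    observed-data log posterior each iteration (non-decreasing up to
    numerical tolerance, by the generalized-EM argument).
    """
    if d.n_genes < 2:
        raise InputError("need at least 2 genes to fit the mixture")
    if np.any(d.values.std(axis=1) == 0) and d.n_genes < 10:
        raise InputError("constant gene rows in a tiny dataset; nothing to fit")

    rng = np.random.default_rng(config.seed if config.seed is not None else 0)
    pi, theta = initialize(d, config)
    trace: list[dict] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        psi = raw_to_natural(theta, p_hi=config.p_hi, p_lo=config.p_lo)
        model = MixtureModel(hyper=psi, pi=tuple(pi), b=config.b)
        resp = e_step(d, model)
        pi_new = m_step_pi(resp, b=config.b)
        theta_new = m_step_psi(d, resp, theta, p_hi=config.p_hi, p_lo=config.p_lo,
                               rng=rng)
        model_new = MixtureModel(
            hyper=raw_to_natural(theta_new, p_hi=config.p_hi, p_lo=config.p_lo),
            pi=tuple(pi_new), b=config.b,
        )
        obj = observed_log_posterior(d, model_new)
        if not np.isfinite(obj):
            raise DegeneracyError(f"non-finite objective at iteration {it}")
        delta = max(
            float(np.max(np.abs(theta_new.as_array() - theta.as_array()))),
            float(np.max(np.abs(pi_new - pi))),
        )
        trace.append({"iter": it, "objective": obj, "delta": delta})
        if config.verbose:
            logger.info("iter %3d  objective %.6f  delta %.3g", it, obj, delta)
        pi, theta = pi_new, theta_new
        if delta < config.tol:
            converged = True
            break

    psi = raw_to_natural(theta, p_hi=config.p_hi, p_lo=config.p_lo)
    model = MixtureModel(hyper=psi, pi=tuple(pi), b=config.b)
    resp = e_step(d, model)
    return FitResult(model=model, resp=resp, labels=labels_from_resp(resp),
                     trace=trace, converged=converged, n_iter=it)
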