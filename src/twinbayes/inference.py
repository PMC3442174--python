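"""Laplace approximation and random-walk Metropolis–Hastings sampling.

The posterior over the transformed parameters (lam, mu_mz, mu_dz) is
explored in two steps, mirroring the estimation scheme the model was
designed around:

1. :func:`laplace_approx` finds the posterior mode by numerical
   optimization and the covariance as the inverse negative Hessian of
   the log posterior at the mode (central finite differences).
2. :func:`run_mh` runs a random-walk Metropolis–Hastings chain whose
   multivariate-normal proposal has covariance equal to the Laplace
   covariance and whose starting point is the Laplace mode.  Proposals
   that land outside the admissible region have log posterior -inf and
   are rejected, so the chain simply stays put there.

Randomness contract: a single integer seed drives the whole run through
``numpy.random.default_rng``; the proposal increments are drawn first
(all n_iter at once), then the acceptance uniforms, so a run is
bit-reproducible for a given seed and numpy version.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import (
    HyperParams,
    TransformedParams,
    TwinCounts,
    delta_from_concordance,
    make_log_posterior,
)
from .simulate import empirical_rates

__all__ = ["LaplaceFit", "Chain", "laplace_approx", "run_mh", "autocorrelation"]


@dataclass(frozen=True)
class LaplaceFit:
    """Posterior mode and Laplace covariance over (lam, mu_mz, mu_dz)."""

    mode: TransformedParams
    covariance: np.ndarray
    log_post_at_mode: float = float("nan")

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (3, 3):
            raise ValueError(f"covariance must be 3x3, got shape {cov.shape}")
        if not np.allclose(cov, cov.T, atol=1e-8 * (1 + np.abs(cov).max())):
            raise ValueError("covariance is not symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() <= 0:
            raise ValueError(f"covariance is not positive definite (eigenvalues {eig})")
        object.__setattr__(self, "covariance", (cov + cov.T) / 2.0)


@dataclass(frozen=True)
class Chain:
    """An MH run: draws over (lam, mu_mz, mu_dz) plus run metadata."""

    draws: np.ndarray  # shape (n_iter, 3)
    acceptance_rate: float
    seed: int
    n_iter: int
    proposal_covariance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        if draws.ndim != 2 or draws.shape[1] != 3:
            raise ValueError("draws must have shape (n_iter, 3)")
        if draws.shape[0] != self.n_iter:
            raise ValueError("draws length must equal n_iter")
        object.__setattr__(self, "draws", draws)

    @property
    def lam(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def mu_mz(self) -> np.ndarray:
        return self.draws[:, 1]

    @property
    def mu_dz(self) -> np.ndarray:
        return self.draws[:, 2]


def _moment_start(y_mz: TwinCounts, y_dz: TwinCounts, h: HyperParams) -> np.ndarray:
    """Naive starting point for the mode search, clipped to admissibility."""
    n_aff = y_mz.n_affected + y_dz.n_affected
    n_ind = 2 * (y_mz.n_pairs + y_dz.n_pairs)
    if n_aff > 0:
        pi0 = n_aff / n_ind
    else:
        # fall back on the prior mean; informative a1 > 1 required upstream
        pi0 = h.a1 / (h.a1 + h.a2)
    pi0 = min(max(pi0, 1e-8), 1.0 - 1e-8)

    mus = []
    for y in (y_mz, y_dz):
        _, q_hat = empirical_rates(y) if y.n_pairs else (pi0, float("nan"))
        if math.isnan(q_hat):
            delta0 = 0.0
        else:
            delta0 = delta_from_concordance(pi0, min(max(q_hat, 0.0), 1.0))
        # keep strictly inside the admissible delta interval
        lo = delta_from_concordance(pi0, max(0.0, 2.0 - 1.0 / pi0))
        delta0 = min(max(delta0, lo * 0.99 if lo < 0 else lo + 1e-6), 0.99)
        mus.append(2.0 * math.atanh(delta0))
    return np.array([math.log(pi0 / (1.0 - pi0)), mus[0], mus[1]])


def _fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian; shrinks steps if a point is inadmissible."""
    n = x.size
    steps = rel_step * np.maximum(1.0, np.abs(x))
    for _ in range(6):
        hess = np.empty((n, n))
        ok = True
        f0 = f(x)
        for i in range(n):
            ei = np.zeros(n)
            ei[i] = steps[i]
            fpp = f(x + 2 * ei)
            fmm = f(x - 2 * ei)
            if not (math.isfinite(fpp) and math.isfinite(fmm)):
                ok = False
                break
            hess[i, i] = (fpp - 2 * f0 + fmm) / (4 * steps[i] ** 2)
            for j in range(i + 1, n):
                ej = np.zeros(n)
                ej[j] = steps[j]
                vals = [f(x + ei + ej), f(x + ei - ej), f(x - ei + ej), f(x - ei - ej)]
                if not all(math.isfinite(v) for v in vals):
                    ok = False
                    break
                hess[i, j] = hess[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (
                    4 * steps[i] * steps[j]
                )
            if not ok:
                break
        if ok:
            return hess
        steps = steps / 10.0
    raise RuntimeError("could not evaluate a finite Hessian near the mode")


def laplace_approx(y_mz: TwinCounts, y_dz: TwinCounts, h: HyperParams) -> LaplaceFit:
    """Posterior mode and inverse-negative-Hessian covariance.

    The mode is found with Nelder–Mead (robust to the hard admissibility
    boundary, where the objective drops to -inf), polished by a second
    Nelder–Mead restart; the Hessian is computed by central finite
    differences at the mode.

    Raises ``ValueError`` when the data contain no affected individual
    and the prevalence prior is flat (the prevalence mode then sits on
    the boundary pi -> 0: supply an informative prior), and
    ``RuntimeError`` on optimizer failure or a non-positive-definite
    Hessian.
    """
    if y_mz.n_pairs + y_dz.n_pairs < 1:
        raise ValueError("no twin pairs supplied")
    if y_mz.n_affected + y_dz.n_affected == 0 and h.a1 <= 1.0:
        raise ValueError(
            "data contain no affected individuals and the prevalence prior is flat; "
            "the posterior mode diverges — supply an informative prevalence prior"
        )
    logpost = make_log_posterior(y_mz, y_dz, h)

    def neg(x):
        v = logpost(x)
        return -v if math.isfinite(v) else 1e300

    x0 = _moment_start(y_mz, y_dz, h)
    if not math.isfinite(logpost(x0)):
        raise RuntimeError(f"starting point {x0} has non-finite log posterior")

    # two derivative-free searches from the moment start (they fail on
    # different landscapes), then a tight Nelder-Mead polish of the winner
    cands = [
        optimize.minimize(neg, x0, method="Nelder-Mead",
                          options={"xatol": 1e-9, "fatol": 1e-10,
                                   "maxiter": 20000, "maxfev": 20000}),
        optimize.minimize(neg, x0, method="Powell", options={"maxiter": 20000}),
    ]
    first = min(cands, key=lambda r: r.fun)
    best = optimize.minimize(
        neg, first.x, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    if best.fun > first.fun:
        best = first
    if not math.isfinite(best.fun) or best.fun >= 1e300:
        raise RuntimeError("mode search failed: non-finite objective at optimum")

    hess = _fd_hessian(logpost, best.x)
    neg_hess = -hess
    try:
        cov = np.linalg.inv(neg_hess)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(f"singular Hessian at the mode: {exc}") from exc
    cov = (cov + cov.T) / 2.0
    if np.linalg.eigvalsh(cov).min() <= 0:
        raise RuntimeError(
            "negative Hessian at the mode is not positive definite; "
            "the Laplace approximation is unavailable for these data"
        )
    mode = TransformedParams(lam=best.x[0], mu_mz=best.x[1], mu_dz=best.x[2])
    return LaplaceFit(mode=mode, covariance=cov, log_post_at_mode=-best.fun)


def run_mh(
    y_mz: TwinCounts,
    y_dz: TwinCounts,
    h: HyperParams,
    n_iter: int,
    seed: int,
    proposal_cov: np.ndarray | None = None,
    start: TransformedParams | None = None,
    proposal_scale: float = 1.0,
    laplace: LaplaceFit | None = None,
) -> Chain:
    """Random-walk Metropolis–Hastings chain targeting the joint posterior.

    When ``proposal_cov`` or ``start`` are omitted they default to the
    Laplace covariance and mode (computed here unless a ``laplace`` fit
    is passed in).  ``proposal_scale`` multiplies the proposal
    covariance; the default 1.0 uses the Laplace covariance as-is.
    Constraint-violating proposals count as ordinary rejections in the
    acceptance rate.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if seed is None:
        raise ValueError("an explicit integer seed is required for reproducibility")
    if proposal_cov is None or start is None:
        if laplace is None:
            laplace = laplace_approx(y_mz, y_dz, h)
        if proposal_cov is None:
            proposal_cov = laplace.covariance
        if start is None:
            start = laplace.mode

    logpost = make_log_posterior(y_mz, y_dz, h)
    x = start.as_array()
    lp = logpost(x)
    if not math.isfinite(lp):
        raise ValueError(f"non-finite log posterior at the starting point {start}")

    cov = proposal_scale * np.asarray(proposal_cov, dtype=float)
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    increments = rng.standard_normal((n_iter, 3)) @ chol.T
    log_u = np.log(rng.random(n_iter))

    draws = np.empty((n_iter, 3))
    accepted = 0
    for t in range(n_iter):
        prop = x + increments[t]
        lp_prop = logpost(prop)
        if lp_prop - lp > log_u[t]:  # -inf proposals always fail
            x = prop
            lp = lp_prop
            accepted += 1
        draws[t] = x
    return Chain(
        draws=draws,
        acceptance_rate=accepted / n_iter,
        seed=seed,
        n_iter=n_iter,
        proposal_covariance=cov,
    )


def autocorrelation(chain: Chain | np.ndarray, index: int = 0, max_lag: int = 50) -> np.ndarray:
    """Sample autocorrelation function of one chain component.

    Returns rho[0..max_lag] with rho[0] = 1.  A constant chain has an
    undefined ACF; an all-NaN array is returned as the error marker.
    """
    x = chain.draws[:, index] if isinstance(chain, Chain) else np.asarray(chain, dtype=float)
    n = x.size
    if n <= max_lag:
        raise ValueError(f"chain length {n} must exceed max_lag {max_lag}")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        return np.full(max_lag + 1, np.nan)
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        acf[k] = float(xc[:-k] @ xc[k:]) / denom
    return acf
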