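"""Core parametrization and posterior for the twin-concordance model.

A dichotomous trait observed on twin pairs is summarized, per zygosity
group, by a 3-cell count vector ``(y11, yd, y00)``: both affected,
discordant, both healthy (twins within a pair are assumed exchangeable,
so the two discordant cells are collapsed).  The model has three
parameters shared across a monozygotic (MZ) and a dizygotic (DZ) group:

* ``pi`` — trait prevalence, identical in MZ twins, DZ twins and
  singletons;
* ``delta_mz``, ``delta_dz`` — the *dependence difference*
  ``P(affected | co-twin affected) - P(affected | co-twin healthy)``
  for each zygosity, a label-invariant measure of within-pair
  association (0 under independence).

The case-wise concordance rate follows as ``q = delta*(1-pi) + pi``, and
the multinomial cell probabilities as ``p11 = pi*q``, ``pd = 2*pi*(1-q)``,
``p00 = 1 - p11 - pd``.  Admissibility requires every cell probability to
lie in [0, 1]; this is stronger than the bare inequality
``delta > (pi-1)/pi`` (which only keeps ``p00`` non-negative) because it
also rules out negative ``q`` when ``pi < 1/2``.

For sampling, parameters are mapped to the real line with
``lam = logit(pi)`` and ``mu = ln((1+delta)/(1-delta))``; the log joint
posterior includes the corresponding Jacobian terms and Beta-family
priors: ``pi ~ Beta(a1, a2)`` and truncated scaled-Beta densities on each
delta with shapes ``(b1, b2)`` and ``(g1, g2)``.  All-ones hyperparameters
give the non-informative model whose posterior is proportional to the
likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TwinCounts",
    "ModelParams",
    "TransformedParams",
    "HyperParams",
    "CellProbs",
    "concordance",
    "delta_from_concordance",
    "cell_probs",
    "constraint_ok",
    "to_real",
    "from_real",
    "log_likelihood",
    "log_posterior",
    "make_log_posterior",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class TwinCounts:
    """Collapsed pair counts for one zygosity group.

    ``y11`` pairs with both twins affected, ``yd`` discordant pairs
    (one affected, one healthy), ``y00`` pairs with both healthy.
    """

    y11: int
    yd: int
    y00: int

    def __post_init__(self) -> None:
        for name in ("y11", "yd", "y00"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_pairs(self) -> int:
        return self.y11 + self.yd + self.y00

    @property
    def n_affected(self) -> int:
        """Affected individuals (two per concordant pair, one per discordant)."""
        return 2 * self.y11 + self.yd

    def __add__(self, other: "TwinCounts") -> "TwinCounts":
        return TwinCounts(self.y11 + other.y11, self.yd + other.yd, self.y00 + other.y00)


@dataclass(frozen=True)
class ModelParams:
    """Natural-scale parameters (pi, delta_mz, delta_dz).

    Construction does not enforce the admissibility constraint (use
    :func:`constraint_ok`); it only checks the basic ranges.
    """

    pi: float
    delta_mz: float
    delta_dz: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"pi must be in (0, 1), got {self.pi}")
        for name in ("delta_mz", "delta_dz"):
            d = getattr(self, name)
            if not -1.0 <= d <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1], got {d}")

    def is_admissible(self) -> bool:
        return constraint_ok(self.pi, self.delta_mz) and constraint_ok(self.pi, self.delta_dz)


@dataclass(frozen=True)
class TransformedParams:
    """Real-line parameters (lam, mu_mz, mu_dz) used by the sampler."""

    lam: float
    mu_mz: float
    mu_dz: float

    def __post_init__(self) -> None:
        for name in ("lam", "mu_mz", "mu_dz"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    def as_array(self):
        import numpy as np

        return np.array([self.lam, self.mu_mz, self.mu_dz], dtype=float)


@dataclass(frozen=True)
class HyperParams:
    """Beta-family shape hyperparameters.

    ``a1, a2`` for the prevalence Beta prior; ``b1, b2`` and ``g1, g2``
    for the truncated scaled-Beta priors on delta_mz and delta_dz.  The
    all-ones instance (:meth:`flat`) is the non-informative default.
    """

    a1: float = 1.0
    a2: float = 1.0
    b1: float = 1.0
    b2: float = 1.0
    g1: float = 1.0
    g2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "b1", "b2", "g1", "g2"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"hyperparameter {name} must be a positive real, got {v}")

    @classmethod
    def flat(cls) -> "HyperParams":
        return cls()

    def is_flat(self) -> bool:
        return all(getattr(self, k) == 1.0 for k in ("a1", "a2", "b1", "b2", "g1", "g2"))


@dataclass(frozen=True)
class CellProbs:
    """Multinomial cell probabilities (p11, pd, p00) for one zygosity."""

    p11: float
    pd: float
    p00: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p11, self.pd, self.p00)


def concordance(pi: float, delta: float) -> float:
    """Case-wise concordance rate q = delta*(1-pi) + pi.

    Raises ``ValueError`` if (pi, delta) is inadmissible, naming the
    offending value.
    """
    if not constraint_ok(pi, delta):
        raise ValueError(
            f"inadmissible parameters: delta={delta} with pi={pi} "
            "yields a cell probability outside [0, 1]"
        )
    return delta * (1.0 - pi) + pi


def delta_from_concordance(pi: float, q: float) -> float:
    """Dependence difference implied by a concordance rate: (q-pi)/(1-pi)."""
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must be in (0, 1), got {pi}")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    return (q - pi) / (1.0 - pi)


def constraint_ok(pi: float, delta: float) -> bool:
    """True iff (pi, delta) gives valid multinomial cell probabilities.

    Admissibility means all of p11, pd, p00 lie in [0, 1], i.e. the
    concordance rate q is in [max(0, 2 - 1/pi), 1].  This implies the
    weaker inequality delta > (pi-1)/pi but additionally excludes
    negative q, which that inequality alone permits for pi < 1/2.
    """
    if not 0.0 < pi < 1.0 or not -1.0 <= delta <= 1.0:
        return False
    q = delta * (1.0 - pi) + pi
    if q < 0.0 or q > 1.0:
        return False
    # p00 = 1 + pi*(q - 2) >= 0  <=>  q >= 2 - 1/pi
    return 1.0 + pi * (q - 2.0) >= 0.0


def cell_probs(pi: float, delta: float) -> CellProbs:
    """Multinomial cell probabilities for one zygosity group."""
    q = concordance(pi, delta)  # validates admissibility
    p11 = pi * q
    pd = 2.0 * pi * (1.0 - q)
    p00 = 1.0 - p11 - pd
    return CellProbs(p11, pd, p00)


def to_real(params: ModelParams) -> TransformedParams:
    """Map natural parameters to the real line.

    lam = ln(pi/(1-pi)); mu = ln((1+delta)/(1-delta)).  Boundary values
    (pi in {0,1}, delta in {-1,1}) have no finite image and raise.
    """
    pi, dm, dd = params.pi, params.delta_mz, params.delta_dz
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi={pi} is on the boundary; logit undefined")
    if not (-1.0 < dm < 1.0 and -1.0 < dd < 1.0):
        raise ValueError("delta on the boundary {-1, 1}; transform undefined")
    return TransformedParams(
        lam=math.log(pi / (1.0 - pi)),
        mu_mz=math.log((1.0 + dm) / (1.0 - dm)),
        mu_dz=math.log((1.0 + dd) / (1.0 - dd)),
    )


def from_real(t: TransformedParams) -> ModelParams:
    """Inverse of :func:`to_real`; total on finite inputs.

    The admissibility constraint is *not* enforced here — the sampler
    handles inadmissible points through a -inf log posterior.
    """
    pi = _expit(t.lam)
    return ModelParams(
        pi=pi,
        delta_mz=math.tanh(0.5 * t.mu_mz),
        delta_dz=math.tanh(0.5 * t.mu_dz),
    )


def _expit(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _xlogy(x: float, y: float) -> float:
    # 0*log(0) := 0; positive count with zero probability -> -inf
    if x == 0.0:
        return 0.0
    if y <= 0.0:
        return _NEG_INF
    return x * math.log(y)


def log_likelihood(params: ModelParams, y_mz: TwinCounts, y_dz: TwinCounts) -> float:
    """Log likelihood (multinomial constant dropped) of two zygosity groups.

    Returns -inf for inadmissible parameters or for a zero cell
    probability paired with a positive count; never raises, so it can sit
    inside a sampler.
    """
    total = 0.0
    for delta, y in ((params.delta_mz, y_mz), (params.delta_dz, y_dz)):
        if not constraint_ok(params.pi, delta):
            return _NEG_INF
        p = cell_probs(params.pi, delta)
        term = _xlogy(y.y11, p.p11) + _xlogy(y.yd, p.pd) + _xlogy(y.y00, p.p00)
        if term == _NEG_INF:
            return _NEG_INF
        total += term
    return total


def _log1pexp(x: float) -> float:
    # log(1 + exp(x)) without overflow
    if x > 35.0:
        return x
    if x < -35.0:
        return math.exp(x)
    return math.log1p(math.exp(x))


def make_log_posterior(y_mz: TwinCounts, y_dz: TwinCounts, h: HyperParams):
    """Return a fast callable ``f(theta) -> float`` for the log posterior.

    ``theta`` is the length-3 sequence (lam, mu_mz, mu_dz).  The callable
    evaluates the log of the transformed joint posterior: Beta prior on
    pi, scaled-Beta priors on the deltas, the three change-of-variable
    Jacobian terms exp(x)/(1+exp(x))^2, and the two-group multinomial log
    likelihood.  Inadmissible points (a cell probability outside [0, 1])
    return -inf, which makes a Metropolis step reject and stay put.
    """
    a1, a2, b1, b2, g1, g2 = h.a1, h.a2, h.b1, h.b2, h.g1, h.g2
    counts = (
        (float(y_mz.y11), float(y_mz.yd), float(y_mz.y00)),
        (float(y_dz.y11), float(y_dz.yd), float(y_dz.y00)),
    )
    shapes = ((b1, b2), (g1, g2))
    log2 = math.log(2.0)

    def logpost(theta) -> float:
        lam, mu0, mu1 = float(theta[0]), float(theta[1]), float(theta[2])
        if not (math.isfinite(lam) and math.isfinite(mu0) and math.isfinite(mu1)):
            return _NEG_INF
        log_pi = -_log1pexp(-lam)  # log expit(lam)
        log_1mpi = -_log1pexp(lam)
        pi = math.exp(log_pi)

        # prevalence prior + lambda Jacobian (pi*(1-pi))
        out = (a1 - 1.0) * log_pi + (a2 - 1.0) * log_1mpi + log_pi + log_1mpi

        for mu, (s1, s2), (c11, cd, c00) in zip((mu0, mu1), shapes, counts):
            delta = math.tanh(0.5 * mu)
            q = delta * (1.0 - pi) + pi
            p11 = pi * q
            pd = 2.0 * pi * (1.0 - q)
            p00 = 1.0 - p11 - pd
            if q < 0.0 or q > 1.0 or p00 < 0.0:
                return _NEG_INF
            # log(1+delta) = log2 + log expit(mu); log(1-delta) = log2 + log expit(-mu)
            log_e_pos = -_log1pexp(-mu)
            log_e_neg = -_log1pexp(mu)
            out += (s1 - 1.0) * (log2 + log_e_pos) + (s2 - 1.0) * (log2 + log_e_neg)
            out += log_e_pos + log_e_neg  # mu Jacobian, constant dropped
            ll = _xlogy(c11, p11) + _xlogy(cd, pd) + _xlogy(c00, p00)
            if ll == _NEG_INF:
                return _NEG_INF
            out += ll
        return out

    return logpost


def log_posterior(
    t: TransformedParams, y_mz: TwinCounts, y_dz: TwinCounts, h: HyperParams
) -> float:
    """Log joint posterior density (up to a constant) at a transformed point.

    Convenience wrapper over :func:`make_log_posterior`; use the factory
    directly when evaluating many points for the same data.
    """
    return make_log_posterior(y_mz, y_dz, h)((t.lam, t.mu_mz, t.mu_dz))
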