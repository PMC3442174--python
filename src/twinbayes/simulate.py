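"""Simulation of twin-pair count data with the model's multinomial structure.

Pairs are simulated directly at the pair level: one multinomial draw of
size ``n`` per zygosity over the three collapsed cells.  Under within-pair
exchangeability this is equivalent to simulating individual twins and
tabulating, and the split of discordant pairs into (affected, healthy)
orderings is irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TwinCounts, cell_probs, constraint_ok, delta_from_concordance

__all__ = ["SimScenario", "simulate", "empirical_rates"]


@dataclass(frozen=True)
class SimScenario:
    """Generating parameters for a two-group twin simulation.

    ``pi`` is the prevalence, ``q_mz``/``q_dz`` the case-wise concordance
    rates, ``n_mz``/``n_dz`` the numbers of pairs per zygosity.  The seed
    is part of the scenario so a dataset is reproducible from its file.
    """

    pi: float
    q_mz: float
    q_dz: float
    n_mz: int
    n_dz: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_mz < 1 or self.n_dz < 1:
            raise ValueError("pair counts must be >= 1")
        for name in ("q_mz", "q_dz"):
            q = getattr(self, name)
            delta = delta_from_concordance(self.pi, q)  # validates pi, q ranges
            if not constraint_ok(self.pi, delta):
                raise ValueError(
                    f"{name}={q} is inadmissible at pi={self.pi} "
                    "(implied cell probability outside [0, 1])"
                )

    @property
    def delta_mz(self) -> float:
        return delta_from_concordance(self.pi, self.q_mz)

    @property
    def delta_dz(self) -> float:
        return delta_from_concordance(self.pi, self.q_dz)


def simulate(scenario: SimScenario) -> tuple[TwinCounts, TwinCounts]:
    """Draw one dataset: a multinomial count vector per zygosity.

    The random stream is ``numpy.random.default_rng(seed)``; the MZ
    vector is drawn first, then the DZ vector, so output is reproducible
    bit-for-bit for a given seed and numpy version.
    """
    rng = np.random.default_rng(scenario.seed)
    out = []
    for q, n in ((scenario.q_mz, scenario.n_mz), (scenario.q_dz, scenario.n_dz)):
        delta = delta_from_concordance(scenario.pi, q)
        p = cell_probs(scenario.pi, delta)
        draw = rng.multinomial(n, [p.p11, p.pd, p.p00])
        out.append(TwinCounts(int(draw[0]), int(draw[1]), int(draw[2])))
    return out[0], out[1]


def empirical_rates(y: TwinCounts) -> tuple[float, float]:
    """Naive moment estimates (prevalence, case-wise concordance).

    prevalence = (2*y11 + yd) / (2*n); concordance = 2*y11 / (2*y11 + yd),
    i.e. the fraction of affected individuals whose co-twin is affected.
    With no affected individuals the concordance is undefined and NaN is
    returned in its place.
    """
    if y.n_pairs < 1:
        raise ValueError("need at least one pair")
    prevalence = y.n_affected / (2 * y.n_pairs)
    if y.n_affected == 0:
        return prevalence, float("nan")
    return prevalence, 2 * y.y11 / y.n_affected
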