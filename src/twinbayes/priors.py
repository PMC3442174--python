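"""Informative priors from prevalence studies and pooling of twin studies.

A general-population prevalence study with ``n1`` affected out of ``n``
individuals updates the flat Beta(1, 1) prevalence prior to
Beta(1 + n1, 1 + (n - n1)) — exactly the binomial likelihood of the
study folded into the prior.  An earlier *twin* study informs both
prevalence and concordance; with flat base priors its posterior equals
its likelihood, so using it as the prior for a new study is the same as
fitting the elementwise *sum* of the two count vectors per zygosity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .model import HyperParams, TwinCounts

__all__ = ["PrevalenceStudy", "prevalence_prior", "pool_twin_studies", "power_prior_pool"]


@dataclass(frozen=True)
class PrevalenceStudy:
    """A prevalence study: ``n_affected`` cases out of ``n_total`` individuals."""

    n_affected: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_affected < 0 or self.n_total < 0:
            raise ValueError("prevalence-study counts must be non-negative")
        if self.n_affected > self.n_total:
            raise ValueError(
                f"n_affected ({self.n_affected}) exceeds n_total ({self.n_total})"
            )


def prevalence_prior(study: PrevalenceStudy, base: HyperParams | None = None) -> HyperParams:
    """Fold a prevalence study into the prevalence Beta prior.

    Returns hyperparameters with ``a1 = 1 + n_affected`` and
    ``a2 = 1 + n_healthy``; the delta shapes are carried over from
    ``base`` (flat if omitted) untouched.  The empty study (0 of 0)
    leaves the flat Beta(1, 1) prior.
    """
    if base is None:
        base = HyperParams.flat()
    return HyperParams(
        a1=1.0 + study.n_affected,
        a2=1.0 + (study.n_total - study.n_affected),
        b1=base.b1,
        b2=base.b2,
        g1=base.g1,
        g2=base.g2,
    )


def pool_twin_studies(
    studies: Sequence[tuple[TwinCounts, TwinCounts]],
) -> tuple[TwinCounts, TwinCounts]:
    """Combine twin studies by summing their (MZ, DZ) count vectors.

    Equal weighting of all studies: with flat priors, fitting the summed
    vectors is distributionally identical to chaining each study's
    posterior into the next study's prior.
    """
    if len(studies) == 0:
        raise ValueError("need at least one study to pool")
    z_mz = TwinCounts(0, 0, 0)
    z_dz = TwinCounts(0, 0, 0)
    for mz, dz in studies:
        z_mz = z_mz + mz
        z_dz = z_dz + dz
    return z_mz, z_dz


def power_prior_pool(
    studies: Sequence[tuple[TwinCounts, TwinCounts]], weights: Sequence[float]
) -> tuple[TwinCounts, TwinCounts]:
    """Unequal (power-prior) weighting of historical studies.

    Not implemented; only equal-weight pooling is supported.
    """
    raise NotImplementedError(
        "power-prior weighting of historical studies is not implemented; "
        "use pool_twin_studies for equal weighting"
    )
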