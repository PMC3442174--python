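"""High-level one-call fitting workflow.

``fit`` chains the full estimation pipeline — Laplace approximation,
random-walk Metropolis–Hastings, back-transformation, posterior
summaries — and returns everything a report needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .inference import Chain, LaplaceFit, laplace_approx, run_mh
from .model import HyperParams, TwinCounts
from .summaries import DerivedDraws, backtransform, summarize

__all__ = ["FitResult", "fit"]


@dataclass(frozen=True)
class FitResult:
    """Everything produced by one model fit."""

    laplace: LaplaceFit
    chain: Chain
    draws: DerivedDraws
    summary: pd.DataFrame
    hyper: HyperParams
    burn_in: int


def fit(
    y_mz: TwinCounts,
    y_dz: TwinCounts,
    hyper: HyperParams | None = None,
    n_iter: int = 100_000,
    seed: int = 0,
    burn_in: int = 0,
    hpd_mass: float = 0.95,
    proposal_scale: float = 1.0,
) -> FitResult:
    """Fit the twin-concordance model to one MZ and one DZ count vector.

    Runs the Laplace approximation (mode start, covariance proposal),
    ``n_iter`` Metropolis–Hastings iterations, then back-transforms and
    summarizes.  ``burn_in`` draws are discarded before summarizing
    (default 0: the chain already starts at the posterior mode).
    """
    if hyper is None:
        hyper = HyperParams.flat()
    lap = laplace_approx(y_mz, y_dz, hyper)
    chain = run_mh(
        y_mz, y_dz, hyper,
        n_iter=n_iter, seed=seed, laplace=lap, proposal_scale=proposal_scale,
    )
    draws = backtransform(chain, burn_in=burn_in)
    summary = summarize(draws, mass=hpd_mass)
    return FitResult(
        laplace=lap, chain=chain, draws=draws, summary=summary,
        hyper=hyper, burn_in=burn_in,
    )
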