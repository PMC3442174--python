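"""Compare MCMC posteriors with the Laplace (normal) approximation.

For a rare trait the prevalence posterior is close to normal, but the
concordance-rate posteriors are right-skewed, so a normal approximation
misstates their intervals.  This is the reason for sampling the exact
posterior instead of relying on asymptotic normality.
"""

from scipy import stats

import twinbayes as tb

# simulated realization: 100k MZ + 100k DZ pairs at pi = 1%, q = pi
y_mz = tb.TwinCounts(6, 1876, 98118)
y_dz = tb.TwinCounts(12, 2007, 97981)

hyper = tb.HyperParams.flat()
lap = tb.laplace_approx(y_mz, y_dz, hyper)
chain = tb.run_mh(y_mz, y_dz, hyper, n_iter=100_000, seed=1, laplace=lap)
draws = tb.backtransform(chain)

mcmc = tb.summarize(draws)
normal = tb.normal_approx_summary(lap, n_draws=100_000, seed=2)

print(f"{'quantity':<6} {'MCMC 95% HPD':>22} {'normal-approx 95% HPD':>24} {'skew':>7}")
for name in ("pi", "q_mz", "q_dz"):
    m, n = mcmc.loc[name], normal.loc[name]
    skew = stats.skew(draws.as_dict()[name])
    print(
        f"{name:<6} ({m['hpd_low']:.4f}, {m['hpd_high']:.4f})"
        f"{'':>6} ({n['hpd_low']:.4f}, {n['hpd_high']:.4f}){'':>8} {skew:>6.2f}"
    )
print(
    "\nThe two intervals agree for pi (skew near 0, 400,000 individuals)"
    "\nbut diverge for the skewed concordance rates: the sampled HPDs are"
    "\nasymmetric around the mode where the normal ones cannot be."
)
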