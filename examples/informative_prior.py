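"""Add an informative prevalence prior from a population registry.

A registry that observed 1,693 cleft-lip cases among 2,524,359 boys
updates the flat Beta(1, 1) prevalence prior to Beta(1694, 2522667) —
exactly the binomial likelihood of the registry folded into the prior.
The extra information sharpens the prevalence posterior and, indirectly,
both concordance-rate posteriors.
"""

import twinbayes as tb

y_mz = tb.TwinCounts(3, 8, 4474)
y_dz = tb.TwinCounts(1, 14, 8164)

registry = tb.PrevalenceStudy(n_affected=1693, n_total=2524359)
hyper = tb.prevalence_prior(registry)
print(f"prevalence prior: Beta({hyper.a1:.0f}, {hyper.a2:.0f})\n")

flat = tb.fit(y_mz, y_dz, n_iter=100_000, seed=1)
informed = tb.fit(y_mz, y_dz, hyper, n_iter=100_000, seed=1)

for label, res in (("flat prior", flat), ("registry prior", informed)):
    s = res.summary
    print(
        f"{label:>14}: pi = {100 * s.loc['pi', 'mean']:.2f}% "
        f"(sd {100 * s.loc['pi', 'sd']:.3f}%), "
        f"q_mz = {s.loc['q_mz', 'mean']:.2f}, q_dz = {s.loc['q_dz', 'mean']:.2f}"
    )
print(
    "\nThe registry prior lowers the prevalence estimate and shrinks its"
    "\nSD by an order of magnitude; the concordance means shift with it."
)
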