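"""Fit the 7-term sqrt-product ERGM to a synthetic friendship network.

The generating coefficients are known (sex homophily 3.808,
prosociality sqrt-product 0.211), so the printed estimates can be read
against their true values. Estimation: MPLE start, then MCMC-MLE under
the out-degree <= 7 sample-space constraint.
"""

import prosonet as pn

truth = pn.study_like_truth()
attrs = pn.generate_attributes(truth, seed=1)
net = pn.generate_network(truth, attrs, seed=1)
print(f"network: {net.n_nodes} nodes, {net.n_edges} directed ties")

mple_fit = pn.mple(net, truth.model, truth.constraint)
print("\nMPLE start:")
print(mple_fit.to_frame().to_string(float_format=lambda v: f"{v:.3f}"))

fit = pn.mcmc_mle(
    net,
    truth.model,
    truth.constraint,
    settings=pn.McmcSettings(
        burnin=100_000, interval=3_000, ndraws=2_500, tol=1e-3, max_iter=12
    ),
    seed=1,
)
print("\nMCMC-MLE:")
print(fit.report())
print(
    "\ntrue generating values:",
    {k: round(float(v), 3) for k, v in zip(truth.model.names, truth.model.coefficients)},
)
# A positive sqrt-product coefficient is the assortment signal: ties
# are most likely when both actors are highly prosocial. Each estimate
# should sit within ~2 standard errors of its generating value.
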