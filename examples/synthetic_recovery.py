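"""Parameter recovery: generate -> refit -> tabulate bias and coverage.

Networks are drawn from a known 5-term model (with gwesp closure and
the out-degree <= 7 cap); each replicate is re-estimated and the table
reports per-term bias, RMSE and 95% CI coverage. Honest estimation
shows small bias and coverage near 0.95.
"""

import prosonet as pn
from prosonet import ModelSpec, TermSpec

model = ModelSpec(
    [
        TermSpec("edges"),
        TermSpec("nodematch", attribute="sex"),
        TermSpec("edgecov", covariate="sqrt_product:prosociality"),
        TermSpec("odegree0"),
        TermSpec("gwesp", alpha=0.25),
    ]
).with_coefficients([-6.0, 2.0, 0.25, 1.0, 0.6])
truth = pn.SyntheticTruth(n_nodes=120, model=model)

table = pn.recovery_experiment(
    truth,
    n_replicates=10,
    seed=7,
    estimators=("mple", "mcmc"),
    fit_settings=pn.McmcSettings(
        burnin=30_000, interval=200, ndraws=2_000, tol=1e-3, max_iter=8
    ),
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# MPLE attenuates dyad-dependent effects (gwesp); MCMC-MLE corrects
# toward the true values with near-nominal interval coverage.
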