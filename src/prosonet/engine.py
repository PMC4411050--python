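"""ERGM simulation and estimation under a capped-out-degree sample space.

The survey instrument allowed at most seven friendship nominations, so
the model's sample space is restricted to directed simple graphs in
which every node has out-degree <= 7. The sampler enforces this by
rejecting, at the proposal stage, any toggle-on that would breach the
cap, which leaves the chain's stationary law equal to the ERGM
restricted to the constrained space.

Estimators:

- :func:`mple` — maximum pseudo-likelihood: logistic regression of tie
  indicators on change statistics (IRLS via statsmodels). Exact MLE for
  dyad-independent models; the standard initializer otherwise. Dyads
  whose toggle-on would violate the constraint are excluded from the
  pseudo-likelihood (a conditioning approximation).
- :func:`mcmc_mle` — Geyer-Thompson importance-sampled likelihood-ratio
  maximization with Newton-Raphson, started at the MPLE.
- :func:`exact_mle` — exact likelihood by enumerating all directed
  graphs (n <= 5); the test oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps
from scipy.special import expit, logsumexp

from . import _kernel
from .network import ATTRIBUTE_COLUMNS, AttributedNetwork
from .terms import ModelSpec, bind, change_matrix, global_statistics, is_dyad_independent

logger = logging.getLogger(__name__)

STUDY_MAX_OUT_DEGREE = 7  # the survey's nomination cap


class SeparationError(ValueError):
    """The pseudo-likelihood is separable; no finite MPLE exists."""


class DegeneracyError(RuntimeError):
    """Simulation collapsed to a near-empty/near-complete region."""


@dataclass(frozen=True)
class Constraint:
    """Sample-space restriction: every node's out-degree <= max_out_degree."""

    max_out_degree: int | None = None

    def satisfied_by(self, net: AttributedNetwork) -> bool:
        if self.max_out_degree is None:
            return True
        return int(net.out_degrees().max(initial=0)) <= self.max_out_degree

    @property
    def cap(self) -> int:
        return -1 if self.max_out_degree is None else int(self.max_out_degree)


STUDY_CONSTRAINT = Constraint(STUDY_MAX_OUT_DEGREE)
NO_CONSTRAINT = Constraint(None)


@dataclass(frozen=True)
class McmcSettings:
    """Sampler and MCMC-MLE controls.

    Defaults suit a ~240-node sparse network; scale ``burnin``,
    ``interval`` and ``ndraws`` down for small test problems.
    """

    burnin: int = 100_000  # toggles before the first retained draw
    interval: int = 1_000  # toggles between retained draws
    ndraws: int = 10_000  # retained statistic draws per sample
    proposal: str = "tnt"  # "tnt" (tie/no-tie) or "uniform"
    max_iter: int = 20  # outer MCMC-MLE iterations
    tol: float = 1e-4  # stop when est. log-likelihood gain < tol
    ess_floor: float = 100.0  # min effective importance-sample size
    newton_max: int = 50  # inner Newton iterations

    def __post_init__(self):
        if self.proposal not in ("tnt", "uniform"):
            raise ValueError("proposal must be 'tnt' or 'uniform'")


@dataclass
class SampleSet:
    """Draws from one MCMC run: statistics and (optionally) networks."""

    statistics: np.ndarray  # (ndraws, T)
    names: list[str]
    networks: np.ndarray | None  # (ndraws, n, n) uint8 or None
    seed: int
    settings: McmcSettings
    acceptance_rate: float
    final_adjacency: np.ndarray = field(repr=False, default=None)


@dataclass
class FitResult:
    """An estimated ERGM: theta with uncertainties and diagnostics."""

    spec: ModelSpec  # coefficients filled
    std_errors: np.ndarray
    p_values: np.ndarray
    method: str  # "MPLE" | "MCMC-MLE" | "exact"
    converged: bool
    observed_stats: np.ndarray
    mcmc_settings: McmcSettings | None = None
    constraint: Constraint = NO_CONSTRAINT
    seed: int | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def coefficients(self) -> np.ndarray:
        return self.spec.coefficients

    @property
    def names(self) -> list[str]:
        return self.spec.names

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "Estimate": self.coefficients,
                "Std. Error": self.std_errors,
                "p-value": self.p_values,
            },
            index=self.names,
        )

    def report(self) -> str:
        lines = [
            f"method: {self.method}   converged: {self.converged}",
            self.to_frame().to_string(float_format=lambda v: f"{v:.3f}"),
        ]
        gwesp = [t for t in self.spec.terms if t.kind == "gwesp"]
        if gwesp:
            lines.append(
                f"gwesp decay alpha = {gwesp[0].alpha:g}, "
                f"shared partners: {gwesp[0].sp_type}"
            )
        if self.constraint.max_out_degree is not None:
            lines.append(f"sample space: out-degree <= {self.constraint.max_out_degree}")
        for k, v in self.diagnostics.items():
            if np.isscalar(v):
                lines.append(f"{k}: {v:.4g}" if isinstance(v, float) else f"{k}: {v}")
        if self.seed is not None:
            lines.append(f"seed: {self.seed}")
        return "\n".join(lines)


def _empty_network(n_nodes: int, attributes=None) -> AttributedNetwork:
    import pandas as pd

    if attributes is None:
        attributes = pd.DataFrame(
            {c: np.full(n_nodes, np.nan) for c in ATTRIBUTE_COLUMNS},
            index=[f"n{i}" for i in range(n_nodes)],
        )
    n = len(attributes)
    return AttributedNetwork(
        [str(i) for i in attributes.index], np.zeros((n, n), dtype=bool), attributes
    )


def _static_mats_and_indices(net, spec):
    """Per-term toggle-delta matrices; odegree0/gwesp slots zeroed and indexed."""
    mats = change_matrix(net, spec)
    idx_od0 = idx_gwesp = -1
    r = 0.0
    exp_alpha = 1.0
    code = 0
    for t, (term, b) in enumerate(zip(spec.terms, bind(net, spec))):
        if term.kind == "odegree0":
            idx_od0 = t
            mats[t] = 0.0
        elif term.kind == "gwesp":
            idx_gwesp = t
            mats[t] = 0.0
            r, exp_alpha, code = b.r, b.exp_alpha, b.code
    return np.ascontiguousarray(mats), idx_od0, idx_gwesp, r, exp_alpha, code


def _kernel_seed(seed: int, stream: int = 0) -> int:
    s = np.random.SeedSequence([int(seed), int(stream)])
    return int(s.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def sample_networks(
    spec: ModelSpec,
    *,
    net: AttributedNetwork | None = None,
    n_nodes: int | None = None,
    attributes=None,
    constraint: Constraint = NO_CONSTRAINT,
    settings: McmcSettings | None = None,
    seed: int = 0,
    return_networks: bool = False,
) -> SampleSet:
    """Draw statistic (and optionally network) samples from an ERGM.

    The chain starts at ``net`` when given (its attribute table also
    binds the terms), otherwise at the empty graph on ``n_nodes`` nodes
    or on ``attributes``. Coefficients must be set on ``spec``.
    """
    if spec.coefficients is None:
        raise ValueError("spec has no coefficients")
    theta = np.asarray(spec.coefficients, dtype=float)
    if not np.isfinite(theta).all():
        bad = spec.names[int(np.argmax(~np.isfinite(theta)))]
        raise DegeneracyError(f"non-finite coefficient on term {bad!r}")
    settings = settings or McmcSettings()
    if net is None:
        if n_nodes is None and attributes is None:
            raise ValueError("give net, n_nodes or attributes")
        net = _empty_network(n_nodes or 0, attributes)
    elif not constraint.satisfied_by(net):
        raise ValueError("starting network violates the out-degree constraint")
    mats, idx_od0, idx_gwesp, r, exp_alpha, code = _static_mats_and_indices(net, spec)
    if not np.isfinite(mats).all():
        bad = spec.names[int(np.argmax(~np.isfinite(mats).reshape(len(spec), -1).all(1)))]
        raise DegeneracyError(f"non-finite change statistic on term {bad!r}")
    A = np.ascontiguousarray(net.adjacency, dtype=np.uint8)
    g0 = global_statistics(net, spec)
    kseed = _kernel_seed(seed)
    stats_out, nets, n_accept, n_prop = _kernel.mh_kernel(
        A,
        g0.copy(),
        mats,
        theta,
        idx_od0,
        idx_gwesp,
        r,
        exp_alpha,
        code,
        constraint.cap,
        settings.burnin,
        settings.interval,
        settings.ndraws,
        settings.proposal == "tnt",
        return_networks,
        kseed,
    )
    return SampleSet(
        statistics=stats_out,
        names=spec.names,
        networks=nets if return_networks else None,
        seed=seed,
        settings=settings,
        acceptance_rate=n_accept / max(n_prop, 1),
        final_adjacency=A,
    )


# -- MPLE --------------------------------------------------------------


def pseudolikelihood_design(net, spec, constraint=NO_CONSTRAINT):
    """(X, y) over non-self dyads for the logistic pseudo-likelihood.

    Absent dyads whose toggle-on would break the out-degree cap are
    excluded (conditioning on their infeasibility).
    """
    A = net.adjacency
    n = net.n_nodes
    mats = change_matrix(net, spec)
    off = ~np.eye(n, dtype=bool)
    keep = off.copy()
    if constraint.max_out_degree is not None:
        at_cap = net.out_degrees() >= constraint.max_out_degree
        keep &= A | ~at_cap[:, None]
    X = mats[:, keep].T
    y = A[keep].astype(float)
    return X, y


def mple(
    net: AttributedNetwork,
    spec: ModelSpec,
    constraint: Constraint = NO_CONSTRAINT,
) -> FitResult:
    """Maximum pseudo-likelihood estimate (logistic IRLS fit).

    Exactly the MLE when the model is dyad-independent; otherwise the
    standard starting point for :func:`mcmc_mle`.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    if not constraint.satisfied_by(net):
        raise ValueError("observed network violates the out-degree constraint")
    X, y = pseudolikelihood_design(net, spec, constraint)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected below from the fit itself
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, X).fit(method="newton", disp=False, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(
            f"pseudo-likelihood separation ({_separating_term(X, y, spec)}): {exc}"
        ) from None
    if not res.mle_retvals.get("converged", False) or not np.isfinite(res.bse).all():
        raise SeparationError(
            f"pseudo-likelihood did not converge "
            f"(suspect term: {_separating_term(X, y, spec)})"
        )
    theta = np.asarray(res.params, dtype=float)
    return FitResult(
        spec=spec.with_coefficients(theta),
        std_errors=np.asarray(res.bse, dtype=float),
        p_values=np.asarray(res.pvalues, dtype=float),
        method="MPLE",
        converged=True,
        observed_stats=global_statistics(net, spec),
        constraint=constraint,
        diagnostics={"n_dyads": int(len(y)), "pseudo_loglik": float(res.llf)},
    )


def _separating_term(X, y, spec) -> str:
    """Name the most plausibly separating term (single-column screen)."""
    for t, name in enumerate(spec.names):
        x1, x0 = X[y == 1, t], X[y == 0, t]
        if len(x1) == 0 or len(x0) == 0:
            return name
        if x1.min() >= x0.max() or x0.min() >= x1.max():
            if x1.min() != x1.max() or x0.min() != x0.max():
                return name
    return "unidentified"


# -- MCMC-MLE ----------------------------------------------------------


def _ess(logw: np.ndarray) -> float:
    lw = logw - logw.max()
    w = np.exp(lw)
    return float(w.sum() ** 2 / (w**2).sum())


def _llr(eta, Sc) -> float:
    """Estimated l(theta0+eta) - l(theta0); Sc = draws, centered at g_obs."""
    return float(-logsumexp(Sc @ eta) + np.log(len(Sc)))


def _newton_step(S, g_obs, ess_floor, newton_max):
    """Maximize the importance-sampled log-likelihood ratio in eta.

    Steps are halved until the objective improves and the weights'
    effective sample size stays above the floor. Returns
    (eta, gain, ess, hit_floor).
    """
    Sc = S - g_obs
    eta = np.zeros(S.shape[1])
    f = _llr(eta, Sc)
    hit_floor = False
    for _ in range(newton_max):
        lw = Sc @ eta
        lw -= lw.max()
        w = np.exp(lw)
        w /= w.sum()
        mu = w @ Sc
        C = (Sc - mu).T @ ((Sc - mu) * w[:, None])
        grad = -mu
        try:
            step = np.linalg.solve(C + 1e-10 * np.eye(len(grad)), grad)
        except np.linalg.LinAlgError:
            step = grad
        scale = 1.0
        improved = False
        for _ in range(30):
            cand = eta + scale * step
            if _ess(Sc @ cand) >= ess_floor:
                f_cand = _llr(cand, Sc)
                if f_cand >= f - 1e-12:
                    eta, f = cand, f_cand
                    improved = True
                    break
            else:
                hit_floor = True
            scale /= 2.0
        if not improved or np.linalg.norm(scale * step) < 1e-10:
            break
    return eta, f, _ess(Sc @ eta), hit_floor


def _chain_neff(S: np.ndarray) -> float:
    """Autocorrelation-adjusted effective draw count (batch means).

    Per column, N_eff = (sd / mcse)^2; the median over columns guards
    against a single noisy estimate."""
    sd = S.std(axis=0, ddof=1)
    mcse = _batch_mcse(S)
    ok = (sd > 0) & (mcse > 0)
    if not ok.any():
        return float(len(S))
    return float(np.median((sd[ok] / mcse[ok]) ** 2))


def _batch_mcse(S: np.ndarray, n_batches: int = 25) -> np.ndarray:
    """Monte-Carlo SE of column means by batch means (autocorrelation-aware)."""
    n = len(S)
    b = max(n // n_batches, 1)
    k = n // b
    means = S[: k * b].reshape(k, b, -1).mean(axis=1)
    return means.std(axis=0, ddof=1) / np.sqrt(k)


def mcmc_mle(
    net: AttributedNetwork,
    spec: ModelSpec,
    constraint: Constraint = NO_CONSTRAINT,
    settings: McmcSettings | None = None,
    seed: int = 0,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Monte-Carlo maximum likelihood (importance-sampled Newton-Raphson).

    Starting from the MPLE, each outer iteration simulates a sample at
    the current theta0 and maximizes the estimated log-likelihood ratio
    l(theta) - l(theta0); iteration stops when the estimated gain drops
    below ``settings.tol``. Standard errors come from the inverse
    covariance of simulated statistics at the final theta (the Fisher
    information of an exponential family).
    """
    settings = settings or McmcSettings()
    if theta0 is None:
        theta0 = mple(net, spec, constraint).coefficients
    theta0 = np.asarray(theta0, dtype=float)
    g_obs = global_statistics(net, spec)
    converged = False
    ess = np.nan
    n_resample = 0
    for it in range(settings.max_iter):
        sset = sample_networks(
            spec.with_coefficients(theta0),
            net=net,
            constraint=constraint,
            settings=settings,
            seed=_kernel_seed(seed, stream=it + 1),
        )
        eta, gain, ess, hit_floor = _newton_step(
            sset.statistics, g_obs, settings.ess_floor, settings.newton_max
        )
        theta0 = theta0 + eta
        if hit_floor:
            n_resample += 1
        # the maximized gain estimate is biased upward by about
        # dim/(2 N_eff), the noise of a fitted quadratic; N_eff is
        # limited both by importance-weight concentration and by chain
        # autocorrelation (batch-means estimate), so stop once the gain
        # is indistinguishable from that floor
        n_eff = min(ess, _chain_neff(sset.statistics))
        if gain < settings.tol + len(spec) / (2.0 * n_eff) and not hit_floor:
            converged = True
            break
    # final sample at theta-hat: SEs and moment-matching diagnostics
    final = sample_networks(
        spec.with_coefficients(theta0),
        net=net,
        constraint=constraint,
        settings=settings,
        seed=_kernel_seed(seed, stream=10_000),
    )
    S = final.statistics
    Sigma = np.cov(S.T) if len(spec) > 1 else np.atleast_2d(np.var(S[:, 0], ddof=1))
    try:
        Sigma_inv = np.linalg.inv(Sigma)
    except np.linalg.LinAlgError:
        Sigma_inv = np.linalg.pinv(Sigma)
    se = np.sqrt(np.maximum(np.diag(Sigma_inv), 0.0))
    z = np.divide(theta0, se, out=np.zeros_like(theta0), where=se > 0)
    mcse = _batch_mcse(S)
    return FitResult(
        spec=spec.with_coefficients(theta0),
        std_errors=se,
        p_values=2 * sps.norm.sf(np.abs(z)),
        method="MCMC-MLE",
        converged=converged,
        observed_stats=g_obs,
        mcmc_settings=settings,
        constraint=constraint,
        seed=seed,
        diagnostics={
            "iterations": it + 1,
            "final_llr_gain": gain,
            "importance_ess": ess,
            "ess_floor_hits": n_resample,
            "acceptance_rate": final.acceptance_rate,
            "mean_sim_stats": S.mean(axis=0),
            "mcse_sim_stats": mcse,
            "moment_z": (S.mean(axis=0) - g_obs) / np.where(mcse > 0, mcse, np.inf),
        },
    )


# -- exact enumeration (oracle, n <= 5) --------------------------------


def dyad_order(n: int) -> list[tuple[int, int]]:
    """Bit order used by the enumeration code of a directed graph."""
    return [(i, j) for i in range(n) for j in range(n) if i != j]


def network_code(A: np.ndarray, n: int) -> int:
    """Bitmask identifying a directed graph under :func:`dyad_order`."""
    code = 0
    for b, (i, j) in enumerate(dyad_order(n)):
        if A[i, j]:
            code |= 1 << b
    return code


def enumerate_statistics(
    net_template: AttributedNetwork,
    spec: ModelSpec,
    constraint: Constraint = NO_CONSTRAINT,
):
    """Statistic vectors of all 2^(n(n-1)) directed graphs (n <= 5).

    Walks the state space in Gray-code order so each move is a single
    toggle handled by change statistics. Returns (stats, feasible)
    arrays indexed by the graph's :func:`network_code`.
    """
    n = net_template.n_nodes
    if n > 5:
        raise ValueError(f"exact enumeration refuses n = {n} > 5")
    dyads = dyad_order(n)
    D = len(dyads)
    bound = bind(net_template, spec)
    T = len(bound)
    empty = _empty_network(n, net_template.attributes)
    A = np.zeros((n, n), dtype=np.uint8)
    out_deg = np.zeros(n, dtype=np.int64)
    g = global_statistics(empty, spec)
    cap = constraint.max_out_degree
    stats = np.empty((1 << D, T))
    feasible = np.empty(1 << D, dtype=bool)
    code = 0
    stats[0] = g
    feasible[0] = True
    from .terms import _change_one  # local per-toggle deltas

    for k in range(1, 1 << D):
        b = (k & -k).bit_length() - 1  # Gray code: toggle trailing-zero bit
        i, j = dyads[b]
        if A[i, j]:
            A[i, j] = 0
            out_deg[i] -= 1
            delta = np.array([_change_one(A, out_deg, i, j, t) for t in bound])
            g = g - delta
            code ^= 1 << b
        else:
            delta = np.array([_change_one(A, out_deg, i, j, t) for t in bound])
            g = g + delta
            A[i, j] = 1
            out_deg[i] += 1
            code |= 1 << b
        stats[code] = g
        feasible[code] = cap is None or out_deg.max() <= cap
    return stats, feasible


def exact_distribution(
    net_template: AttributedNetwork,
    spec: ModelSpec,
    constraint: Constraint = NO_CONSTRAINT,
):
    """Exact ERGM probabilities over all feasible graphs (n <= 5).

    Returns (codes, probabilities); codes are :func:`network_code` values.
    """
    if spec.coefficients is None:
        raise ValueError("spec has no coefficients")
    stats, feasible = enumerate_statistics(net_template, spec, constraint)
    codes = np.nonzero(feasible)[0]
    logp = stats[codes] @ spec.coefficients
    logp -= logsumexp(logp)
    return codes, np.exp(logp)


def exact_mle(
    net: AttributedNetwork,
    spec: ModelSpec,
    constraint: Constraint = NO_CONSTRAINT,
) -> FitResult:
    """Exact MLE via the full normalizing constant (n <= 5 only)."""
    if not constraint.satisfied_by(net):
        raise ValueError("observed network violates the out-degree constraint")
    stats, feasible = enumerate_statistics(net, spec, constraint)
    G = stats[feasible]
    g_obs = global_statistics(net, spec)
    theta = np.zeros(len(spec))
    converged = False
    for _ in range(200):
        lp = G @ theta
        lp -= logsumexp(lp)
        w = np.exp(lp)
        mu = w @ G
        grad = g_obs - mu
        C = (G - mu).T @ ((G - mu) * w[:, None])
        try:
            step = np.linalg.solve(C + 1e-12 * np.eye(len(theta)), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(C, grad, rcond=None)[0]
        theta = theta + step
        if np.linalg.norm(theta) > 60:
            raise SeparationError(
                "exact MLE diverges: observed statistics lie on the boundary "
                "of the convex hull"
            )
        if np.linalg.norm(grad) < 1e-10:
            converged = True
            break
    lp = G @ theta
    lp -= logsumexp(lp)
    w = np.exp(lp)
    mu = w @ G
    C = (G - mu).T @ ((G - mu) * w[:, None])
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(C)), 0.0))
    except np.linalg.LinAlgError:
        se = np.sqrt(np.maximum(np.diag(np.linalg.pinv(C)), 0.0))
    z = np.divide(theta, se, out=np.zeros_like(theta), where=se > 0)
    return FitResult(
        spec=spec.with_coefficients(theta),
        std_errors=se,
        p_values=2 * sps.norm.sf(np.abs(z)),
        method="exact",
        converged=converged,
        observed_stats=g_obs,
        constraint=constraint,
        diagnostics={"n_feasible_graphs": int(feasible.sum())},
    )
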