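"""Goodness-of-fit by simulation.

A fitted ERGM is judged by whether networks simulated from it reproduce
higher-order statistics of the observed network that were not in the
model: the in- and out-degree distributions, the edgewise shared-partner
(ESP) distribution, and the directed geodesic-distance distribution
(with an "NR" bucket for unreachable ordered pairs). Each family is
summarized as proportions — of nodes, edges or dyads — and the observed
curve is compared to a quantile envelope over replicate simulations
(100 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import FitResult, McmcSettings, sample_networks
from .network import AttributedNetwork
from .terms import SP_CODES, edge_shared_partners

FAMILIES = ("in_degree", "out_degree", "edgewise_shared_partners", "geodesic_distance")

NR = "NR"  # label of the unreachable-pair bucket on the geodesic axis


@dataclass
class GofSummary:
    """Observed vs simulated distribution of one statistic family.

    ``values`` are the axis labels (ints as strings; geodesics end with
    "NR"). All rows are proportions of the family's unit: nodes for
    degrees, edges for ESP, ordered dyads for geodesics.
    """

    family: str
    values: list[str]
    observed: np.ndarray
    q_min: np.ndarray
    q025: np.ndarray
    median: np.ndarray
    q975: np.ndarray
    q_max: np.ndarray
    n_replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": self.family,
                "value": self.values,
                "observed": self.observed,
                "q025": self.q025,
                "median": self.median,
                "q975": self.q975,
            }
        )

    def coverage(self) -> float:
        """Share of buckets where the observed curve is inside [q025, q975]."""
        inside = (self.observed >= self.q025 - 1e-12) & (
            self.observed <= self.q975 + 1e-12
        )
        return float(inside.mean()) if len(inside) else 1.0


# -- per-network distributions ----------------------------------------


def degree_proportions(A: np.ndarray, axis: int) -> np.ndarray:
    """Proportion of nodes at each degree 0..max (axis 1 = out, 0 = in)."""
    deg = A.sum(axis=axis)
    return np.bincount(deg) / A.shape[0]


def esp_proportions(A: np.ndarray, sp_code: int = 0) -> np.ndarray:
    """Proportion of edges with k shared partners, k = 0..max."""
    n_edges = int(A.sum())
    if n_edges == 0:
        return np.array([])
    sp = edge_shared_partners(A.astype(bool), sp_code)
    return np.bincount(sp) / n_edges


def geodesic_proportions(A: np.ndarray) -> np.ndarray:
    """Proportion of ordered pairs at each directed geodesic distance.

    Entry d-1 is the share at finite distance d; the last entry is the
    NR (unreachable) share. Distances via breadth-first search on the
    directed graph (scipy's csgraph).
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import shortest_path

    n = A.shape[0]
    if n < 2:
        return np.array([1.0])
    dist = shortest_path(csr_matrix(A.astype(np.int8)), method="D", unweighted=True)
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    finite = d[np.isfinite(d)].astype(int)
    n_pairs = n * (n - 1)
    counts = np.bincount(finite, minlength=1)[1:]  # distances start at 1
    props = counts / n_pairs
    nr = 1.0 - props.sum()
    return np.concatenate([props, [nr]])


def _family_distribution(A: np.ndarray, family: str, sp_code: int) -> np.ndarray:
    if family == "in_degree":
        return degree_proportions(A, axis=0)
    if family == "out_degree":
        return degree_proportions(A, axis=1)
    if family == "edgewise_shared_partners":
        return esp_proportions(A, sp_code)
    if family == "geodesic_distance":
        return geodesic_proportions(A)
    raise ValueError(f"unknown family {family!r}")


def _pad(rows: list[np.ndarray], width: int) -> np.ndarray:
    out = np.zeros((len(rows), width))
    for k, r in enumerate(rows):
        out[k, : len(r)] = r
    return out


# -- the comparison ----------------------------------------------------


def gof_compare(
    net: AttributedNetwork,
    fit: FitResult,
    n_replicates: int = 100,
    seed: int = 0,
    settings: McmcSettings | None = None,
    degree_quantile: float = 0.995,
) -> list[GofSummary]:
    """Simulate from a fit and compare all four statistic families.

    Replicate networks are retained draws of one chain started at the
    observed network (one per ``interval`` toggles after burn-in). The
    ESP orientation follows the fitted gwesp term when present. Degree
    and ESP axes are truncated at the pooled ``degree_quantile`` so
    tables stay finite; geodesics always end with the NR bucket.
    """
    if not fit.converged:
        raise ValueError("refusing goodness-of-fit on a non-converged fit")
    if n_replicates < 1:
        raise ValueError("no simulations requested")
    if settings is None:
        base = fit.mcmc_settings or McmcSettings()
        settings = McmcSettings(
            burnin=base.burnin, interval=base.interval, ndraws=n_replicates
        )
    else:
        settings = McmcSettings(
            burnin=settings.burnin,
            interval=settings.interval,
            ndraws=n_replicates,
            proposal=settings.proposal,
        )
    sp_code = 0
    for t in fit.spec.terms:
        if t.kind == "gwesp":
            sp_code = SP_CODES[t.sp_type]
    sset = sample_networks(
        fit.spec,
        net=net,
        constraint=fit.constraint,
        settings=settings,
        seed=seed,
        return_networks=True,
    )
    A_obs = net.adjacency.astype(np.uint8)
    summaries = []
    for family in FAMILIES:
        obs = _family_distribution(A_obs, family, sp_code)
        sims = [
            _family_distribution(sset.networks[k], family, sp_code)
            for k in range(n_replicates)
        ]
        width = max(len(obs), *(len(s) for s in sims))
        obs_p = _pad([obs], width)[0]
        sim_p = _pad(sims, width)
        if family == "geodesic_distance":
            # realign: the NR bucket is each row's last entry
            obs_p = np.concatenate([obs[:-1], np.zeros(width - len(obs)), obs[-1:]])
            sim_p = np.zeros((n_replicates, width))
            for k, s in enumerate(sims):
                sim_p[k, : len(s) - 1] = s[:-1]
                sim_p[k, -1] = s[-1]
            values = [str(d + 1) for d in range(width - 1)] + [NR]
        else:
            values = [str(v) for v in range(width)]
            # truncate sparse upper tails (full mass retained up to here)
            pooled = np.vstack([obs_p[None, :], sim_p])
            nonzero = np.nonzero(pooled.sum(axis=0) > 0)[0]
            cum = pooled.mean(axis=0).cumsum()
            keep = max(
                int(nonzero.max()) if len(nonzero) else 0,
                int(np.searchsorted(cum, degree_quantile)),
            )
            keep = min(keep, width - 1)
            obs_p, sim_p, values = obs_p[: keep + 1], sim_p[:, : keep + 1], values[: keep + 1]
        summaries.append(
            GofSummary(
                family=family,
                values=values,
                observed=obs_p,
                q_min=sim_p.min(axis=0),
                q025=np.quantile(sim_p, 0.025, axis=0),
                median=np.quantile(sim_p, 0.5, axis=0),
                q975=np.quantile(sim_p, 0.975, axis=0),
                q_max=sim_p.max(axis=0),
                n_replicates=n_replicates,
                seed=seed,
            )
        )
    return summaries


def gof_report(summaries: list[GofSummary], out_dir) -> dict[str, list]:
    """Write one panel image and one CSV table per family.

    Panels show the observed distribution as a dark line over the
    simulated 95% envelope (shaded) and median, proportions on the
    y-axis. Returns the written paths keyed 'plots'/'tables'.
    """
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not summaries:
        raise ValueError("no simulations: empty summary list")
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, list] = {"plots": [], "tables": []}
    for s in summaries:
        table = out_dir / f"gof_{s.family}.csv"
        s.to_frame().to_csv(table, index=False)
        paths["tables"].append(table)
        fig, ax = plt.subplots(figsize=(6, 4))
        x = np.arange(len(s.values))
        ax.fill_between(
            x, s.q025, s.q975, color="lightsteelblue", label="simulated 95% envelope"
        )
        ax.plot(x, s.median, color="steelblue", lw=1, label="simulated median")
        ax.plot(x, s.observed, color="black", lw=2, label="observed")
        ax.set_xticks(x)
        ax.set_xticklabels(s.values, fontsize=7)
        ax.set_xlabel(s.family.replace("_", " "))
        ax.set_ylabel("proportion")
        ax.set_title(f"{s.family.replace('_', ' ')} ({s.n_replicates} simulations)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        plot = out_dir / f"gof_{s.family}.png"
        fig.savefig(plot, dpi=120)
        plt.close(fig)
        paths["plots"].append(plot)
    return paths
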