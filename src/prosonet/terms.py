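"""ERGM terms: sufficient statistics and change statistics.

An ERGM places P(Y = y) proportional to exp(theta' g(y)) over directed
simple graphs. This module defines g for the eight terms the analysis
uses — edges, nodematch, nodeicov, nodeocov, absdiff, edgecov,
odegree(0) and gwesp — and their toggle ("change") statistics
g(y + ij) - g(y - ij), the quantity both the pseudo-likelihood and the
MCMC sampler are built on.

The gwesp decay alpha is a required, always-echoed configuration value
(default 0.25): published fits rarely state it, yet coefficients are
not comparable across alphas. The directed shared-partner orientation
defaults to "transitive" (k is a shared partner of i -> j when i -> k
and k -> j), the closure mechanism of friend-of-a-friend formation;
"cyclic" and "any" are also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import _kernel
from .network import AttributedNetwork

TERM_KINDS = (
    "edges",
    "nodematch",
    "nodeicov",
    "nodeocov",
    "absdiff",
    "edgecov",
    "odegree0",
    "gwesp",
)
_ATTR_KINDS = ("nodematch", "nodeicov", "nodeocov", "absdiff")
SP_CODES = {"transitive": 0, "cyclic": 1, "any": 2}

DEFAULT_GWESP_ALPHA = 0.25


class MissingAttributeError(ValueError):
    """A term touches a node with a missing attribute (complete-case rule)."""


@dataclass(frozen=True)
class TermSpec:
    """One ERGM term.

    ``covariate`` (edgecov only) is either an (n, n) dyadic matrix or a
    source string resolved against the network's attributes:
    ``"sqrt_product:<attr>"`` for the square-root-of-products covariate,
    or ``"ones"`` for the all-ones matrix.
    """

    kind: str
    attribute: str | None = None
    covariate: object = None
    alpha: float | None = None
    sp_type: str = "transitive"
    label: str | None = None

    def __post_init__(self):
        if self.kind not in TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind in _ATTR_KINDS and not self.attribute:
            raise ValueError(f"{self.kind} requires an attribute")
        if self.kind not in _ATTR_KINDS and self.attribute is not None:
            raise ValueError(f"{self.kind} takes no attribute")
        if self.kind == "edgecov" and self.covariate is None:
            raise ValueError("edgecov requires a covariate matrix or source")
        if self.kind != "edgecov" and self.covariate is not None:
            raise ValueError(f"{self.kind} takes no covariate")
        if self.kind == "gwesp":
            if self.alpha is None:
                object.__setattr__(self, "alpha", DEFAULT_GWESP_ALPHA)
            if self.alpha < 0:
                raise ValueError("gwesp decay alpha must be >= 0")
            if self.sp_type not in SP_CODES:
                raise ValueError(f"sp_type must be one of {sorted(SP_CODES)}")
        elif self.alpha is not None:
            raise ValueError(f"{self.kind} takes no alpha")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        if self.kind in _ATTR_KINDS:
            return f"{self.kind}.{self.attribute}"
        if self.kind == "gwesp":
            return f"gwesp({self.alpha:g},{self.sp_type})"
        if self.kind == "edgecov":
            src = self.covariate if isinstance(self.covariate, str) else "matrix"
            return f"edgecov.{src}"
        return self.kind


@dataclass
class ModelSpec:
    """Ordered term list defining g(y), optionally with coefficients theta."""

    terms: list[TermSpec]
    coefficients: np.ndarray | None = None

    def __post_init__(self):
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate term names: {names}")
        if self.coefficients is not None:
            theta = np.asarray(self.coefficients, dtype=float)
            if theta.shape != (len(self.terms),):
                raise ValueError("coefficient length != term count")
            self.coefficients = theta

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    def __len__(self) -> int:
        return len(self.terms)

    def with_coefficients(self, theta) -> "ModelSpec":
        return ModelSpec(list(self.terms), np.asarray(theta, dtype=float))

    # -- serialization (covariates must be source strings) ------------

    def to_dict(self) -> dict:
        terms = []
        for t in self.terms:
            d: dict = {"kind": t.kind}
            if t.attribute:
                d["attribute"] = t.attribute
            if t.covariate is not None:
                if not isinstance(t.covariate, str):
                    raise ValueError(
                        "only source-string edgecov covariates serialize"
                    )
                d["covariate"] = t.covariate
            if t.kind == "gwesp":
                d["alpha"] = float(t.alpha)
                d["sp_type"] = t.sp_type
            if t.label:
                d["label"] = t.label
            terms.append(d)
        out = {"terms": terms}
        if self.coefficients is not None:
            out["coefficients"] = [float(c) for c in self.coefficients]
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        terms = [TermSpec(**t) for t in d["terms"]]
        coef = d.get("coefficients")
        return cls(terms, None if coef is None else np.asarray(coef, float))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def sqrt_product_covariate(scores) -> np.ndarray:
    """Dyadic covariate sqrt(score_i * score_j), the assortment metric
    of the second model: it grows with either actor's score but fastest
    when both are high, and the square root keeps it on the attribute's
    own 1-5 scale. Diagonal entries are zeroed (self-dyads do not exist).
    """
    x = np.asarray(scores, dtype=float)
    if np.isnan(x).any():
        raise MissingAttributeError("scores contain missing values")
    if (x <= 0).any():
        raise ValueError("sqrt-product covariate requires strictly positive scores")
    M = np.sqrt(np.outer(x, x))
    np.fill_diagonal(M, 0.0)
    return M


# -- binding terms to a concrete network ------------------------------


@dataclass
class _Bound:
    """A TermSpec resolved against one network's attributes."""

    kind: str
    name: str
    x: np.ndarray | None = None  # node values
    M: np.ndarray | None = None  # dyadic covariate
    r: float = 0.0
    exp_alpha: float = 1.0
    code: int = 0


def _attr_vector(net: AttributedNetwork, name: str, term: str) -> np.ndarray:
    x = net.attribute_values(name)
    if np.isnan(x).any():
        bad = int(np.isnan(x).sum())
        raise MissingAttributeError(
            f"term {term} uses attribute {name!r} with {bad} missing value(s); "
            "the models are complete-case"
        )
    return x


def resolve_covariate(net: AttributedNetwork, covariate) -> np.ndarray:
    """Resolve an edgecov covariate (matrix or source string) to (n, n)."""
    n = net.n_nodes
    if isinstance(covariate, str):
        if covariate == "ones":
            M = np.ones((n, n))
            np.fill_diagonal(M, 0.0)
            return M
        if covariate.startswith("sqrt_product:"):
            attr = covariate.split(":", 1)[1]
            return sqrt_product_covariate(_attr_vector(net, attr, "edgecov"))
        raise ValueError(f"unknown covariate source {covariate!r}")
    M = np.asarray(covariate, dtype=float)
    if M.shape != (n, n):
        raise ValueError(f"edgecov matrix shape {M.shape} != ({n}, {n})")
    if not np.isfinite(M[~np.eye(n, dtype=bool)]).all():
        raise MissingAttributeError("edgecov matrix has non-finite off-diagonal entries")
    return M


def bind(net: AttributedNetwork, spec: ModelSpec) -> list[_Bound]:
    """Resolve every term against the network (complete-case validation)."""
    bound = []
    for t in spec.terms:
        b = _Bound(kind=t.kind, name=t.name)
        if t.kind in _ATTR_KINDS:
            b.x = _attr_vector(net, t.attribute, t.name)
        elif t.kind == "edgecov":
            b.M = resolve_covariate(net, t.covariate)
        elif t.kind == "gwesp":
            b.r = 1.0 - np.exp(-t.alpha)
            b.exp_alpha = float(np.exp(t.alpha))
            b.code = SP_CODES[t.sp_type]
        bound.append(b)
    return bound


# -- statistics -------------------------------------------------------


def _global_one(A: np.ndarray, b: _Bound) -> float:
    if b.kind == "edges":
        return float(A.sum())
    if b.kind == "nodematch":
        eq = b.x[:, None] == b.x[None, :]
        return float((A & eq).sum())
    if b.kind == "nodeocov":
        return float((A.sum(axis=1) * b.x).sum())
    if b.kind == "nodeicov":
        return float((A.sum(axis=0) * b.x).sum())
    if b.kind == "absdiff":
        return float((A * np.abs(b.x[:, None] - b.x[None, :])).sum())
    if b.kind == "edgecov":
        return float((A * b.M).sum())
    if b.kind == "odegree0":
        return float((A.sum(axis=1) == 0).sum())
    if b.kind == "gwesp":
        sp = edge_shared_partners(A, b.code)
        return float((b.exp_alpha * (1.0 - b.r**sp)).sum())
    raise AssertionError(b.kind)


def edge_shared_partners(A: np.ndarray, code: int = 0) -> np.ndarray:
    """Shared-partner count of every existing edge (matmul route).

    Independent of the loop-based kernel formulas; used for global
    statistics and the goodness-of-fit ESP distribution.
    """
    A = A.astype(np.int64)
    if code == 0:
        P = A @ A
        sp = P[A.astype(bool)]
    elif code == 1:
        P = (A @ A).T
        sp = P[A.astype(bool)]
    else:
        S = (A | A.T).astype(np.int64)
        np.fill_diagonal(S, 0)
        P = S @ S
        sp = P[A.astype(bool)]
    return sp


def global_statistics(net: AttributedNetwork, spec: ModelSpec) -> np.ndarray:
    """The sufficient-statistic vector g(y)."""
    A = net.adjacency
    return np.array([_global_one(A, b) for b in bind(net, spec)])


def _change_one(A: np.ndarray, out_deg: np.ndarray, i: int, j: int, b: _Bound) -> float:
    """Toggle delta of one term at dyad (i, j); A must not contain (i, j)."""
    if b.kind == "edges":
        return 1.0
    if b.kind == "nodematch":
        return float(b.x[i] == b.x[j])
    if b.kind == "nodeocov":
        return float(b.x[i])
    if b.kind == "nodeicov":
        return float(b.x[j])
    if b.kind == "absdiff":
        return float(abs(b.x[i] - b.x[j]))
    if b.kind == "edgecov":
        return float(b.M[i, j])
    if b.kind == "odegree0":
        return -1.0 if out_deg[i] == 0 else 0.0
    if b.kind == "gwesp":
        return float(
            _kernel.gwesp_delta_add(
                np.ascontiguousarray(A, dtype=np.uint8), i, j, b.r, b.exp_alpha, b.code
            )
        )
    raise AssertionError(b.kind)


def change_statistics(
    net: AttributedNetwork, dyad: tuple, spec: ModelSpec
) -> np.ndarray:
    """Toggle difference g(y + ij) - g(y - ij) for one ordered dyad.

    Computed locally from the dyad's neighborhoods, never by a full
    recount. ``dyad`` is an (ego, alter) pair of node ids (or integer
    indices). The sign convention is always "with edge minus without",
    regardless of whether the edge is currently present.
    """
    i, j = (
        d if isinstance(d, (int, np.integer)) else net.index_of(d) for d in dyad
    )
    if i == j:
        raise ValueError(f"self-loop dyad ({i}, {j})")
    bound = bind(net, spec)
    A = net.adjacency.copy()
    had = A[i, j]
    A[i, j] = False
    out_deg = A.sum(axis=1)
    out = np.array([_change_one(A, out_deg, i, j, b) for b in bound])
    A[i, j] = had
    return out


def change_matrix(net: AttributedNetwork, spec: ModelSpec) -> np.ndarray:
    """Toggle deltas for every ordered dyad, shape (T, n, n), diag 0.

    The workhorse of the pseudo-likelihood and of dyad-independent
    simulation. Dyad-independent terms vectorize directly; gwesp runs
    through the compiled per-dyad kernel.
    """
    A = net.adjacency
    n = net.n_nodes
    out_deg = A.sum(axis=1)
    mats = np.zeros((len(spec), n, n))
    off = ~np.eye(n, dtype=bool)
    for t, b in enumerate(bind(net, spec)):
        if b.kind == "edges":
            mats[t][off] = 1.0
        elif b.kind == "nodematch":
            mats[t] = (b.x[:, None] == b.x[None, :]).astype(float)
        elif b.kind == "nodeocov":
            mats[t] = np.broadcast_to(b.x[:, None], (n, n)).copy()
        elif b.kind == "nodeicov":
            mats[t] = np.broadcast_to(b.x[None, :], (n, n)).copy()
        elif b.kind == "absdiff":
            mats[t] = np.abs(b.x[:, None] - b.x[None, :])
        elif b.kind == "edgecov":
            mats[t] = b.M.copy()
        elif b.kind == "odegree0":
            # ego's out-degree with the dyad's own edge removed
            mats[t] = -((out_deg[:, None] - A) == 0).astype(float)
        elif b.kind == "gwesp":
            mats[t] = _kernel.gwesp_change_matrix(
                np.ascontiguousarray(A, dtype=np.uint8), b.r, b.exp_alpha, b.code
            )
        mats[t][~off] = 0.0
    return mats


def is_dyad_independent(spec: ModelSpec) -> bool:
    """True when no term's change statistic depends on the rest of y."""
    return all(t.kind not in ("odegree0", "gwesp") for t in spec.terms)


# -- the study's two model specifications -----------------------------


def study_model(
    which: int,
    alpha: float = DEFAULT_GWESP_ALPHA,
    sp_type: str = "transitive",
) -> ModelSpec:
    """The two published model specifications.

    Model 1 (13 terms): edges; sex nodematch; nodeicov/nodeocov/absdiff
    for prosociality, household income and father's education;
    odegree(0); gwesp. Model 2 (7 terms): edges; sex nodematch;
    sqrt-product edge covariates for the three numeric attributes;
    odegree(0); gwesp.
    """
    gwesp = TermSpec("gwesp", alpha=alpha, sp_type=sp_type)
    if which == 1:
        terms = [TermSpec("edges"), TermSpec("nodematch", attribute="sex")]
        for attr in ("prosociality", "income", "father_education"):
            terms += [
                TermSpec("nodeicov", attribute=attr),
                TermSpec("nodeocov", attribute=attr),
                TermSpec("absdiff", attribute=attr),
            ]
        terms += [TermSpec("odegree0"), gwesp]
        return ModelSpec(terms)
    if which == 2:
        terms = [
            TermSpec("edges"),
            TermSpec("nodematch", attribute="sex"),
            TermSpec("edgecov", covariate="sqrt_product:prosociality"),
            TermSpec("edgecov", covariate="sqrt_product:income"),
            TermSpec("edgecov", covariate="sqrt_product:father_education"),
            TermSpec("odegree0"),
            gwesp,
        ]
        return ModelSpec(terms)
    raise ValueError("which must be 1 or 2")
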