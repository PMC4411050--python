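"""Attributed directed network: data model, plain-text I/O, descriptives.

The friendship data analyzed throughout the package is a simple directed
graph (ego nominates alter) over surveyed students, each carrying four
node attributes: a prosociality score (mean of eight 5-point Likert
items, so a multiple of 1/8 in [1, 5]), binary sex, a household-income
band (1-5; band 6 means "unable to answer" and is treated as missing),
and a father's-education band (1-9).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ATTRIBUTE_COLUMNS = ("prosociality", "sex", "income", "father_education")

#: income band meaning "unable to answer"; excluded from numeric covariates
INCOME_MISSING_BAND = 6


class NetworkLoadError(ValueError):
    """Structured load failure; carries the offending file row when known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


@dataclass(frozen=True)
class DegreeSummary:
    """Descriptive degree statistics of a directed network.

    ``n_isolates`` counts nodes with neither in- nor out-ties;
    ``n_zero_out`` counts nodes that nominated nobody (the "loners" the
    ERGM's odegree(0) term targets).
    """

    n_nodes: int
    n_edges: int
    mean_out_degree: float
    n_isolates: int
    n_zero_out: int
    max_out_degree: int


@dataclass
class AttributedNetwork:
    """Simple directed graph plus a node-attribute table.

    Parameters
    ----------
    node_ids
        Ordered unique node identifiers (opaque strings).
    adjacency
        Boolean (n, n) matrix; ``adjacency[i, j]`` is the directed tie
        i -> j in the order of ``node_ids``. Diagonal must be False.
    attributes
        DataFrame indexed by node id with columns
        ``prosociality, sex, income, father_education`` (missing allowed
        in the ordinal bands).
    """

    node_ids: list[str]
    adjacency: np.ndarray
    attributes: pd.DataFrame
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.node_ids = [str(i) for i in self.node_ids]
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids")
        A = np.asarray(self.adjacency, dtype=bool)
        n = len(self.node_ids)
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} != ({n}, {n})")
        if A.diagonal().any():
            raise ValueError("self-loop: adjacency diagonal must be empty")
        self.adjacency = A
        if not isinstance(self.attributes, pd.DataFrame):
            raise ValueError("attributes must be a DataFrame")
        self.attributes = self.attributes.copy()
        self.attributes.index = self.attributes.index.astype(str)
        missing = set(self.node_ids) - set(self.attributes.index)
        if missing:
            raise ValueError(f"nodes without attribute records: {sorted(missing)[:5]}")
        self.attributes = self.attributes.loc[self.node_ids]
        self._index = {v: k for k, v in enumerate(self.node_ids)}

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str]],
        attributes: pd.DataFrame,
        node_ids: list[str] | None = None,
    ) -> "AttributedNetwork":
        """Build from an iterable of (ego, alter) id pairs.

        Duplicate pairs collapse to one edge; self-loops raise.
        """
        if node_ids is None:
            node_ids = [str(i) for i in attributes.index]
        idx = {str(v): k for k, v in enumerate(node_ids)}
        n = len(node_ids)
        A = np.zeros((n, n), dtype=bool)
        for ego, alter in edges:
            ego, alter = str(ego), str(alter)
            if ego == alter:
                raise NetworkLoadError(f"self-loop {ego}->{alter}")
            A[idx[ego], idx[alter]] = True
        return cls(list(node_ids), A, attributes)

    # -- basic accessors ----------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def edges(self) -> set[tuple[str, str]]:
        ii, jj = np.nonzero(self.adjacency)
        return {(self.node_ids[i], self.node_ids[j]) for i, j in zip(ii, jj)}

    def index_of(self, node_id: str) -> int:
        return self._index[str(node_id)]

    def attribute_values(self, name: str) -> np.ndarray:
        """Float array of an attribute in node order (NaN = missing)."""
        if name not in self.attributes.columns:
            raise KeyError(f"unknown attribute {name!r}")
        return self.attributes[name].to_numpy(dtype=float)

    def out_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def in_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    def copy(self) -> "AttributedNetwork":
        return AttributedNetwork(
            list(self.node_ids), self.adjacency.copy(), self.attributes.copy()
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for nid in self.node_ids:
            rec = self.attributes.loc[nid]
            g.add_node(nid, **{k: _graphml_safe(rec[k]) for k in self.attributes.columns})
        g.add_edges_from(sorted(self.edges))
        return g


def _graphml_safe(v):
    if pd.isna(v):
        return ""
    return float(v) if isinstance(v, (int, float, np.floating, np.integer)) else v


# -- operations -------------------------------------------------------


def prosociality_score(item_responses) -> float:
    """Mean of the eight 5-point Likert prosociality items.

    Raises ``ValueError`` unless exactly 8 responses, each in {1,...,5},
    are given. The result is a multiple of 1/8 in [1, 5].
    """
    items = list(item_responses)
    if len(items) != 8:
        raise ValueError(f"expected 8 Likert items, got {len(items)}")
    arr = np.asarray(items, dtype=float)
    if not np.all(np.isin(arr, [1, 2, 3, 4, 5])):
        raise ValueError("Likert responses must each be in {1,...,5}")
    return float(arr.mean())


def degree_summary(net: AttributedNetwork) -> DegreeSummary:
    """Compute the degree descriptives the study reports."""
    out_deg = net.out_degrees()
    in_deg = net.in_degrees()
    return DegreeSummary(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        mean_out_degree=net.n_edges / net.n_nodes if net.n_nodes else 0.0,
        n_isolates=int(((out_deg == 0) & (in_deg == 0)).sum()),
        n_zero_out=int((out_deg == 0).sum()),
        max_out_degree=int(out_deg.max()) if net.n_nodes else 0,
    )


# -- I/O --------------------------------------------------------------


def read_attributes(path) -> pd.DataFrame:
    """Read the node-attribute CSV (header id,prosociality,sex,income,father_education)."""
    df = pd.read_csv(path, dtype={"id": str})
    required = ["id", *ATTRIBUTE_COLUMNS]
    if list(df.columns[: len(required)]) != required:
        raise NetworkLoadError(
            f"attribute file must start with columns {required}, got {list(df.columns)}"
        )
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise NetworkLoadError(f"duplicate node id {dup!r} in attribute file")
    df = df.set_index("id")
    for col in ATTRIBUTE_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise NetworkLoadError(f"malformed value in column {col!r}: {exc}") from None
    bad = df["prosociality"].dropna()
    if ((bad < 1) | (bad > 5)).any():
        raise NetworkLoadError("prosociality scores must lie in [1, 5]")
    n_band6 = int((df["income"] == INCOME_MISSING_BAND).sum())
    if n_band6:
        logger.warning(
            "income band %d ('unable to answer') on %d nodes treated as missing",
            INCOME_MISSING_BAND,
            n_band6,
        )
        df.loc[df["income"] == INCOME_MISSING_BAND, "income"] = np.nan
    return df


def read_network(
    edge_list_path,
    attribute_path,
    on_unknown: str = "drop",
) -> AttributedNetwork:
    """Read an edge-list CSV plus attribute CSV into an AttributedNetwork.

    Parameters
    ----------
    edge_list_path
        CSV with header ``ego,alter``, one directed nomination per row.
    attribute_path
        CSV with header ``id,prosociality,sex,income,father_education``.
    on_unknown
        ``"drop"`` (default): nominations of ids absent from the
        attribute table (non-participants) are dropped with a logged
        count. ``"error"``: raise a load error naming the row.
    """
    if on_unknown not in ("drop", "error"):
        raise ValueError("on_unknown must be 'drop' or 'error'")
    attrs = read_attributes(attribute_path)
    edf = pd.read_csv(edge_list_path, dtype=str)
    if list(edf.columns[:2]) != ["ego", "alter"]:
        raise NetworkLoadError(
            f"edge file must have header ego,alter, got {list(edf.columns)}"
        )
    known = set(attrs.index)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = n_unknown = 0
    for row_no, (ego, alter) in enumerate(zip(edf["ego"], edf["alter"]), start=2):
        if pd.isna(ego) or pd.isna(alter):
            raise NetworkLoadError("missing ego or alter id", row=row_no)
        ego, alter = str(ego).strip(), str(alter).strip()
        if ego == alter:
            raise NetworkLoadError(f"self-loop {ego}->{alter}", row=row_no)
        if ego not in known or alter not in known:
            if on_unknown == "error":
                missing = ego if ego not in known else alter
                raise NetworkLoadError(f"unknown node id {missing!r}", row=row_no)
            n_unknown += 1
            continue
        if (ego, alter) in seen:
            n_dup += 1
            continue
        seen.add((ego, alter))
        edges.append((ego, alter))
    if n_dup:
        logger.warning("collapsed %d duplicate edge rows", n_dup)
    if n_unknown:
        logger.warning("dropped %d nominations of non-participants", n_unknown)
    return AttributedNetwork.from_edges(edges, attrs)


def write_network(net: AttributedNetwork, edge_list_path, attribute_path) -> None:
    """Write the CSV pair that :func:`read_network` reads (round-trips)."""
    pd.DataFrame(sorted(net.edges), columns=["ego", "alter"]).to_csv(
        edge_list_path, index=False
    )
    out = net.attributes.copy()
    out.index.name = "id"
    out.to_csv(attribute_path)


def write_graphml(net: AttributedNetwork, path) -> None:
    """Export for external viewers (Gephi, Cytoscape)."""
    import networkx as nx

    nx.write_graphml(net.to_networkx(), path)
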