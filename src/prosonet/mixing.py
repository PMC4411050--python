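"""Dichotomized mixing-matrix test for assortment.

The first of the study's two analyses: split nodes into "more" and
"less" prosocial at a threshold (the study uses the median score, 3),
cross-tabulate directed tie counts by the groups of ego and alter, and
compare to the counts expected under proportionate (random) mixing.
Each expected cell is the product of three numbers — the ego group's
node share, the alter group's node share, and the total number of ties.

A note on degrees of freedom: because the expected counts come from
node-share proportions (known group sizes), not from margins fitted to
the tie table, the large-sample null reference for the Pearson statistic
is the 3-df multinomial chi-square. The study reports the test with
1 df, the convention for a 2x2 table with fitted margins; ``df`` is
therefore an explicit argument, defaulting to 1 to replicate the
published analysis. Calibration checks should use ``df=3``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .network import AttributedNetwork

logger = logging.getLogger(__name__)

GROUPS = ("more", "less")  # row/column order of all 2x2 matrices


class DegenerateGroupingError(ValueError):
    """All nodes fell into one group; the mixing test is undefined."""


@dataclass(frozen=True)
class MixingResult:
    """2x2 observed/expected directed tie counts with the chi-square test.

    Rows index the ego's group, columns the alter's, in the order
    ("more", "less"). ``chi_square``, ``df`` and ``p_value`` are None
    until :func:`chi_square_test` fills them.
    """

    group_sizes: tuple[int, int]  # (n_more, n_less)
    observed: np.ndarray  # (2, 2) int
    expected: np.ndarray  # (2, 2) float
    chi_square: float | None = None
    df: int | None = None
    p_value: float | None = None
    threshold: float | None = None
    note: str = (
        "expected counts derive from node-share proportions, not fitted margins"
    )

    @property
    def total_edges(self) -> int:
        return int(self.observed.sum())

    def to_frame(self) -> pd.DataFrame:
        """Observed tie counts with expected counts in parentheses."""
        cells = [
            [
                f"{self.observed[i, j]} ({self.expected[i, j]:.1f})"
                for j in range(2)
            ]
            for i in range(2)
        ]
        labels = [
            f"{'More' if g == 'more' else 'Less'} prosocial (N = {n})"
            for g, n in zip(GROUPS, self.group_sizes)
        ]
        return pd.DataFrame(cells, index=labels, columns=labels)

    def report(self) -> str:
        lines = [
            "Mixing matrix (observed, expected in parentheses); rows = ego group:",
            self.to_frame().to_string(),
        ]
        if self.chi_square is not None:
            lines.append(
                f"chi-square = {self.chi_square:.3f}, {self.df} d.f., "
                f"p = {self.p_value:.4g}"
            )
        lines.append(f"note: {self.note}")
        return "\n".join(lines)


def dichotomize(
    scores: pd.Series | np.ndarray,
    threshold: float,
    side: str = ">",
) -> tuple[np.ndarray, tuple[int, int]]:
    """Label each node "more" or "less" prosocial at a threshold.

    ``side=">"`` (default) puts scores strictly above the threshold in
    the "more" group; ``side=">="`` moves scores equal to the threshold
    there instead. The study splits at the median (3) without stating
    which side ties fell on, so both rules are exposed; on the study
    data only one of them yields the published (115, 123) split.

    Returns (labels array of "more"/"less" in node order, (n_more, n_less)).
    """
    if side not in (">", ">="):
        raise ValueError("side must be '>' or '>='")
    values = np.asarray(scores, dtype=float)
    if np.isnan(values).any():
        raise ValueError("scores contain missing values")
    if not (values.min() <= threshold <= values.max()):
        raise ValueError(
            f"threshold {threshold} outside score range "
            f"[{values.min()}, {values.max()}]"
        )
    more = values > threshold if side == ">" else values >= threshold
    labels = np.where(more, "more", "less")
    sizes = (int(more.sum()), int((~more).sum()))
    if 0 in sizes:
        logger.warning(
            "degenerate dichotomization: all %d nodes labelled %r",
            len(values),
            "more" if sizes[1] == 0 else "less",
        )
    return labels, sizes


def expected_counts(group_sizes: tuple[int, int], total_edges: int) -> np.ndarray:
    """Expected 2x2 tie counts under proportionate mixing.

    Cell (g, h) = p_g * p_h * total_edges with p_g the exact node share
    of group g (the study's printed 0.483/0.517 are rounded displays of
    115/238 and 123/238).
    """
    n = sum(group_sizes)
    if n == 0:
        raise ValueError("empty network")
    p = np.asarray(group_sizes, dtype=float) / n
    return np.outer(p, p) * total_edges


def mixing_matrix(net: AttributedNetwork, labels: np.ndarray) -> MixingResult:
    """Observed and expected mixing matrix for a binary node labelling.

    ``labels`` must give "more"/"less" for every node, in node order.
    """
    labels = np.asarray(labels)
    if labels.shape != (net.n_nodes,):
        raise ValueError("labels must cover every node, in node order")
    more = labels == "more"
    A = net.adjacency
    observed = np.array(
        [
            [int(A[np.ix_(more, more)].sum()), int(A[np.ix_(more, ~more)].sum())],
            [int(A[np.ix_(~more, more)].sum()), int(A[np.ix_(~more, ~more)].sum())],
        ]
    )
    sizes = (int(more.sum()), int((~more).sum()))
    return MixingResult(
        group_sizes=sizes,
        observed=observed,
        expected=expected_counts(sizes, int(observed.sum())),
    )


def mixing_from_counts(
    observed, group_sizes: tuple[int, int], total_edges: int | None = None
) -> MixingResult:
    """Build a MixingResult from a printed tie table and group sizes.

    Lets the expected counts and chi-square be recomputed from a
    published 2x2 table when the underlying network is unavailable.
    """
    observed = np.asarray(observed, dtype=int)
    if observed.shape != (2, 2):
        raise ValueError("observed must be 2x2")
    if total_edges is None:
        total_edges = int(observed.sum())
    elif total_edges != observed.sum():
        raise ValueError(
            f"total_edges {total_edges} != sum of observed {observed.sum()}"
        )
    return MixingResult(
        group_sizes=tuple(int(g) for g in group_sizes),
        observed=observed,
        expected=expected_counts(group_sizes, total_edges),
    )


def chi_square_test(m: MixingResult, df: int = 1) -> MixingResult:
    """Pearson chi-square of observed vs proportionate-mixing expected counts.

    ``df=1`` replicates the published convention; ``df=3`` is the
    multinomial reference appropriate to known group shares (see module
    docstring). The statistic itself does not depend on ``df``.
    """
    if (m.expected <= 0).any():
        raise DegenerateGroupingError(
            "degenerate grouping: an expected cell is zero"
        )
    chi2 = float(((m.observed - m.expected) ** 2 / m.expected).sum())
    p = float(stats.chi2.sf(chi2, df))
    return replace(m, chi_square=chi2, df=df, p_value=p)
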