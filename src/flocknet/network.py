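"""Weekly association networks from group-by-individual matrices.

Edge weights are the simple ratio index (SRI): the fraction of grouping
events containing either member of a pair in which both were present.  Under
gambit-of-the-group sampling there are no simultaneous separate sightings, so
``SRI(a, b) = x / (x + y_a + y_b)`` with ``x`` the number of shared events and
``y_a, y_b`` the events with only one of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .events import GroupByIndividualMatrix

__all__ = [
    "WeeklyNetwork",
    "sri_matrix",
    "weighted_degree",
    "eigenvector_centrality",
    "normalized_ranks",
]


@dataclass
class WeeklyNetwork:
    """SRI network for one site-week with derived centralities."""

    site_id: str
    week_id: int
    individuals: tuple
    sri: np.ndarray
    weighted_degree: np.ndarray = None
    eigen_centrality: np.ndarray = None
    rank_degree: np.ndarray = None
    rank_eigen: np.ndarray = None

    @property
    def n(self) -> int:
        return len(self.individuals)


def sri_matrix(gbi: GroupByIndividualMatrix, compute_metrics: bool = True) -> WeeklyNetwork:
    """Simple-ratio-index association matrix for one site-week.

    Individuals with zero occurrences in the week's events are excluded from
    the network (and hence from that week's ranks).  With ``compute_metrics``
    the weighted degree, eigenvector centrality and their normalised ranks are
    filled in as well.
    """
    m = gbi.matrix
    if m.shape[0] < 1 or m.shape[1] < 2:
        raise ValueError("GBI needs at least 1 event and 2 individuals")
    occ = m.sum(axis=0)
    keep = occ > 0
    inds = tuple(t for t, k in zip(gbi.individuals, keep) if k)
    mk = m[:, keep].astype(np.float64)
    x = mk.T @ mk  # co-occurrence counts; diagonal = occurrence counts
    n_occ = np.diag(x).copy()
    denom = n_occ[:, None] + n_occ[None, :] - x
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(denom > 0, x / denom, 0.0)
    np.fill_diagonal(sri, 0.0)
    net = WeeklyNetwork(
        site_id=gbi.site_id, week_id=gbi.week_id, individuals=inds, sri=sri
    )
    if compute_metrics:
        net.weighted_degree = weighted_degree(net)
        net.eigen_centrality = eigenvector_centrality(net)
        n = len(inds)
        net.rank_degree = normalized_ranks(net.weighted_degree, n)
        net.rank_eigen = normalized_ranks(net.eigen_centrality, n)
    return net


def weighted_degree(net: WeeklyNetwork) -> np.ndarray:
    """Row sums of the SRI matrix (strength)."""
    return net.sri.sum(axis=1)


def eigenvector_centrality(
    net: WeeklyNetwork,
    component_wise: bool = False,
) -> np.ndarray:
    """Principal-eigenvector centrality, nonnegative, rescaled so max = 1.

    Solved on the full weighted matrix (symmetric eigendecomposition), so on
    a disconnected network the dominant component carries the mass — the
    documented default.  With ``component_wise`` each connected component is
    solved separately and rescaled to its own maximum.  An all-zero matrix
    yields all zeros.
    """
    a = net.sri
    n = a.shape[0]
    if not a.any():
        return np.zeros(n)
    if component_wise:
        out = np.zeros(n)
        for comp in _components(a):
            sub = a[np.ix_(comp, comp)]
            if sub.any():
                out[comp] = _principal_eigenvector(sub)
        return out
    return _principal_eigenvector(a)


def _principal_eigenvector(a: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(a)
    v = np.abs(vecs[:, -1])  # Perron vector of a nonnegative symmetric matrix
    return v / v.max()


def _components(a: np.ndarray):
    n = a.shape[0]
    seen = np.zeros(n, dtype=bool)
    adj = a > 0
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.flatnonzero(adj[i]):
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        yield np.asarray(comp)


def normalized_ranks(values: np.ndarray, n_present: int | None = None) -> np.ndarray:
    """Ascending average ranks divided by the weekly network size.

    Maps metric values to a size-free scale in ``(0, 1]`` so that rank
    variances are comparable across weeks with different numbers of birds.
    Ties receive their average rank.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("normalized_ranks needs at least one value")
    n = n_present if n_present is not None else values.size
    return rankdata(values, method="average") / n
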