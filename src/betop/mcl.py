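"""Markov Clustering (MCL) of weighted surface graphs.

The graph is represented as a column-stochastic flow matrix.  Each iteration
expands (matrix self-product, spreading flow along paths) and inflates
(entrywise Hadamard power with coefficient r followed by column
renormalization, sharpening intra-cluster flow) until the matrix stops
changing.  Clusters are read from the attractor rows of the equilibrium
matrix.  The inflation coefficient controls granularity; 1.8 is the default
used throughout this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from ._constants import EPITOPE, NON_EPITOPE, NOISE, UNLABELED
from .structure_io import ResidueKey
from .surface_graph import SurfaceGraph


@dataclass
class SubgraphCluster:
    """One MCL cluster of surface residues."""

    members: list[ResidueKey]
    training_label: str = UNLABELED


class MarkovClustering(BaseEstimator, ClusterMixin):
    """MCL on a precomputed affinity (weight) matrix.

    Parameters
    ----------
    inflation : float
        Hadamard-power coefficient r; larger values give finer clusters.
    expansion : int
        Matrix power used in the expansion step.
    max_iter, tol : convergence controls (max-entry change below ``tol``).
    prune : float
        Entries below this are zeroed after each iteration to keep the flow
        matrix sparse-ish.
    add_self_loops : bool
        Add a self loop per node with weight equal to the maximum incident
        edge weight (1 for isolated nodes) before normalization; standard
        MCL stabilization.

    Attributes
    ----------
    labels_ : ndarray of cluster indices per node.
    matrix_ : equilibrium flow matrix.
    n_iter_ : iterations run.
    converged_ : whether ``tol`` was reached before ``max_iter``.
    """

    def __init__(
        self,
        inflation: float = 1.8,
        expansion: int = 2,
        max_iter: int = 200,
        tol: float = 1e-8,
        prune: float = 1e-6,
        add_self_loops: bool = True,
    ):
        self.inflation = inflation
        self.expansion = expansion
        self.max_iter = max_iter
        self.tol = tol
        self.prune = prune
        self.add_self_loops = add_self_loops

    @staticmethod
    def _normalize(m: np.ndarray) -> np.ndarray:
        sums = m.sum(axis=0)
        sums[sums == 0.0] = 1.0  # all-zero column: leave as-is, handled later
        return m / sums

    def _iterate_once(self, m: np.ndarray) -> np.ndarray:
        m = np.linalg.matrix_power(m, self.expansion)
        m = self._normalize(m)
        m = np.power(m, self.inflation)
        m[m < self.prune] = 0.0
        return self._normalize(m)

    def fit(self, X, y=None):
        m = np.asarray(X, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("affinity matrix must be square")
        if (m < 0).any():
            raise ValueError("affinity matrix must be non-negative")
        n = m.shape[0]
        if n == 0:
            raise ValueError("empty graph")
        m = m.copy()
        if self.add_self_loops:
            incident = m.max(axis=0)
            np.fill_diagonal(m, np.where(incident > 0, incident, 1.0))
        m = self._normalize(m)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            nxt = self._iterate_once(m)
            if np.abs(nxt - m).max() < self.tol:
                m = nxt
                converged = True
                break
            m = nxt
        self.matrix_ = m
        self.n_iter_ = it
        self.converged_ = converged
        self.labels_ = self._read_clusters(m)
        return self

    def _read_clusters(self, m: np.ndarray) -> np.ndarray:
        n = m.shape[0]
        attractors = [i for i in range(n) if m[i, i] > self.prune]
        labels = np.full(n, -1, dtype=int)
        if attractors:
            sub = m[attractors, :]  # support of each attractor row
            for j in range(n):
                col = sub[:, j]
                if col.max() > 0.0:
                    # largest-support attractor wins; ties -> lowest index
                    labels[j] = attractors[int(np.argmax(col))]
        # attractors sharing a cluster: map each attractor to its own label
        for i in attractors:
            if labels[i] == -1:
                labels[i] = i
        # uncovered nodes (all-zero columns) become singletons
        for j in range(n):
            if labels[j] == -1:
                labels[j] = j
        # canonicalize to 0..k-1 in order of first appearance
        remap: dict[int, int] = {}
        out = np.empty(n, dtype=int)
        for j in range(n):
            out[j] = remap.setdefault(labels[j], len(remap))
        return out

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def mcl_cluster(
    graph: SurfaceGraph,
    inflation: float = 1.8,
    expansion: int = 2,
    max_iter: int = 200,
    tol: float = 1e-8,
    prune: float = 1e-6,
) -> list[SubgraphCluster]:
    """Cluster a surface graph into exclusive subgraphs with MCL."""
    if not graph.nodes:
        raise ValueError("cannot cluster an empty graph")
    adj, order = graph.adjacency()
    est = MarkovClustering(
        inflation=inflation, expansion=expansion,
        max_iter=max_iter, tol=tol, prune=prune,
    ).fit(adj)
    clusters: dict[int, list[ResidueKey]] = {}
    for key, lab in zip(order, est.labels_):
        clusters.setdefault(int(lab), []).append(key)
    return [SubgraphCluster(members=clusters[c]) for c in sorted(clusters)]


def assign_training_label(
    cluster: SubgraphCluster, node_labels: dict[ResidueKey, str],
    max_epitope_in_negative: int = 2,
) -> str:
    """Label a training cluster from its members' residue labels.

    Epitope when epitope members outnumber non-epitope members; otherwise
    non-epitope when at most ``max_epitope_in_negative`` epitope members show
    up; anything else is noise (mixed clusters are dropped from training).
    The majority rule takes precedence when both conditions hold.
    """
    n_epi = n_non = 0
    for key in cluster.members:
        lab = node_labels.get(key)
        if lab == EPITOPE:
            n_epi += 1
        elif lab == NON_EPITOPE:
            n_non += 1
        else:
            raise ValueError(f"unlabeled cluster member {key}")
    if n_epi > n_non:
        return EPITOPE
    if n_epi <= max_epitope_in_negative:
        return NON_EPITOPE
    return NOISE
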