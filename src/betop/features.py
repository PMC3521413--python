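"""Subgraph feature vectors and feature selection.

A subgraph is represented in a fixed 1770-dimensional space: 20 single-residue
multisets, 210 unordered residue pairs and 1540 unordered residue triples over
the 20-letter alphabet, in lexicographic order.  Single features scale the
learned per-type statistic by the count of that residue type in the subgraph;
pair features sum the weights of subgraph edges of that type; triple features
sum, over geometric 3-cliques of the subgraph whose residue types form the
multiset, the mean of the clique's three edge weights.  Vectors are additive
over disconnected unions and invariant to node enumeration order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from ._constants import AMINO_ACIDS
from .mcl import SubgraphCluster
from .surface_graph import SurfaceGraph
from .weights import WeightTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered enumeration of the 20 + 210 + 1540 = 1770 feature keys."""

    singles: tuple[tuple[str, ...], ...]
    pairs: tuple[tuple[str, ...], ...]
    triples: tuple[tuple[str, ...], ...]

    @property
    def keys(self) -> tuple[tuple[str, ...], ...]:
        return self.singles + self.pairs + self.triples

    def __len__(self) -> int:
        return len(self.singles) + len(self.pairs) + len(self.triples)

    def index(self) -> dict[tuple[str, ...], int]:
        return {k: i for i, k in enumerate(self.keys)}


def enumerate_feature_space(alphabet: tuple[str, ...] = AMINO_ACIDS) -> FeatureSpace:
    """Multisets of sizes 1, 2 and 3 over the alphabet, lexicographic."""
    abc = tuple(sorted(alphabet))
    return FeatureSpace(
        singles=tuple((a,) for a in abc),
        pairs=tuple(combinations_with_replacement(abc, 2)),
        triples=tuple(combinations_with_replacement(abc, 3)),
    )


def vectorize_subgraph(
    cluster: SubgraphCluster,
    graph: SurfaceGraph,
    table: WeightTable,
    space: FeatureSpace | None = None,
) -> np.ndarray:
    """Dense 1770-vector of one subgraph (zeros for absent patterns)."""
    space = space or enumerate_feature_space()
    idx = space.index()
    vec = np.zeros(len(space))

    members = [m for m in cluster.members if m in graph.nodes]
    member_set = set(members)
    for key in members:
        aa = graph.nodes[key].amino_acid
        stat = table.singles.get(aa)
        if stat is None:
            continue
        vec[idx[(aa,)]] += stat

    sub_edges = graph.subgraph_edges(member_set)
    adj: dict = {}
    for (u, v), ed in sub_edges.items():
        w = 0.0 if ed.weight is None else ed.weight
        vec[idx[ed.edge_type]] += w
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    # geometric 3-cliques of the subgraph
    for u, v in sub_edges:
        common = set(adj.get(u, ())) & set(adj.get(v, ()))
        for w_node in common:
            if not (u < v < w_node):  # count each clique once
                continue
            types = tuple(sorted(
                (graph.nodes[u].amino_acid, graph.nodes[v].amino_acid,
                 graph.nodes[w_node].amino_acid)
            ))
            mean_w = (adj[u][v] + adj[u][w_node] + adj[v][w_node]) / 3.0
            vec[idx[types]] += mean_w
    return vec


def fisher_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-class Fisher discriminant score per feature:
    (mean gap)^2 / (sum of within-class variances); 0 for constant features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("Fisher scores require exactly two classes")
    a, b = X[y == classes[0]], X[y == classes[1]]
    gap = (a.mean(axis=0) - b.mean(axis=0)) ** 2
    spread = a.var(axis=0) + b.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(spread > 0, gap / np.where(spread > 0, spread, 1.0), 0.0)
    return s


class FisherScoreSelector(BaseEstimator, SelectorMixin):
    """Select discriminative features by Fisher-score ranking with a
    cross-validated cut-size sweep.

    Candidate cut sizes (powers of two up to ``target_count``) are compared by
    mean f-score of a small RBF-SVM under stratified k-fold CV; the best cut
    wins.  If no feature discriminates at all, the smallest cut is kept with a
    warning.

    Attributes: ``scores_``, ``n_selected_``, ``support_``.
    """

    def __init__(self, target_count: int = 144, cv: int = 5, random_state: int = 0):
        self.target_count = target_count
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("feature selection requires two classes")
        # binarize with the minority class as positive (f-score target)
        n_per = np.array([(y == c).sum() for c in classes])
        pos = classes[int(np.argmin(n_per))]
        y01 = (y == pos).astype(int)
        self.scores_ = fisher_scores(X, y01)
        order = np.argsort(-self.scores_, kind="stable")

        sizes = []
        s = 8
        while s < self.target_count:
            sizes.append(s)
            s *= 2
        sizes.append(self.target_count)
        sizes = [min(s, X.shape[1]) for s in sizes]
        sizes = sorted(set(sizes))

        if not np.any(self.scores_ > 0):
            logger.warning("no discriminative features; keeping smallest cut")
            best_size = sizes[0]
        else:
            n_splits = min(self.cv, int(n_per.min()))
            best_size, best_score = sizes[0], -1.0
            if n_splits >= 2:
                skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                      random_state=self.random_state)
                for size in sizes:
                    cols = order[:size]
                    # class_weight balances the sweep on imbalanced matrices
                    clf = SVC(kernel="rbf", C=8.0, gamma="scale",
                              class_weight="balanced",
                              random_state=self.random_state)
                    score = cross_val_score(clf, X[:, cols], y01, cv=skf,
                                            scoring="f1").mean()
                    if score > best_score:
                        best_size, best_score = size, score
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[order[:best_size]] = True
        self.support_ = mask
        self.n_selected_ = int(best_size)
        return self

    def _get_support_mask(self):
        return self.support_


def select_features(
    X: np.ndarray, y: np.ndarray, target_count: int = 144,
    cv: int = 5, random_state: int = 0,
) -> np.ndarray:
    """Boolean mask of selected features (thin wrapper over the selector)."""
    sel = FisherScoreSelector(target_count=target_count, cv=cv,
                              random_state=random_state).fit(X, y)
    return sel.support_
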