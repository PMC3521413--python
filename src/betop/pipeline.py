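"""End-to-end training and prediction.

`EpitopePredictor` is the user-facing estimator.  ``fit`` consumes labeled
antibody-antigen complexes and chains together curation, 4 A contact
labeling, surface-graph construction, edge-weight learning, boundary-edge
suppression, Markov clustering, subgraph labeling, vectorization, feature
selection and the trust-reliable SVM ensemble.  ``predict`` consumes a bare
antigen and returns zero or more disjoint epitopes, each a residue set with a
confidence score.

The fitted model serializes to a single JSON bundle: weight tables, boundary
model, feature mask, per-classifier balanced training matrices and selected
SVM hyperparameters, and every seed.  Loading refits the SVMs
deterministically from the stored matrices, so a reloaded model predicts
identically and retraining with the same seed reproduces the bundle byte for
byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.svm import SVC

from ._constants import EPITOPE, NOISE, NON_EPITOPE
from . import structure_io
from .structure_io import ComplexRecord, ResidueKey
from .surface_graph import SurfaceGraph, build_surface_graph, edge_key
from .weights import (
    BoundaryModel, ContrastParams, WeightTable,
    apply_weights, boundary_model, build_weight_table,
)
from .mcl import SubgraphCluster, assign_training_label, mcl_cluster
from .features import FisherScoreSelector, enumerate_feature_space, vectorize_subgraph
from .ensemble import TrustReliableEnsemble

logger = logging.getLogger(__name__)


@dataclass
class EpitopePrediction:
    """Predicted epitopes of one antigen."""

    epitopes: list[set[ResidueKey]]
    scores: list[float]                       # one confidence per epitope
    residue_scores: dict[ResidueKey, float]   # vote score per surface residue
    provenance: dict = field(default_factory=dict)

    def predicted_residues(self) -> set[ResidueKey]:
        out: set[ResidueKey] = set()
        for e in self.epitopes:
            out |= e
        return out

    def to_dict(self) -> dict:
        return {
            "epitopes": [
                {"score": s, "residues": [list(k) for k in sorted(e)]}
                for e, s in zip(self.epitopes, self.scores)
            ],
            "residue_scores": {
                "|".join((k[0], str(k[1]), k[2])): v
                for k, v in sorted(self.residue_scores.items())
            },
            "provenance": self.provenance,
        }


class EpitopePredictor(BaseEstimator):
    """Graph-based conformational B-cell epitope predictor.

    Parameters mirror the method's tunables: ``alpha`` mixes the chi-square
    and log-odds edge statistics, ``contrast_theta``/``contrast_gamma`` shape
    the weight-sharpening transform, ``inflation`` sets MCL granularity,
    ``w0_percentile`` the boundary-suppression threshold, ``theta0``/``tau0``
    the voting threshold and dubiety band.
    """

    def __init__(
        self,
        alpha: float = 0.3,
        contrast_theta: float = 3.0,
        contrast_gamma: float = 3.0,
        inflation: float = 1.8,
        w0_percentile: float = 60.0,
        suppress_boundary: bool = True,
        theta0: float = 0.3,
        tau0: float = 0.05,
        asa_threshold: float = 10.0,
        contact_cutoff: float = 4.0,
        edge_cutoff: float = 6.0,
        probe_radius: float = 1.4,
        target_features: int = 144,
        curate_input: bool = True,
        param_grid: dict | None = None,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.contrast_theta = contrast_theta
        self.contrast_gamma = contrast_gamma
        self.inflation = inflation
        self.w0_percentile = w0_percentile
        self.suppress_boundary = suppress_boundary
        self.theta0 = theta0
        self.tau0 = tau0
        self.asa_threshold = asa_threshold
        self.contact_cutoff = contact_cutoff
        self.edge_cutoff = edge_cutoff
        self.probe_radius = probe_radius
        self.target_features = target_features
        self.curate_input = curate_input
        self.param_grid = param_grid
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _antigen_graph(
        self, cx: ComplexRecord, labels: dict[ResidueKey, str] | None = None
    ) -> SurfaceGraph:
        atoms = cx.antigen_atoms()
        asa = structure_io.compute_asa(atoms, probe_radius=self.probe_radius)
        surf = structure_io.surface_atoms(asa, threshold=self.asa_threshold)
        if len(surf) < 4:
            raise structure_io.StructureError(
                f"{cx.name or 'antigen'}: fewer than 4 surface atoms")
        graph = build_surface_graph(atoms, surf, max_dist=self.edge_cutoff,
                                    labels=labels)
        logger.info("%s: %d atoms, %d surface, %d nodes, %d edges",
                    cx.name or "antigen", len(atoms), len(surf),
                    len(graph.nodes), len(graph.edges))
        return graph

    def fit(self, X, y=None):
        """Train from a list of antibody-antigen :class:`ComplexRecord`."""
        complexes = list(X)
        if len(complexes) < 2:
            raise ValueError("training requires at least 2 complexes")
        if self.curate_input:
            complexes = structure_io.curate(complexes)
            if len(complexes) < 2:
                raise ValueError("fewer than 2 complexes survive curation")

        graphs: list[SurfaceGraph] = []
        for cx in complexes:
            epi = structure_io.label_epitope_residues(cx, cutoff=self.contact_cutoff)
            graph = self._antigen_graph(cx)
            for key, nd in graph.nodes.items():
                nd.label = EPITOPE if key in epi else NON_EPITOPE
            graphs.append(graph)

        params = ContrastParams(theta=self.contrast_theta, gamma=self.contrast_gamma)
        self.weight_table_ = build_weight_table(graphs, alpha=self.alpha,
                                                contrast_params=params)
        self.boundary_model_ = boundary_model(
            graphs, alpha=self.alpha, contrast_params=params,
            w0_percentile=self.w0_percentile)

        self.feature_space_ = enumerate_feature_space()
        vectors, labels = [], []
        n_noise = 0
        for graph in graphs:
            weighted = apply_weights(graph, self.weight_table_,
                                     self.boundary_model_,
                                     suppress=self.suppress_boundary)
            node_labels = {k: nd.label for k, nd in graph.nodes.items()}
            for cluster in mcl_cluster(weighted, inflation=self.inflation):
                lab = assign_training_label(cluster, node_labels)
                if lab == NOISE:
                    n_noise += 1
                    continue  # mixed clusters are overlooked during training
                vectors.append(vectorize_subgraph(cluster, weighted,
                                                  self.weight_table_,
                                                  self.feature_space_))
                labels.append(lab)
        logger.info("training subgraphs: %d epitope, %d non-epitope, %d noise",
                    labels.count(EPITOPE), labels.count(NON_EPITOPE), n_noise)
        if not vectors or EPITOPE not in labels or NON_EPITOPE not in labels:
            raise ValueError(
                "training produced no usable subgraphs of both classes "
                f"(epitope={labels.count(EPITOPE)}, "
                f"non-epitope={labels.count(NON_EPITOPE)}, noise={n_noise})")

        Xm = np.vstack(vectors)
        ym = np.array([1 if l == EPITOPE else -1 for l in labels])
        self.selector_ = FisherScoreSelector(
            target_count=self.target_features,
            random_state=self.random_state).fit(Xm, ym)
        Xs = Xm[:, self.selector_.support_]
        self.ensemble_ = TrustReliableEnsemble(
            theta0=self.theta0, tau0=self.tau0, param_grid=self.param_grid,
            random_state=self.random_state).fit(Xs, ym)
        self._train_X_ = Xs
        self._train_y_ = ym
        return self

    # ------------------------------------------------------------------
    def predict(self, antigen: ComplexRecord) -> EpitopePrediction:
        """Predict epitopes for a bare antigen (empty antibody role)."""
        if not hasattr(self, "ensemble_"):
            raise ValueError("predictor is not fitted")
        original = self._antigen_graph(antigen)
        weighted = apply_weights(original, self.weight_table_,
                                 self.boundary_model_,
                                 suppress=self.suppress_boundary)
        clusters = mcl_cluster(weighted, inflation=self.inflation)

        residue_scores: dict[ResidueKey, float] = {}
        positive: list[tuple[SubgraphCluster, float]] = []
        for cluster in clusters:
            vec = vectorize_subgraph(cluster, weighted, self.weight_table_,
                                     self.feature_space_)
            trace = self.ensemble_.vote(vec[self.selector_.support_])
            for key in cluster.members:
                residue_scores[key] = trace.score
            if trace.decision == 1:
                positive.append((cluster, trace.score))

        # merge predicted subgraphs joined by an edge of the original graph
        merged: list[list[int]] = []
        parent = list(range(len(positive)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(positive)):
            for j in range(i + 1, len(positive)):
                mi, mj = positive[i][0].members, positive[j][0].members
                if any(edge_key(u, v) in original.edges for u in mi for v in mj):
                    parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(len(positive)):
            groups.setdefault(find(i), []).append(i)

        epitopes, scores = [], []
        for members in groups.values():
            residues: set[ResidueKey] = set()
            for i in members:
                residues |= set(positive[i][0].members)
            epitopes.append(residues)
            scores.append(float(np.mean([positive[i][1] for i in members])))
        order = np.argsort(-np.asarray(scores)) if scores else []
        return EpitopePrediction(
            epitopes=[epitopes[i] for i in order],
            scores=[scores[i] for i in order],
            residue_scores=residue_scores,
            provenance={
                "model": "betop", "seed": self.random_state,
                "params": {k: v for k, v in self.get_params().items()
                           if not isinstance(v, dict)},
            },
        )

    # ------------------------------------------------------------------
    # bundle serialization
    def to_bundle(self) -> dict:
        if not hasattr(self, "ensemble_"):
            raise ValueError("predictor is not fitted")
        ens = self.ensemble_
        return {
            "format": "betop-bundle-1",
            "params": {k: v for k, v in self.get_params().items()},
            "weight_table": self.weight_table_.to_dict(),
            "boundary_model": self.boundary_model_.to_dict(),
            "feature_mask": [int(i) for i in np.flatnonzero(self.selector_.support_)],
            "n_features": int(self.selector_.support_.size),
            "ensemble": {
                "k": ens.k_,
                "theta0": ens.theta0,
                "tau0": ens.tau0,
                "weights": [float(w) for w in ens.weights_],
                "best_params": ens.best_params_,
                "groups": ens.groups_,
            },
            "train_X": [[float(v) for v in row] for row in self._train_X_],
            "train_y": [int(v) for v in self._train_y_],
            "seed": self.random_state,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_bundle(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_bundle(cls, bundle: dict) -> "EpitopePredictor":
        model = cls(**bundle["params"])
        model.weight_table_ = WeightTable.from_dict(bundle["weight_table"])
        model.boundary_model_ = BoundaryModel.from_dict(bundle["boundary_model"])
        model.feature_space_ = enumerate_feature_space()
        support = np.zeros(bundle["n_features"], dtype=bool)
        support[bundle["feature_mask"]] = True
        sel = FisherScoreSelector(target_count=model.target_features)
        sel.support_ = support
        sel.n_selected_ = int(support.sum())
        model.selector_ = sel

        X = np.array(bundle["train_X"], dtype=float)
        y = np.array(bundle["train_y"], dtype=int)
        eb = bundle["ensemble"]
        ens = TrustReliableEnsemble(theta0=eb["theta0"], tau0=eb["tau0"],
                                    random_state=bundle["seed"])
        ens.classes_ = np.array([-1, 1])
        ens.k_ = int(eb["k"])
        ens.groups_ = [list(map(int, g)) for g in eb["groups"]]
        ens.weights_ = np.array(eb["weights"], dtype=float)
        ens.best_params_ = eb["best_params"]
        pos = np.flatnonzero(y == 1)
        ens.classifiers_ = []
        for i, (group, bp) in enumerate(zip(ens.groups_, eb["best_params"])):
            Xi = np.vstack([X[pos], X[group]])
            yi = np.concatenate([np.ones(len(pos)), -np.ones(len(group))])
            clf = SVC(kernel="rbf", probability=True, C=bp["C"],
                      gamma=bp["gamma"], random_state=bundle["seed"] + i)
            ens.classifiers_.append(clf.fit(Xi, yi))
        model.ensemble_ = ens
        model._train_X_ = X
        model._train_y_ = y
        return model

    @classmethod
    def load(cls, path) -> "EpitopePredictor":
        with open(path) as fh:
            return cls.from_bundle(json.load(fh))


def train(complexes: list[ComplexRecord], **config) -> EpitopePredictor:
    """Train an :class:`EpitopePredictor` (thin functional wrapper)."""
    return EpitopePredictor(**config).fit(complexes)


def predict(antigen: ComplexRecord, model: EpitopePredictor) -> EpitopePrediction:
    """Predict epitopes for one antigen with a trained model."""
    return model.predict(antigen)
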