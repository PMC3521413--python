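"""Imbalance-aware SVM ensemble with trust-reliable voting.

Because non-epitope subgraphs far outnumber epitope subgraphs, the negative
class is split into k = round(#negative / #positive) disjoint groups and one
RBF-SVM is trained per group on a balanced set (its group plus all
positives).  At prediction time each classifier casts a signed vote f_i in
{-1, +1} with a calibrated probability; the final decision is

    y = sgn( sum_i w_i * f_i * delta_i - theta_0 )

where w_i is the classifier's normalized validation f-score and delta_i is a
trust determinant: a classifier whose non-epitope probability p_i0 lies within
tau_0 of 0.5 (dubious) is silenced (delta_i = 0) whenever the other
classifiers lean one way on balance; if the confident leanings cancel exactly,
every vote is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC


@dataclass
class VoteTrace:
    """Per-classifier vote record and the aggregated decision."""

    labels: np.ndarray       # f_i in {-1, +1}
    p_nonepitope: np.ndarray  # p_i0 in [0, 1]
    delta: np.ndarray        # delta_i in {0, 1}
    score: float             # sum_i w_i f_i delta_i
    decision: int            # +1 epitope / -1 non-epitope


def _default_grid() -> dict:
    # coarse cost sweep with data-scaled kernel width; the balanced groups
    # are small, so a dense (C, gamma) grid only overfits the folds
    return {
        "C": [2.0**e for e in range(-3, 12, 2)],
        "gamma": ["scale"],
    }


def trust_reliable_vote(
    labels: np.ndarray,
    p_nonepitope: np.ndarray,
    weights: np.ndarray,
    theta0: float = 0.3,
    tau0: float = 0.05,
) -> VoteTrace:
    """Aggregate per-classifier votes into one trust-reliable decision."""
    f = np.asarray(labels, dtype=float)
    p0 = np.asarray(p_nonepitope, dtype=float)
    w = np.asarray(weights, dtype=float)
    if ((p0 < 0) | (p0 > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    margin = p0 - 0.5
    # sgn with 0 contributing nothing to the consensus sum
    consensus = np.sum(np.sign(margin))
    h = 1.0 if consensus != 0 else 0.0
    g = (tau0 - np.abs(margin)) > 0  # strictly dubious classifiers
    delta = 1.0 - g.astype(float) * h
    score = float(np.sum(w * f * delta))
    decision = 1 if score > theta0 else -1
    return VoteTrace(labels=f.astype(int), p_nonepitope=p0, delta=delta,
                     score=score, decision=decision)


class TrustReliableEnsemble(BaseEstimator, ClassifierMixin):
    """k balanced RBF-SVMs + trust-reliable vote, sklearn-style.

    ``fit(X, y)`` expects y in {+1, -1} (or {1, 0}) with +1/1 the epitope
    (minority) class.  ``decision_function`` returns the vote score minus
    theta0, ``predict`` the thresholded labels in {-1, +1}.

    Attributes
    ----------
    k_ : number of base classifiers.
    classifiers_ : fitted SVCs.
    weights_ : normalized per-classifier validation f-scores.
    best_params_ : chosen (C, gamma) per classifier.
    groups_ : indices of negative samples per classifier group.
    """

    def __init__(
        self,
        theta0: float = 0.3,
        tau0: float = 0.05,
        param_grid: dict | None = None,
        cv: int = 5,
        random_state: int = 0,
    ):
        self.theta0 = theta0
        self.tau0 = tau0
        self.param_grid = param_grid
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        pos_mask = (y == 1)
        neg_mask = ~pos_mask
        n_pos, n_neg = int(pos_mask.sum()), int(neg_mask.sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError("both classes must be non-empty")
        self.classes_ = np.array([-1, 1])
        self.k_ = max(1, round(n_neg / n_pos))

        rng = np.random.default_rng(self.random_state)
        neg_idx = np.flatnonzero(neg_mask)
        neg_idx = neg_idx[rng.permutation(len(neg_idx))]
        self.groups_ = [list(map(int, g)) for g in np.array_split(neg_idx, self.k_)]

        grid = self.param_grid or _default_grid()
        X_pos = X[pos_mask]
        self.classifiers_ = []
        self.best_params_ = []
        raw_scores = []
        for i, group in enumerate(self.groups_):
            Xi = np.vstack([X_pos, X[group]])
            yi = np.concatenate([np.ones(n_pos), -np.ones(len(group))])
            n_splits = min(self.cv, n_pos, len(group))
            base = SVC(kernel="rbf", probability=True,
                       random_state=self.random_state + i)
            if n_splits >= 2:
                skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                      random_state=self.random_state + i)
                search = GridSearchCV(base, grid, scoring="f1", cv=skf)
                search.fit(Xi, yi)
                clf = search.best_estimator_
                raw_scores.append(float(search.best_score_))
                self.best_params_.append(
                    {"C": clf.C, "gamma": clf.gamma})
            else:  # too few samples to validate: fit with defaults
                clf = base.fit(Xi, yi)
                raw_scores.append(1.0)
                self.best_params_.append({"C": clf.C, "gamma": clf.gamma})
            self.classifiers_.append(clf)
        raw = np.clip(np.asarray(raw_scores, dtype=float), 0.0, None)
        self.weights_ = raw / raw.sum() if raw.sum() > 0 else np.full(self.k_, 1.0 / self.k_)
        return self

    def _votes(self, X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        f = np.empty((len(self.classifiers_), X.shape[0]))
        p0 = np.empty_like(f)
        for i, clf in enumerate(self.classifiers_):
            f[i] = clf.predict(X)
            proba = clf.predict_proba(X)
            neg_col = int(np.flatnonzero(clf.classes_ == -1)[0])
            p0[i] = proba[:, neg_col]
        return f, p0

    def vote(self, x) -> VoteTrace:
        """Full vote trace for a single sample."""
        f, p0 = self._votes(np.atleast_2d(x))
        return trust_reliable_vote(f[:, 0], p0[:, 0], self.weights_,
                                   self.theta0, self.tau0)

    def score_samples(self, X) -> np.ndarray:
        """Aggregated vote score sum_i w_i f_i delta_i per sample."""
        f, p0 = self._votes(X)
        return np.array([
            trust_reliable_vote(f[:, j], p0[:, j], self.weights_,
                                self.theta0, self.tau0).score
            for j in range(f.shape[1])
        ])

    def decision_function(self, X) -> np.ndarray:
        return self.score_samples(X) - self.theta0

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, 1, -1)


def build_ensemble(
    epi_vectors: np.ndarray,
    non_vectors: np.ndarray,
    theta0: float = 0.3,
    tau0: float = 0.05,
    param_grid: dict | None = None,
    cv: int = 5,
    random_state: int = 0,
) -> TrustReliableEnsemble:
    """Train the ensemble from per-class feature matrices."""
    epi = np.atleast_2d(np.asarray(epi_vectors, dtype=float))
    non = np.atleast_2d(np.asarray(non_vectors, dtype=float))
    if epi.size == 0 or non.size == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([epi, non])
    y = np.concatenate([np.ones(len(epi)), -np.ones(len(non))])
    return TrustReliableEnsemble(
        theta0=theta0, tau0=tau0, param_grid=param_grid,
        cv=cv, random_state=random_state,
    ).fit(X, y)


def predict_subgraph(vector: np.ndarray, model: TrustReliableEnsemble) -> tuple[int, float]:
    """(label, continuous vote score) for one masked feature vector."""
    vector = np.asarray(vector, dtype=float).ravel()
    n_features = model.classifiers_[0].n_features_in_
    if vector.shape[0] != n_features:
        raise ValueError(f"expected {n_features} features, got {vector.shape[0]}")
    trace = model.vote(vector)
    return trace.decision, trace.score
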