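"""Edge-type propensity weights.

For each of the 210 unordered residue-type pairs the training graphs yield two
counts per class contrast (e.g. edges inside epitopes vs edges inside
non-epitopes).  A chi-square association statistic and a smoothed log-odds
ratio are computed per type, min-max normalized across the 210 types, mixed
convexly (alpha), and finally passed through a sigmoid-like contrast

    f(W) = 1 / (1 + theta * (W / (1 - W))**(-gamma))

which amplifies strong weights and suppresses weak ones (f(0)=0, f(1)=1,
strictly increasing; theta = gamma = 3 by default).

Boundary edges (one epitope endpoint, one non-epitope endpoint) get their own
score: the same machinery contrasts the boundary class against the epitope
class (W') and against the non-epitope class (W''); the boundary score of a
type is max(W', W'').  Types scoring above a percentile threshold w0 are
removed from graphs before clustering -- they are confidently
epitope/non-epitope dividers and removing them sharpens the cluster structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from ._constants import AMINO_ACIDS, BOUNDARY, EPITOPE, NON_EPITOPE, UNKNOWN
from .surface_graph import SurfaceGraph

logger = logging.getLogger(__name__)

PairType = tuple[str, str]

ALL_PAIR_TYPES: tuple[PairType, ...] = tuple(combinations_with_replacement(AMINO_ACIDS, 2))
N_PAIR_TYPES = len(ALL_PAIR_TYPES)  # 210


@dataclass
class ContrastParams:
    theta: float = 3.0
    gamma: float = 3.0

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.gamma <= 0:
            raise ValueError("theta and gamma must be positive")


@dataclass
class EdgeTypeCounts:
    """Per-edge-type counts for a two-class contrast."""

    class_pair: tuple[str, str]
    counts: dict[PairType, tuple[int, int]]

    def __post_init__(self) -> None:
        if set(self.counts) != set(ALL_PAIR_TYPES):
            raise ValueError("counts must cover exactly the 210 pair types")

    def totals(self) -> tuple[int, int]:
        t1 = sum(c[0] for c in self.counts.values())
        t2 = sum(c[1] for c in self.counts.values())
        return t1, t2


@dataclass
class WeightTable:
    """Learned weights for one class contrast plus single-residue statistics."""

    class_pair: tuple[str, str]
    chi2: dict[PairType, float]
    log_odds: dict[PairType, float]
    combined: dict[PairType, float]  # normalized, mixed, contrasted; in [0, 1]
    alpha: float = 0.3
    contrast_params: ContrastParams = field(default_factory=ContrastParams)
    singles: dict[str, float] = field(default_factory=dict)  # 20 keys

    def to_dict(self) -> dict:
        return {
            "class_pair": list(self.class_pair),
            "alpha": self.alpha,
            "theta": self.contrast_params.theta,
            "gamma": self.contrast_params.gamma,
            "chi2": {"".join(k): v for k, v in self.chi2.items()},
            "log_odds": {"".join(k): v for k, v in self.log_odds.items()},
            "combined": {"".join(k): v for k, v in self.combined.items()},
            "singles": dict(self.singles),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeightTable":
        unpack = lambda m: {(k[0], k[1]): float(v) for k, v in m.items()}
        return cls(
            class_pair=tuple(d["class_pair"]),
            chi2=unpack(d["chi2"]),
            log_odds=unpack(d["log_odds"]),
            combined=unpack(d["combined"]),
            alpha=d["alpha"],
            contrast_params=ContrastParams(theta=d["theta"], gamma=d["gamma"]),
            singles=dict(d["singles"]),
        )


@dataclass
class BoundaryModel:
    """Boundary-edge suppression: per-type score and threshold w0."""

    boundary_score: dict[PairType, float]
    w0: float

    def suppressed_types(self) -> set[PairType]:
        return {t for t, s in self.boundary_score.items() if s > self.w0}

    def to_dict(self) -> dict:
        return {"w0": self.w0,
                "boundary_score": {"".join(k): v for k, v in self.boundary_score.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "BoundaryModel":
        return cls(
            boundary_score={(k[0], k[1]): float(v) for k, v in d["boundary_score"].items()},
            w0=float(d["w0"]),
        )


def _edge_class(label_u: str, label_v: str) -> str | None:
    if label_u == EPITOPE and label_v == EPITOPE:
        return EPITOPE
    if label_u == NON_EPITOPE and label_v == NON_EPITOPE:
        return NON_EPITOPE
    if {label_u, label_v} == {EPITOPE, NON_EPITOPE}:
        return BOUNDARY
    return None  # an unknown endpoint


def count_edge_types(
    graphs: list[SurfaceGraph], class_pair: tuple[str, str]
) -> EdgeTypeCounts:
    """Count edges of each type falling in each class of ``class_pair``.

    An edge is epitope if both endpoints are epitope residues, non-epitope if
    both are non-epitope, boundary if mixed.
    """
    valid = {
        (EPITOPE, NON_EPITOPE),
        (BOUNDARY, EPITOPE),
        (BOUNDARY, NON_EPITOPE),
    }
    if tuple(class_pair) not in valid:
        raise ValueError(f"unsupported class pair {class_pair}")
    counts = {t: [0, 0] for t in ALL_PAIR_TYPES}
    n_labeled = 0
    for g in graphs:
        for (u, v), ed in g.edges.items():
            cls = _edge_class(g.nodes[u].label, g.nodes[v].label)
            if cls is None:
                continue
            n_labeled += 1
            if cls == class_pair[0]:
                counts[ed.edge_type][0] += 1
            elif cls == class_pair[1]:
                counts[ed.edge_type][1] += 1
    if n_labeled == 0:
        raise ValueError("no labeled edges in training graphs")
    return EdgeTypeCounts(
        class_pair=tuple(class_pair),
        counts={t: (c[0], c[1]) for t, c in counts.items()},
    )


def chi2_stat(n1: int, n2: int, total1: int, total2: int) -> float:
    """Chi-square association of one edge type with the class, expected counts
    under independence over the two-class table.  Zero when the type is absent.
    """
    row = n1 + n2
    grand = total1 + total2
    if row == 0 or grand == 0 or total1 == 0 or total2 == 0:
        return 0.0
    e1 = row * total1 / grand
    e2 = row * total2 / grand
    return (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2


def log_odds(
    n1: int, n2: int, total1: int, total2: int,
    pseudocount: float = 0.5, n_types: int = N_PAIR_TYPES,
) -> float:
    """Natural-log ratio of smoothed within-class type frequencies."""
    p = (n1 + pseudocount) / (total1 + n_types * pseudocount)
    q = (n2 + pseudocount) / (total2 + n_types * pseudocount)
    return math.log(p / q)


def _minmax(values: dict, label: str) -> dict:
    arr = np.array(list(values.values()), dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        logger.warning("constant %s table; normalizing to all-0.5", label)
        return {k: 0.5 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def normalize_and_combine(
    chi2_table: dict, log_odds_table: dict, alpha: float = 0.3
) -> dict:
    """Min-max normalize each table over its keys, then mix convexly."""
    if set(chi2_table) != set(log_odds_table):
        raise ValueError("tables must share the same keys")
    nc = _minmax(chi2_table, "chi2")
    nl = _minmax(log_odds_table, "log-odds")
    return {k: alpha * nc[k] + (1.0 - alpha) * nl[k] for k in chi2_table}


def contrast(w: float, params: ContrastParams | None = None) -> float:
    """Weight-sharpening transform f(W) = 1/(1 + theta*(W/(1-W))**(-gamma))."""
    params = params or ContrastParams()
    w = min(max(float(w), 1e-9), 1.0 - 1e-9)
    return 1.0 / (1.0 + params.theta * (w / (1.0 - w)) ** (-params.gamma))


def _contrasted_table(
    counts: EdgeTypeCounts,
    alpha: float,
    params: ContrastParams,
    pseudocount: float = 0.5,
) -> tuple[dict, dict, dict]:
    """chi2, log-odds and contrasted-combined tables from one count set."""
    t1, t2 = counts.totals()
    chi2_table = {t: chi2_stat(*counts.counts[t], t1, t2) for t in ALL_PAIR_TYPES}
    lo_table = {t: log_odds(*counts.counts[t], t1, t2, pseudocount) for t in ALL_PAIR_TYPES}
    combined = normalize_and_combine(chi2_table, lo_table, alpha)
    return chi2_table, lo_table, {t: contrast(w, params) for t, w in combined.items()}


def _single_statistics(
    graphs: list[SurfaceGraph], alpha: float, pseudocount: float = 0.5
) -> dict[str, float]:
    """Per-residue-type statistic, built like the pair weights but over node
    frequencies in epitope vs non-epitope residues (normalized + mixed, no
    contrast)."""
    counts = {aa: [0, 0] for aa in AMINO_ACIDS}
    for g in graphs:
        for nd in g.nodes.values():
            if nd.label == EPITOPE:
                counts[nd.amino_acid][0] += 1
            elif nd.label == NON_EPITOPE:
                counts[nd.amino_acid][1] += 1
    t1 = sum(c[0] for c in counts.values())
    t2 = sum(c[1] for c in counts.values())
    chi2_table = {aa: chi2_stat(c[0], c[1], t1, t2) for aa, c in counts.items()}
    lo_table = {
        aa: log_odds(c[0], c[1], t1, t2, pseudocount, n_types=len(AMINO_ACIDS))
        for aa, c in counts.items()
    }
    return normalize_and_combine(chi2_table, lo_table, alpha)


def build_weight_table(
    graphs: list[SurfaceGraph],
    alpha: float = 0.3,
    contrast_params: ContrastParams | None = None,
    pseudocount: float = 0.5,
) -> WeightTable:
    """Learn the epitope-vs-non-epitope weight table from labeled graphs."""
    params = contrast_params or ContrastParams()
    counts = count_edge_types(graphs, (EPITOPE, NON_EPITOPE))
    chi2_table, lo_table, combined = _contrasted_table(counts, alpha, params, pseudocount)
    return WeightTable(
        class_pair=(EPITOPE, NON_EPITOPE),
        chi2=chi2_table,
        log_odds=lo_table,
        combined=combined,
        alpha=alpha,
        contrast_params=params,
        singles=_single_statistics(graphs, alpha, pseudocount),
    )


def boundary_model(
    graphs: list[SurfaceGraph],
    alpha: float = 0.3,
    contrast_params: ContrastParams | None = None,
    w0_percentile: float = 60.0,
    pseudocount: float = 0.5,
) -> BoundaryModel:
    """Score each edge type as a boundary indicator and set the threshold w0.

    W' contrasts boundary vs epitope edges, W'' boundary vs non-epitope; the
    score is max(W', W'').  w0 is the given percentile of the 210 scores.
    """
    params = contrast_params or ContrastParams()
    counts_be = count_edge_types(graphs, (BOUNDARY, EPITOPE))
    counts_bn = count_edge_types(graphs, (BOUNDARY, NON_EPITOPE))
    if counts_be.totals()[0] == 0:
        raise ValueError("no boundary edges in training graphs")
    _, _, w_prime = _contrasted_table(counts_be, alpha, params, pseudocount)
    _, _, w_dprime = _contrasted_table(counts_bn, alpha, params, pseudocount)
    score = {t: max(w_prime[t], w_dprime[t]) for t in ALL_PAIR_TYPES}
    w0 = float(np.percentile(np.array(list(score.values())), w0_percentile))
    return BoundaryModel(boundary_score=score, w0=w0)


def apply_weights(
    graph: SurfaceGraph,
    table: WeightTable,
    boundary: BoundaryModel | None = None,
    suppress: bool = True,
) -> SurfaceGraph:
    """Return a copy of ``graph`` with trained weights on every edge.

    Edges whose type scores above the boundary threshold are removed when
    ``suppress`` is true (down-weighting to zero weight otherwise).  Edges
    touching a residue outside the 20-letter alphabet are skipped with a
    warning.
    """
    suppressed = boundary.suppressed_types() if boundary is not None else set()
    out = SurfaceGraph(nodes=dict(graph.nodes), edges={})
    for (u, v), ed in graph.edges.items():
        if ed.edge_type not in table.combined:
            logger.warning("unknown edge type %s; edge skipped", ed.edge_type)
            continue
        if ed.edge_type in suppressed:
            if suppress:
                continue
            out.add_edge(u, v, weight=0.0)
            continue
        out.add_edge(u, v, weight=table.combined[ed.edge_type])
    return out
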