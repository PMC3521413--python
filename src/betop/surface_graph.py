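"""Residue-level antigen surface graphs from Delaunay tessellation.

Surface atoms are tessellated in 3D; tessellation edges are then lifted to the
residue level: intra-residue contacts are discarded, atom contacts longer than
6 A are discarded, and the remaining atom contacts between two residues
collapse into a single undirected residue edge typed by the unordered pair of
amino-acid identities of its endpoints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.spatial import Delaunay, QhullError

from ._constants import UNKNOWN
from .structure_io import AtomRecord, ResidueKey


class DegeneracyError(ValueError):
    """Raised when the atom set cannot be tessellated (coplanar/collinear/<4)."""


EdgeKey = tuple[ResidueKey, ResidueKey]  # canonically ordered


def edge_key(u: ResidueKey, v: ResidueKey) -> EdgeKey:
    return (u, v) if u <= v else (v, u)


def edge_type(aa_u: str, aa_v: str) -> tuple[str, str]:
    """Unordered amino-acid pair identifying an edge type (210 possibilities)."""
    return (aa_u, aa_v) if aa_u <= aa_v else (aa_v, aa_u)


@dataclass
class NodeData:
    amino_acid: str
    position: np.ndarray
    label: str = UNKNOWN


@dataclass
class EdgeData:
    edge_type: tuple[str, str]
    weight: float | None = None


@dataclass
class SurfaceGraph:
    """Weighted undirected residue graph of an antigen surface."""

    nodes: dict[ResidueKey, NodeData] = field(default_factory=dict)
    edges: dict[EdgeKey, EdgeData] = field(default_factory=dict)

    def add_edge(self, u: ResidueKey, v: ResidueKey, weight: float | None = None) -> None:
        if u == v:
            raise ValueError("self-edges are not allowed")
        et = edge_type(self.nodes[u].amino_acid, self.nodes[v].amino_acid)
        self.edges[edge_key(u, v)] = EdgeData(edge_type=et, weight=weight)

    def neighbors(self, u: ResidueKey) -> list[ResidueKey]:
        out = []
        for (a, b) in self.edges:
            if a == u:
                out.append(b)
            elif b == u:
                out.append(a)
        return out

    def subgraph_edges(self, members: set[ResidueKey]) -> dict[EdgeKey, EdgeData]:
        return {k: d for k, d in self.edges.items() if k[0] in members and k[1] in members}

    def adjacency(self, order: list[ResidueKey] | None = None, default_weight: float = 1.0):
        """Dense symmetric weight matrix plus the node order used."""
        if order is None:
            order = sorted(self.nodes)
        idx = {k: i for i, k in enumerate(order)}
        m = np.zeros((len(order), len(order)))
        for (u, v), d in self.edges.items():
            w = default_weight if d.weight is None else d.weight
            m[idx[u], idx[v]] = m[idx[v], idx[u]] = w
        return m, order

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for k, nd in self.nodes.items():
            g.add_node(k, amino_acid=nd.amino_acid, label=nd.label,
                       position=tuple(np.asarray(nd.position, dtype=float)))
        for (u, v), ed in self.edges.items():
            g.add_edge(u, v, edge_type=ed.edge_type, weight=ed.weight)
        return g

    # -- JSON round trip (reproducibility / fixtures) --------------------
    def to_json(self) -> str:
        payload = {
            "nodes": [
                {"key": list(k), "amino_acid": d.amino_acid, "label": d.label,
                 "position": [float(x) for x in np.asarray(d.position)]}
                for k, d in sorted(self.nodes.items())
            ],
            "edges": [
                {"u": list(u), "v": list(v), "edge_type": list(d.edge_type),
                 "weight": d.weight}
                for (u, v), d in sorted(self.edges.items())
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SurfaceGraph":
        payload = json.loads(text)
        g = cls()
        for n in payload["nodes"]:
            c, num, ins = n["key"]
            g.nodes[(c, int(num), ins)] = NodeData(
                amino_acid=n["amino_acid"],
                position=np.array(n["position"], dtype=float),
                label=n["label"],
            )
        for e in payload["edges"]:
            u = (e["u"][0], int(e["u"][1]), e["u"][2])
            v = (e["v"][0], int(e["v"][1]), e["v"][2])
            g.edges[edge_key(u, v)] = EdgeData(
                edge_type=tuple(e["edge_type"]), weight=e["weight"]
            )
        return g


def delaunay_atom_graph(surface: list[AtomRecord]) -> set[tuple[int, int]]:
    """Edge set (atom serial pairs) of the 3D Delaunay tessellation.

    Exactly degenerate inputs (fewer than 4 atoms, or all atoms affinely
    coplanar/collinear) raise :class:`DegeneracyError`.  A numerically
    marginal Qhull failure is retried once with a deterministic 1e-6 A joggle.
    """
    if len(surface) < 4:
        raise DegeneracyError(f"need >=4 atoms for 3D tessellation, got {len(surface)}")
    coords = np.array([a.position for a in surface], dtype=float)
    centered = coords - coords.mean(axis=0)
    # exact affine degeneracy check (coplanar/collinear input)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 3:
        raise DegeneracyError("atoms are coplanar or collinear; 3D tessellation undefined")
    serials = [a.serial for a in surface]
    try:
        tess = Delaunay(coords)
    except QhullError:
        rng = np.random.default_rng(0)
        jog = rng.normal(scale=1e-6, size=coords.shape)
        try:
            tess = Delaunay(coords + jog)
        except QhullError as exc:  # pragma: no cover - extremely rare
            raise DegeneracyError(f"tessellation failed: {exc}") from exc
    edges: set[tuple[int, int]] = set()
    for simplex in tess.simplices:
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = serials[simplex[i]], serials[simplex[j]]
                edges.add((a, b) if a < b else (b, a))
    return edges


def upgrade_to_residue_graph(
    atom_edges: set[tuple[int, int]],
    atoms: list[AtomRecord],
    max_dist: float = 6.0,
    labels: dict[ResidueKey, str] | None = None,
) -> SurfaceGraph:
    """Lift an atom-level tessellation to a residue-level surface graph.

    Intra-residue contacts are ignored; atom contacts strictly longer than
    ``max_dist`` are removed before merging; all surviving atom contacts
    between the same residue pair collapse into one edge.  Every residue with
    a surface atom appears as a node (isolated if no edge survives), with the
    centroid of its surface atoms as the representative position.
    """
    by_serial = {a.serial: a for a in atoms}
    graph = SurfaceGraph()
    groups: dict[ResidueKey, list[AtomRecord]] = {}
    for a in atoms:
        groups.setdefault(a.residue_key, []).append(a)
    for key, members in groups.items():
        pos = np.mean([m.position for m in members], axis=0)
        label = labels.get(key, UNKNOWN) if labels else UNKNOWN
        graph.nodes[key] = NodeData(amino_acid=members[0].amino_acid, position=pos, label=label)

    for sa, sb in atom_edges:
        a, b = by_serial[sa], by_serial[sb]
        if a.residue_key == b.residue_key:
            continue
        if np.linalg.norm(a.xyz - b.xyz) > max_dist:
            continue
        graph.add_edge(a.residue_key, b.residue_key)
    return graph


def build_surface_graph(
    atoms: list[AtomRecord],
    surface_serials: set[int],
    max_dist: float = 6.0,
    labels: dict[ResidueKey, str] | None = None,
) -> SurfaceGraph:
    """Convenience: tessellate the surface atoms and lift to residue level."""
    surf = [a for a in atoms if a.serial in surface_serials]
    atom_edges = delaunay_atom_graph(surf)
    return upgrade_to_residue_graph(atom_edges, surf, max_dist=max_dist, labels=labels)
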