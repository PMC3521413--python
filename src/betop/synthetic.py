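"""Seeded synthetic antibody-antigen complexes and planted-partition graphs.

The generator emulates the geometry and statistics the predictor relies on,
with known ground truth:

* an antigen-like shell of pseudo-residues (3-5 dummy heavy atoms each) on a
  jittered sphere, so every residue is solvent-exposed;
* one or two contiguous geodesic caps designated as epitope patches, sized by
  ``epitope_fraction`` (default 0.12, matching the roughly 15:120
  epitope:non-epitope residue imbalance of real antigen surfaces);
* epitope residue types drawn from a composition enriched for configurable
  pair/triple patterns (defaults echo the polar QQ-centred triangles that
  favour real epitopes), non-epitope types uniform;
* a dummy antibody chain whose atoms sit within 4 A of every epitope residue
  and strictly beyond 4 A of every non-epitope residue, so contact labeling
  provably recovers the planted truth.

Nothing about side-chain geometry or energetics is physical; the shells test
the pipeline's statistics and graph machinery, not forcefield realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._constants import AMINO_ACIDS, ONE_TO_THREE
from .structure_io import ResidueKey
from .surface_graph import NodeData, SurfaceGraph

_ATOM_NAMES = ("CA", "CB", "CG", "CD", "CE")

DEFAULT_ENRICHED_PAIRS: tuple[tuple[str, str], ...] = (("Q", "Q"), ("D", "D"))
DEFAULT_ENRICHED_TRIPLES: tuple[tuple[str, str, str], ...] = (
    ("Q", "Q", "R"), ("Q", "Q", "S"), ("D", "D", "Y"),
)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic complex."""

    n_residues: int = 135
    epitope_fraction: float = 0.12   # per patch
    n_patches: int = 1
    enriched_pairs: tuple = DEFAULT_ENRICHED_PAIRS
    enriched_triples: tuple = DEFAULT_ENRICHED_TRIPLES
    enrichment_odds: float = 30.0
    noise_sd: float = 0.3            # A, jitter on residue centers
    radius: float = 18.0             # A, shell radius
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.epitope_fraction < 1.0:
            raise ValueError("epitope_fraction must be in (0, 1)")
        if self.n_patches not in (1, 2):
            raise ValueError("n_patches must be 1 or 2")

    def enriched_types(self) -> set[str]:
        types: set[str] = set()
        for pat in tuple(self.enriched_pairs) + tuple(self.enriched_triples):
            types.update(pat)
        return types


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resnum: int, xyz: np.ndarray, element: str) -> str:
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resnum:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def generate_complex(spec: SyntheticSpec) -> tuple[str, dict]:
    """Write one synthetic complex as PDB text plus a truth record.

    Returns ``(pdb_text, truth)`` where truth holds the planted epitope
    patches (lists of residue keys), chain roles and the generator seed.
    Raises if the requested patches would overlap.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    dirs = _fibonacci_sphere(n)
    # decorrelate the cap location from the lattice through a random rotation
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    dirs = dirs @ q
    centers = spec.radius * dirs + rng.normal(scale=spec.noise_sd, size=(n, 3))

    n_epi = max(3, round(spec.epitope_fraction * n))
    cap_dirs = [dirs[0]] if spec.n_patches == 1 else [dirs[0], -dirs[0]]
    patches: list[list[int]] = []
    taken: set[int] = set()
    for cd in cap_dirs:
        order = np.argsort(-(dirs @ cd))  # nearest on the sphere first
        members = [int(i) for i in order[:n_epi]]
        if taken & set(members):
            raise ValueError("epitope patches overlap; reduce epitope_fraction")
        taken.update(members)
        patches.append(members)
    epi_set = set(taken)

    # residue types: enriched composition inside patches, uniform background
    weights = np.ones(len(AMINO_ACIDS))
    enriched = spec.enriched_types()
    for i, aa in enumerate(AMINO_ACIDS):
        if aa in enriched:
            weights[i] *= spec.enrichment_odds
    weights /= weights.sum()
    aa_arr = np.array(AMINO_ACIDS)
    types = [
        str(rng.choice(aa_arr, p=weights)) if i in epi_set else str(rng.choice(aa_arr))
        for i in range(n)
    ]

    # 3-5 dummy heavy atoms per residue, offsets clipped to stay compact
    atoms: list[tuple[int, np.ndarray]] = []  # (residue index, xyz)
    for i in range(n):
        k = int(rng.integers(3, 6))
        offs = rng.normal(scale=1.0, size=(k, 3))
        norms = np.linalg.norm(offs, axis=1, keepdims=True)
        offs = np.where(norms > 1.6, offs * 1.6 / norms, offs)
        for o in offs:
            atoms.append((i, centers[i] + o))

    # antibody: two probe atoms radially above the outermost atom of each
    # epitope residue, at 3.5 and 3.9 A (inside the 4 A labeling cutoff)
    ab_atoms: list[np.ndarray] = []
    for i in sorted(epi_set):
        res_atoms = [xyz for j, xyz in atoms if j == i]
        anchor = max(res_atoms, key=lambda p: float(np.linalg.norm(p)))
        u = anchor / np.linalg.norm(anchor)
        ab_atoms.append(anchor + 3.5 * u)
        ab_atoms.append(anchor + 3.9 * u)

    # repair: pull any non-epitope atom that strays within the labeling
    # cutoff of an antibody probe radially inward until it clears 4.3 A
    ab_arr = np.array(ab_atoms)
    for idx, (i, xyz) in enumerate(atoms):
        if i in epi_set:
            continue
        guard = 0
        while np.min(np.linalg.norm(ab_arr - xyz, axis=1)) <= 4.3 and guard < 60:
            xyz = 0.97 * xyz
            guard += 1
        atoms[idx] = (i, xyz)
    ag_non = np.array([xyz for i, xyz in atoms if i not in epi_set])
    if ag_non.size:
        from scipy.spatial import cKDTree
        d, _ = cKDTree(ab_arr).query(ag_non, k=1)
        assert d.min() > 4.0, "synthetic geometry violates the labeling margin"

    lines = ["REMARK   2 RESOLUTION.    2.00 ANGSTROMS."]
    serial = 1
    res_keys: list[ResidueKey] = []
    for i in range(n):
        resname = ONE_TO_THREE[types[i]]
        res_atoms = [xyz for j, xyz in atoms if j == i]
        for a_i, xyz in enumerate(res_atoms):
            lines.append(_pdb_atom_line(serial, _ATOM_NAMES[a_i], resname,
                                        "A", i + 1, xyz, "C"))
            serial += 1
        res_keys.append(("A", i + 1, ""))
    lines.append("TER")
    for b_i, xyz in enumerate(ab_atoms):
        lines.append(_pdb_atom_line(serial, "CA", "GLY", "B", b_i + 1, xyz, "C"))
        serial += 1
    lines.append("TER")
    lines.append("END")

    truth = {
        "antigen_chains": ["A"],
        "antibody_chains": ["B"],
        "epitopes": [[list(res_keys[i]) for i in patch] for patch in patches],
        "seed": spec.seed,
        "n_residues": n,
    }
    return "\n".join(lines) + "\n", truth


def generate_weighted_graph(
    n_blocks: int = 2,
    block_size: int = 8,
    intra_weight: float = 1.0,
    inter_weight: float = 0.01,
    inter_prob: float = 0.3,
    seed: int = 0,
) -> tuple[SurfaceGraph, dict[ResidueKey, int]]:
    """Planted-partition graph: dense heavy blocks, sparse light cross edges.

    Returns the graph and the planted block membership per node.
    """
    if not intra_weight > inter_weight > 0:
        raise ValueError("require intra_weight > inter_weight > 0")
    rng = np.random.default_rng(seed)
    g = SurfaceGraph()
    membership: dict[ResidueKey, int] = {}
    keys: list[list[ResidueKey]] = []
    node_id = 1
    for b in range(n_blocks):
        block: list[ResidueKey] = []
        for _ in range(block_size):
            key = ("A", node_id, "")
            aa = str(rng.choice(np.array(AMINO_ACIDS)))
            g.nodes[key] = NodeData(amino_acid=aa, position=rng.normal(size=3))
            membership[key] = b
            block.append(key)
            node_id += 1
        keys.append(block)
    for block in keys:
        for i, u in enumerate(block):
            for v in block[i + 1:]:
                g.add_edge(u, v, weight=intra_weight)
    for b1 in range(n_blocks):
        for b2 in range(b1 + 1, n_blocks):
            for u in keys[b1]:
                for v in keys[b2]:
                    if rng.random() < inter_prob:
                        g.add_edge(u, v, weight=inter_weight)
    return g, membership


def simulate_dataset(
    out_dir: str | Path,
    n_complexes: int = 20,
    seed: int = 0,
    n_patches: int = 1,
    spec_kwargs: dict | None = None,
) -> list[Path]:
    """Write a directory of synthetic PDB files + truth and roles manifests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    roles = {}
    for i in range(n_complexes):
        spec = SyntheticSpec(seed=seed + i, n_patches=n_patches,
                             **(spec_kwargs or {}))
        pdb_text, truth = generate_complex(spec)
        name = f"synth_{seed + i:04d}"
        pdb_path = out / f"{name}.pdb"
        pdb_path.write_text(pdb_text)
        (out / f"{name}.truth.json").write_text(json.dumps(truth, indent=1))
        roles[name] = {"antigen_chains": truth["antigen_chains"],
                       "antibody_chains": truth["antibody_chains"]}
        paths.append(pdb_path)
    (out / "roles.json").write_text(json.dumps(roles, indent=1))
    return paths
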