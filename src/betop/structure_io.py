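"""Structure input: PDB parsing, solvent accessibility, surface atoms,
epitope labeling by antibody contact, and training-set curation.

An antibody-antigen complex is held as a flat list of heavy-atom records with
user-supplied chain roles.  Accessibility is computed with the Shrake-Rupley
sphere-sampling algorithm on a fixed deterministic point set, so values are
reproducible bit-for-bit; they track NACCESS closely but not exactly (different
point sets and radii tables).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._constants import DEFAULT_VDW_RADIUS, THREE_TO_ONE, VDW_RADII

logger = logging.getLogger(__name__)

ResidueKey = tuple[str, int, str]  # (chain_id, residue_number, insertion_code)


class StructureError(ValueError):
    """Raised for unusable structure input (missing chains, no atoms...)."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a standard residue."""

    serial: int
    atom_name: str
    element: str
    residue_key: ResidueKey
    amino_acid: str  # one-letter code
    position: tuple[float, float, float]
    vdw_radius: float

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class ComplexRecord:
    """An antibody-antigen complex (or a bare antigen: empty antibody role)."""

    antigen_chains: list[str]
    antibody_chains: list[str]
    atoms: list[AtomRecord]
    resolution: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.antigen_chains) & set(self.antibody_chains)
        if overlap:
            raise StructureError(f"chains in both roles: {sorted(overlap)}")

    def antigen_atoms(self) -> list[AtomRecord]:
        keep = set(self.antigen_chains)
        return [a for a in self.atoms if a.residue_key[0] in keep]

    def antibody_atoms(self) -> list[AtomRecord]:
        keep = set(self.antibody_chains)
        return [a for a in self.atoms if a.residue_key[0] in keep]

    def chain_sequences(self) -> dict[str, str]:
        """One-letter sequence per chain, in residue order of appearance."""
        seqs: dict[str, list[str]] = {}
        seen: set[ResidueKey] = set()
        for a in self.atoms:
            if a.residue_key in seen:
                continue
            seen.add(a.residue_key)
            seqs.setdefault(a.residue_key[0], []).append(a.amino_acid)
        return {c: "".join(s) for c, s in seqs.items()}


@dataclass
class AsaTable:
    """Per-atom accessible surface area in Angstrom^2."""

    areas: dict[int, float]  # atom serial -> ASA
    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        bad = [s for s, v in self.areas.items() if v < 0]
        if bad:
            raise ValueError(f"negative ASA for serials {bad[:5]}")


def parse_structure(
    pdb_text: str,
    antigen_chains: list[str],
    antibody_chains: list[str],
    name: str = "",
) -> ComplexRecord:
    """Parse PDB text into a heavy-atom :class:`ComplexRecord`.

    Keeps the highest-occupancy alternate location, drops hydrogens, waters
    and non-standard residues (with a logged warning), uses the first model
    only.  Chain roles must name chains actually present in the file.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(name or "complex", io.StringIO(pdb_text))
    resolution = structure.header.get("resolution")

    models = list(structure)
    if not models:
        raise StructureError("no ATOM records found")
    model = models[0]

    present = {chain.id for chain in model}
    for cid in list(antigen_chains) + list(antibody_chains):
        if cid not in present:
            raise StructureError(f"chain {cid!r} not present in structure")

    wanted = set(antigen_chains) | set(antibody_chains)
    atoms: list[AtomRecord] = []
    dropped: set[str] = set()
    for chain in model:
        if chain.id not in wanted:
            continue
        for residue in chain:
            hetflag, resnum, icode = residue.id
            resname = residue.get_resname().strip()
            if hetflag.strip() or resname not in THREE_TO_ONE:
                if resname not in ("HOH", "WAT"):
                    dropped.add(resname)
                continue
            for atom in residue:  # disordered atoms yield highest-occupancy child
                element = (atom.element or "").strip().upper()
                if element in ("H", "D", ""):
                    continue
                x, y, z = (float(v) for v in atom.coord)
                atoms.append(
                    AtomRecord(
                        serial=int(atom.get_serial_number()),
                        atom_name=atom.get_name(),
                        element=element,
                        residue_key=(chain.id, int(resnum), icode.strip()),
                        amino_acid=THREE_TO_ONE[resname],
                        position=(x, y, z),
                        vdw_radius=VDW_RADII.get(element, DEFAULT_VDW_RADIUS),
                    )
                )
    if dropped:
        logger.warning("dropped non-standard residues: %s", sorted(dropped))
    if not atoms:
        raise StructureError("no usable ATOM records in requested chains")
    return ComplexRecord(
        antigen_chains=list(antigen_chains),
        antibody_chains=list(antibody_chains),
        atoms=atoms,
        resolution=resolution,
        name=name,
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-section spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_asa(
    atoms: list[AtomRecord],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> AsaTable:
    """Shrake-Rupley accessible surface area, one value per atom.

    Each atom is inflated by the probe radius and sampled with ``n_points``
    test points; a point is accessible when it lies outside every neighbour's
    inflated sphere.  Deterministic for a fixed point count.
    """
    if not atoms:
        raise StructureError("compute_asa requires at least one atom")
    coords = np.array([a.position for a in atoms], dtype=float)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float) + probe_radius
    pts = _sphere_points(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas: dict[int, float] = {}
    for i, atom in enumerate(atoms):
        ri = radii[i]
        neigh = tree.query_ball_point(coords[i], ri + max_r)
        neigh = [j for j in neigh if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + radii[j]]
        sample = coords[i] + ri * pts  # (n_points, 3)
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", sample - coords[j], sample - coords[j])
            accessible &= d2 > radii[j] ** 2
        areas[atom.serial] = 4.0 * np.pi * ri**2 * accessible.mean()
    return AsaTable(areas=areas, probe_radius=probe_radius)


def surface_atoms(asa: AsaTable, threshold: float = 10.0) -> set[int]:
    """Atom serials with ASA >= threshold (inclusive)."""
    return {serial for serial, area in asa.areas.items() if area >= threshold}


def label_epitope_residues(
    complex_record: ComplexRecord, cutoff: float = 4.0
) -> set[ResidueKey]:
    """Antigen residues with any heavy atom within ``cutoff`` (inclusive) of
    any antibody heavy atom."""
    ag = complex_record.antigen_atoms()
    ab = complex_record.antibody_atoms()
    if not ab:
        raise StructureError("cannot label epitopes: antibody role is empty")
    if not ag:
        raise StructureError("cannot label epitopes: antigen role is empty")
    ab_tree = cKDTree(np.array([a.position for a in ab]))
    ag_coords = np.array([a.position for a in ag])
    dists, _ = ab_tree.query(ag_coords, k=1)
    return {a.residue_key for a, d in zip(ag, dists) if d <= cutoff}


def _pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matched identical positions / shorter length.

    Scoring: match +1, mismatch 0, linear gap -1.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_a, seq_b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        sa, sb = seq_a[a0:a1], seq_b[b0:b1]
        matches += sum(x == y for x, y in zip(sa, sb))
    return matches / min(len(seq_a), len(seq_b))


def curate(
    complexes: list[ComplexRecord],
    min_chain_len: int = 30,
    max_resolution: float = 3.0,
    identity_threshold: float = 0.80,
) -> list[ComplexRecord]:
    """Apply training-set quality filters.

    Drops complexes with any modeled chain shorter than ``min_chain_len`` or
    X-ray resolution >= ``max_resolution`` (a missing resolution passes).
    Then removes antigen chains whose pairwise identity with an already
    retained antigen chain exceeds ``identity_threshold`` (first seen wins);
    a complex left without antigen chains is dropped.
    """
    retained_seqs: list[str] = []
    out: list[ComplexRecord] = []
    for cx in complexes:
        seqs = cx.chain_sequences()
        if any(len(s) < min_chain_len for s in seqs.values()):
            logger.info("curate: %s dropped (chain shorter than %d)", cx.name, min_chain_len)
            continue
        if cx.resolution is not None and cx.resolution >= max_resolution:
            logger.info("curate: %s dropped (resolution %.2f)", cx.name, cx.resolution)
            continue
        keep_chains: list[str] = []
        for cid in cx.antigen_chains:
            seq = seqs.get(cid, "")
            if any(_pairwise_identity(seq, prev) > identity_threshold for prev in retained_seqs):
                logger.info("curate: %s chain %s dropped as duplicate", cx.name, cid)
                continue
            keep_chains.append(cid)
        if not keep_chains:
            continue
        for cid in keep_chains:
            retained_seqs.append(seqs[cid])
        if keep_chains != cx.antigen_chains:
            keep = set(keep_chains) | set(cx.antibody_chains)
            cx = ComplexRecord(
                antigen_chains=keep_chains,
                antibody_chains=list(cx.antibody_chains),
                atoms=[a for a in cx.atoms if a.residue_key[0] in keep],
                resolution=cx.resolution,
                name=cx.name,
            )
        out.append(cx)
    return out
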