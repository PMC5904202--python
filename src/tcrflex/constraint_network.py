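"""All-atom constraint network: covalent bonds, scored polar contacts, tethers.

Rigidity analysis treats the protein as a body-bar framework, so the first
step is to enumerate the constraints acting between heavy atoms:

* covalent bonds, from per-residue templates plus peptide and disulfide
  linkages; double/partial-double bonds (peptide, carbonyl, carboxylate,
  guanidinium, amide, aromatic-ring bonds) are *locked* — they carry no
  rotational freedom;
* hydrogen bonds and salt bridges, scored from heavy-atom geometry on a
  0 to −10 kcal/mol scale and later filtered at an energy cutoff E_cut
  (default −3.0 kcal/mol, boundary inclusive);
* hydrophobic tethers between carbon/sulfur atoms of different residues
  whose separation is below the van der Waals sum plus a small gap.

Deposited X-ray models carry no hydrogens, so donor geometry is judged via
the donor's covalent antecedent: a linear D-H···A arrangement corresponds to
an antecedent-donor-acceptor angle near the donor's ~120° bonding angle, and
the angular factor penalises the deviation from that ideal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_model import Atom, Structure

__all__ = [
    "Edge",
    "NetworkParams",
    "ConstraintNetwork",
    "infer_covalent_bonds",
    "score_hydrogen_bond",
    "detect_hydrogen_bonds",
    "detect_hydrophobic_tethers",
    "apply_energy_cutoff",
    "build_network",
]

EdgeKind = Literal["covalent_single", "covalent_locked", "hbond", "tether"]


@dataclass(frozen=True)
class Edge:
    """A typed constraint between two atoms (indices into network atom list)."""

    i: int
    j: int
    kind: EdgeKind
    energy: float | None = None

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-edge")
        if self.kind == "hbond":
            if self.energy is None or not -10.0 <= self.energy <= 0.0:
                raise ValueError(f"hbond energy {self.energy} outside [-10, 0]")
        elif self.energy is not None:
            raise ValueError(f"{self.kind} edge must not carry an energy")

    @property
    def pair(self) -> tuple[int, int]:
        return (min(self.i, self.j), max(self.i, self.j))


@dataclass(frozen=True)
class NetworkParams:
    """Tunables of network construction (defaults follow the analysis setup)."""

    e_cut: float = -3.0
    hbond_distance_cutoff: float = 3.5
    tether_gap: float = 0.25
    vdw_radii: tuple[tuple[str, float], ...] = (
        ("C", 1.70), ("S", 1.80), ("N", 1.55), ("O", 1.52),
    )

    def __post_init__(self) -> None:
        if self.e_cut > 0:
            raise ValueError("e_cut must be <= 0")

    def vdw(self, element: str) -> float:
        for el, r in self.vdw_radii:
            if el == element.upper():
                return r
        return 1.70


@dataclass
class ConstraintNetwork:
    """Atoms as vertices plus the typed constraint edges between them."""

    atoms: list[Atom]
    edges: list[Edge]
    params: NetworkParams
    _adjacency: dict[int, set[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for e in self.edges:
            if not (0 <= e.i < len(self.atoms) and 0 <= e.j < len(self.atoms)):
                raise ValueError(f"edge endpoint out of range: {e}")
        for e in self.covalent_edges():
            self._adjacency.setdefault(e.i, set()).add(e.j)
            self._adjacency.setdefault(e.j, set()).add(e.i)

    def covalent_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.kind.startswith("covalent")]

    def covalent_neighbors(self, i: int) -> set[int]:
        return self._adjacency.get(i, set())

    def bonded_within_two(self, i: int, j: int) -> bool:
        """True when i and j are 1-2 or 1-3 covalent neighbours."""
        ni = self.covalent_neighbors(i)
        if j in ni:
            return True
        return bool(ni & self.covalent_neighbors(j))

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def index_of(self) -> dict[tuple, int]:
        return {a.key: idx for idx, a in enumerate(self.atoms)}


# ---------------------------------------------------------------------------
# Covalent templates

_BACKBONE = [("N", "CA", False), ("CA", "C", False), ("C", "O", True), ("C", "OXT", True)]

# side-chain bonds per residue; True marks non-rotatable (locked) bonds
_SIDE_CHAINS: dict[str, list[tuple[str, str, bool]]] = {
    "GLY": [],
    "ALA": [("CA", "CB", False)],
    "SER": [("CA", "CB", False), ("CB", "OG", False)],
    "CYS": [("CA", "CB", False), ("CB", "SG", False)],
    "THR": [("CA", "CB", False), ("CB", "OG1", False), ("CB", "CG2", False)],
    "VAL": [("CA", "CB", False), ("CB", "CG1", False), ("CB", "CG2", False)],
    "LEU": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", False), ("CG", "CD2", False)],
    "ILE": [("CA", "CB", False), ("CB", "CG1", False), ("CB", "CG2", False), ("CG1", "CD1", False)],
    "MET": [("CA", "CB", False), ("CB", "CG", False), ("CG", "SD", False), ("SD", "CE", False)],
    "MSE": [("CA", "CB", False), ("CB", "CG", False), ("CG", "SE", False), ("SE", "CE", False)],
    "PRO": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False), ("CD", "N", False)],
    "PHE": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", True), ("CG", "CD2", True),
            ("CD1", "CE1", True), ("CD2", "CE2", True), ("CE1", "CZ", True), ("CE2", "CZ", True)],
    "TYR": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", True), ("CG", "CD2", True),
            ("CD1", "CE1", True), ("CD2", "CE2", True), ("CE1", "CZ", True), ("CE2", "CZ", True),
            ("CZ", "OH", False)],
    "TRP": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", True), ("CG", "CD2", True),
            ("CD1", "NE1", True), ("NE1", "CE2", True), ("CD2", "CE2", True),
            ("CD2", "CE3", True), ("CE3", "CZ3", True), ("CZ3", "CH2", True),
            ("CH2", "CZ2", True), ("CZ2", "CE2", True)],
    "HIS": [("CA", "CB", False), ("CB", "CG", False), ("CG", "ND1", True), ("CG", "CD2", True),
            ("ND1", "CE1", True), ("CD2", "NE2", True), ("CE1", "NE2", True)],
    "ASP": [("CA", "CB", False), ("CB", "CG", False), ("CG", "OD1", True), ("CG", "OD2", True)],
    "GLU": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "OE1", True), ("CD", "OE2", True)],
    "ASN": [("CA", "CB", False), ("CB", "CG", False), ("CG", "OD1", True), ("CG", "ND2", True)],
    "GLN": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "OE1", True), ("CD", "NE2", True)],
    "LYS": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "CE", False), ("CE", "NZ", False)],
    "ARG": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False), ("CD", "NE", False),
            ("NE", "CZ", True), ("CZ", "NH1", True), ("CZ", "NH2", True)],
}

PEPTIDE_BOND_MAX = 1.7
DISULFIDE_MAX = 2.3

# heavy-atom H-bond chemistry (PRO backbone N carries no hydrogen)
_DONOR_NAMES: dict[str, set[str]] = {
    "*": {"N"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "TRP": {"NE1"}, "HIS": {"ND1", "NE2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"},
}
_ACCEPTOR_NAMES: dict[str, set[str]] = {
    "*": {"O", "OXT"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"}, "GLN": {"OE1"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "HIS": {"ND1", "NE2"},
    "MET": {"SD"}, "MSE": {"SE"},
}
_CHARGED_DONORS = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"), ("LYS", "NZ")}
_CHARGED_ACCEPTORS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}


def _is_donor(atom: Atom) -> bool:
    if atom.res_name == "PRO" and atom.name == "N":
        return False
    return (atom.name in _DONOR_NAMES["*"]
            or atom.name in _DONOR_NAMES.get(atom.res_name, set()))


def _is_acceptor(atom: Atom) -> bool:
    return (atom.name in _ACCEPTOR_NAMES["*"]
            or atom.name in _ACCEPTOR_NAMES.get(atom.res_name, set()))


def _heavy_atoms(structure: Structure) -> list[Atom]:
    return [a for a in structure.protein_only().atoms() if a.element.upper() not in ("H", "D")]


def infer_covalent_bonds(
    structure: Structure, atoms: Sequence[Atom] | None = None
) -> tuple[list[Atom], list[Edge]]:
    """Template-derived covalent bonds plus peptide and disulfide linkages.

    Returns the heavy-atom list (the network vertex set) and the covalent
    edges over it.  A missing peptide bond between consecutive residues of a
    chain raises a warning, not an error (chain breaks are common in real
    models).
    """
    if atoms is None:
        atoms = _heavy_atoms(structure)
    index = {a.key: i for i, a in enumerate(atoms)}
    edges: list[Edge] = []
    seen: set[tuple[int, int]] = set()

    def add(i: int, j: int, kind: EdgeKind) -> None:
        pair = (min(i, j), max(i, j))
        if pair not in seen:
            seen.add(pair)
            edges.append(Edge(i, j, kind))

    by_residue: dict[tuple[str, int, str], dict[str, int]] = {}
    residue_order: list[tuple[str, int, str]] = []
    res_names: dict[tuple[str, int, str], str] = {}
    for i, a in enumerate(atoms):
        rkey = (a.chain_id, a.res_seq, a.insertion_code)
        if rkey not in by_residue:
            by_residue[rkey] = {}
            residue_order.append(rkey)
            res_names[rkey] = a.res_name
        by_residue[rkey][a.name] = i

    for rkey in residue_order:
        res_name = res_names[rkey]
        if res_name not in _SIDE_CHAINS:
            raise ValueError(f"no covalent template for residue {res_name!r} at {rkey}")
        names = by_residue[rkey]
        for a_name, b_name, locked in _BACKBONE + _SIDE_CHAINS[res_name]:
            if a_name in names and b_name in names:
                add(names[a_name], names[b_name],
                    "covalent_locked" if locked else "covalent_single")

    # peptide bonds: consecutive residues of the same chain, C(i)-N(i+1)
    for prev, curr in zip(residue_order, residue_order[1:]):
        if prev[0] != curr[0]:
            continue
        ci = by_residue[prev].get("C")
        ni = by_residue[curr].get("N")
        if ci is None or ni is None:
            continue
        d = np.linalg.norm(atoms[ci].coords - atoms[ni].coords)
        if d < PEPTIDE_BOND_MAX:
            add(ci, ni, "covalent_locked")
        else:
            warnings.warn(
                f"chain {prev[0]}: no peptide bond between residues {prev[1]} and "
                f"{curr[1]} (C-N distance {d:.2f} A)", stacklevel=2,
            )

    # disulfides
    sg = [i for i, a in enumerate(atoms) if a.res_name == "CYS" and a.name == "SG"]
    for ii, i in enumerate(sg):
        for j in sg[ii + 1:]:
            if np.linalg.norm(atoms[i].coords - atoms[j].coords) < DISULFIDE_MAX:
                add(i, j, "covalent_single")
    return list(atoms), edges


# ---------------------------------------------------------------------------
# Hydrogen bonds

HBOND_D0 = 2.9
SALT_BRIDGE_D0 = 3.0
_WELL_HALF_WIDTH = 0.6
_IDEAL_ANTECEDENT_ANGLE = 120.0
_MAX_ANGLE_DEVIATION = 60.0


def score_hydrogen_bond(
    donor: Atom,
    acceptor: Atom,
    donor_antecedent: Atom,
    acceptor_antecedent: Atom | None = None,
    salt_bridge: bool = False,
) -> float | None:
    """Geometric energy of a polar contact, in [-10, 0] kcal/mol, or None.

    energy = -10 · f_dist(d) · f_ang(θ) with a clamped parabolic distance
    well centred at 2.9 Å (3.0 Å for salt bridges) and f_ang = cos²θ′, where
    θ′ is the deviation of the antecedent-donor-acceptor angle from the 120°
    ideal of a linear D-H···A arrangement.  Either factor reaching zero
    (d beyond the well, deviation beyond 60°) means no interaction.  Salt
    bridges get a 20% depth bonus, capped at the -10 floor.
    """
    if donor_antecedent is None:
        raise ValueError(f"donor {donor.key} has no covalent antecedent")
    d = float(np.linalg.norm(donor.coords - acceptor.coords))
    d0 = SALT_BRIDGE_D0 if salt_bridge else HBOND_D0
    f_dist = 1.0 - ((d - d0) / _WELL_HALF_WIDTH) ** 2
    if f_dist <= 0.0:
        return None
    v1 = donor_antecedent.coords - donor.coords
    v2 = acceptor.coords - donor.coords
    cos_theta = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    theta = np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
    deviation = abs(theta - _IDEAL_ANTECEDENT_ANGLE)
    if deviation >= _MAX_ANGLE_DEVIATION:
        return None
    f_ang = np.cos(np.radians(deviation)) ** 2
    energy = -10.0 * f_dist * f_ang
    if salt_bridge:
        energy = max(energy * 1.2, -10.0)
    return float(energy)


def detect_hydrogen_bonds(
    structure: Structure,
    params: NetworkParams | None = None,
    atoms: Sequence[Atom] | None = None,
    covalent_edges: Sequence[Edge] | None = None,
) -> list[Edge]:
    """Score every donor-acceptor pair within the distance cutoff.

    Pairs that are covalently bonded, 1-3 bonded, or within the same residue
    are excluded.  The donor antecedent giving the most favourable energy is
    used when the donor has several covalent neighbours.
    """
    params = params or NetworkParams()
    if atoms is None or covalent_edges is None:
        atoms, covalent_edges = infer_covalent_bonds(structure)
    net = ConstraintNetwork(list(atoms), list(covalent_edges), params)
    donors = [i for i, a in enumerate(atoms) if _is_donor(a)]
    acceptors = [i for i, a in enumerate(atoms) if _is_acceptor(a)]
    if not donors or not acceptors:
        return []
    xyz = net.coords_array()
    acc_tree = cKDTree(xyz[acceptors])
    edges: list[Edge] = []
    seen: set[tuple[int, int]] = set()
    for di in donors:
        datom = atoms[di]
        antecedents = sorted(net.covalent_neighbors(di))
        if not antecedents:
            continue
        for k in acc_tree.query_ball_point(xyz[di], max(params.hbond_distance_cutoff, 3.6 + 0.1)):
            ai = acceptors[k]
            if ai == di:
                continue
            aatom = atoms[ai]
            if (datom.chain_id, datom.res_seq, datom.insertion_code) == (
                aatom.chain_id, aatom.res_seq, aatom.insertion_code
            ):
                continue
            if net.bonded_within_two(di, ai):
                continue
            pair = (min(di, ai), max(di, ai))
            if pair in seen:
                continue
            salt = ((datom.res_name, datom.name) in _CHARGED_DONORS
                    and (aatom.res_name, aatom.name) in _CHARGED_ACCEPTORS)
            best: float | None = None
            for anti in antecedents:
                e = score_hydrogen_bond(datom, aatom, atoms[anti], salt_bridge=salt)
                if e is not None and (best is None or e < best):
                    best = e
            if best is not None:
                seen.add(pair)
                edges.append(Edge(di, ai, "hbond", energy=best))
    return edges


def detect_hydrophobic_tethers(
    structure: Structure,
    params: NetworkParams | None = None,
    atoms: Sequence[Atom] | None = None,
    covalent_edges: Sequence[Edge] | None = None,
) -> list[Edge]:
    """Carbon/sulfur pairs from different residues within vdW sum + gap."""
    params = params or NetworkParams()
    if atoms is None or covalent_edges is None:
        atoms, covalent_edges = infer_covalent_bonds(structure)
    net = ConstraintNetwork(list(atoms), list(covalent_edges), params)
    hydrophobic = [i for i, a in enumerate(atoms) if a.element.upper() in ("C", "S", "SE")]
    xyz = net.coords_array()
    if not hydrophobic:
        return []
    tree = cKDTree(xyz[hydrophobic])
    max_reach = 2 * 1.80 + params.tether_gap
    edges: list[Edge] = []
    for ka, kb in sorted(tree.query_pairs(max_reach)):
        i, j = hydrophobic[ka], hydrophobic[kb]
        ai, aj = atoms[i], atoms[j]
        if (ai.chain_id, ai.res_seq, ai.insertion_code) == (aj.chain_id, aj.res_seq, aj.insertion_code):
            continue
        if net.bonded_within_two(i, j):
            continue
        cutoff = params.vdw(ai.element) + params.vdw(aj.element) + params.tether_gap
        if np.linalg.norm(xyz[i] - xyz[j]) < cutoff:
            edges.append(Edge(i, j, "tether"))
    return edges


def apply_energy_cutoff(network: ConstraintNetwork, e_cut: float) -> ConstraintNetwork:
    """Keep hbond edges with energy <= e_cut; other kinds pass through."""
    if e_cut > 0:
        raise ValueError("e_cut must be <= 0")
    kept = [e for e in network.edges
            if e.kind != "hbond" or (e.energy is not None and e.energy <= e_cut)]
    return ConstraintNetwork(network.atoms, kept, replace(network.params, e_cut=e_cut))


def build_network(structure: Structure, params: NetworkParams | None = None) -> ConstraintNetwork:
    """Full constraint network before energy filtering."""
    params = params or NetworkParams()
    atoms, covalent = infer_covalent_bonds(structure)
    hbonds = detect_hydrogen_bonds(structure, params, atoms, covalent)
    tethers = detect_hydrophobic_tethers(structure, params, atoms, covalent)
    return ConstraintNetwork(atoms, covalent + hbonds + tethers, params)
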