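"""Conformational comparison of crystal structures and lattice-contact analysis.

Two questions drive this module.  First, how much do the surface loops of the
same protein move between independently solved crystal structures?  That is
answered by least-squares superposition on a framework selection followed by
per-residue Cα displacement profiles and pairwise loop-shift matrices.
Second, could those movements be suppressed (or permitted) by crystal
packing?  For that we rebuild the lattice environment from the unit cell and
space-group operators and flag every atom pair closer than a cutoff
(default 4.0 Å, strict inequality) between the asymmetric unit and any
symmetry/lattice image.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .structure_model import LoopDefinition, Structure, extract_calpha

__all__ = [
    "SuperpositionResult",
    "DisplacementProfile",
    "ContactRecord",
    "SymmetryImage",
    "kabsch_superpose",
    "per_residue_displacement",
    "pairwise_loop_shift_matrix",
    "space_group_operators",
    "parse_operator_triplets",
    "apply_symmetry",
    "find_crystal_contacts",
    "loop_contact_freedom",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Least-squares rigid-body fit: y ≈ rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class DisplacementProfile:
    """Per-residue Cα displacement after framework superposition."""

    entries: list[tuple[int, float]]

    @property
    def max_displacement(self) -> float:
        return max((d for _, d in self.entries), default=0.0)

    @property
    def argmax_residue(self) -> int | None:
        if not self.entries:
            return None
        return max(self.entries, key=lambda e: e[1])[0]


@dataclass(frozen=True)
class ContactRecord:
    """A lattice contact between an asymmetric-unit atom and a symmetry image."""

    atom_a: tuple[str, int, str, str]
    atom_b: tuple[str, int, str, str]
    operator_index: int
    lattice_translation: tuple[int, int, int]
    distance: float


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares proper-rotation fit of ``mobile`` onto ``reference``.

    Returns the rotation/translation minimising the RMSD between the
    transformed mobile set and the reference set (Kabsch algorithm; the SVD
    determinant correction guarantees det(R) = +1).
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {x.shape} vs {y.shape}")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cov = xc.T @ yc
    if np.linalg.matrix_rank(cov, tol=1e-10) < 2:
        raise ValueError("degenerate (rank < 2) point sets")
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = y.mean(axis=0) - rotation @ x.mean(axis=0)
    fitted = x @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation, translation, rmsd, n)


def _ca_map(structure: Structure, chain_id: str) -> dict[int, np.ndarray]:
    trace = extract_calpha(structure, chain_id)
    return {seq: xyz for seq, xyz in trace.entries}


def per_residue_displacement(
    a: Structure,
    b: Structure,
    fit_selection: Iterable[int],
    measure_selection: Iterable[int],
    chain_id: str,
) -> DisplacementProfile:
    """Superpose ``b`` onto ``a`` on the fit residues' Cα, then measure.

    Both selections are author-numbered residue sets on ``chain_id``;
    residues absent from either structure are dropped from the intersection.
    """
    ca_a = _ca_map(a, chain_id)
    ca_b = _ca_map(b, chain_id)
    fit = sorted(set(fit_selection) & ca_a.keys() & ca_b.keys())
    measure = sorted(set(measure_selection) & ca_a.keys() & ca_b.keys())
    if not fit or not measure:
        raise ValueError("empty selection after intersecting with shared Cα residues")
    sup = kabsch_superpose(
        np.array([ca_b[r] for r in fit]), np.array([ca_a[r] for r in fit])
    )
    entries = []
    for r in measure:
        moved = sup.transform(ca_b[r][None, :])[0]
        entries.append((r, float(np.linalg.norm(moved - ca_a[r]))))
    return DisplacementProfile(entries)


def pairwise_loop_shift_matrix(
    structures: Sequence[Structure],
    loop: LoopDefinition,
    fit_selection: Iterable[int],
) -> tuple[np.ndarray, tuple[int, int]]:
    """Symmetric matrix of maximal loop-Cα displacement between all pairs.

    Entry (i, j) is the maximum over the loop residues of the Cα displacement
    after fitting structure j onto structure i on the framework selection.
    Returns the matrix and the index pair realising the global maximum (the
    two extreme conformations).
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    fit_sel = list(fit_selection)
    loop_sel = list(loop.residues())
    n = len(structures)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            prof = per_residue_displacement(
                structures[i], structures[j], fit_sel, loop_sel, loop.chain_id
            )
            missing = set(loop_sel) - {r for r, _ in prof.entries}
            if missing:
                raise ValueError(
                    f"loop {loop.loop_name}: residues {sorted(missing)} missing in "
                    f"{structures[i].id!r} or {structures[j].id!r}"
                )
            mat[i, j] = mat[j, i] = prof.max_displacement
    imax, jmax = np.unravel_index(np.argmax(mat), mat.shape)
    return mat, (int(imax), int(jmax))


# ---------------------------------------------------------------------------
# Lattice contacts


@dataclass(frozen=True)
class SymmetryImage:
    """Cartesian coordinates of the whole model under one (operator, shift)."""

    operator_index: int
    lattice_translation: tuple[int, int, int]
    coords: np.ndarray
    is_self: bool


def space_group_operators(hm_symbol: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fractional-coordinate (rotation, translation) pairs for a space group.

    Looked up from the standard Hermann-Mauguin table; non-standard settings
    must be supplied explicitly via :func:`parse_operator_triplets`.
    """
    sg = gemmi.find_spacegroup_by_name(hm_symbol)
    if sg is None:
        raise ValueError(
            f"unknown space-group symbol {hm_symbol!r}; supply operator triplets explicitly"
        )
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append((rot, tran))
    return ops


def parse_operator_triplets(triplets: Iterable[str]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Parse operators given as triplet strings like ``-x,y+1/2,-z``."""
    ops = []
    for t in triplets:
        op = gemmi.Op(t)
        ops.append((np.array(op.rot, dtype=float) / op.DEN,
                    np.array(op.tran, dtype=float) / op.DEN))
    return ops


def _orth_frac_matrices(cell: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    uc = gemmi.UnitCell(*cell)
    orth = np.array(uc.orth.mat.tolist(), dtype=float)
    frac = np.array(uc.frac.mat.tolist(), dtype=float)
    return orth, frac


def apply_symmetry(
    structure: Structure,
    operators: Sequence[tuple[np.ndarray, np.ndarray]],
    translation_range: int = 1,
) -> list[SymmetryImage]:
    """Generate Cartesian images under every operator × lattice translation.

    Translations run over ±``translation_range`` cells along each axis.  The
    identity operator with zero shift is included and tagged ``is_self``.
    """
    if structure.cell is None:
        raise ValueError(f"structure {structure.id!r} has no unit cell")
    if not any(
        np.allclose(rot, np.eye(3)) and np.allclose(tran % 1.0, 0.0)
        for rot, tran in operators
    ):
        raise ValueError("operator list must include the identity")
    orth, frac_m = _orth_frac_matrices(structure.cell)
    xyz = structure.coords_array()
    frac = xyz @ frac_m.T
    shifts = range(-translation_range, translation_range + 1)
    images = []
    for op_index, (rot, tran) in enumerate(operators):
        base = frac @ rot.T + tran
        identity = np.allclose(rot, np.eye(3)) and np.allclose(tran % 1.0, 0.0)
        for tvec in product(shifts, shifts, shifts):
            moved = base + np.array(tvec, dtype=float)
            images.append(
                SymmetryImage(
                    operator_index=op_index,
                    lattice_translation=tvec,
                    coords=moved @ orth.T,
                    is_self=identity and tvec == (0, 0, 0),
                )
            )
    return images


def find_crystal_contacts(
    structure: Structure,
    operators: Sequence[tuple[np.ndarray, np.ndarray]],
    cutoff: float = 4.0,
    translation_range: int = 1,
) -> list[ContactRecord]:
    """All atom pairs closer than ``cutoff`` (strict) to a non-self image.

    Each physical contact is reported once: the pair of asymmetric-unit atom
    indices is canonicalised (unordered) and the closest image realising it
    is kept.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atoms = [a.key for a in structure.atoms()]
    xyz = structure.coords_array()
    tree = cKDTree(xyz)
    best: dict[tuple, ContactRecord] = {}
    for image in apply_symmetry(structure, operators, translation_range):
        if image.is_self:
            continue
        pairs = tree.query_ball_point(image.coords, cutoff)
        for j_img, neighbours in enumerate(pairs):
            for i_asu in neighbours:
                d = float(np.linalg.norm(xyz[i_asu] - image.coords[j_img]))
                if d >= cutoff:
                    continue
                # a physical contact appears twice (i vs image-of-j and j vs
                # image-of-i at the same distance); distinct contacts between
                # the same pair through different images differ in distance
                key = (min(i_asu, j_img), max(i_asu, j_img), round(d, 6))
                rec = ContactRecord(
                    atom_a=atoms[i_asu],
                    atom_b=atoms[j_img],
                    operator_index=image.operator_index,
                    lattice_translation=image.lattice_translation,
                    distance=d,
                )
                if key not in best:
                    best[key] = rec
    return sorted(best.values(), key=lambda r: (r.atom_a, r.atom_b))


def loop_contact_freedom(
    contacts: Sequence[ContactRecord],
    loops: Sequence[LoopDefinition],
) -> dict[str, tuple[bool, int]]:
    """Per loop: (free of lattice contacts, number of contacts touching it).

    A loop is free iff no contact involves any atom of any residue in its
    range — on either side of the contact, since the image atom belongs to
    the same molecule in a neighbouring lattice position.
    """
    out: dict[str, tuple[bool, int]] = {}
    for loop in loops:
        n = 0
        for c in contacts:
            for key in (c.atom_a, c.atom_b):
                chain_id, res_seq = key[0], key[1]
                if loop.contains(chain_id, res_seq):
                    n += 1
                    break
        out[loop.loop_name] = (n == 0, n)
    return out
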