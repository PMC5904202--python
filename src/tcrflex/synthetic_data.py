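"""Self-contained structural fixtures with known ground truth.

Every stage of the pipeline is testable without external coordinate files:
the generators below build small glycine/alanine hairpins with an
hydrogen-bonded two-strand core and a flexible loop, multi-conformer pairs
with an exactly known loop displacement, a two-domain dumbbell whose lowest
nontrivial elastic-network mode is an interdomain hinge, and a P1 lattice
fixture with exactly one designed inter-image contact.

The geometry is idealised, not biological: residues are rigid copies of a
planar backbone template (N-CA 1.46 Å, CA-C ~1.51 Å, C-N 1.33 Å), strands
are straight, and the inter-strand spacing is solved so that the designed
backbone hydrogen bonds score near the bottom of the energy well while all
non-designed pairs stay outside both the hydrogen-bond well and the steric
floor.  Construction is deterministic for a fixed seed (the seed only feeds
a tiny symmetry-breaking jitter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .structure_model import Atom, Chain, LoopDefinition, Residue, Structure

__all__ = [
    "ToySpec",
    "GroundTruth",
    "make_hairpin_scaffold",
    "make_conformer_pair",
    "make_two_domain_chain",
    "make_lattice_fixture",
    "write_ground_truth",
]

# planar residue template, chain advancing along +x (repeat 3.69 A)
_TPL = {
    "N": np.array([0.0, 0.0, 0.0]),
    "CA": np.array([1.15, 0.898, 0.0]),
    "C": np.array([2.36, 0.0, 0.0]),
    "O": np.array([2.36, -1.23, 0.0]),
}
_RESIDUE_REPEAT = 3.69
_PEPTIDE_CN = 1.33
_NC_SPAN = 2.36  # N -> C along the local x axis

# designed inter-strand hydrogen-bond displacement (donor N of one strand to
# acceptor O of the other): length 2.9 A, antecedent angle ~114.5 degrees,
# neighbours pushed outside the 3.5 A well
_HB_DX = 1.2
_HB_DZ = 1.3
_HB_DY = float(np.sqrt(2.9**2 - _HB_DX**2 - _HB_DZ**2))
_JITTER_SIGMA = 0.001


@dataclass(frozen=True)
class ToySpec:
    """Parameters of the synthetic fixtures."""

    n_core_residues: int = 8
    loop_length: int = 4
    loop_displacement: float = 2.5
    two_domain: bool = False
    cell: tuple[float, float, float, float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core_residues < 6:
            raise ValueError("need at least 6 core residues (3 per strand)")
        if self.loop_length < 2:
            raise ValueError("loop needs at least 2 residues")


@dataclass
class GroundTruth:
    """Designed properties a test can assert against."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]


def _residue(name: str, seq: int, chain_id: str, rot: np.ndarray, origin: np.ndarray,
             serial_start: int) -> Residue:
    res = Residue(name, seq)
    serial = serial_start
    for atom_name, local in _TPL.items():
        res.atoms.append(
            Atom(
                serial=serial, name=atom_name, element=atom_name[0],
                alt_loc="", chain_id=chain_id, res_name=name, res_seq=seq,
                insertion_code="", coords=rot @ local + origin,
            )
        )
        serial += 1
    return res


def _rot_about(axis: np.ndarray, angle: float) -> np.ndarray:
    return Rotation.from_rotvec(np.asarray(axis, dtype=float) * angle).as_matrix()


_ROT_FWD = np.eye(3)
_ROT_BWD = _rot_about(np.array([0.0, 0.0, 1.0]), np.pi)  # strand running -x


def _solve_loop_frames(
    start_c: np.ndarray,
    target_n: np.ndarray,
    n_res: int,
    context: list[tuple[int, str, np.ndarray]] | None = None,
    first_res_index: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Place ``n_res`` residues turning the chain from +x to -x.

    Residue i has orientation R(n, phi_i) with phi running 0 -> pi about a
    rolled in-plane axis; the free angles are solved so that the last
    residue's C sits one peptide bond (+x side) from ``target_n``, giving an
    ideal antecedent direction for the first residue of the next strand.
    ``context`` atoms (res_index, name, xyz) let the solver keep loop atoms
    clear of the strands: polar atoms of residues more than one apart must
    stay outside the hydrogen-bond well and all such pairs outside a steric
    margin, so the loop designs in no accidental constraints.
    """
    target_c = target_n + np.array([_PEPTIDE_CN, 0.0, 0.0])
    xhat = np.array([1.0, 0.0, 0.0])
    # the turn sweeps perpendicular displacement along (0, cos r, -sin r)
    perp = target_c - start_c
    roll0 = float(np.arctan2(-perp[2], perp[1] if abs(perp[1]) > 1e-9 else -1.0))

    def chain_positions(params: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        roll = params[0]
        phis = params[1:]
        axis = np.array([0.0, np.sin(roll), np.cos(roll)])
        rots = [_rot_about(axis, p) for p in phis]
        origins = []
        pos = start_c + _PEPTIDE_CN * (rots[0] @ xhat)
        for i, rot in enumerate(rots):
            origins.append(pos)
            c_pos = pos + rot @ _TPL["C"]
            if i + 1 < len(rots):
                pos = c_pos + _PEPTIDE_CN * (rots[i + 1] @ xhat)
        return origins, rots

    local_atoms = np.stack(list(_TPL.values()))
    local_names = list(_TPL.keys())
    is_n_local = np.array([n == "N" for n in local_names])
    is_o_local = np.array([n == "O" for n in local_names])
    if context:
        ctx_xyz = np.stack([xyz for _, _, xyz in context])
        ctx_res = np.array([r for r, _, _ in context])
        ctx_is_n = np.array([n == "N" for _, n, _ in context])
        ctx_is_o = np.array([n in ("O", "OXT") for _, n, _ in context])
    POLAR_MIN, STERIC_MIN = 3.7, 3.0

    def clash_penalty(origins, rots) -> np.ndarray:
        loop_xyz = np.concatenate(
            [(rot @ local_atoms.T).T + origin for origin, rot in zip(origins, rots)]
        )
        loop_res = np.repeat(first_res_index + np.arange(n_res), len(local_names))
        loop_is_n = np.tile(is_n_local, n_res)
        loop_is_o = np.tile(is_o_local, n_res)
        pens = []
        # against the fixed context (strand atoms)
        if context:
            d = np.linalg.norm(loop_xyz[:, None, :] - ctx_xyz[None, :, :], axis=2)
            nonadj = np.abs(loop_res[:, None] - ctx_res[None, :]) > 1
            donor_acceptor = (loop_is_n[:, None] & ctx_is_o[None, :]) | (
                loop_is_o[:, None] & ctx_is_n[None, :])
            floor = np.where(donor_acceptor, POLAR_MIN, STERIC_MIN)
            pens.append(np.clip((floor - d) * nonadj, 0.0, None).ravel())
        # intra-loop
        d = np.linalg.norm(loop_xyz[:, None, :] - loop_xyz[None, :, :], axis=2)
        nonadj = np.abs(loop_res[:, None] - loop_res[None, :]) > 1
        donor_acceptor = (loop_is_n[:, None] & loop_is_o[None, :]) | (
            loop_is_o[:, None] & loop_is_n[None, :])
        floor = np.where(donor_acceptor, POLAR_MIN, STERIC_MIN)
        pens.append(np.clip((floor - d) * nonadj, 0.0, None)[np.triu_indices(len(loop_xyz), 1)])
        return 1.0 * np.concatenate(pens)

    def residuals(params: np.ndarray) -> np.ndarray:
        origins, rots = chain_positions(params)
        c_last = origins[-1] + rots[-1] @ _TPL["C"]
        # the hard requirement is the peptide-bond length into the next
        # strand; the exact approach direction is only weakly guided
        bond_err = np.linalg.norm(c_last - target_n) - _PEPTIDE_CN
        guide = 0.3 * (c_last - target_c)
        phis = params[1:]
        smooth = 0.05 * np.diff(phis, prepend=0.0, append=np.pi)
        return np.concatenate([[5.0 * bond_err], guide, smooth, clash_penalty(origins, rots)])

    # racetrack-like start: turn concentrated mid-loop, straights at the ends
    centre = (n_res - 1) / 2.0
    phi0 = np.pi / (1.0 + np.exp(-(np.arange(n_res) - centre) * 3.0))
    x0 = np.concatenate([[roll0], phi0])
    sol = least_squares(residuals, x0, method="lm", max_nfev=5000)
    gap = abs(float(residuals(sol.x)[0])) / 5.0
    if gap > 0.25:
        raise ValueError(
            f"loop of {n_res} residues cannot span the strand offset (gap {gap:.2f} A)"
        )
    origins, rots = chain_positions(sol.x)
    return list(zip(origins, rots))


def _build_hairpin(spec: ToySpec, chain_id: str = "A", first_seq: int = 1,
                   serial_start: int = 1) -> tuple[list[Residue], GroundTruth]:
    n_strand = spec.n_core_residues // 2
    residues: list[Residue] = []
    seq = first_seq
    serial = serial_start

    # strand A: +x at y=0, z=0
    for k in range(n_strand):
        origin = np.array([_RESIDUE_REPEAT * k, 0.0, 0.0])
        residues.append(_residue("ALA", seq, chain_id, _ROT_FWD, origin, serial))
        seq += 1
        serial += len(_TPL)

    # strand B: -x, offset so facing pairs make two ~-9.9 kcal/mol H-bonds;
    # B residue j faces strand-A residue (n_strand - 2 - j)
    strand_b_frames = []
    y_b = -_TPL["O"][1] * 0 - 1.23 - _HB_DY
    for j in range(n_strand):
        k_facing = n_strand - 2 - j
        n_x = _RESIDUE_REPEAT * k_facing + _NC_SPAN + _HB_DX
        strand_b_frames.append(np.array([n_x, y_b, _HB_DZ]))

    # loop: from strand A's last C around to strand B's first N, solved to
    # stay clear of both strands
    context: list[tuple[int, str, np.ndarray]] = []
    for k in range(n_strand):
        for name, local in _TPL.items():
            context.append((k, name, local + np.array([_RESIDUE_REPEAT * k, 0.0, 0.0])))
    for j, origin in enumerate(strand_b_frames):
        for name, local in _TPL.items():
            context.append((n_strand + spec.loop_length + j, name, _ROT_BWD @ local + origin))
    last_c = np.array([_RESIDUE_REPEAT * (n_strand - 1), 0.0, 0.0]) + _TPL["C"]
    loop_frames = _solve_loop_frames(
        last_c, strand_b_frames[0], spec.loop_length,
        context=context, first_res_index=n_strand,
    )
    loop_first_seq = seq
    for origin, rot in loop_frames:
        residues.append(_residue("GLY", seq, chain_id, rot, origin, serial))
        seq += 1
        serial += len(_TPL)
    loop_last_seq = seq - 1

    for origin in strand_b_frames:
        residues.append(_residue("ALA", seq, chain_id, _ROT_BWD, origin, serial))
        seq += 1
        serial += len(_TPL)

    n_pairs = n_strand - 1
    designed = []
    for j in range(n_pairs):
        k = n_strand - 2 - j
        a_seq = first_seq + k
        b_seq = loop_last_seq + 1 + j
        designed.append(((chain_id, b_seq, "N"), (chain_id, a_seq, "O")))
        designed.append(((chain_id, a_seq, "N"), (chain_id, b_seq, "O")))
    truth = GroundTruth(
        {
            "n_designed_hbonds": 2 * n_pairs,
            "designed_hbond_pairs": designed,
            "loop_range": (loop_first_seq, loop_last_seq),
            "strand_residues": (
                list(range(first_seq, first_seq + n_strand))
                + list(range(loop_last_seq + 1, loop_last_seq + 1 + n_strand))
            ),
            "n_residues": spec.n_core_residues + spec.loop_length,
        }
    )
    return residues, truth


def _jitter(structure: Structure, seed: int) -> None:
    rng = np.random.default_rng(seed)
    coords = structure.coords_array()
    structure.set_coords(coords + rng.normal(0.0, _JITTER_SIGMA, coords.shape))


def make_hairpin_scaffold(spec: ToySpec | None = None) -> tuple[Structure, GroundTruth]:
    """Two antiparallel strands joined by a glycine loop.

    The strand core carries 2·(n_core/2 − 1) designed backbone hydrogen
    bonds at near-ideal geometry (both strands donate and accept across each
    facing pair), making the core rigid at the default energy cutoff while
    the loop stays floppy.
    """
    spec = spec or ToySpec()
    residues, truth = _build_hairpin(spec)
    st = Structure("hairpin", [Chain("A", residues)])
    _jitter(st, spec.seed)
    st.validate()
    return st, truth


def make_conformer_pair(
    base: Structure,
    loop: LoopDefinition,
    displacement: float,
    seed: int = 0,
) -> tuple[Structure, Structure]:
    """A conformer pair whose loop apex moves by exactly ``displacement`` Å.

    The second conformer rotates the loop residues rigidly about the axis
    through the loop's first N and last C atoms (a hinge flap), which
    preserves all bond lengths including the two junction bonds.  The
    rotation angle is solved so the apex Cα (median loop residue) moves by
    the requested amount; a displacement beyond the flap's geometric reach
    raises a ValueError.
    """
    if displacement < 0:
        raise ValueError("displacement must be non-negative")
    chain = base.chain(loop.chain_id)
    loop_res = [r for r in chain.residues if loop.start <= r.res_seq <= loop.end]
    if len(loop_res) != loop.end - loop.start + 1:
        raise ValueError(f"loop {loop.loop_name} not fully present in {base.id!r}")
    other = base.copy()
    if displacement == 0:
        return base.copy(), other

    p0 = loop_res[0].atom("N").coords
    p1 = loop_res[-1].atom("C").coords
    axis = (p1 - p0) / np.linalg.norm(p1 - p0)

    from statistics import median_low

    apex_seq = median_low(range(loop.start, loop.end + 1))
    radii = {}
    for r in loop_res:
        ca = r.atom("CA").coords
        v = ca - p0
        radii[r.res_seq] = float(np.linalg.norm(v - np.dot(v, axis) * axis))
    r_apex = radii[apex_seq]
    if displacement > 2.0 * r_apex * 0.999:
        raise ValueError(
            f"displacement {displacement:.2f} A unreachable: apex is only "
            f"{r_apex:.2f} A from the hinge axis"
        )
    theta_apex = 2.0 * np.arcsin(displacement / (2.0 * r_apex))

    # non-apex residues get individually damped angles so the apex is the
    # *maximal* mover; the inter-residue bond lengths are restored softly
    seqs = [r.res_seq for r in loop_res]
    apex_pos = seqs.index(apex_seq)
    free = [k for k in range(len(seqs)) if k != apex_pos]
    bump = np.sin(np.pi * (np.arange(len(seqs)) + 1) / (len(seqs) + 1))
    bump = np.minimum(0.95 * bump / bump[apex_pos], 0.95)

    def conformer_coords(thetas_free: np.ndarray) -> list[np.ndarray]:
        thetas = np.empty(len(seqs))
        thetas[apex_pos] = theta_apex
        thetas[free] = thetas_free
        out = []
        for k, r in enumerate(loop_res):
            rot = _rot_about(axis, float(thetas[k]))
            out.append(np.stack([rot @ (a.coords - p0) + p0 for a in r.atoms]))
        return out

    bond0 = [
        float(np.linalg.norm(loop_res[k + 1].atom("N").coords - loop_res[k].atom("C").coords))
        for k in range(len(seqs) - 1)
    ]
    name_idx_per_res = [
        {a.name: i for i, a in enumerate(r.atoms)} for r in loop_res
    ]

    def residuals(thetas_free: np.ndarray) -> np.ndarray:
        coords = conformer_coords(thetas_free)
        bonds = [
            np.linalg.norm(
                coords[k + 1][name_idx_per_res[k + 1]["N"]]
                - coords[k][name_idx_per_res[k]["C"]]
            ) - bond0[k]
            for k in range(len(seqs) - 1)
        ]
        disp = np.array([
            np.linalg.norm(
                coords[k][name_idx_per_res[k]["CA"]] - loop_res[k].atom("CA").coords
            )
            for k in range(len(seqs))
        ])
        profile = (disp[free] - displacement * bump[free])
        overshoot = np.clip(disp - 0.995 * displacement, 0.0, None)
        overshoot[apex_pos] = 0.0
        return np.concatenate([10.0 * np.array(bonds), profile, 20.0 * overshoot])

    if len(free):
        x0 = theta_apex * bump[free]
        sol = least_squares(residuals, x0, method="lm", max_nfev=2000)
        coords = conformer_coords(sol.x)
    else:
        coords = conformer_coords(np.empty(0))
    for k, res_seq in enumerate(seqs):
        target = other.chain(loop.chain_id).residue(res_seq)
        for ia, a in enumerate(target.atoms):
            a.coords = coords[k][ia]
    return base.copy(), other


def make_two_domain_chain(spec: ToySpec | None = None) -> tuple[Structure, GroundTruth]:
    """Two hairpin domains joined by an extended 10-residue linker.

    The dumbbell shape makes the lowest nontrivial elastic-network mode a
    relative domain motion hinging at the linker.
    """
    spec = spec or ToySpec(two_domain=True)
    if not spec.two_domain:
        raise ValueError("spec.two_domain must be true")
    linker_length = 10
    dom1, truth1 = _build_hairpin(spec, first_seq=1, serial_start=1)

    residues = list(dom1)
    n_atoms = sum(len(r.atoms) for r in residues)
    seq = residues[-1].res_seq + 1
    serial = n_atoms + 1

    # linker: a gently zig-zagging strand continuing -x; the kinks and the
    # roll about the chain axis keep the linker Calphas off any straight
    # line, so its elastic network has no spurious soft transverse modes
    xhat = np.array([1.0, 0.0, 0.0])
    zhat = np.array([0.0, 0.0, 1.0])
    linker_first = seq
    last_c = residues[-1].atom("C").coords
    for i in range(linker_length):
        rot = _ROT_BWD @ _rot_about(zhat, 0.35 * (-1.0) ** i) @ _rot_about(xhat, 2.0 * i)
        pos = last_c + _PEPTIDE_CN * (rot @ xhat)
        residue = _residue("GLY", seq, "A", rot, pos, serial)
        residues.append(residue)
        last_c = residue.atom("C").coords
        seq += 1
        serial += len(_TPL)
    linker_last = seq - 1

    # second hairpin, rotated 180 degrees about z so its strands run -x
    dom2_spec = ToySpec(
        spec.n_core_residues, spec.loop_length, spec.loop_displacement,
        two_domain=True, seed=spec.seed,
    )
    dom2, truth2 = _build_hairpin(dom2_spec, first_seq=seq, serial_start=serial)
    # roll the second domain about the chain axis so its returning strand
    # clears the linker; the junction bond direction (-x) is unaffected
    rot2 = _rot_about(xhat, 0.9) @ _ROT_BWD
    shift = last_c + _ROT_BWD @ np.array([_PEPTIDE_CN, 0.0, 0.0])
    for r in dom2:
        for a in r.atoms:
            a.coords = rot2 @ a.coords + shift
    residues.extend(dom2)

    st = Structure("two_domain", [Chain("A", residues)])
    _jitter(st, spec.seed)
    st.validate()
    truth = GroundTruth(
        {
            "domain1_residues": list(range(1, truth1["n_residues"] + 1)),
            "linker_residues": list(range(linker_first, linker_last + 1)),
            "domain2_residues": [r.res_seq for r in dom2],
            "loop_range_domain1": truth1["loop_range"],
            "loop_range_domain2": truth2["loop_range"],
            "n_designed_hbonds": truth1["n_designed_hbonds"] + truth2["n_designed_hbonds"],
        }
    )
    return st, truth


def make_lattice_fixture(
    spec: ToySpec | None = None,
    contact_distance: float = 3.8,
    clearance: float = 4.2,
) -> tuple[Structure, GroundTruth]:
    """The hairpin in a P1 cell with exactly one designed inter-image contact.

    The cell edge along x is solved (bisection) so that the closest pair
    between the model and its +x lattice neighbour sits at
    ``contact_distance``; the generator then verifies that every other
    inter-image pair clears ``clearance``.
    """
    spec = spec or ToySpec(cell=(0, 0, 0, 90.0, 90.0, 90.0))
    if spec.cell is None:
        raise ValueError("spec.cell must be present for a lattice fixture")
    st, truth = make_hairpin_scaffold(
        ToySpec(spec.n_core_residues, spec.loop_length, spec.loop_displacement,
                seed=spec.seed)
    )
    # give the C-terminus its carboxylate OXT, protruding outward from the
    # body so the designed contact atom stands clear of its neighbours
    last_res = st.chains[-1].residues[-1]
    c_atom = last_res.atom("C")
    all_xyz = st.coords_array()
    far = all_xyz[np.argmax(np.linalg.norm(all_xyz - c_atom.coords, axis=1))]
    direction = c_atom.coords - far
    direction /= np.linalg.norm(direction)
    last_serial = max(a.serial for a in st.atoms())
    last_res.atoms.append(
        Atom(
            serial=last_serial + 1, name="OXT", element="O", alt_loc="",
            chain_id=last_res.atoms[0].chain_id, res_name=last_res.res_name,
            res_seq=last_res.res_seq, insertion_code="",
            coords=c_atom.coords + 1.25 * direction,
        )
    )

    # align the model's diameter (its two most distant atoms) with the x
    # axis: those atoms are then the exact x extremes with no perpendicular
    # offset, so the +x lattice neighbour touches the model through that
    # single designed pair at a - |PQ|
    xyz = st.coords_array()
    d_all = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    q, p = np.unravel_index(np.argmax(d_all), d_all.shape)
    if xyz[p, 0] < xyz[q, 0]:
        p, q = q, p
    u = (xyz[p] - xyz[q]) / d_all[p, q]
    v = np.cross(u, np.array([1.0, 0.0, 0.0]))
    s = np.linalg.norm(v)
    if s < 1e-12:
        rot = np.eye(3)
    else:
        rot = Rotation.from_rotvec(v / s * np.arcsin(np.clip(s, -1, 1))).as_matrix()
        if (rot @ u)[0] < 0.999:
            rot = Rotation.from_rotvec(v / s * (np.pi - np.arcsin(np.clip(s, -1, 1)))).as_matrix()
    st.set_coords(xyz @ rot.T)
    xyz = st.coords_array()
    span = xyz.max(axis=0) - xyz.min(axis=0)
    a = float(xyz[p, 0] - xyz[q, 0] + contact_distance)

    shifted = xyz + np.array([a, 0.0, 0.0])
    d = np.linalg.norm(xyz[:, None, :] - shifted[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    dmin = float(d[i, j])
    second = float(np.partition(d.ravel(), 1)[1])
    if abs(dmin - contact_distance) > 0.01 or (i, j) != (p, q):
        raise RuntimeError("lattice solve failed to hit the contact distance")
    if second < clearance:
        raise RuntimeError(
            f"second-closest inter-image pair at {second:.2f} A is inside the clearance"
        )
    b = float(span[1] + clearance + 2.0)
    c = float(span[2] + clearance + 2.0)
    out = st.copy()
    out.id = "lattice_fixture"
    out.cell = (float(a), b, c, 90.0, 90.0, 90.0)
    out.space_group = "P 1"
    atoms = list(out.atoms())
    truth.values.update(
        {
            "contact_pair": (atoms[i].key, atoms[j].key),
            "contact_distance": dmin,
            "second_distance": second,
            "cell": out.cell,
        }
    )
    return out, truth


def add_obstacle_wall(
    structure: Structure,
    center: np.ndarray,
    normal: np.ndarray,
    half_extent: float = 4.0,
    spacing: float = 2.0,
) -> tuple[Structure, list[int]]:
    """Append a rigid wall of glycine residues blocking a motion path.

    The wall is a square grid of single-residue 'atoms-only' glycines on the
    plane through ``center`` with the given ``normal``, added as chain "X".
    Returns the new structure and the flat atom indices of the wall atoms
    (to be passed as ``pinned`` to the simulation).
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    ref = np.array([0.0, 0.0, 1.0]) if abs(normal[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    out = structure.copy()
    body = out.coords_array()
    serial = max(a.serial for a in out.atoms()) + 1
    wall = Chain("X")
    ticks = np.arange(-half_extent, half_extent + 1e-9, spacing)
    seq = 1
    for u in ticks:
        for v in ticks:
            pos = np.asarray(center) + u * e1 + v * e2
            # the wall must not clash with the starting structure
            if np.min(np.linalg.norm(body - pos, axis=1)) < 3.2:
                continue
            res = Residue("GLY", seq)
            res.atoms.append(
                Atom(
                    serial=serial, name="CA", element="C", alt_loc="",
                    chain_id="X", res_name="GLY", res_seq=seq,
                    insertion_code="", coords=pos,
                )
            )
            serial += 1
            seq += 1
            wall.residues.append(res)
    n_before = out.n_atoms
    out.chains.append(wall)
    pinned = list(range(n_before, out.n_atoms))
    return out, pinned


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Sidecar TSV of designed values (stringified) for external checks."""
    rows = [(k, repr(v)) for k, v in truth.values.items()]
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(path, sep="\t", index=False)
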