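"""Template-based geometric simulation of mode-biased flexible motion.

The simulation drives an all-atom structure along a normal-mode direction in
small steps, and after every step relaxes the atomic positions back onto the
constraint network: rigid-cluster templates are least-squares fitted to the
perturbed positions and each atom is moved to the average of its templates'
fitted predictions, clashing non-bonded pairs are pushed apart, and
hydrogen-bond/tether lengths are kept inside a window around their input
values.  Motion is "easy" while the constraints can absorb the perturbation;
when relaxation stops converging the run is *jammed* and the last valid
frame marks the natural amplitude limit of that mode and direction.

No force field is involved: geometry (bond lengths/angles inside templates,
constraint-length windows, hard-sphere sterics) is the only physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constraint_network import ConstraintNetwork
from .rigidity import RigidClusterDecomposition
from .structure_model import Structure

__all__ = [
    "SimParams",
    "Template",
    "ConformerEnsemble",
    "Variant",
    "ViolationReport",
    "build_templates",
    "run_geometric_simulation",
    "select_extreme_variants",
    "check_constraints",
]


@dataclass(frozen=True)
class SimParams:
    """Knobs of the perturb/relax loop.

    ``step_size`` is the per-atom displacement scale in Å: the collective
    perturbation applied each iteration is step_size·√N along the unit mode
    field, so a typical atom moves about ``step_size`` Å before relaxation.
    """

    step_size: float = 0.01
    relax_tolerance: float = 0.1
    max_relax_iters: int = 200
    max_frames: int = 2000
    steric_scale: float = 0.85
    frame_stride: int = 100
    stall_window: int = 20
    stall_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.step_size, self.relax_tolerance, self.max_relax_iters,
               self.max_frames, self.frame_stride, self.stall_window) <= 0:
            raise ValueError("all simulation parameters must be positive")
        if not 0.0 < self.steric_scale <= 1.0:
            raise ValueError("steric_scale must lie in (0, 1]")


@dataclass
class Template:
    """A rigid unit: atom indices plus their reference geometry."""

    indices: np.ndarray
    reference: np.ndarray  # (m, 3) centred reference coordinates

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass
class ConformerEnsemble:
    """Frames of one (mode, direction) run plus per-frame diagnostics."""

    frames: list[np.ndarray]
    frame_iterations: list[int]
    amplitudes: list[float]  # cumulative driven amplitude, Å (collective)
    max_bond_deviation: list[float]
    min_steric_gap: list[float]
    termination: str  # "completed" | "jammed"
    mode_index: int
    direction: int

    @property
    def final_frame(self) -> np.ndarray:
        return self.frames[-1]

    @property
    def final_amplitude(self) -> float:
        return self.amplitudes[-1]


@dataclass(frozen=True)
class Variant:
    """The conformer at the natural amplitude limit of one mode direction."""

    coords: np.ndarray
    mode_index: int
    direction: int
    amplitude: float


@dataclass
class ViolationReport:
    max_covalent_deviation: float
    max_window_violation: float
    min_nonbonded_gap: float
    n_violations: int

    def worst(self) -> float:
        steric_penetration = max(0.0, -self.min_nonbonded_gap)
        return max(self.max_covalent_deviation, self.max_window_violation, steric_penetration)


def build_templates(
    structure: Structure,
    decomposition: RigidClusterDecomposition,
    network: ConstraintNetwork,
) -> list[Template]:
    """One template per rigid cluster; tiny clusters become bonded units.

    Clusters of one or two atoms carry no internal geometry, so each of
    their atoms is grouped with its covalent neighbours into a minimal
    angle-preserving unit.  Atoms shared between adjacent templates form the
    articulation sets through which flexible motion propagates.
    """
    coords = network.coords_array()
    clusters: dict[int, list[int]] = {}
    for i, c in decomposition.cluster_of.items():
        clusters.setdefault(c, []).append(i)

    member_sets: list[frozenset[int]] = []
    for members in clusters.values():
        if len(members) >= 3:
            member_sets.append(frozenset(members))
        else:
            for i in members:
                unit = frozenset({i} | network.covalent_neighbors(i))
                member_sets.append(unit)
    # drop units wholly contained in another template
    member_sets = sorted(set(member_sets), key=lambda s: (-len(s), sorted(s)))
    kept: list[frozenset[int]] = []
    for unit in member_sets:
        if not any(unit <= other for other in kept):
            kept.append(unit)

    covered: set[int] = set()
    templates = []
    for unit in kept:
        idx = np.array(sorted(unit), dtype=int)
        ref = coords[idx]
        templates.append(Template(idx, ref - ref.mean(axis=0)))
        covered.update(unit)
    missing = set(range(len(network.atoms))) - covered
    if missing:
        raise ValueError(f"atoms missing from all templates: {sorted(missing)}")
    return templates


class _Relaxer:
    """Precomputed machinery for fast relaxation onto the constraint network."""

    def __init__(
        self,
        network: ConstraintNetwork,
        templates: Sequence[Template],
        params: SimParams,
        pinned: Sequence[int] = (),
    ):
        self.params = params
        self.n = len(network.atoms)
        coords0 = network.coords_array()
        self.pinned = np.asarray(sorted(pinned), dtype=int)
        self.pinned_coords = coords0[self.pinned] if len(self.pinned) else None

        # padded template arrays for batched Kabsch fits
        self.templates = list(templates)
        m = max(t.size for t in templates)
        t = len(templates)
        self.pad_idx = np.zeros((t, m), dtype=int)
        self.pad_mask = np.zeros((t, m), dtype=bool)
        self.pad_ref = np.zeros((t, m, 3))
        for k, tpl in enumerate(templates):
            self.pad_idx[k, : tpl.size] = tpl.indices
            self.pad_mask[k, : tpl.size] = True
            self.pad_ref[k, : tpl.size] = tpl.reference
        self.tpl_sizes = self.pad_mask.sum(axis=1)[:, None]
        self.multiplicity = np.zeros(self.n)
        np.add.at(self.multiplicity, self.pad_idx[self.pad_mask], 1.0)

        # covalent bonds with reference lengths
        cov = network.covalent_edges()
        self.cov_pairs = np.array([[e.i, e.j] for e in cov], dtype=int).reshape(-1, 2)
        self.cov_len = np.linalg.norm(
            coords0[self.cov_pairs[:, 0]] - coords0[self.cov_pairs[:, 1]], axis=1
        )
        # hbond/tether windows around the input-structure lengths
        nc = [e for e in network.edges if e.kind in ("hbond", "tether")]
        self.win_pairs = np.array([[e.i, e.j] for e in nc], dtype=int).reshape(-1, 2)
        self.win_len = np.linalg.norm(
            coords0[self.win_pairs[:, 0]] - coords0[self.win_pairs[:, 1]], axis=1
        )

        # steric exclusions: covalent neighbours up to 1-4, constrained
        # pairs, and pairs held inside one template
        excluded: set[tuple[int, int]] = set()
        for e in network.edges:
            excluded.add(e.pair)
        for i in range(self.n):
            reach = {i}
            frontier = {i}
            for _ in range(3):
                frontier = {k for j in frontier for k in network.covalent_neighbors(j)} - reach
                reach |= frontier
            for k in reach - {i}:
                excluded.add((min(i, k), max(i, k)))
        for tpl in templates:
            idx = tpl.indices
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    excluded.add((min(idx[a], idx[b]), max(idx[a], idx[b])))
        # immobile atoms never clash with each other
        for a in range(len(self.pinned)):
            for b in range(a + 1, len(self.pinned)):
                excluded.add((int(self.pinned[a]), int(self.pinned[b])))
        self.excluded = excluded
        radii = np.array([params.steric_scale * network.params.vdw(a.element)
                          for a in network.atoms])
        self.pair_floor = radii[:, None] + radii[None, :]
        self.max_floor = float(2 * radii.max())

    # -- primitive moves ----------------------------------------------------

    def fit_templates(self, coords: np.ndarray) -> np.ndarray:
        """Average of per-template rigid fits (batched Kabsch)."""
        cur = coords[self.pad_idx] * self.pad_mask[:, :, None]
        centroid = cur.sum(axis=1) / self.tpl_sizes
        cur_c = (cur - centroid[:, None, :]) * self.pad_mask[:, :, None]
        cov = np.einsum("tmi,tmj->tij", self.pad_ref, cur_c)
        u, _, vt = np.linalg.svd(cov)
        det = np.linalg.det(np.einsum("tij,tjk->tik", u, vt))
        d = np.ones_like(u[:, :, 0])
        d[:, -1] = det
        rot = np.einsum("tij,tj,tjk->tik", u, d, vt)  # maps ref -> current frame
        fitted = np.einsum("tmi,tik->tmk", self.pad_ref, rot) + centroid[:, None, :]
        out = np.zeros_like(coords)
        np.add.at(out, self.pad_idx[self.pad_mask], fitted[self.pad_mask])
        return out / self.multiplicity[:, None]

    def _pair_corrections(self, coords: np.ndarray) -> tuple[np.ndarray, float]:
        """Displacements restoring constraint windows and sterics."""
        tol = self.params.relax_tolerance
        delta = np.zeros_like(coords)
        worst = 0.0

        def project(pairs: np.ndarray, target_lo: np.ndarray, target_hi: np.ndarray) -> float:
            nonlocal delta
            if len(pairs) == 0:
                return 0.0
            vec = coords[pairs[:, 1]] - coords[pairs[:, 0]]
            d = np.linalg.norm(vec, axis=1)
            d = np.where(d < 1e-9, 1e-9, d)
            target = np.clip(d, target_lo, target_hi)
            err = target - d  # positive: push apart
            unit = vec / d[:, None]
            half = 0.5 * err[:, None] * unit
            np.add.at(delta, pairs[:, 1], half)
            np.add.at(delta, pairs[:, 0], -half)
            return float(np.abs(err).max())

        worst = max(worst, project(self.cov_pairs, self.cov_len, self.cov_len))
        worst = max(
            worst,
            project(self.win_pairs, self.win_len - tol, self.win_len + tol),
        )
        # sterics: non-excluded pairs below the hard floor
        tree = cKDTree(coords)
        steric_pairs = []
        floors = []
        for i, j in tree.query_pairs(self.max_floor):
            pair = (min(i, j), max(i, j))
            if pair in self.excluded:
                continue
            floor = self.pair_floor[i, j]
            if np.linalg.norm(coords[i] - coords[j]) < floor:
                steric_pairs.append(pair)
                floors.append(floor)
        if steric_pairs:
            sp = np.array(steric_pairs, dtype=int)
            fl = np.array(floors)
            worst = max(worst, project(sp, fl, np.full_like(fl, np.inf)))
        return delta, worst

    def _hold_pinned(self, x: np.ndarray) -> np.ndarray:
        if self.pinned_coords is not None:
            x[self.pinned] = self.pinned_coords
        return x

    def relax(self, coords: np.ndarray) -> tuple[np.ndarray, bool]:
        """Iterate template fitting + pair corrections until tolerance."""
        x = self._hold_pinned(coords.copy())
        for _ in range(self.params.max_relax_iters):
            x = self._hold_pinned(self.fit_templates(x))
            delta, worst = self._pair_corrections(x)
            if worst < self.params.relax_tolerance:
                return x, True
            x = self._hold_pinned(x + delta)
        x = self._hold_pinned(self.fit_templates(x))
        _, worst = self._pair_corrections(x)
        return x, worst < self.params.relax_tolerance


def run_geometric_simulation(
    structure: Structure,
    templates: Sequence[Template],
    network: ConstraintNetwork,
    mode_field: np.ndarray,
    direction: int,
    params: SimParams | None = None,
    mode_index: int = 0,
    pinned: Sequence[int] = (),
) -> ConformerEnsemble:
    """Drive the structure along ±mode_field until jamming or the frame cap.

    Each iteration displaces all atoms by direction·step_size·√N·mode_field
    and relaxes back onto the network.  The motion coordinate is the
    *realized* amplitude: the peak projection of the displacement from the
    start frame onto the signed mode field (a running maximum, so it is
    non-decreasing by construction and equals the instantaneous projection
    throughout the easy phase).  The run terminates *jammed* when
    relaxation fails to reach tolerance, or when the realized amplitude
    stops advancing (its gain over ``stall_window`` iterations drops below
    ``stall_fraction`` of the driven displacement) — constraints then block
    further progress along the mode.  ``pinned`` atoms (obstacles, anchors)
    are never moved.
    """
    params = params or SimParams()
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    field_arr = np.asarray(mode_field, dtype=float)
    n = len(network.atoms)
    if field_arr.shape != (n, 3):
        raise ValueError(f"mode field shape {field_arr.shape} != ({n}, 3)")
    norm = np.linalg.norm(field_arr)
    if norm != 0.0 and abs(norm - 1.0) > 1e-6:
        raise ValueError(f"mode field must have unit norm or be zero (got {norm:.6f})")

    relaxer = _Relaxer(network, templates, params, pinned=pinned)
    step = params.step_size * np.sqrt(n) * direction * field_arr
    collective_step = params.step_size * np.sqrt(n)
    signed_field = direction * field_arr

    coords = structure.coords_array() if hasattr(structure, "coords_array") else np.asarray(structure, dtype=float)
    if coords.shape != (n, 3):
        raise ValueError("structure and network atom sets differ")

    def diagnostics(x: np.ndarray) -> tuple[float, float]:
        report = check_constraints(x, network, templates, params, pinned=pinned)
        return report.max_covalent_deviation, report.min_nonbonded_gap

    def projection(x: np.ndarray) -> float:
        return float(np.sum((x - coords) * signed_field))

    frames = [coords.copy()]
    dev0, gap0 = diagnostics(coords)
    ens = ConformerEnsemble(
        frames=frames,
        frame_iterations=[0],
        amplitudes=[0.0],
        max_bond_deviation=[dev0],
        min_steric_gap=[gap0],
        termination="completed",
        mode_index=mode_index,
        direction=direction,
    )
    amplitude = 0.0
    history: list[float] = [0.0]
    last_valid = coords
    best_frame = coords
    it = 0
    for it in range(1, params.max_frames + 1):
        proposed = last_valid + step
        relaxed, ok = relaxer.relax(proposed)
        if not np.all(np.isfinite(relaxed)):
            raise FloatingPointError(f"NaN coordinates at iteration {it}")
        if not ok:
            ens.termination = "jammed"
            break
        last_valid = relaxed
        proj = projection(relaxed)
        if proj > amplitude:
            amplitude = proj
            best_frame = relaxed
        history.append(proj)
        if norm != 0.0 and len(history) > params.stall_window:
            gain = history[-1] - history[-1 - params.stall_window]
            if gain < params.stall_fraction * params.stall_window * collective_step:
                ens.termination = "jammed"
                break
        if it % params.frame_stride == 0:
            dev, gap = diagnostics(relaxed)
            ens.frames.append(relaxed.copy())
            ens.frame_iterations.append(it)
            ens.amplitudes.append(amplitude)
            ens.max_bond_deviation.append(dev)
            ens.min_steric_gap.append(gap)
    final = best_frame if ens.termination == "jammed" else last_valid
    if not np.array_equal(ens.frames[-1], final):
        dev, gap = diagnostics(final)
        ens.frames.append(final.copy())
        ens.frame_iterations.append(it)
        ens.amplitudes.append(amplitude)
        ens.max_bond_deviation.append(dev)
        ens.min_steric_gap.append(gap)
    elif ens.amplitudes[-1] != amplitude:
        ens.amplitudes[-1] = amplitude
    return ens


def select_extreme_variants(ensembles: Sequence[ConformerEnsemble]) -> list[Variant]:
    """Final valid frame of each (mode, direction) run; exactly two per mode."""
    seen: dict[tuple[int, int], ConformerEnsemble] = {}
    for ens in ensembles:
        seen[(ens.mode_index, ens.direction)] = ens
    modes = sorted({m for m, _ in seen})
    variants = []
    for m in modes:
        for direction in (1, -1):
            if (m, direction) not in seen:
                raise ValueError(f"missing ensemble for mode {m}, direction {direction:+d}")
            ens = seen[(m, direction)]
            variants.append(
                Variant(ens.final_frame.copy(), m, direction, ens.final_amplitude)
            )
    return variants


def check_constraints(
    conformer: np.ndarray,
    network: ConstraintNetwork,
    templates: Sequence[Template],
    params: SimParams | None = None,
    pinned: Sequence[int] = (),
) -> ViolationReport:
    """Measure how far a conformer strays from the constraint network.

    Covalent deviations are measured against the input-structure bond
    lengths, hbond/tether violations as the excess outside the ±tolerance
    window, and the steric gap as distance minus the scaled vdW floor over
    all non-excluded pairs.
    """
    params = params or SimParams()
    coords = np.asarray(conformer, dtype=float)
    n = len(network.atoms)
    if coords.shape != (n, 3):
        raise ValueError(f"conformer shape {coords.shape} != ({n}, 3)")
    coords0 = network.coords_array()
    tol = params.relax_tolerance

    max_cov = 0.0
    max_win = 0.0
    n_violations = 0
    for e in network.edges:
        d = float(np.linalg.norm(coords[e.i] - coords[e.j]))
        d0 = float(np.linalg.norm(coords0[e.i] - coords0[e.j]))
        if e.kind.startswith("covalent"):
            dev = abs(d - d0)
            max_cov = max(max_cov, dev)
            if dev > tol:
                n_violations += 1
        else:
            excess = max(0.0, abs(d - d0) - tol)
            max_win = max(max_win, excess)
            if excess > 1e-9:
                n_violations += 1

    relaxer = _Relaxer(network, templates, params, pinned=pinned)
    tree = cKDTree(coords)
    min_gap = np.inf
    for i, j in tree.query_pairs(relaxer.max_floor + 2.0):
        pair = (min(i, j), max(i, j))
        if pair in relaxer.excluded:
            continue
        gap = float(np.linalg.norm(coords[i] - coords[j]) - relaxer.pair_floor[i, j])
        min_gap = min(min_gap, gap)
        if gap < -tol:
            n_violations += 1
    if not np.isfinite(min_gap):
        min_gap = float(relaxer.max_floor)
    return ViolationReport(max_cov, max_win, min_gap, n_violations)
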