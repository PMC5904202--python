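"""Cα elastic-network normal modes (anisotropic network model).

One site per residue at the Cα position; identical springs between all site
pairs within a distance cutoff (default 12 Å, inclusive).  The Hessian's six
zero eigenvalues are the rigid-body motions of a connected network; the
low-frequency nontrivial eigenvectors (modes 7-16 by default) are the
collective motion directions fed to the geometric simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .structure_model import Structure, extract_calpha

__all__ = [
    "ENMParams",
    "ModeSet",
    "DisconnectedNetworkError",
    "build_hessian",
    "compute_modes",
    "calpha_modes",
    "expand_mode_to_atoms",
]

N_TRIVIAL = 6


class DisconnectedNetworkError(ValueError):
    """The spring network splits into several components."""


@dataclass(frozen=True)
class ENMParams:
    cutoff: float = 12.0
    spring_constant: float = 1.0
    n_nontrivial_modes: int = 10

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.n_nontrivial_modes < 1:
            raise ValueError("need at least one nontrivial mode")


@dataclass
class ModeSet:
    """Nontrivial normal modes: ascending eigenvalues, orthonormal vectors."""

    sites: list[tuple[str, int]]
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_modes, 3N), unit norm rows
    mode_indices: list[int]  # 1-based; 7.. for the default ten modes

    def mode(self, mode_index: int) -> np.ndarray:
        return self.eigenvectors[self.mode_indices.index(mode_index)]


def build_hessian(calpha_coords: np.ndarray, params: ENMParams | None = None) -> np.ndarray:
    """3N×3N anisotropic-network Hessian.

    The off-diagonal 3×3 block for a pair (i, j) within the cutoff is
    -k·r̂ᵢⱼr̂ᵢⱼᵀ; diagonal blocks accumulate the negated sum of the row's
    off-diagonal blocks, which makes every row sum to zero (translational
    invariance) and the matrix positive semi-definite.
    """
    params = params or ENMParams()
    x = np.asarray(calpha_coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 2:
        raise ValueError("need an (N>=2, 3) coordinate array")
    n = x.shape[0]
    dist = squareform(pdist(x))
    if np.any(dist[np.triu_indices(n, 1)] < 0.1):
        raise ValueError("coincident sites (distance < 0.1 A)")
    hessian = np.zeros((3 * n, 3 * n))
    within = (dist <= params.cutoff)
    for i in range(n):
        for j in range(i + 1, n):
            if not within[i, j]:
                continue
            rij = (x[j] - x[i]) / dist[i, j]
            block = -params.spring_constant * np.outer(rij, rij)
            hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
            hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
            hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return hessian


def _spring_components(hessian: np.ndarray) -> np.ndarray:
    n = hessian.shape[0] // 3
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] != 0.0):
                adj[i, j] = adj[j, i] = True
    _, labels = connected_components(adj, directed=False)
    return labels


def compute_modes(
    hessian: np.ndarray,
    params: ENMParams | None = None,
    sites: list[tuple[str, int]] | None = None,
) -> ModeSet:
    """Eigendecompose the Hessian and return the nontrivial low modes.

    Exactly six near-zero eigenvalues are required; more indicate a
    disconnected spring network and raise
    :class:`DisconnectedNetworkError` naming the components.  Each returned
    eigenvector's sign is fixed so its largest-magnitude component is
    positive.
    """
    params = params or ENMParams()
    h = np.asarray(hessian, dtype=float)
    if not np.allclose(h, h.T, atol=1e-10):
        raise ValueError("Hessian must be symmetric")
    n3 = h.shape[0]
    eigenvalues, eigenvectors = scipy.linalg.eigh(h)
    scale = eigenvalues[-1] if eigenvalues[-1] > 0 else 1.0
    zero_tol = max(1e-8 * scale, 1e-12)
    n_zero = int(np.sum(np.abs(eigenvalues) < zero_tol))
    if n_zero > N_TRIVIAL:
        labels = _spring_components(h)
        groups = [list(np.flatnonzero(labels == g)) for g in range(labels.max() + 1)]
        raise DisconnectedNetworkError(
            f"{n_zero} near-zero modes: spring network has {len(groups)} components {groups}"
        )
    if n_zero < N_TRIVIAL:
        raise ValueError(f"only {n_zero} near-zero modes; expected 6 rigid-body motions")
    last = min(N_TRIVIAL + params.n_nontrivial_modes, n3)
    picked = range(N_TRIVIAL, last)
    vectors = []
    for k in picked:
        v = eigenvectors[:, k].copy()
        imax = int(np.argmax(np.abs(v)))
        if v[imax] < 0:
            v = -v
        vectors.append(v / np.linalg.norm(v))
    return ModeSet(
        sites=sites or [],
        eigenvalues=eigenvalues[list(picked)].copy(),
        eigenvectors=np.array(vectors),
        mode_indices=[k + 1 for k in picked],
    )


def calpha_modes(structure: Structure, params: ENMParams | None = None) -> ModeSet:
    """Build the Cα network over all chains of a structure and solve it."""
    params = params or ENMParams()
    sites: list[tuple[str, int]] = []
    coords = []
    for chain in structure.protein_only().chains:
        trace = extract_calpha(structure, chain.chain_id)
        for seq, xyz in trace.entries:
            sites.append((chain.chain_id, seq))
            coords.append(xyz)
    hessian = build_hessian(np.array(coords), params)
    return compute_modes(hessian, params, sites=sites)


def expand_mode_to_atoms(
    mode: np.ndarray,
    sites: list[tuple[str, int]],
    atoms,
) -> np.ndarray:
    """Broadcast a Cα-site mode to a unit-norm per-atom displacement field.

    Every atom inherits its residue's Cα mode vector; a residue without a
    site is a mapping error.
    """
    mode = np.asarray(mode, dtype=float).reshape(len(sites), 3)
    site_index = {s: k for k, s in enumerate(sites)}
    field = np.empty((len(atoms), 3))
    for i, atom in enumerate(atoms):
        key = (atom.chain_id, atom.res_seq)
        if key not in site_index:
            raise KeyError(f"residue {key} has atoms but no Calpha site in the mode")
        field[i] = mode[site_index[key]]
    norm = np.linalg.norm(field)
    if norm == 0:
        raise ValueError("zero mode field")
    return field / norm
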