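"""Body-bar pebble-game rigidity analysis of the constraint network.

Each atom is a rigid body with 6 degrees of freedom; each constraint edge
contributes a fixed number of generic bars between its endpoints:

==================  ====
edge kind           bars
==================  ====
covalent_single        5
covalent_locked        6
hbond (post E_cut)     5
tether                 2
==================  ====

The (6, 6) pebble game (Lee & Streinu's family of (k, l) games, specialised
to body-bar frameworks, where it computes the generic rank of the body-bar
rigidity matroid) matches degrees of freedom against bars: every body starts
with six pebbles, a bar is independent iff seven pebbles can be gathered on
its endpoints, and each accepted bar consumes one pebble.  The free pebbles
left at the end count the floppy modes (including the six rigid-body motions
of each connected molecule); a failed seven-pebble search delimits a maximal
rigid component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .constraint_network import ConstraintNetwork, Edge, NetworkParams, apply_energy_cutoff, build_network
from .structure_model import Structure

__all__ = [
    "BAR_MULTIPLICITY",
    "PebbleGame",
    "RigidClusterDecomposition",
    "pebble_game",
    "rigidity_profile",
]

BODY_DOF = 6
BAR_MULTIPLICITY: dict[str, int] = {
    "covalent_single": 5,
    "covalent_locked": 6,
    "hbond": 5,
    "tether": 2,
}


@dataclass
class RigidClusterDecomposition:
    """Partition of atoms into rigid clusters plus the floppy-mode count."""

    cluster_of: dict[int, int]
    cluster_sizes: dict[int, int]
    floppy_modes: int
    rotatable_dihedrals: list[Edge]
    n_atoms: int

    @property
    def largest_cluster_fraction(self) -> float:
        if not self.cluster_sizes:
            return 0.0
        return max(self.cluster_sizes.values()) / self.n_atoms

    def atoms_in_cluster(self, cluster_id: int) -> list[int]:
        return [i for i, c in self.cluster_of.items() if c == cluster_id]


class PebbleGame:
    """The (6, 6) pebble game on a multigraph of bodies and bars."""

    def __init__(self, n_bodies: int):
        self.n = n_bodies
        self.pebbles = [BODY_DOF] * n_bodies
        # oriented bars: out[u][v] = number of bars directed u -> v
        self.out: list[dict[int, int]] = [dict() for _ in range(n_bodies)]

    # -- pebble search ------------------------------------------------------

    def _find_pebble(self, root: int, exclude: tuple[int, int]) -> bool:
        """DFS from ``root`` for a free pebble outside ``exclude``; on success
        move it to ``root`` by reversing the path."""
        stack = [root]
        parent: dict[int, int] = {root: -1}
        while stack:
            u = stack.pop()
            for w in self.out[u]:
                if w in parent:
                    continue
                parent[w] = u
                if self.pebbles[w] > 0 and w not in exclude:
                    # reverse the path root ... w
                    node = w
                    while parent[node] != -1:
                        p = parent[node]
                        self.out[p][node] -= 1
                        if self.out[p][node] == 0:
                            del self.out[p][node]
                        self.out[node][p] = self.out[node].get(p, 0) + 1
                        node = p
                    self.pebbles[w] -= 1
                    self.pebbles[root] += 1
                    return True
                stack.append(w)
        return False

    def _gather(self, u: int, v: int, target: int) -> bool:
        """Try to accumulate ``target`` pebbles on {u, v}."""
        while self.pebbles[u] + self.pebbles[v] < target:
            if not (self._find_pebble(u, (u, v)) or self._find_pebble(v, (u, v))):
                return False
        return True

    def insert_bar(self, u: int, v: int) -> bool:
        """Insert one bar; returns False when the bar is redundant."""
        if u == v:
            raise ValueError("self-bar")
        if not self._gather(u, v, BODY_DOF + 1):
            return False
        if self.pebbles[u] == 0:
            u, v = v, u
        self.pebbles[u] -= 1
        self.out[u][v] = self.out[u].get(v, 0) + 1
        return True

    # -- queries ------------------------------------------------------------

    def free_pebbles(self) -> int:
        return sum(self.pebbles)

    def rigid_component(self, u: int, v: int) -> frozenset[int] | None:
        """The maximal rigid component containing edge (u, v), or None.

        The pair is mutually rigid iff only six pebbles can be gathered on
        it; the bodies swept by the failed search (those that cannot hand
        over a pebble) form the component.
        """
        if self._gather(u, v, BODY_DOF + 1):
            return None
        # failed search: everything reachable from u or v holds no free pebble
        reached = {u, v}
        stack = [u, v]
        while stack:
            x = stack.pop()
            for w in self.out[x]:
                if w not in reached:
                    reached.add(w)
                    stack.append(w)
        return frozenset(r for r in reached if self.pebbles[r] == 0 or r in (u, v))


def pebble_game(network: ConstraintNetwork) -> RigidClusterDecomposition:
    """Run the body-bar pebble game and decompose into rigid clusters.

    Clusters are labelled by decreasing size, ties broken by the smallest
    member atom serial; every atom belongs to exactly one cluster (atoms
    shared between overlapping rigid components are assigned to the larger
    one, matching the usual rigid-cluster reports).
    """
    n = len(network.atoms)
    if n == 0:
        raise ValueError("empty network")
    game = PebbleGame(n)
    for edge in sorted(network.edges, key=lambda e: e.pair):
        bars = BAR_MULTIPLICITY[edge.kind]
        if bars < 0:
            raise ValueError(f"negative bar multiplicity for {edge.kind}")
        for _ in range(bars):
            game.insert_bar(edge.i, edge.j)
    floppy = game.free_pebbles()

    # mutual rigidity is an equivalence relation on 6-dof bodies (if u~v and
    # v~w, the relative motions u-w vanish too), so testing each edge's
    # endpoint pair and union-finding gives the maximal rigid clusters
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rotatable: list[Edge] = []
    rigid_pair: dict[tuple[int, int], bool] = {}
    for edge in sorted(network.edges, key=lambda e: e.pair):
        pair = edge.pair
        if pair not in rigid_pair:
            if find(pair[0]) == find(pair[1]):
                rigid_pair[pair] = True
            else:
                rigid_pair[pair] = game.rigid_component(edge.i, edge.j) is not None
                if rigid_pair[pair]:
                    parent[find(pair[0])] = find(pair[1])
        if edge.kind == "covalent_single" and not rigid_pair[pair]:
            rotatable.append(edge)

    classes: dict[int, list[int]] = {}
    for i in range(n):
        classes.setdefault(find(i), []).append(i)
    serial = [a.serial for a in network.atoms]
    ordered = sorted(classes.values(), key=lambda c: (-len(c), min(serial[i] for i in c)))
    cluster_of: dict[int, int] = {}
    cluster_sizes: dict[int, int] = {}
    for cid, members in enumerate(ordered):
        for i in members:
            cluster_of[i] = cid
        cluster_sizes[cid] = len(members)
    return RigidClusterDecomposition(cluster_of, cluster_sizes, floppy, rotatable, n)


def rigidity_profile(
    structure: Structure,
    params: NetworkParams | None = None,
    e_cut_values: Iterable[float] = (-2.0, -3.0),
) -> list[dict]:
    """Rigid-cluster summaries of one structure at several energy cutoffs."""
    params = params or NetworkParams()
    network = build_network(structure, params)
    rows = []
    for e_cut in e_cut_values:
        if e_cut > 0:
            raise ValueError("e_cut values must be <= 0")
        decomp = pebble_game(apply_energy_cutoff(network, e_cut))
        rows.append(
            {
                "e_cut": e_cut,
                "floppy_modes": decomp.floppy_modes,
                "largest_cluster_fraction": decomp.largest_cluster_fraction,
                "n_clusters": len(decomp.cluster_sizes),
                "n_hbonds": sum(
                    1 for e in apply_energy_cutoff(network, e_cut).edges if e.kind == "hbond"
                ),
            }
        )
    return rows
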