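"""Loop apex-amplitude measurement over generated conformer ensembles.

Generated variants are aligned, chain by chain, onto the crystal reference
using only the *stable base* — the N-terminal-domain residues (6-110 by
default) minus the loop intervals — so that loop excursions are measured
relative to a fixed frame rather than absorbed into the fit.  Each loop's
apex is the Cα of the median residue of its range, and the reported
amplitude is the maximum pairwise apex distance across the reference plus
all variants.  A Table-style report aggregates per-structure and per-loop
means.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median_low
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crystal_compare import kabsch_superpose
from .structure_model import LoopDefinition, Structure

__all__ = [
    "StableBase",
    "AmplitudeReport",
    "stable_base",
    "align_on_stable_base",
    "apex_residue",
    "apex_amplitude",
    "amplitude_report",
]

DEFAULT_BASE_RANGE = (6, 110)


@dataclass(frozen=True)
class StableBase:
    """Per-chain alignment residues: a base interval minus the loop ranges."""

    residues_by_chain: tuple[tuple[str, tuple[int, ...]], ...]

    def residues(self, chain_id: str) -> tuple[int, ...]:
        for cid, res in self.residues_by_chain:
            if cid == chain_id:
                return res
        raise KeyError(f"no stable base defined for chain {chain_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.residues_by_chain]


def stable_base(
    loops: Sequence[LoopDefinition],
    base_range: tuple[int, int] = DEFAULT_BASE_RANGE,
) -> StableBase:
    """Non-loop residues of the base interval, per chain appearing in loops."""
    chains = sorted({lp.chain_id for lp in loops})
    per_chain = []
    for cid in chains:
        loop_res = {r for lp in loops if lp.chain_id == cid for r in lp.residues()}
        keep = tuple(r for r in range(base_range[0], base_range[1] + 1) if r not in loop_res)
        if not keep:
            raise ValueError(f"chain {cid}: stable base empty after removing loops")
        per_chain.append((cid, keep))
    return StableBase(tuple(per_chain))


def _chain_ca_indices(reference: Structure, chain_id: str, residues: Sequence[int]) -> list[int]:
    """Flat atom indices (structure iteration order) of the chain's base CAs."""
    wanted = set(residues)
    idx = []
    for i, atom in enumerate(reference.atoms()):
        if atom.chain_id == chain_id and atom.name == "CA" and atom.res_seq in wanted:
            idx.append(i)
    return idx


def align_on_stable_base(
    variants: Sequence[np.ndarray],
    reference: Structure,
    chain_id: str,
    base: StableBase,
) -> list[np.ndarray]:
    """Superpose each variant coordinate set onto the reference base CAs.

    Variants are full-structure coordinate arrays in the reference's atom
    order; the fit uses only the stable-base Cα atoms of ``chain_id``, and
    the returned arrays have the whole structure transformed accordingly
    (per-chain alignment is achieved by calling this once per chain and
    measuring that chain's loops on the matching result).
    """
    idx = _chain_ca_indices(reference, chain_id, base.residues(chain_id))
    if len(idx) < 3:
        raise ValueError(f"chain {chain_id}: fewer than 3 stable-base CA atoms")
    ref_xyz = reference.coords_array()
    aligned = []
    for v in variants:
        v = np.asarray(v, dtype=float)
        if v.shape != ref_xyz.shape:
            raise ValueError("variant atom count differs from reference")
        sup = kabsch_superpose(v[idx], ref_xyz[idx])
        aligned.append(sup.transform(v))
    return aligned


def apex_residue(loop: LoopDefinition) -> int:
    """The median residue of the loop range (lower median for even length)."""
    return median_low(loop.residues())


def apex_amplitude(
    aligned_variants: Sequence[np.ndarray],
    reference: Structure,
    loop: LoopDefinition,
    mode: str = "max_pairwise",
) -> float:
    """Maximal apex excursion of one loop across reference + variants.

    ``mode='max_pairwise'`` (default) is the maximum apex-apex distance over
    all conformer pairs; ``mode='max_from_reference'`` measures only
    excursions from the crystal structure.
    """
    apex_seq = apex_residue(loop)
    idx = _chain_ca_indices(reference, loop.chain_id, [apex_seq])
    if not idx:
        raise ValueError(f"loop {loop.loop_name}: apex residue {apex_seq} has no CA")
    i = idx[0]
    positions = [reference.coords_array()[i]]
    positions += [np.asarray(v, dtype=float)[i] for v in aligned_variants]
    pts = np.array(positions)
    if mode == "max_pairwise":
        diff = pts[:, None, :] - pts[None, :, :]
        return float(np.sqrt((diff ** 2).sum(axis=2)).max())
    if mode == "max_from_reference":
        return float(np.linalg.norm(pts[1:] - pts[0], axis=1).max()) if len(pts) > 1 else 0.0
    raise ValueError(f"unknown amplitude mode {mode!r}")


@dataclass
class AmplitudeReport:
    """Per-(structure, loop) amplitudes with per-structure and per-loop means."""

    table: pd.DataFrame  # rows: loop names; columns: structure ids
    mode: str = "max_pairwise"

    @property
    def per_structure_mean(self) -> pd.Series:
        return self.table.mean(axis=0)

    @property
    def per_loop_mean(self) -> pd.Series:
        return self.table.mean(axis=1)

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        out = self.table.copy()
        out.loc["mean"] = self.per_structure_mean
        out["mean"] = out.mean(axis=1)
        out.loc[out.index != "mean", "mean"] = self.per_loop_mean
        return out.round(decimals)

    def to_tsv(self, path) -> None:
        self.rounded().to_csv(path, sep="\t", index_label=f"loop (amplitude mode: {self.mode})")


def amplitude_report(
    amplitudes: Mapping[str, Mapping[str, float]],
    mode: str = "max_pairwise",
) -> AmplitudeReport:
    """Assemble {structure id -> {loop name -> amplitude}} into a report.

    Every structure must provide the same full loop set; amplitudes must be
    non-negative.
    """
    df = pd.DataFrame(amplitudes)
    if df.isna().any().any():
        missing = [(i, c) for c in df.columns for i in df.index[df[c].isna()]]
        raise ValueError(f"missing loop amplitudes: {missing}")
    if (df.values < 0).any():
        raise ValueError("amplitudes must be non-negative")
    return AmplitudeReport(df, mode)
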