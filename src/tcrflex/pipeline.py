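"""End-to-end orchestration: multi-crystal comparison and the flexibility
pipeline (network → rigidity → modes → simulation → loop report).

Each stage writes plain-text artifacts (TSV/CSV tables, multi-MODEL PDB
ensembles) into an output directory together with a run log recording every
parameter, seed, and input checksum, so a run can be reproduced from its log
alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import crystal_compare as cc
from . import loop_analysis as la
from .constraint_network import NetworkParams, apply_energy_cutoff, build_network
from .enm import ENMParams, calpha_modes, expand_mode_to_atoms
from .geomsim import (
    SimParams,
    build_templates,
    run_geometric_simulation,
    select_extreme_variants,
)
from .rigidity import pebble_game
from .structure_model import LoopDefinition, Structure, write_pdb

__all__ = ["PipelineConfig", "FlexResult", "CompareResult", "cmd_compare", "cmd_flex",
           "load_config", "network_structure"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings; the defaults are the analysis conditions
    (E_cut -3 kcal/mol, 12 Å elastic-network cutoff, 10 nontrivial modes,
    2000-frame cap, 4.0 Å lattice contacts)."""

    e_cut: float = -3.0
    contact_cutoff: float = 4.0
    network: NetworkParams = field(default_factory=NetworkParams)
    enm: ENMParams = field(default_factory=ENMParams)
    sim: SimParams = field(default_factory=SimParams)
    amplitude_mode: str = "max_pairwise"
    base_range: tuple[int, int] = la.DEFAULT_BASE_RANGE
    seed: int = 0


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a flat key=value config file; keyword overrides win."""
    values: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected key=value")
        key, val = (s.strip() for s in line.split("=", 1))
        values[key] = val
    cfg = PipelineConfig()
    simple = {
        "e_cut": float, "contact_cutoff": float, "amplitude_mode": str, "seed": int,
    }
    kwargs: dict = {}
    for key, val in values.items():
        if key in simple:
            kwargs[key] = simple[key](val)
        elif key == "enm_cutoff":
            kwargs.setdefault("enm", {})["cutoff"] = float(val)
        elif key == "n_modes":
            kwargs.setdefault("enm", {})["n_nontrivial_modes"] = int(val)
        elif key in ("step_size", "relax_tolerance", "steric_scale"):
            kwargs.setdefault("sim", {})[key] = float(val)
        elif key in ("max_frames", "max_relax_iters", "frame_stride"):
            kwargs.setdefault("sim", {})[key] = int(val)
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    kwargs.update(overrides)
    if isinstance(kwargs.get("enm"), dict):
        kwargs["enm"] = replace(cfg.enm, **kwargs["enm"])
    if isinstance(kwargs.get("sim"), dict):
        kwargs["sim"] = replace(cfg.sim, **kwargs["sim"])
    return replace(cfg, **kwargs)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_log(outdir: Path, stage: str, config: PipelineConfig,
               inputs: dict[str, str], extra: dict) -> None:
    log = {
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "inputs": inputs,
        **extra,
    }
    (outdir / f"{stage}_run_log.json").write_text(json.dumps(log, indent=2))


def network_structure(structure: Structure) -> Structure:
    """Protein-only, hydrogen-free copy whose atom order matches the
    constraint network built from it."""
    st = structure.protein_only().copy()
    for chain in st.chains:
        for res in chain.residues:
            res.atoms = [a for a in res.atoms if a.element.upper() not in ("H", "D")]
    return st


@dataclass
class CompareResult:
    shift_matrices: dict[str, np.ndarray]
    extreme_pairs: dict[str, tuple[int, int]]
    max_shift_loop: str
    max_shift: float
    contact_freedom: dict[str, dict[str, tuple[bool, int]]] | None


def cmd_compare(
    structures: Sequence[Structure],
    loops: Sequence[LoopDefinition],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    operators_by_structure: dict[str, list] | None = None,
    input_paths: Sequence[str] = (),
) -> CompareResult:
    """Pairwise loop-shift analysis over same-protein crystal structures,
    plus lattice-contact freedom where cell metadata and operators allow."""
    config = config or PipelineConfig()
    if len(structures) < 2:
        raise ValueError("need at least 2 structures to compare")
    base = la.stable_base(loops, config.base_range)
    matrices: dict[str, np.ndarray] = {}
    extremes: dict[str, tuple[int, int]] = {}
    for loop in loops:
        fit_sel = base.residues(loop.chain_id)
        mat, pair = cc.pairwise_loop_shift_matrix(structures, loop, fit_sel)
        matrices[loop.loop_name] = mat
        extremes[loop.loop_name] = pair

    contact_freedom = None
    if operators_by_structure:
        contact_freedom = {}
        for st in structures:
            ops = operators_by_structure.get(st.id)
            if ops is None and st.space_group:
                ops = cc.space_group_operators(st.space_group)
            if ops is None or st.cell is None:
                continue
            contacts = cc.find_crystal_contacts(st, ops, cutoff=config.contact_cutoff)
            contact_freedom[st.id] = cc.loop_contact_freedom(contacts, loops)

    max_loop = max(matrices, key=lambda name: matrices[name].max())
    result = CompareResult(
        matrices, extremes, max_loop, float(matrices[max_loop].max()), contact_freedom
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ids = [st.id for st in structures]
        for name, mat in matrices.items():
            pd.DataFrame(mat, index=ids, columns=ids).to_csv(
                outdir / f"loop_shift_{name}.csv"
            )
        if contact_freedom is not None:
            rows = [
                {"structure": sid, "loop": loop, "free": free, "n_contacts": n}
                for sid, per_loop in contact_freedom.items()
                for loop, (free, n) in per_loop.items()
            ]
            pd.DataFrame(rows).to_csv(outdir / "contact_freedom.tsv", sep="\t", index=False)
        summary = pd.DataFrame(
            [
                {
                    "loop": name,
                    "max_shift_A": matrices[name].max(),
                    "extreme_i": ids[extremes[name][0]],
                    "extreme_j": ids[extremes[name][1]],
                }
                for name in matrices
            ]
        )
        summary.to_csv(outdir / "shift_summary.tsv", sep="\t", index=False)
        _write_log(
            outdir, "compare", config,
            {p: _checksum(p) for p in input_paths},
            {"max_shift_loop": max_loop, "max_shift_A": result.max_shift},
        )
    return result


@dataclass
class FlexResult:
    reference: Structure
    variants: list
    report: la.AmplitudeReport
    rigidity_summary: dict
    jammed_modes: list[tuple[int, int]]


def cmd_flex(
    structure: Structure,
    loops: Sequence[LoopDefinition],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    input_paths: Sequence[str] = (),
) -> FlexResult:
    """Full flexibility pipeline on one structure.

    Builds the constraint network at E_cut, decomposes it with the pebble
    game, computes the low-frequency Cα modes, runs the geometric simulation
    parallel and antiparallel to each mode, aligns the resulting variants on
    the stable base, and reports per-loop apex amplitudes.
    """
    config = config or PipelineConfig()
    ref = network_structure(structure)
    network = apply_energy_cutoff(build_network(ref, config.network), config.e_cut)
    decomposition = pebble_game(network)
    templates = build_templates(ref, decomposition, network)
    modes = calpha_modes(ref, config.enm)

    ensembles = []
    jammed = []
    for mode_index in modes.mode_indices:
        field_atoms = expand_mode_to_atoms(modes.mode(mode_index), modes.sites, network.atoms)
        for direction in (1, -1):
            ens = run_geometric_simulation(
                ref, templates, network, field_atoms, direction,
                config.sim, mode_index=mode_index,
            )
            ensembles.append(ens)
            if ens.termination == "jammed":
                jammed.append((mode_index, direction))
    variants = select_extreme_variants(ensembles)

    base = la.stable_base(loops, config.base_range)
    amplitudes: dict[str, dict[str, float]] = {ref.id: {}}
    variant_coords = [v.coords for v in variants]
    for chain_id in base.chain_ids:
        aligned = la.align_on_stable_base(variant_coords, ref, chain_id, base)
        for loop in loops:
            if loop.chain_id != chain_id:
                continue
            amplitudes[ref.id][loop.loop_name] = la.apex_amplitude(
                aligned, ref, loop, mode=config.amplitude_mode
            )
    report = la.amplitude_report(amplitudes, mode=config.amplitude_mode)
    rigidity_summary = {
        "floppy_modes": decomposition.floppy_modes,
        "n_clusters": len(decomposition.cluster_sizes),
        "largest_cluster_fraction": decomposition.largest_cluster_fraction,
    }
    result = FlexResult(ref, variants, report, rigidity_summary, jammed)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_tsv(outdir / "amplitude_report.tsv")
        write_pdb(ref, outdir / "variants.pdb", multi_model=[v.coords for v in variants])
        diag = pd.DataFrame(
            [
                {
                    "mode": e.mode_index,
                    "direction": e.direction,
                    "termination": e.termination,
                    "amplitude": e.final_amplitude,
                    "iterations": e.frame_iterations[-1],
                }
                for e in ensembles
            ]
        )
        diag.to_csv(outdir / "simulation_summary.tsv", sep="\t", index=False)
        _write_log(
            outdir, "flex", config,
            {p: _checksum(p) for p in input_paths},
            {
                "structure": ref.id,
                "rigidity": rigidity_summary,
                "jammed": jammed,
                "n_variants": len(variants),
            },
        )
    return result
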