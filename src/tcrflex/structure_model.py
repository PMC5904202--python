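"""All-atom structural data model and PDB-format I/O.

The in-memory model is deliberately thin: a :class:`Structure` is an ordered
list of chains, each an ordered list of residues holding :class:`Atom` records
with Cartesian coordinates in Angstroms.  Unit-cell and space-group metadata
from the CRYST1 record are kept so that lattice-contact analysis can
reconstruct the crystal environment.  Reading and writing go through gemmi;
this module adds the conventions the downstream analysis relies on:

* alternate locations are collapsed to the highest-occupancy conformer
  (ties resolved in file order), so every downstream stage sees a single
  conformer per atom;
* residue numbering is taken verbatim from the file (loop definitions use
  author numbering);
* waters and non-amino-acid heteroatoms can be stripped with
  :meth:`Structure.protein_only` before rigidity/simulation stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "LoopDefinition",
    "CalphaTrace",
    "PDBFormatError",
    "EmptyStructureError",
    "read_pdb",
    "write_pdb",
    "extract_calpha",
    "read_loop_table",
]

#: Three-letter codes treated as protein residues.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "MSE", "PHE", "PRO", "SER", "THR", "TRP", "TYR",
    "VAL",
}


class PDBFormatError(ValueError):
    """A coordinate record could not be parsed (message names the line)."""


class EmptyStructureError(ValueError):
    """The file contained no ATOM records."""


@dataclass
class Atom:
    """One atom record: identity, position and crystallographic attributes."""

    serial: int
    name: str
    element: str
    alt_loc: str
    chain_id: str
    res_name: str
    res_seq: int
    insertion_code: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element symbol required")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Unique atom key within a structure: (chain, res_seq, icode, name)."""
        return (self.chain_id, self.res_seq, self.insertion_code, self.name)


@dataclass
class Residue:
    res_name: str
    res_seq: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_protein(self) -> bool:
        return self.res_name in AMINO_ACIDS

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, res_seq: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.res_seq == res_seq and r.insertion_code == insertion_code:
                return r
        return None


@dataclass
class Structure:
    """An all-atom model with optional crystal metadata."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"structure {self.id!r} has no chain {chain_id!r}")

    def atoms(self) -> Iterator[Atom]:
        for c in self.chains:
            for r in c.residues:
                yield from r.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def coords_array(self) -> np.ndarray:
        """(N, 3) coordinate array in atom iteration order."""
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        atoms = list(self.atoms())
        if coords.shape != (len(atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match {len(atoms)} atoms"
            )
        for atom, xyz in zip(atoms, coords):
            atom.coords = xyz.copy()

    def protein_only(self) -> "Structure":
        """Copy without waters and non-amino-acid heteroatom residues."""
        chains = []
        for c in self.chains:
            residues = [
                Residue(r.res_name, r.res_seq, r.insertion_code, list(r.atoms))
                for r in c.residues
                if r.is_protein
            ]
            if residues:
                chains.append(Chain(c.chain_id, residues))
        return Structure(self.id, chains, self.cell, self.space_group)

    def copy(self) -> "Structure":
        chains = [
            Chain(
                c.chain_id,
                [
                    Residue(
                        r.res_name,
                        r.res_seq,
                        r.insertion_code,
                        [
                            Atom(
                                a.serial, a.name, a.element, a.alt_loc,
                                a.chain_id, a.res_name, a.res_seq,
                                a.insertion_code, a.coords.copy(),
                                a.occupancy, a.b_factor,
                            )
                            for a in r.atoms
                        ],
                    )
                    for r in c.residues
                ],
            )
            for c in self.chains
        ]
        return Structure(self.id, chains, self.cell, self.space_group)

    def validate(self) -> None:
        """Check uniqueness and ordering invariants; raise ValueError on breach."""
        seen: set[tuple] = set()
        for c in self.chains:
            order = [(r.res_seq, r.insertion_code) for r in c.residues]
            if order != sorted(order):
                raise ValueError(f"chain {c.chain_id}: residues not ordered by (res_seq, icode)")
            for r in c.residues:
                for a in r.atoms:
                    k = (c.chain_id, r.res_seq, r.insertion_code, a.name, a.alt_loc)
                    if k in seen:
                        raise ValueError(f"duplicate atom {k}")
                    seen.add(k)


@dataclass(frozen=True)
class LoopDefinition:
    """A named loop: an inclusive author-numbered residue interval on one chain."""

    loop_name: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"loop {self.loop_name}: empty range {self.start}-{self.end}")

    def residues(self) -> range:
        return range(self.start, self.end + 1)

    def contains(self, chain_id: str, res_seq: int) -> bool:
        return chain_id == self.chain_id and self.start <= res_seq <= self.end


class CalphaTrace(NamedTuple):
    """Ordered Cα positions of a chain plus residues lacking a CA atom."""

    entries: list[tuple[int, np.ndarray]]
    missing: list[int]

    def coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.entries], dtype=float)


# ---------------------------------------------------------------------------
# I/O


def _scan_pdb_lines(path: Path) -> int:
    """Validate coordinate fields line by line; return the ATOM/HETATM count."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            n += 1
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fld = line[lo:hi].strip()
                try:
                    float(fld)
                except ValueError:
                    raise PDBFormatError(
                        f"{path}: line {lineno}: unparsable {what} coordinate {fld!r}"
                    ) from None
    return n


def _pick_alt_conformer(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties keep the first encountered
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    All ATOM/HETATM records of the first model are kept; alternate locations
    are reduced to the highest-occupancy conformer per atom name.  CRYST1
    cell parameters and the Hermann-Mauguin space-group symbol are attached
    when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_atom_records = _scan_pdb_lines(path)
    if n_atom_records == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")

    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    cell = None
    space_group = None
    if st.cell.is_crystal() and st.cell.a > 1.0:
        cell = (st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    if st.spacegroup_hm:
        space_group = st.spacegroup_hm

    out = Structure(path.stem, cell=cell, space_group=space_group)
    model = st[0]
    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            res = Residue(gres.name, gres.seqid.num, (gres.seqid.icode or " ").strip())
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            for name, alts in by_name.items():
                ga = _pick_alt_conformer(alts)
                res.atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=name,
                        element=ga.element.name or "X",
                        alt_loc=(ga.altloc or "").strip(),
                        chain_id=chain.chain_id,
                        res_name=res.res_name,
                        res_seq=res.res_seq,
                        insertion_code=res.insertion_code,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        b_factor=ga.b_iso,
                    )
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    return out


_COORD_LIMIT = 10_000.0  # PDB %8.3f field width


def write_pdb(
    structure: Structure,
    path: str | Path,
    multi_model: Sequence[np.ndarray] | None = None,
) -> None:
    """Write fixed-column PDB records.

    With ``multi_model``, each (N, 3) coordinate set is emitted as one
    MODEL/ENDMDL block over the same atom list.
    """
    atoms = list(structure.atoms())
    conformers: list[np.ndarray]
    if multi_model is None:
        conformers = [structure.coords_array()]
    else:
        conformers = [np.asarray(c, dtype=float) for c in multi_model]
        for i, c in enumerate(conformers):
            if c.shape != (len(atoms), 3):
                raise ValueError(f"conformer {i}: shape {c.shape} != ({len(atoms)}, 3)")
    for c in conformers:
        if np.any(np.abs(c) >= _COORD_LIMIT):
            raise OverflowError("coordinate magnitude exceeds PDB field width")

    st = gemmi.Structure()
    st.name = structure.id
    if structure.cell is not None:
        st.cell = gemmi.UnitCell(*structure.cell)
    if structure.space_group is not None:
        st.spacegroup_hm = structure.space_group

    for imodel, coords in enumerate(conformers, start=1):
        model = gemmi.Model(imodel)
        i = 0
        for chain in structure.chains:
            gchain = gemmi.Chain(chain.chain_id)
            for res in chain.residues:
                gres = gemmi.Residue()
                gres.name = res.res_name
                gres.seqid = gemmi.SeqId(res.res_seq, res.insertion_code or " ")
                gres.het_flag = "A" if res.is_protein else "H"
                for atom in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element)
                    ga.pos = gemmi.Position(*coords[i])
                    ga.occ = atom.occupancy
                    ga.b_iso = atom.b_factor
                    ga.serial = atom.serial
                    gres.add_atom(ga)
                    i += 1
                gchain.add_residue(gres)
            model.add_chain(gchain)
        st.add_model(model)
    doc = st.make_pdb_string()
    if multi_model is None:
        # single-conformer output carries no MODEL records
        doc = "\n".join(
            ln for ln in doc.splitlines() if not ln.startswith(("MODEL", "ENDMDL"))
        ) + "\n"
    Path(path).write_text(doc)


def extract_calpha(
    structure: Structure,
    chain_id: str,
    residue_range: tuple[int, int] | None = None,
) -> CalphaTrace:
    """Ordered (res_seq, Cα position) entries for one chain.

    Residues without a CA atom are skipped and reported in ``missing``.
    ``residue_range`` is an inclusive author-numbered interval.
    """
    chain = structure.chain(chain_id)
    entries: list[tuple[int, np.ndarray]] = []
    missing: list[int] = []
    for res in chain.residues:
        if residue_range is not None and not residue_range[0] <= res.res_seq <= residue_range[1]:
            continue
        if not res.is_protein:
            continue
        ca = res.atom("CA")
        if ca is None:
            missing.append(res.res_seq)
        else:
            entries.append((res.res_seq, ca.coords.copy()))
    return CalphaTrace(entries, missing)


def read_loop_table(path: str | Path) -> list[LoopDefinition]:
    """Read loop definitions from TSV: loop_name, chain_id, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str})
    required = {"loop_name", "chain_id", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"loop table must have columns {sorted(required)}")
    return [
        LoopDefinition(row.loop_name, row.chain_id, int(row.start), int(row.end))
        for row in df.itertuples()
    ]
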