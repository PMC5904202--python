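# Methods

This note documents the models and numerical choices behind `tcrflex`, in
the order the pipeline runs them: structure handling, multi-crystal
comparison, constraint-network construction, pebble-game rigidity analysis,
Cα elastic-network modes, mode-biased geometric simulation, and loop
apex-amplitude reporting. It also documents what the synthetic fixtures do
and do not emulate.

## Structural model and conventions

Structures are read from PDB files through gemmi. Alternate conformations
are collapsed to the highest-occupancy conformer per atom (ties keep the
first in file order) so that every downstream stage sees a single,
deterministic conformer. Residue numbering is taken verbatim from the file:
loop definitions use author numbering, supplied as a TSV
(`loop_name  chain_id  start  end`, inclusive bounds). Waters and
non-amino-acid heteroatoms are stripped, and hydrogens (absent from the
X-ray models this pipeline targets) are ignored, before any network or
simulation stage.

## Multi-crystal comparison

Superposition is a standard Kabsch least-squares fit (SVD with the
determinant correction, so the result is always a proper rotation).
Per-residue displacement profiles fit two structures on a chosen framework
selection — by default the *stable base*, residues 6–110 of each chain minus
the loop intervals — and then measure Cα distances over the loops only.
"Shifts up to X Å" are maxima over all structure pairs and all loop
residues of these displacements.

Lattice contacts are defined as any interatomic distance strictly below
4.0 Å between the asymmetric unit and a symmetry or lattice translate of
itself. Space-group operators come from the standard Hermann–Mauguin table
(via gemmi); non-standard settings can be supplied as explicit operator
triplets. The translation search covers ±1 cell along each axis, which is
sufficient because a 4 Å contact cannot span more than one cell at these
cell dimensions. Contacts are deduplicated so each physical contact appears
once: the pair of asymmetric-unit atom indices is canonicalised as an
unordered pair and two records are considered the same contact when their
distances agree to 1e-6 Å (the two orientations of one physical contact
have identical distance; distinct contacts between the same atom pair
through different images differ in distance). A loop is "free of lattice
contacts" iff no contact touches any atom of any residue in its range, on
either side of the contact.

## Constraint network

Heavy atoms are vertices; edges come in four kinds.

**Covalent bonds** are taken from per-residue templates plus peptide bonds
(C–N < 1.7 Å between consecutive residues) and disulfides (SG–SG < 2.3 Å).
Bonds with no rotational freedom — peptide bonds, carbonyls, carboxylates,
guanidinium and amide groups, aromatic-ring bonds — are labelled *locked*;
all others are rotatable single bonds.

**Hydrogen bonds and salt bridges** are scored from heavy-atom geometry on
a 0 to −10 kcal/mol scale:

    E = −10 · f_dist(d) · f_ang(θ)

with `f_dist = max(0, 1 − ((d − d₀)/0.6)²)`, a clamped parabolic well
centred at d₀ = 2.9 Å (donor–acceptor distance; value 1 at d₀, 0 at
d₀ ± 0.6), and `f_ang = cos²θ′`, zero beyond 60°, where θ′ is the deviation
of the antecedent–donor–acceptor angle from 120°. Because the models carry
no hydrogens, donor linearity must be judged through the donor's covalent
antecedent: for an sp²/sp³ donor, a linear D–H···A arrangement puts the
antecedent at roughly 120° from the acceptor, which is why 120° — not
180° — is the ideal of this heavy-atom proxy. When a donor has several
covalent antecedents, the most favourable one is used. Salt bridges
(Arg/Lys donors against Asp/Glu carboxylates) use d₀ = 3.0 Å and receive a
20% depth bonus capped at the −10 floor. Pairs that are covalently bonded,
1–3 bonded, or within one residue are never scored.

The exact functional form is this package's own choice; only its range
(0 to −10 kcal/mol) and the cutoff semantics are inherited from the
rigidity-analysis literature the method follows. The energy cutoff E_cut
(default −3.0 kcal/mol) then retains hydrogen bonds with `E ≤ E_cut`
(boundary inclusive); covalent bonds and tethers always remain. Lowering
E_cut removes edges monotonically.

**Hydrophobic tethers** connect carbon/sulfur atoms of different residues
closer than the van der Waals sum plus 0.25 Å (radii: C 1.70, S 1.80,
N 1.55, O 1.52 Å), excluding 1–2/1–3 pairs.

## Pebble-game rigidity

Each atom is a rigid body with 6 degrees of freedom; each edge contributes
generic bars: 5 for a rotatable covalent bond (one dihedral left), 6 for a
locked bond, 5 for a retained hydrogen bond, 2 for a tether. The (6,6)
pebble game computes the generic rank of this body-bar matroid: every body
starts with six pebbles, a bar is accepted iff seven pebbles can be
gathered on its endpoints, each accepted bar consumes one pebble. Free
pebbles left at the end are the floppy modes (including the six rigid-body
motions of each connected component).

Rigid clusters exploit the fact that mutual rigidity is an equivalence
relation on 6-dof bodies: each edge's endpoint pair is tested (a failed
seven-pebble search means the pair is mutually rigid) and pairs are merged
by union–find. Clusters are labelled by decreasing size with ties broken by
the smallest member atom serial, so reports are reproducible. A rotatable
covalent bond whose endpoints do not share a cluster is an independent
rotatable dihedral. The implementation is validated against an independent
oracle: the numerical rank of an explicitly constructed generic body-bar
rigidity matrix (random bar attachment points, one row per bar) on random
multigraphs of up to 12 bodies, for both floppy-mode counts and pairwise
rigidity decisions.

## Elastic-network modes

One site per residue at the Cα position; identical springs (k = 1,
arbitrary units — only mode shapes are used downstream) between all site
pairs within 12 Å (inclusive), over all chains as one network. The
anisotropic-network Hessian has off-diagonal blocks −k·r̂r̂ᵀ and diagonal
blocks that make every row sum to zero. A connected network has exactly six
zero eigenvalues; more indicate a disconnected (or mechanically degenerate)
spring network and are an error rather than silently dropped. The ten
lowest nontrivial modes (indices 7–16, 1-based) are returned with a fixed
sign convention (largest-magnitude component positive) so parallel and
antiparallel directions are reproducible. Site masses are uniform — the
method needs directions, not frequencies. The Cα mode is broadcast to all
atoms of each residue and renormalised to a unit 3N field for the
simulation.

## Geometric simulation

The simulation is template-based: one template per rigid cluster stores the
cluster's internal geometry; atoms in clusters of fewer than three atoms
are grouped with their covalent neighbours into minimal angle-preserving
units; atoms shared between templates are the articulation sets through
which motion propagates.

Each iteration displaces all atoms by `direction · step_size · √N` along
the unit mode field (step_size 0.01 Å, so a typical atom moves ~0.01 Å) and
then relaxes: every template is rigid-fitted to the current positions
(batched Kabsch) and each atom moves to the average of its templates'
predictions; covalent bond lengths are projected back to their input
values; hydrogen-bond and tether lengths are kept inside a window of ±0.1 Å
(the relaxation tolerance) around their input lengths; non-bonded pairs
closer than 0.85× the van der Waals sum are pushed apart. Steric checks
exclude covalent neighbours up to 1–4 — with heavy-atom geometry the
carbonyl O(i)–CA(i+1) pair sits inside any reasonable floor — as well as
constrained pairs and atoms held inside one template. Relaxation iterates
(at most 200 cycles) until the worst violation is below tolerance.

The motion coordinate is the *realized amplitude*: the peak projection of
the displacement from the start frame onto the signed mode field. It is a
running maximum, hence non-decreasing, and equals the instantaneous
projection throughout the easy phase of the motion. A run terminates
*jammed* when relaxation fails to converge **or** when the realized
amplitude stalls (its gain over a 20-iteration window falls below 5% of the
driven displacement): with projection-based relaxation a blocked run can
always "converge" by undoing the step, so stall detection is what
operationalises the onset of jamming — the point where constraints stop
further progress along the mode. Otherwise the run completes at the frame
cap (default 2,000 iterations; frames are stored every 100 iterations plus
the final frame to bound memory). Runs are deterministic for fixed inputs.
Atoms may be pinned (never moved), which is how obstacle walls and
lattice-like anchors are modelled in the validation fixtures.

For each of the ten modes the simulation is run parallel and antiparallel,
and the final valid frame of each run is the variant at that direction's
natural amplitude limit — 20 structural variants per structure.

## Loop amplitude reporting

Variants are aligned on the stable base of each chain independently
(Kabsch on base Cα only), so loop excursions are measured in a fixed
domain frame. A loop's *apex* is the Cα of the median residue of its range
(lower median for even length) — the paper-style tables do not define the
apex, and the median is deterministic and matches the visual apex for short
loops. The *apex amplitude* is, by default, the maximum pairwise distance
between apex positions across the crystal reference plus all 20 variants;
a `max_from_reference` mode (maximal excursion from the crystal structure
only) is also available and reports label which was used. Reports list
per-(structure, loop) amplitudes with per-structure means over the eight
loops (CDR1/2/3 and the framework loop, both chains) and per-loop means
over structures, displayed at one decimal.

## Synthetic fixtures

The generators in `tcrflex.synthetic_data` produce fully self-contained
fixtures with declared ground truth:

* **Hairpin scaffold** — two antiparallel strands of idealised residues
  (planar backbone template, N–CA 1.46 Å, CA–C ≈ 1.51 Å, C–N 1.33 Å)
  joined by a solved glycine loop. Facing strand pairs both donate and
  accept hydrogen bonds at near-ideal geometry (≈ −8 to −10 kcal/mol), so
  the strand core forms one dominant rigid cluster at E_cut = −3 while the
  loop stays floppy; the loop path is solved (least squares over residue
  orientations) to keep loop atoms outside both the hydrogen-bond well and
  the steric floor of all non-adjacent residues, so no accidental
  constraints are designed in. A weak intra-loop turn hydrogen bond
  (≈ −4.8 kcal/mol) remains, as in a real β-turn.
* **Conformer pairs** — the loop is flapped rigidly about the axis through
  its first N and last C (which preserves both junction bonds exactly),
  with per-residue damped angles solved so the apex moves by exactly the
  requested displacement, every other residue moves strictly less, and
  inter-residue bond lengths are restored. Displacements beyond the flap's
  geometric reach raise an error.
* **Two-domain chain** — two hairpin domains joined by a 10-residue
  zig-zagging linker (the kinks and axial roll keep the linker Cα sites
  off any straight line, which an anisotropic network needs). Its lowest
  nontrivial mode is an interdomain hinge: each domain's dominant rigid
  cluster moves essentially rigidly under simulation while no global rigid
  fit explains the motion.
* **Lattice fixture** — the hairpin in a P1 cell, rotated so its two most
  distant atoms (one being a C-terminal OXT added to protrude from the
  body) lie along the cell's x axis; the cell edge is set analytically so
  that exactly one inter-image pair sits at 3.80 Å while every other pair
  clears 4.2 Å.

All generators are seed-deterministic; the seed feeds only a 0.001 Å
symmetry-breaking jitter.

What the fixtures do **not** emulate: real side chains and rotamers, real
β-sheet twist and pleat, solvent, crystallographic disorder, and the size
(~440 residues) and interaction density of a real two-chain receptor.
Passing tests therefore demonstrate the correctness of the machinery
(constraint counting, rank-matching rigidity, mode computation, constraint
preservation, jamming, amplitude bookkeeping), not that amplitudes computed
on real receptors reproduce any particular published value — that requires
the deposited coordinate files, which the test suite will fetch (or read
from `data/deposited/`) when available.

## Problem sizes and defaults used in validation

The bundled validation runs use the fixture defaults: 12-residue hairpins
(48 atoms), a 34-residue two-domain chain (136 atoms), simulations of
120–300 iterations (the easy phase plus, for obstacle runs, the jam), and
25–50 random body-bar graphs of up to 12 bodies for the rank oracle. The
production defaults (2,000-iteration cap, 10 modes, E_cut −3.0, 12 Å ENM
cutoff, 4.0 Å contacts) are the analysis conditions and are what
`PipelineConfig()` reproduces.

## Known limitations

* The hydrogen-bond energy function is a deliberately simple geometric
  proxy; absolute energies should not be over-interpreted — only the
  filtration they induce matters for rigidity.
* Rigid-cluster membership for atoms shared between overlapping rigid
  environments is resolved by union–find merging, which is exact for
  bodies but means clusters are reported as atom partitions, not bond
  partitions.
* The realized-amplitude stall detector can declare jamming during a
  genuinely slow (but nonzero) phase of motion if the free fraction of the
  mode field is below 5%; the threshold is exposed in `SimParams`.
* `P 21 21 1`-style non-standard space-group settings are not in the
  operator table and must be supplied as explicit triplets.
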