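"""Superposition, displacement profiles, and lattice-contact detection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tcrflex.crystal_compare import (
    apply_symmetry,
    find_crystal_contacts,
    kabsch_superpose,
    loop_contact_freedom,
    pairwise_loop_shift_matrix,
    parse_operator_triplets,
    per_residue_displacement,
    space_group_operators,
)
from tcrflex.structure_model import LoopDefinition
from tcrflex.synthetic_data import ToySpec, make_conformer_pair, make_hairpin_scaffold


def quaternion_fit_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent oracle: optimal-rotation RMSD via Horn's quaternion method."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    sxx = x.T @ y
    key = np.array(
        [
            [sxx[0, 0] + sxx[1, 1] + sxx[2, 2], sxx[1, 2] - sxx[2, 1], sxx[2, 0] - sxx[0, 2], sxx[0, 1] - sxx[1, 0]],
            [sxx[1, 2] - sxx[2, 1], sxx[0, 0] - sxx[1, 1] - sxx[2, 2], sxx[0, 1] + sxx[1, 0], sxx[2, 0] + sxx[0, 2]],
            [sxx[2, 0] - sxx[0, 2], sxx[0, 1] + sxx[1, 0], -sxx[0, 0] + sxx[1, 1] - sxx[2, 2], sxx[1, 2] + sxx[2, 1]],
            [sxx[0, 1] - sxx[1, 0], sxx[2, 0] + sxx[0, 2], sxx[1, 2] + sxx[2, 1], -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(key)[-1]
    e0 = (x ** 2).sum() + (y ** 2).sum()
    return float(np.sqrt(max(e0 - 2 * lam, 0.0) / len(x)))


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_recovers_rotation_translation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([1.0, 2.0, 3.0])
        res = kabsch_superpose(pts, moved)
        assert res.rmsd < 1e-9
        np.testing.assert_allclose(res.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(res.transform(pts), moved, atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quaternion_oracle_with_noise(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(10, 3)) * 5
        rot = Rotation.random(random_state=seed).as_matrix()
        moved = pts @ rot.T + rng.normal(size=3) + rng.normal(scale=0.5, size=(10, 3))
        res = kabsch_superpose(pts, moved)
        assert res.rmsd == pytest.approx(quaternion_fit_rmsd(pts, moved), abs=1e-6)

    def test_symmetry_of_rmsd(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(7, 3))
        b = a + rng.normal(scale=0.3, size=(7, 3))
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-9
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.c_[np.arange(5.0), np.zeros(5), np.zeros(5)]
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)


class TestDisplacement:
    def test_identical_structures_zero(self, hairpin):
        st, truth = hairpin
        prof = per_residue_displacement(
            st, st, truth["strand_residues"], truth["strand_residues"], "A"
        )
        assert prof.max_displacement == pytest.approx(0.0, abs=1e-9)

    def test_designed_loop_displacement(self, hairpin, hairpin_loop):
        st, truth = hairpin
        a, b = make_conformer_pair(st, hairpin_loop, 2.5)
        prof = per_residue_displacement(
            a, b, truth["strand_residues"], list(hairpin_loop.residues()), "A"
        )
        assert prof.max_displacement == pytest.approx(2.5, abs=0.01)

    def test_invariant_under_joint_rigid_transform(self, hairpin, hairpin_loop):
        st, truth = hairpin
        a, b = make_conformer_pair(st, hairpin_loop, 2.0)
        rot = Rotation.from_euler("xyz", [10, 40, 70], degrees=True).as_matrix()
        for s in (a, b):
            s.set_coords(s.coords_array() @ rot.T + np.array([5.0, -3.0, 2.0]))
        prof = per_residue_displacement(
            a, b, truth["strand_residues"], list(hairpin_loop.residues()), "A"
        )
        assert prof.max_displacement == pytest.approx(2.0, abs=0.01)

    def test_empty_selection_is_error(self, hairpin):
        st, _ = hairpin
        with pytest.raises(ValueError, match="selection"):
            per_residue_displacement(st, st, [999], [999], "A")


class TestLoopShiftMatrix:
    def test_identical_pair_zero_matrix(self, hairpin, hairpin_loop):
        st, truth = hairpin
        mat, _ = pairwise_loop_shift_matrix(
            [st, st.copy()], hairpin_loop, truth["strand_residues"]
        )
        np.testing.assert_allclose(mat, 0.0, atol=1e-9)

    def test_known_shift_set(self, hairpin, hairpin_loop):
        st, truth = hairpin
        _, c1 = make_conformer_pair(st, hairpin_loop, 1.0)
        _, c4 = make_conformer_pair(st, hairpin_loop, 4.0)
        mat, extreme = pairwise_loop_shift_matrix(
            [st, c1, c4], hairpin_loop, truth["strand_residues"]
        )
        assert mat.max() == pytest.approx(4.0, abs=0.05)
        assert np.allclose(mat, mat.T) and np.allclose(np.diag(mat), 0.0)
        assert set(extreme) == {0, 2}


class TestSymmetry:
    def test_p1_translations_give_27_images(self, lattice_fixture):
        st, _ = lattice_fixture
        images = apply_symmetry(st, space_group_operators("P 1"), translation_range=1)
        assert len(images) == 27
        assert sum(im.is_self for im in images) == 1

    def test_fractional_operator_evaluation(self):
        ops = parse_operator_triplets(["-x,-y,z+1/2"])
        rot, tran = ops[0]
        frac = np.array([0.1, 0.1, 0.1])
        np.testing.assert_allclose(rot @ frac + tran, [-0.1, -0.1, 0.6])
        # on the standard orthorhombic operator table
        p21212 = space_group_operators("P 21 21 2")
        assert len(p21212) == 4

    def test_images_match_brute_force(self, lattice_fixture):
        st, _ = lattice_fixture
        small = st.copy()
        # keep it tiny: first 10 atoms
        atoms = list(small.atoms())[:10]
        xyz = np.array([a.coords for a in atoms])
        import gemmi

        cell = gemmi.UnitCell(*st.cell)
        frac_m = np.array(cell.frac.mat.tolist())
        orth_m = np.array(cell.orth.mat.tolist())
        images = apply_symmetry(st, space_group_operators("P 1"), translation_range=1)
        got = sorted(
            float(np.linalg.norm(im.coords[0] - xyz[1])) for im in images
        )
        expected = []
        for tx in (-1, 0, 1):
            for ty in (-1, 0, 1):
                for tz in (-1, 0, 1):
                    shifted = orth_m @ (frac_m @ xyz[0] + np.array([tx, ty, tz]))
                    expected.append(float(np.linalg.norm(shifted - xyz[1])))
        np.testing.assert_allclose(got, sorted(expected), atol=1e-8)

    def test_missing_cell_is_error(self, hairpin):
        st, _ = hairpin
        with pytest.raises(ValueError, match="cell"):
            apply_symmetry(st, space_group_operators("P 1"))


class TestContacts:
    def test_designed_single_contact(self, lattice_fixture):
        st, truth = lattice_fixture
        contacts = find_crystal_contacts(st, space_group_operators("P 1"), cutoff=4.0)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(truth["contact_distance"], abs=1e-6)
        keys = {contacts[0].atom_a, contacts[0].atom_b}
        assert keys == set(truth["contact_pair"])

    def test_strict_inequality_at_cutoff(self, lattice_fixture):
        st, truth = lattice_fixture
        at_boundary = find_crystal_contacts(
            st, space_group_operators("P 1"), cutoff=truth["contact_distance"]
        )
        assert at_boundary == []

    def test_matches_brute_force_enumeration(self, lattice_fixture):
        st, _ = lattice_fixture
        cutoff = 4.4
        contacts = find_crystal_contacts(st, space_group_operators("P 1"), cutoff=cutoff)
        xyz = st.coords_array()
        import gemmi

        cell = gemmi.UnitCell(*st.cell)
        frac_m = np.array(cell.frac.mat.tolist())
        orth_m = np.array(cell.orth.mat.tolist())
        frac = xyz @ frac_m.T
        brute = set()
        for tx in (-1, 0, 1):
            for ty in (-1, 0, 1):
                for tz in (-1, 0, 1):
                    if (tx, ty, tz) == (0, 0, 0):
                        continue
                    img = (frac + np.array([tx, ty, tz])) @ orth_m.T
                    d = np.linalg.norm(xyz[:, None, :] - img[None, :, :], axis=2)
                    for i, j in zip(*np.where(d < cutoff)):
                        brute.add((min(i, j), max(i, j), round(float(d[i, j]), 6)))
        assert len(contacts) == len(brute)

    def test_cutoff_validation(self, lattice_fixture):
        st, _ = lattice_fixture
        with pytest.raises(ValueError):
            find_crystal_contacts(st, space_group_operators("P 1"), cutoff=-1.0)


class TestContactFreedom:
    def test_empty_contacts_all_free(self, hairpin_loop):
        freedom = loop_contact_freedom([], [hairpin_loop])
        assert freedom["loop"] == (True, 0)

    def test_contact_on_loop_residue_flags_loop(self, lattice_fixture, hairpin_loop):
        st, truth = lattice_fixture
        contacts = find_crystal_contacts(st, space_group_operators("P 1"), cutoff=4.0)
        touched_res = {contacts[0].atom_a[1], contacts[0].atom_b[1]}
        strand_loop = LoopDefinition("strandB", "A", 9, 12)
        freedom = loop_contact_freedom(contacts, [hairpin_loop, strand_loop])
        # the designed contact touches residue 12 (OXT) and residue 6 (loop)
        assert 12 in touched_res and 6 in touched_res
        assert freedom["strandB"] == (False, 1)
        assert freedom["loop"] == (False, 1)
        other = LoopDefinition("strandA", "A", 1, 4)
        assert loop_contact_freedom(contacts, [other])["strandA"] == (True, 0)
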