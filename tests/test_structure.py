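import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from actinovar.geometry import AtomRecord, build_gxg, build_residue
from actinovar.structure import (ASAClass, classify_ratio, coil_reference_asa,
                                 kabsch_superpose, read_structure, shrake_rupley,
                                 sidechain_ratio, write_pdb)
from actinovar.synthetic import generate_toy_structure

R_C = 1.70
PROBE = 1.4


def carbon(serial, xyz):
    return AtomRecord(serial, "C", "DUM", "A", serial, tuple(map(float, xyz)), "C")


def two_sphere_accessible_area(r1, r2, d):
    """Closed-form accessible area of two intersecting expanded spheres."""
    a1 = 4 * np.pi * r1 ** 2
    a2 = 4 * np.pi * r2 ** 2
    if d >= r1 + r2:
        return a1, a2
    x1 = (d ** 2 + r1 ** 2 - r2 ** 2) / (2 * d)
    h1 = r1 - x1
    h2 = r2 - (d - x1)
    return a1 - 2 * np.pi * r1 * h1, a2 - 2 * np.pi * r2 * h2


class TestShrakeRupley:
    def test_isolated_atom_is_analytic_sphere(self):
        asa = shrake_rupley([carbon(1, (0, 0, 0))])
        assert asa[0] == pytest.approx(4 * np.pi * (R_C + PROBE) ** 2, rel=1e-12)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_spheres_match_cap_formula(self, d):
        atoms = [carbon(1, (0, 0, 0)), carbon(2, (d, 0, 0))]
        asa = shrake_rupley(atoms, n_points=4000)
        r = R_C + PROBE
        e1, e2 = two_sphere_accessible_area(r, r, d)
        assert asa[0] == pytest.approx(e1, rel=0.01)
        assert asa[1] == pytest.approx(e2, rel=0.01)

    def test_two_unequal_spheres(self):
        atoms = [carbon(1, (0, 0, 0)),
                 AtomRecord(2, "O", "DUM", "A", 2, (3.0, 0.0, 0.0), "O")]
        asa = shrake_rupley(atoms, n_points=4000)
        e1, e2 = two_sphere_accessible_area(R_C + PROBE, 1.52 + PROBE, 3.0)
        assert asa[0] == pytest.approx(e1, rel=0.01)
        assert asa[1] == pytest.approx(e2, rel=0.01)

    def test_enclosed_atom_has_zero_asa(self):
        atoms = generate_toy_structure("buried_residue", "ALA")
        asa = shrake_rupley(atoms)
        residue_idx = [i for i, a in enumerate(atoms) if a.residue_name == "ALA"]
        assert asa[residue_idx].sum() == pytest.approx(0.0, abs=1e-9)

    def test_rotation_translation_invariance(self):
        atoms = build_gxg("TRP")
        R = Rotation.from_euler("xyz", [30, 45, 60], degrees=True).as_matrix()
        coords = np.array([a.xyz for a in atoms]) @ R.T + np.array([10.0, -3.0, 7.0])
        moved = [AtomRecord(a.serial, a.name, a.residue_name, a.chain,
                            a.residue_number, tuple(c), a.element)
                 for a, c in zip(atoms, coords)]
        asa1 = shrake_rupley(moved, n_points=2000)
        asa0 = shrake_rupley(atoms, n_points=2000)
        assert asa1.sum() == pytest.approx(asa0.sum(), rel=0.005)

    def test_convergence_on_doubling_points(self):
        atoms = build_gxg("PHE")
        a1 = shrake_rupley(atoms, n_points=960).sum()
        a2 = shrake_rupley(atoms, n_points=1920).sum()
        assert abs(a2 - a1) / a2 < 0.01

    def test_agrees_with_independent_sasa_implementation(self):
        import biotite.structure as struc

        atoms = build_gxg("PHE")
        arr = struc.AtomArray(len(atoms))
        for i, a in enumerate(atoms):
            arr.coord[i] = a.xyz
            arr.atom_name[i] = a.name
            arr.res_name[i] = a.residue_name
            arr.chain_id[i] = a.chain
            arr.res_id[i] = a.residue_number
            arr.element[i] = a.element
        mine = shrake_rupley(atoms, n_points=960).sum()
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                            vdw_radii="Single").sum()
        assert mine == pytest.approx(theirs, rel=0.02)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            shrake_rupley([AtomRecord(1, "Q", "DUM", "A", 1, (0, 0, 0), "Q")])


class TestSidechainRatio:
    def test_coil_reference_conformation_has_unit_ratio(self):
        atoms = generate_toy_structure("extended_tripeptide", "ALA")
        entry = sidechain_ratio(atoms, "A", 2)
        assert entry.ratio == pytest.approx(1.0, abs=0.05)

    def test_buried_residue_low_class(self):
        atoms = generate_toy_structure("buried_residue", "LEU")
        entry = sidechain_ratio(atoms, "A", 1)
        assert entry.ratio == pytest.approx(0.0, abs=1e-9)
        assert entry.asa_class is ASAClass.LOW

    def test_glycine_uses_calpha(self):
        atoms = build_gxg("GLY")
        entry = sidechain_ratio(atoms, "A", 2)
        assert entry.ratio > 0

    @pytest.mark.parametrize("ratio,cls", [
        (0.05, ASAClass.LOW), (0.35, ASAClass.PARTIAL), (0.75, ASAClass.HIGH),
        (0.199, ASAClass.LOW), (0.51, ASAClass.HIGH)])
    def test_threshold_bookkeeping(self, ratio, cls):
        assert classify_ratio(ratio) is cls

    def test_missing_residue(self):
        atoms = build_residue("ALA")
        with pytest.raises(KeyError):
            sidechain_ratio(atoms, "A", 99)

    def test_coil_reference_positive_for_all_standard_types(self):
        for resname in ("ALA", "ARG", "TRP", "GLY", "PRO"):
            assert coil_reference_asa(resname) > 0


class TestPDBRoundtrip:
    def test_write_then_read(self, tmp_path):
        atoms = build_gxg("ALA")
        path = tmp_path / "toy.pdb"
        write_pdb(atoms, path)
        back = read_structure(path)
        assert len(back) == len(atoms)
        orig = np.array([a.xyz for a in atoms])
        got = np.array([a.xyz for a in back])
        assert np.allclose(orig, got, atol=1e-3)
        assert [a.name for a in back] == [a.name for a in atoms]


class TestKabsch:
    def test_identical_sets(self):
        A = np.random.default_rng(0).normal(size=(10, 3))
        res = kabsch_superpose(A, A)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_rotated_translated_copy_recovers_zero_rmsd(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(25, 3))
        for i in range(100):
            R = Rotation.random(random_state=i).as_matrix()
            t = rng.normal(scale=10.0, size=3)
            B = A @ R.T + t
            res = kabsch_superpose(A, B)
            assert res.rmsd <= 1e-8
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(40, 3))
        B = rng.normal(size=(40, 3))
        res = kabsch_superpose(A, B)
        rot, rssd = Rotation.align_vectors(A - A.mean(0), B - B.mean(0))
        assert res.rmsd == pytest.approx(rssd / np.sqrt(40), rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
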