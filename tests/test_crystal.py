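import numpy as np
import pytest

from gelscan.crystal import (
    CrystalModel,
    backbone_torsions,
    expand_symmetry,
    find_crystal_hbonds,
    find_stacked_pairs,
    frac_to_cart,
    orthogonalization_matrix,
    read_cif,
)
from gelscan.geometry import torsion_angle
from gelscan.synthetic import build_synthetic_crystal_cif

TEMPLATE_ROLES = {
    "carbamate_C": "C11",
    "amide_N": "N",
    "CA": "CA",
    "carboxyl_C": "C",
    "carboxyl_O1": "O1",
    "carboxyl_O2": "O2",
}


@pytest.fixture(scope="module")
def synth_model(tmp_path_factory):
    path = tmp_path_factory.mktemp("cif") / "synthetic.cif"
    build_synthetic_crystal_cif(path)
    return read_cif(path)


def _simple_cif(tmp_path, cell=(10, 12, 14), symops=("x, y, z",), atoms=None):
    atoms = atoms or [("C1", "C", 0.1, 0.1, 0.1)]
    lines = [
        "data_fixture",
        f"_cell_length_a {cell[0]}",
        f"_cell_length_b {cell[1]}",
        f"_cell_length_c {cell[2]}",
        "_cell_angle_alpha 90",
        "_cell_angle_beta 90",
        "_cell_angle_gamma 90",
        "loop_",
        "_space_group_symop_operation_xyz",
    ]
    lines += [f"  '{s}'" for s in symops]
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    lines += [f"  {a[0]} {a[1]} {a[2]} {a[3]} {a[4]}" for a in atoms]
    p = tmp_path / "fix.cif"
    p.write_text("\n".join(lines) + "\n")
    return p


class TestReadCif:
    def test_orthorhombic_cell_round_trips(self, tmp_path):
        model = read_cif(_simple_cif(tmp_path))
        assert model.cell[:3] == (10.0, 12.0, 14.0)

    def test_synthetic_structure_has_gelator_and_dmso(self, synth_model):
        assert len(synth_model.molecules) == 2
        assert len(synth_model.gelator_molecule()) == 50
        assert len(synth_model.solvent_molecules()) == 1

    def test_malformed_symop_reports_text(self, tmp_path):
        p = _simple_cif(tmp_path, symops=("x, y, bogus$",))
        with pytest.raises(ValueError, match="bogus"):
            read_cif(p)

    def test_missing_cell_tag_named(self, tmp_path):
        p = tmp_path / "nocell.cif"
        p.write_text("data_x\n_cell_length_a 10\n")
        with pytest.raises(ValueError, match="_cell_length_b"):
            read_cif(p)


class TestFracToCart:
    def test_orthorhombic_is_componentwise(self, tmp_path):
        model = read_cif(_simple_cif(tmp_path))
        assert np.allclose(frac_to_cart(model, [0.5, 0.5, 0.5]), [5, 6, 7])
        assert np.allclose(frac_to_cart(model, [0, 0, 0]), [0, 0, 0])

    def test_triclinic_matches_gemmi(self):
        import gemmi

        cell = (7.1, 9.3, 11.7, 72.0, 81.5, 95.0)
        mine = orthogonalization_matrix(cell)
        ref = gemmi.UnitCell(*cell)
        for frac in ([0.2, 0.3, 0.4], [0.9, 0.1, 0.7]):
            want = ref.orthogonalize(gemmi.Fractional(*frac))
            got = np.asarray(frac) @ mine.T
            assert np.allclose(got, [want.x, want.y, want.z], atol=1e-9)


class TestSymmetry:
    def test_p212121_shell0_gives_four_images(self, synth_model):
        images = expand_symmetry(synth_model, shell=0)
        per_mol = len(images) / len(synth_model.molecules)
        assert per_mol == 4

    def test_p1_shell_gives_translation_cube(self, tmp_path):
        model = read_cif(_simple_cif(tmp_path))
        for s in (0, 1, 2):
            assert len(expand_symmetry(model, shell=s)) == (2 * s + 1) ** 3

    def test_images_are_rigid_copies(self, synth_model):
        gel = synth_model.gelator_molecule()
        ref = synth_model.cart[gel]
        d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=2)
        for img in expand_symmetry(synth_model, shell=0):
            if img.molecule_index != 0:
                continue
            d = np.linalg.norm(img.cart[:, None] - img.cart[None, :], axis=2)
            assert np.abs(d - d_ref).max() < 1e-9


class TestTorsion:
    def test_cis_and_trans(self):
        p = [np.array([1.0, 1, 0]), np.zeros(3), np.array([1.0, 0, 0])]
        cis = torsion_angle(p[0], p[1], p[2], np.array([2.0, 1, 0]))
        trans = torsion_angle(p[0], p[1], p[2], np.array([2.0, -1, 0]))
        assert cis == pytest.approx(0.0, abs=1e-9)
        assert trans == pytest.approx(180.0, abs=1e-9)

    def test_sign_flips_under_mirror(self, rng):
        pts = rng.uniform(-3, 3, (4, 3))
        a = torsion_angle(*pts)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        b = torsion_angle(*mirrored)
        assert a == pytest.approx(-b, abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(ValueError, match="collinear"):
            torsion_angle([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_synthetic_crystal_backbone_torsions(self, synth_model):
        tors = backbone_torsions(synth_model, TEMPLATE_ROLES)
        assert tors["phi"] == pytest.approx(-130.0, abs=1e-3)
        assert tors["psi"] == pytest.approx(165.0, abs=1e-3)


class TestStacks:
    def test_screw_related_stack_distance_is_half_c(self, synth_model):
        stacks = find_stacked_pairs(synth_model)
        assert stacks, "no stacked ring pairs found"
        closest = stacks[0]
        assert closest["classification"] == "face_to_face"
        assert closest["centroid_distance"] == pytest.approx(
            synth_model.cell[2] / 2, abs=1e-6
        )

    def test_brute_force_image_scan_agrees(self, synth_model):
        """The reported closest stack must equal the global minimum over
        an exhaustive centroid scan of all ring images within range."""
        from gelscan.crystal import find_aromatic_rings

        gel = synth_model.gelator_molecule()
        rings = find_aromatic_rings(synth_model, gel)
        pos = {a: k for k, a in enumerate(gel)}
        best = np.inf
        for img in expand_symmetry(synth_model, shell=1):
            if img.molecule_index != 0 or img.is_identity:
                continue
            for ra in rings:
                ca = synth_model.cart[ra].mean(axis=0)
                for rb in rings:
                    cb = img.cart[[pos[a] for a in rb]].mean(axis=0)
                    best = min(best, float(np.linalg.norm(cb - ca)))
        stacks = find_stacked_pairs(synth_model)
        assert stacks[0]["centroid_distance"] == pytest.approx(best, abs=1e-9)


class TestHbonds:
    def test_planted_nh_o_found_once(self, tmp_path):
        atoms = [
            ("N1", "N", 0.10, 0.10, 0.10),
            ("H1", "H", 0.10, 0.10, 0.1631),  # N-H 1.01 along +z (c=16)
            ("C9", "C", 0.30, 0.30, 0.30),
            ("O1", "O", 0.10, 0.10, 0.28125),  # 2.9 Å from N along +z
        ]
        p = _simple_cif(tmp_path, cell=(16, 16, 16), atoms=atoms)
        model = read_cif(p)
        bonds = [b for b in find_crystal_hbonds(model, shell=1) if b["type"] == "N-H...O"]
        assert len(bonds) == 1
        assert bonds[0]["da_distance"] == pytest.approx(2.9, abs=1e-3)

    def test_distant_acceptor_yields_empty(self, tmp_path):
        atoms = [
            ("N1", "N", 0.10, 0.10, 0.10),
            ("H1", "H", 0.10, 0.10, 0.165),
            ("O1", "O", 0.10, 0.10, 0.40),  # ~5.5 Å away
        ]
        p = _simple_cif(tmp_path, cell=(18, 18, 18), atoms=atoms)
        model = read_cif(p)
        assert find_crystal_hbonds(model, shell=0) == []

    def test_synthetic_crystal_contains_gelator_dmso_bond(self, synth_model):
        bonds = find_crystal_hbonds(synth_model, shell=0)
        to_solvent = [
            b
            for b in bonds
            if b["type"] == "O-H...O" and b["donor_molecule"] != b["acceptor_molecule"]
        ]
        assert to_solvent
        assert min(b["da_distance"] for b in to_solvent) == pytest.approx(2.77, abs=0.01)

    def test_invariant_to_reference_image_choice(self, tmp_path):
        # translating the whole asymmetric unit by a lattice vector must
        # not change the bond list
        atoms = [
            ("N1", "N", 0.10, 0.10, 0.10),
            ("H1", "H", 0.10, 0.10, 0.1631),
            ("C9", "C", 0.30, 0.30, 0.30),
            ("O1", "O", 0.10, 0.10, 0.28125),
        ]
        shifted = [(n, e, x + 1.0, y, z) for (n, e, x, y, z) in atoms]
        m1 = read_cif(_simple_cif(tmp_path, cell=(16, 16, 16), atoms=atoms))
        p2 = tmp_path / "s2"
        p2.mkdir()
        m2 = read_cif(_simple_cif(p2, cell=(16, 16, 16), atoms=shifted))
        b1 = [(b["type"], round(b["da_distance"], 6)) for b in find_crystal_hbonds(m1, 1)]
        b2 = [(b["type"], round(b["da_distance"], 6)) for b in find_crystal_hbonds(m2, 1)]
        assert b1 == b2
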