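"""Crystal-packing geometry from CIF structures.

Reads a small-molecule CIF (cell, symmetry operators, atom sites),
partitions the asymmetric unit into molecules by covalent connectivity,
expands space-group symmetry into a shell of neighbouring images, and
measures the packing descriptors relevant to Fmoc-amino-acid gelators:
backbone φ/ψ torsions, ring-centroid π-stacking distances between
symmetry-related aromatic rings, and the intermolecular hydrogen-bond
network (N–H···O, O–H···O, C–H···O/F, typed by donor and acceptor).

CIF syntax is parsed with :mod:`gemmi`; all geometry (orthogonalization,
symmetry expansion, torsions, stacking, hydrogen bonds) is computed here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import gemmi
import networkx as nx
import numpy as np

from .geometry import ring_centroid_normal, torsion_angle
from .interactions import (
    CHF_ANGLE_MIN,
    CHF_DA_MAX,
    HBOND_ANGLE_MIN,
    HBOND_DA_MAX,
    classify_stacking,
    detect_hbond,
)

__all__ = [
    "CrystalModel",
    "read_cif",
    "frac_to_cart",
    "orthogonalization_matrix",
    "expand_symmetry",
    "MoleculeImage",
    "find_aromatic_rings",
    "find_stacked_pairs",
    "find_crystal_hbonds",
    "backbone_torsions",
]

# single-bond covalent radii (Å) for connectivity detection
_COVALENT = {"C": 0.77, "N": 0.71, "O": 0.66, "F": 0.64, "H": 0.33, "S": 1.04}
_BOND_SLACK = 0.45


@dataclass
class CrystalModel:
    """Unit cell, symmetry operators and asymmetric-unit atoms."""

    cell: tuple[float, float, float, float, float, float]  # a b c alpha beta gamma
    symops: list[gemmi.Op]
    labels: list[str]
    elements: list[str]
    frac: np.ndarray  # (n, 3) fractional coordinates
    occupancies: np.ndarray
    molecules: list[list[int]] = field(default_factory=list)  # atom index lists

    def __post_init__(self):
        a, b, c, al, be, ga = self.cell
        if min(a, b, c) <= 0:
            raise ValueError("cell lengths must be positive")
        if not all(0 < x < 180 for x in (al, be, ga)):
            raise ValueError("cell angles must lie in (0°, 180°)")
        if not np.all(np.isfinite(self.frac)):
            raise ValueError("fractional coordinates must be finite")
        if not self.molecules:
            self.molecules = self._connected_molecules()

    @property
    def orth(self) -> np.ndarray:
        return orthogonalization_matrix(self.cell)

    @property
    def cart(self) -> np.ndarray:
        return self.frac @ self.orth.T

    def _connected_molecules(self) -> list[list[int]]:
        xyz = self.cart
        g = nx.Graph()
        g.add_nodes_from(range(len(self.labels)))
        for i, j in itertools.combinations(range(len(self.labels)), 2):
            rmax = (
                _COVALENT.get(self.elements[i], 0.8)
                + _COVALENT.get(self.elements[j], 0.8)
                + _BOND_SLACK
            )
            if np.linalg.norm(xyz[i] - xyz[j]) <= rmax:
                g.add_edge(i, j)
        return [sorted(c) for c in nx.connected_components(g)]

    def gelator_molecule(self) -> list[int]:
        """The largest S-free molecule (DMSO carries the sulfur)."""
        candidates = [
            m for m in self.molecules
            if not any(self.elements[i] == "S" for i in m)
        ]
        if not candidates:
            raise ValueError("no sulfur-free molecule found")
        return max(candidates, key=len)

    def solvent_molecules(self) -> list[list[int]]:
        return [
            m for m in self.molecules if any(self.elements[i] == "S" for i in m)
        ]


def orthogonalization_matrix(cell) -> np.ndarray:
    """Standard crystallographic fractional→Cartesian matrix (a along x)."""
    a, b, c, al, be, ga = cell
    al, be, ga = np.radians([al, be, ga])
    v = np.sqrt(
        1
        - np.cos(al) ** 2
        - np.cos(be) ** 2
        - np.cos(ga) ** 2
        + 2 * np.cos(al) * np.cos(be) * np.cos(ga)
    )
    return np.array(
        [
            [a, b * np.cos(ga), c * np.cos(be)],
            [
                0.0,
                b * np.sin(ga),
                c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga),
            ],
            [0.0, 0.0, c * v / np.sin(ga)],
        ]
    )


def frac_to_cart(model: CrystalModel, frac) -> np.ndarray:
    """Fractional → Cartesian Å for one point or an array of points."""
    return np.asarray(frac, dtype=float) @ model.orth.T


def read_cif(path) -> CrystalModel:
    """Read cell, symmetry operators and atom sites from a CIF file."""
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def need(tag: str) -> str:
        val = block.find_value(tag)
        if val is None:
            raise ValueError(f"CIF is missing mandatory tag {tag}")
        return val

    def num(tag: str) -> float:
        return float(need(tag).split("(")[0])

    cell = (
        num("_cell_length_a"),
        num("_cell_length_b"),
        num("_cell_length_c"),
        num("_cell_angle_alpha"),
        num("_cell_angle_beta"),
        num("_cell_angle_gamma"),
    )

    symop_strings = []
    for tag in (
        "_space_group_symop_operation_xyz",
        "_symmetry_equiv_pos_as_xyz",
    ):
        col = block.find_loop(tag)
        symop_strings = [gemmi.cif.as_string(v) for v in col]
        if symop_strings:
            break
    if not symop_strings:
        raise ValueError(
            "CIF is missing symmetry operators "
            "(_space_group_symop_operation_xyz / _symmetry_equiv_pos_as_xyz)"
        )
    symops = []
    for s in symop_strings:
        try:
            symops.append(gemmi.Op(s.strip()))
        except Exception as exc:
            raise ValueError(f"malformed symmetry operator {s!r}") from exc

    table = block.find(
        "_atom_site_",
        ["label", "type_symbol", "fract_x", "fract_y", "fract_z", "?occupancy"],
    )
    if len(table) == 0:
        raise ValueError("CIF is missing the _atom_site_ loop")
    labels, elements, frac, occ = [], [], [], []
    for row in table:
        labels.append(row[0])
        elements.append(row[1].strip().capitalize())
        frac.append([float(row[i].split("(")[0]) for i in (2, 3, 4)])
        occ.append(float(row[5].split("(")[0]) if row.has(5) else 1.0)
    return CrystalModel(
        cell=cell,
        symops=symops,
        labels=labels,
        elements=elements,
        frac=np.array(frac),
        occupancies=np.array(occ),
    )


@dataclass
class MoleculeImage:
    """One symmetry/translation image of an asymmetric-unit molecule."""

    molecule_index: int
    op_index: int
    shift: tuple[int, int, int]
    atom_indices: list[int]  # indices into the asymmetric-unit atom table
    cart: np.ndarray  # (n_atoms, 3) Å

    @property
    def is_identity(self) -> bool:
        return self.op_index == 0 and self.shift == (0, 0, 0)


def _apply_op(op: gemmi.Op, frac: np.ndarray) -> np.ndarray:
    rot = np.array(op.rot, dtype=float) / op.DEN
    tran = np.array(op.tran, dtype=float) / op.DEN
    return frac @ rot.T + tran


def expand_symmetry(model: CrystalModel, shell: int = 1) -> list[MoleculeImage]:
    """All symmetry images of every molecule within ± ``shell`` unit-cell
    translations, deduplicated by (rounded) fractional coordinates."""
    images: list[MoleculeImage] = []
    seen: set = set()
    orth = model.orth
    rng = range(-shell, shell + 1)
    for mi, mol in enumerate(model.molecules):
        f0 = model.frac[mol]
        for oi, op in enumerate(model.symops):
            f_op = _apply_op(op, f0)
            for sx, sy, sz in itertools.product(rng, rng, rng):
                f = f_op + np.array([sx, sy, sz], dtype=float)
                key = (mi, tuple(np.round(f[0], 6)))
                if key in seen:
                    continue
                seen.add(key)
                images.append(
                    MoleculeImage(
                        molecule_index=mi,
                        op_index=oi,
                        shift=(sx, sy, sz),
                        atom_indices=list(mol),
                        cart=f @ orth.T,
                    )
                )
    return images


def find_aromatic_rings(model: CrystalModel, molecule: list[int]) -> list[list[int]]:
    """Six-membered all-carbon rings of a molecule (cycle basis of the
    carbon-only covalent graph).  Returned as asymmetric-unit indices."""
    xyz = model.cart
    carbons = [i for i in molecule if model.elements[i] == "C"]
    g = nx.Graph()
    g.add_nodes_from(carbons)
    for i, j in itertools.combinations(carbons, 2):
        if np.linalg.norm(xyz[i] - xyz[j]) <= 2 * _COVALENT["C"] + _BOND_SLACK:
            g.add_edge(i, j)
    return [sorted(cyc) for cyc in nx.minimum_cycle_basis(g) if len(cyc) == 6]


def find_stacked_pairs(
    model: CrystalModel,
    shell: int = 1,
    max_centroid: float = 6.0,
) -> list[dict]:
    """Face-to-face/offset ring stacks between the reference gelator and
    its symmetry images, sorted by centroid distance."""
    gel = model.gelator_molecule()
    rings = find_aromatic_rings(model, gel)
    images = expand_symmetry(model, shell)
    ref_cart = model.cart
    out = []
    for ring in rings:
        pos = {a: k for k, a in enumerate(gel)}
        for img in images:
            if img.is_identity and img.molecule_index == _mol_index(model, gel):
                continue
            if img.molecule_index != _mol_index(model, gel):
                continue
            img_ring = img.cart[[pos[a] for a in ring]]
            for other_ring in rings:
                a_xyz = ref_cart[other_ring]
                cls, geom = classify_stacking(
                    a_xyz, img_ring, box=None, d_stack=max_centroid
                )
                if cls == "none":
                    continue
                out.append(
                    {
                        "ring_a": other_ring,
                        "ring_b": ring,
                        "op_index": img.op_index,
                        "shift": img.shift,
                        "classification": cls,
                        **geom,
                    }
                )
    out.sort(key=lambda r: r["centroid_distance"])
    # deduplicate symmetric A->B / B->A listings at equal distance
    dedup = []
    for r in out:
        if any(
            abs(r["centroid_distance"] - q["centroid_distance"]) < 1e-6
            and {tuple(r["ring_a"]), tuple(r["ring_b"])}
            == {tuple(q["ring_a"]), tuple(q["ring_b"])}
            for q in dedup
        ):
            continue
        dedup.append(r)
    return dedup


def _mol_index(model: CrystalModel, mol: list[int]) -> int:
    return model.molecules.index(mol)


def place_missing_hydrogens(model: CrystalModel) -> CrystalModel:
    """Add geometrically idealized H to N/O donors that lack one.

    H is placed opposite the mean direction of the heavy neighbours
    (N–H 1.01 Å, O–H 0.96 Å).  Only N with < 3 heavy neighbours and O
    with exactly 1 heavy neighbour receive a hydrogen.
    """
    xyz = model.cart
    g = nx.Graph()
    g.add_nodes_from(range(len(model.labels)))
    for i, j in itertools.combinations(range(len(model.labels)), 2):
        rmax = (
            _COVALENT.get(model.elements[i], 0.8)
            + _COVALENT.get(model.elements[j], 0.8)
            + _BOND_SLACK
        )
        if np.linalg.norm(xyz[i] - xyz[j]) <= rmax:
            g.add_edge(i, j)
    inv = np.linalg.inv(model.orth)
    new_labels, new_elems, new_frac, new_occ = (
        list(model.labels),
        list(model.elements),
        [list(f) for f in model.frac],
        list(model.occupancies),
    )
    added = 0
    for i in range(len(model.labels)):
        el = model.elements[i]
        if el not in ("N", "O"):
            continue
        nbrs = list(g.neighbors(i))
        has_h = any(model.elements[j] == "H" for j in nbrs)
        heavy = [j for j in nbrs if model.elements[j] != "H"]
        # hydroxyl-type O only (bonded to C); S=O oxygens get no H
        wants = (el == "N" and len(heavy) <= 2) or (
            el == "O" and len(heavy) == 1 and model.elements[heavy[0]] == "C"
        )
        if has_h or not wants:
            continue
        direction = -np.sum(
            [(xyz[j] - xyz[i]) / np.linalg.norm(xyz[j] - xyz[i]) for j in heavy],
            axis=0,
        )
        direction /= np.linalg.norm(direction)
        h = xyz[i] + (1.01 if el == "N" else 0.96) * direction
        new_labels.append(f"H{model.labels[i]}")
        new_elems.append("H")
        new_frac.append(list(h @ inv.T))
        new_occ.append(1.0)
        added += 1
    if not added:
        return model
    return CrystalModel(
        cell=model.cell,
        symops=model.symops,
        labels=new_labels,
        elements=new_elems,
        frac=np.array(new_frac),
        occupancies=np.array(new_occ),
    )


def find_crystal_hbonds(model: CrystalModel, shell: int = 1) -> list[dict]:
    """Typed intermolecular hydrogen bonds between the asymmetric unit
    and its symmetry/translation neighbourhood.

    Donors are N–H and O–H (standard thresholds) and C–H against F
    acceptors (looser thresholds for the weak C–H···F class); acceptors
    are O and F.  Bonds are reported once per (donor, acceptor, image).
    """
    model = place_missing_hydrogens(model)
    xyz = model.cart
    g = nx.Graph()
    g.add_nodes_from(range(len(model.labels)))
    for i, j in itertools.combinations(range(len(model.labels)), 2):
        rmax = (
            _COVALENT.get(model.elements[i], 0.8)
            + _COVALENT.get(model.elements[j], 0.8)
            + _BOND_SLACK
        )
        if np.linalg.norm(xyz[i] - xyz[j]) <= rmax:
            g.add_edge(i, j)
    donors = []  # (D, H) asymmetric-unit indices
    for i in range(len(model.labels)):
        if model.elements[i] in ("N", "O", "C"):
            for j in g.neighbors(i):
                if model.elements[j] == "H":
                    donors.append((i, j))
    mol_of = {}
    for mi, mol in enumerate(model.molecules):
        for a in mol:
            mol_of[a] = mi

    images = expand_symmetry(model, shell)
    bonds = []
    for img in images:
        pos = {a: k for k, a in enumerate(img.atom_indices)}
        for d, h in donors:
            d_el = model.elements[d]
            for a in img.atom_indices:
                a_el = model.elements[a]
                if a_el not in ("O", "F"):
                    continue
                # intermolecular only: different molecule or non-identity image
                if img.is_identity and mol_of[a] == mol_of[d]:
                    continue
                if d_el == "C":
                    if a_el != "F":
                        continue
                    da_max, ang_min = CHF_DA_MAX, CHF_ANGLE_MIN
                else:
                    da_max, ang_min = HBOND_DA_MAX, HBOND_ANGLE_MIN
                ok, geom = detect_hbond(
                    xyz[d], xyz[h], img.cart[pos[a]], None, da_max, ang_min
                )
                if ok:
                    bonds.append(
                        {
                            "type": f"{d_el}-H...{a_el}",
                            "donor": model.labels[d],
                            "hydrogen": model.labels[h],
                            "acceptor": model.labels[a],
                            "acceptor_molecule": mol_of[a],
                            "donor_molecule": mol_of[d],
                            "op_index": img.op_index,
                            "shift": img.shift,
                            **geom,
                        }
                    )
    bonds.sort(key=lambda b: b["da_distance"])
    return bonds


def backbone_torsions(model: CrystalModel, atom_names: dict[str, str]) -> dict:
    """φ and ψ of a single-residue backbone, by labelled atoms.

    ``atom_names`` maps the roles ``carbamate_C, amide_N, CA, carboxyl_C,
    carboxyl_O1, carboxyl_O2`` to atom labels in the CIF.  φ is
    C(carbamate)–N–Cα–C(carboxyl); ψ is N–Cα–C–O for both carboxyl
    oxygens (the carbonyl-type oxygen is the conventional choice; both
    values are reported).
    """
    idx = {role: model.labels.index(lbl) for role, lbl in atom_names.items()}
    xyz = model.cart
    phi = torsion_angle(
        xyz[idx["carbamate_C"]], xyz[idx["amide_N"]], xyz[idx["CA"]],
        xyz[idx["carboxyl_C"]],
    )
    psi_o1 = torsion_angle(
        xyz[idx["amide_N"]], xyz[idx["CA"]], xyz[idx["carboxyl_C"]],
        xyz[idx["carboxyl_O1"]],
    )
    psi_o2 = torsion_angle(
        xyz[idx["amide_N"]], xyz[idx["CA"]], xyz[idx["carboxyl_C"]],
        xyz[idx["carboxyl_O2"]],
    )
    return {"phi": phi, "psi": psi_o1, "psi_other_oxygen": psi_o2}
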