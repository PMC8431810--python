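"""Monomer chemistry model for Fmoc-phenylalanine hydrogelators.

Three variants are supported: the parent Fmoc-Phe and the two
double-fluorinated derivatives Fmoc-3,4F-Phe (adjacent fluorines) and
Fmoc-3,5F-Phe (meta fluorines).  The monomer is represented as a rigid,
idealized-geometry template: planar fluorene and phenyl rings with
standard aromatic bond lengths, a tetrahedral Cα, and a trans carbamate.
Absolute accuracy of the internal geometry is not the point — every
downstream analysis (contacts, clusters, Rg, SASA) only needs a
chemically sensible rigid body with correct moiety annotations.

The local reference frame is chosen deliberately: the fluorene ring
system lies in the z = 0 plane, the carbamate C=O points toward +z and
the amide N–H toward −z, and the phenyl ring lies in a plane parallel to
the fluorene.  With this layout a face-to-face π-stacked, backbone
hydrogen-bonded dimer (the β-sheet-like motif seen in these systems) can
be generated from two template copies by a pure rigid motion, which the
synthetic-data module exploits.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import rotation_about_axis

__all__ = [
    "Variant",
    "Moiety",
    "AtomSpec",
    "MonomerTemplate",
    "SystemFrame",
    "build_template",
    "build_grid_system",
    "BONDI_RADII",
]

# Bondi van der Waals radii (Å), the conventional set for SASA work.
BONDI_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "H": 1.20, "S": 1.80}

# idealized bond lengths (Å)
_AROM_CC = 1.39
_FUSED_CC = 1.40
_CC_SP3 = 1.53
_CH = 1.09
_CH_AROM = 1.08
_CF = 1.35
_CO_ESTER = 1.43
_OC_CARB = 1.36
_CO_DOUBLE = 1.23
_CN_AMIDE = 1.35
_NH = 1.01
_NCA = 1.45
_CA_C = 1.52
_C_O_ACID = 1.21
_C_OH_ACID = 1.31
_OH = 0.97

# layout constants of the idealized conformation (see build_template);
# chosen for steric clearance of the rigid-motion dimer constructions
_COOH_ELEVATION_DEG = 60.0
_RING_CENTER_X = -0.4
_RING_CENTER_Y = 7.2  # None -> midpoint of amide-N / carboxyl-O1 footprints
_RING_CENTER_Z = -2.8
_RING_CG_BRANCH = -1.0  # which of the two CG solutions on the ring circle


class Variant(str, enum.Enum):
    PHE = "phe"
    F34 = "f34"
    F35 = "f35"


class Moiety(str, enum.Enum):
    FMOC = "FMOC"
    PHE_SIDECHAIN = "PHE_SIDECHAIN"
    FLUORINE = "FLUORINE"
    CARBOXYL = "CARBOXYL"
    BACKBONE = "BACKBONE"
    LINKER = "LINKER"


@dataclass(frozen=True)
class AtomSpec:
    """One atom of the rigid template, in the idealized local frame."""

    name: str
    element: str
    vdw_radius: float
    moiety: Moiety
    reference_position: np.ndarray

    def __post_init__(self):
        if self.element not in BONDI_RADII:
            raise ValueError(f"unsupported element {self.element!r}")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass
class MonomerTemplate:
    """Rigid idealized monomer with moiety, ring and backbone annotations."""

    variant: Variant
    atoms: list[AtomSpec]
    rings: dict[str, list[int]]
    backbone_map: dict[str, int]
    fluorine_indices: list[int]
    bonds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.reference_position for a in self.atoms])

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.atoms]

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.element != "H"])

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def moiety_indices(self, *moieties: Moiety, heavy_only: bool = True) -> np.ndarray:
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if a.moiety in moieties and (not heavy_only or a.element != "H")
        ]
        return np.array(idx, dtype=int)

    def validate(self) -> None:
        """Enforce the template invariants; raises ``ValueError`` on breach."""
        for ring_name in ("FMOC_RING_A", "FMOC_RING_B", "PHE_RING"):
            if len(self.rings[ring_name]) != 6:
                raise ValueError(f"{ring_name} must have 6 atoms")
        n_f = sum(1 for a in self.atoms if a.element == "F")
        expected = 0 if self.variant is Variant.PHE else 2
        if n_f != expected or len(self.fluorine_indices) != expected:
            raise ValueError(f"variant {self.variant} must carry {expected} fluorines")
        xyz = self.coords
        for i, j in self.bonds:
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if not (0.9 <= d <= 1.8):
                raise ValueError(
                    f"bond {self.atoms[i].name}-{self.atoms[j].name} length "
                    f"{d:.3f} Å outside 0.9–1.8 Å"
                )

    def to_json(self) -> str:
        """Serialize the annotated template (sidecar format)."""
        return json.dumps(
            {
                "variant": self.variant.value,
                "atoms": [
                    {
                        "name": a.name,
                        "element": a.element,
                        "vdw_radius": a.vdw_radius,
                        "moiety": a.moiety.value,
                        "xyz": [round(float(x), 6) for x in a.reference_position],
                    }
                    for a in self.atoms
                ],
                "rings": self.rings,
                "backbone_map": self.backbone_map,
                "fluorine_indices": self.fluorine_indices,
                "bonds": [list(b) for b in self.bonds],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MonomerTemplate":
        d = json.loads(text)
        atoms = [
            AtomSpec(
                a["name"],
                a["element"],
                a["vdw_radius"],
                Moiety(a["moiety"]),
                np.array(a["xyz"], dtype=float),
            )
            for a in d["atoms"]
        ]
        return cls(
            Variant(d["variant"]),
            atoms,
            {k: list(v) for k, v in d["rings"].items()},
            dict(d["backbone_map"]),
            list(d["fluorine_indices"]),
            [tuple(b) for b in d["bonds"]],
        )


@dataclass
class SystemFrame:
    """Solute coordinates of one snapshot: ``coords[monomer, atom, xyz]``."""

    frame_index: int
    time_ns: float
    box: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.time_ns < 0:
            raise ValueError("time_ns must be >= 0")
        if np.any(self.box <= 0):
            raise ValueError("box components must be positive")
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_monomers, n_atoms, 3)")

    @property
    def n_monomers(self) -> int:
        return self.coords.shape[0]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _hexagon_from_edge(p: np.ndarray, q: np.ndarray, outward: np.ndarray):
    """Complete a planar regular-ish hexagon containing edge p–q.

    The remaining four vertices are generated by successive 60° rotations
    about the ring centre, which lies on the ``outward`` side of the edge.
    Works in the z = 0 plane (normal ẑ).
    """
    side = np.linalg.norm(q - p)
    mid = 0.5 * (p + q)
    perp = _unit(np.cross(q - p, np.array([0.0, 0.0, 1.0])))
    if perp @ outward < 0:
        perp = -perp
    center = mid + perp * (np.sqrt(3) / 2.0) * side
    # rotation direction taking p to q
    for sign in (1.0, -1.0):
        rot = rotation_about_axis([0, 0, 1], sign * 60.0)
        if np.linalg.norm(center + rot @ (p - center) - q) < 1e-6 * side + 1e-9:
            break
    verts = [p, q]
    cur = q
    for _ in range(4):
        cur = center + rot @ (cur - center)
        verts.append(cur)
    return verts, center


def _two_tetrahedral(u1: np.ndarray, u2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors completing an sp3 centre given two bonded directions."""
    b = _unit(-(u1 + u2))
    c = _unit(np.cross(u1, u2))
    half = np.radians(109.47 / 2.0)
    return _unit(np.cos(half) * b + np.sin(half) * c), _unit(
        np.cos(half) * b - np.sin(half) * c
    )


def build_template(
    variant: Variant | str,
    phi: float | None = None,
    psi: float | None = None,
) -> MonomerTemplate:
    """Construct the rigid idealized monomer template for a variant.

    ``phi``/``psi`` optionally re-pose the backbone torsions
    φ = C(carbamate)–N–Cα–C(carboxyl) and ψ = N–Cα–C–O(carbonyl) by rigid
    rotation of the downstream atoms, e.g. to reproduce a crystal
    conformation.  The default conformation keeps the stacking-friendly
    layout described in the module docstring.
    """
    try:
        variant = Variant(variant)
    except ValueError as exc:
        raise ValueError(f"unknown variant {variant!r}") from exc

    names: list[str] = []
    elements: list[str] = []
    moieties: list[Moiety] = []
    pos: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []

    def add(name, element, moiety, xyz) -> int:
        names.append(name)
        elements.append(element)
        moieties.append(moiety)
        pos.append(np.asarray(xyz, dtype=float))
        return len(names) - 1

    def bond(i, j):
        bonds.append((min(i, j), max(i, j)))

    z = np.array([0.0, 0.0, 1.0])

    # ---- fluorene ring system (z = 0 plane) -------------------------------
    c4a = np.array([0.735, 0.0, 0.0])
    c4b = np.array([-0.735, 0.0, 0.0])
    c9a = np.array([1.15, 1.337, 0.0])
    c8a = np.array([-1.15, 1.337, 0.0])
    c9 = np.array([0.0, 2.316, 0.0])

    ring_a_pts, ring_a_center = _hexagon_from_edge(c4a, c9a, np.array([1.0, -0.3, 0]))
    ring_b_pts, ring_b_center = _hexagon_from_edge(c4b, c8a, np.array([-1.0, -0.3, 0]))

    i_c4a = add("C4A", "C", Moiety.FMOC, c4a)
    i_c4b = add("C4B", "C", Moiety.FMOC, c4b)
    i_c9a = add("C9A", "C", Moiety.FMOC, c9a)
    i_c8a = add("C8A", "C", Moiety.FMOC, c8a)
    i_c9 = add("C9", "C", Moiety.FMOC, c9)
    bond(i_c4a, i_c4b)
    bond(i_c4a, i_c9a)
    bond(i_c4b, i_c8a)
    bond(i_c9, i_c9a)
    bond(i_c9, i_c8a)

    ring_a_idx = [i_c4a, i_c9a]
    prev = i_c9a
    for k, p in enumerate(ring_a_pts[2:], start=1):
        idx = add(f"C{k}", "C", Moiety.FMOC, p)
        ring_a_idx.append(idx)
        bond(prev, idx)
        h = p + _CH_AROM * _unit(p - ring_a_center)
        ih = add(f"H{k}", "H", Moiety.FMOC, h)
        bond(idx, ih)
        prev = idx
    bond(prev, i_c4a)

    ring_b_idx = [i_c4b, i_c8a]
    prev = i_c8a
    for k, p in enumerate(ring_b_pts[2:], start=5):
        idx = add(f"C{k}", "C", Moiety.FMOC, p)
        ring_b_idx.append(idx)
        bond(prev, idx)
        h = p + _CH_AROM * _unit(p - ring_b_center)
        ih = add(f"H{k}", "H", Moiety.FMOC, h)
        bond(idx, ih)
        prev = idx
    bond(prev, i_c4b)

    # ---- methylene linker and carbamate ----------------------------------
    c10 = c9 + _CC_SP3 * _unit([0.0, 0.55, 0.835])
    h9 = c9 + _CH * _unit([0.0, 0.55, -0.835])
    i_c10 = add("C10", "C", Moiety.LINKER, c10)
    i_h9 = add("H9", "H", Moiety.FMOC, h9)
    bond(i_c9, i_c10)
    bond(i_c9, i_h9)

    o3 = c10 + _CO_ESTER * _unit([0.0, 0.94, -0.34])
    i_o3 = add("O3", "O", Moiety.LINKER, o3)
    bond(i_c10, i_o3)
    h10a_dir, h10b_dir = _two_tetrahedral(_unit(c9 - c10), _unit(o3 - c10))
    i_h10a = add("H10A", "H", Moiety.LINKER, c10 + _CH * h10a_dir)
    i_h10b = add("H10B", "H", Moiety.LINKER, c10 + _CH * h10b_dir)
    bond(i_c10, i_h10a)
    bond(i_c10, i_h10b)

    c11 = o3 + _OC_CARB * np.array([0.0, 1.0, 0.0])
    o4 = c11 + _CO_DOUBLE * _unit([0.0, 0.5, 0.866])  # carbonyl up (+z)
    n = c11 + _CN_AMIDE * _unit([0.0, 0.5, -0.866])  # amide N down
    hn = n + _NH * _unit([0.0, -0.5, -0.866])  # N–H pointing -z
    i_c11 = add("C11", "C", Moiety.BACKBONE, c11)
    i_o4 = add("O4", "O", Moiety.BACKBONE, o4)
    i_n = add("N", "N", Moiety.BACKBONE, n)
    i_hn = add("HN", "H", Moiety.BACKBONE, hn)
    bond(i_o3, i_c11)
    bond(i_c11, i_o4)
    bond(i_c11, i_n)
    bond(i_n, i_hn)

    # ---- Cα, carboxyl, side chain -----------------------------------------
    ca = n + _NCA * np.array([0.0, 1.0, 0.0])
    i_ca = add("CA", "C", Moiety.BACKBONE, ca)
    bond(i_n, i_ca)

    c_dir = _unit([0.943, 0.333, 0.0])
    cb_dir = _unit([-0.471, 0.333, -0.816])
    ha_dir = _unit([-0.471, 0.333, 0.816])
    c_cooh = ca + _CA_C * c_dir
    cb = ca + _CC_SP3 * cb_dir
    ha = ca + _CH * ha_dir
    i_c = add("C", "C", Moiety.CARBOXYL, c_cooh)
    i_ha = add("HA", "H", Moiety.BACKBONE, ha)
    i_cb = add("CB", "C", Moiety.PHE_SIDECHAIN, cb)
    bond(i_ca, i_c)
    bond(i_ca, i_ha)
    bond(i_ca, i_cb)

    # carboxyl sp2 plane spans the Cα→C direction and +z; carbonyl O up
    elev = np.radians(_COOH_ELEVATION_DEG)
    o1_dir = _unit(np.cos(elev) * c_dir + np.sin(elev) * z)
    o2_dir = _unit(np.cos(elev) * c_dir - np.sin(elev) * z)
    o1 = c_cooh + _C_O_ACID * o1_dir
    o2 = c_cooh + _C_OH_ACID * o2_dir
    ho2 = o2 + _OH * o2_dir
    i_o1 = add("O1", "O", Moiety.CARBOXYL, o1)
    i_o2 = add("O2", "O", Moiety.CARBOXYL, o2)
    i_ho2 = add("HO2", "H", Moiety.CARBOXYL, ho2)
    bond(i_c, i_o1)
    bond(i_c, i_o2)
    bond(i_o2, i_ho2)

    # phenyl ring: horizontal plane.  The centroid's y-footprint sits at
    # the midpoint of the amide N and carboxyl carbonyl O footprints
    # (which lets an antiparallel stacked dimer close its hydrogen bond,
    # see module docstring); its x-offset and height keep the ring clear
    # of the backbone.  CG is the ring vertex at bond distance from CB.
    ring_y = 0.5 * (n[1] + o1[1]) if _RING_CENTER_Y is None else _RING_CENTER_Y
    ring_center = np.array([_RING_CENTER_X, ring_y, _RING_CENTER_Z])
    d_xy = np.linalg.norm(cb[:2] - ring_center[:2])
    dz = cb[2] - ring_center[2]
    want = 1.51**2 - dz**2
    if want <= 0:
        raise ValueError("phenyl ring plane out of CB reach")
    # law of cosines on the ring circle: angle of CG around the centre
    cos_a = (d_xy**2 + _AROM_CC**2 - want) / (2 * d_xy * _AROM_CC)
    if not -1.0 <= cos_a <= 1.0:
        raise ValueError("phenyl ring centre out of CB reach")
    base_ang = np.arctan2(cb[1] - ring_center[1], cb[0] - ring_center[0])
    ang = base_ang + np.sign(_RING_CG_BRANCH) * np.arccos(cos_a)
    cg = ring_center + _AROM_CC * np.array([np.cos(ang), np.sin(ang), 0.0])

    phe_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    phe_pts = [cg]
    rot60 = rotation_about_axis(z, 60.0)
    for _ in range(5):
        phe_pts.append(ring_center + rot60 @ (phe_pts[-1] - ring_center))
    phe_idx = []
    for nm, p in zip(phe_names, phe_pts):
        phe_idx.append(add(nm, "C", Moiety.PHE_SIDECHAIN, p))
    for k in range(6):
        bond(phe_idx[k], phe_idx[(k + 1) % 6])
    bond(i_cb, phe_idx[0])
    hb1_dir, hb2_dir = _two_tetrahedral(_unit(ca - cb), _unit(cg - cb))
    i_hb1 = add("HB1", "H", Moiety.PHE_SIDECHAIN, cb + _CH * hb1_dir)
    i_hb2 = add("HB2", "H", Moiety.PHE_SIDECHAIN, cb + _CH * hb2_dir)
    bond(i_cb, i_hb1)
    bond(i_cb, i_hb2)

    # ring positions 2..6 carry H, replaced by F at the variant's pattern;
    # ring position numbering follows the list order (CG = position 1)
    fluorinated = {
        Variant.PHE: set(),
        Variant.F34: {2, 3},  # CE1 (pos 3) and CZ (pos 4) -> list idx 2, 3
        Variant.F35: {2, 4},  # CE1 (pos 3) and CE2 (pos 5)
    }[variant]
    fluorine_indices = []
    for k in range(1, 6):
        base = phe_pts[k]
        out = _unit(base - ring_center)
        if k in fluorinated:
            idx = add(f"F{len(fluorine_indices) + 1}", "F", Moiety.FLUORINE, base + _CF * out)
            fluorine_indices.append(idx)
        else:
            idx = add(f"H{phe_names[k]}", "H", Moiety.PHE_SIDECHAIN, base + _CH_AROM * out)
        bond(phe_idx[k], idx)

    atoms = [
        AtomSpec(nm, el, BONDI_RADII[el], mo, p)
        for nm, el, mo, p in zip(names, elements, moieties, pos)
    ]
    template = MonomerTemplate(
        variant=variant,
        atoms=atoms,
        rings={
            "FMOC_RING_A": ring_a_idx,
            "FMOC_RING_B": ring_b_idx,
            "PHE_RING": phe_idx,
        },
        backbone_map={
            "carbamate_C": i_c11,
            "carbamate_O": i_o4,
            "amide_N": i_n,
            "amide_H": i_hn,
            "CA": i_ca,
            "carboxyl_C": i_c,
            "carboxyl_O1": i_o1,
            "carboxyl_O2": i_o2,
        },
        fluorine_indices=fluorine_indices,
        bonds=sorted(set(bonds)),
    )
    if phi is not None:
        _set_torsion(template, ("C11", "N", "CA", "C"), phi, _downstream_of_ca(template))
    if psi is not None:
        _set_torsion(
            template,
            ("N", "CA", "C", "O1"),
            psi,
            [template.index_of(s) for s in ("O1", "O2", "HO2")],
        )
    template.validate()
    return template


def _downstream_of_ca(t: MonomerTemplate) -> list[int]:
    names = ["C", "O1", "O2", "HO2", "HA", "CB", "HB1", "HB2"]
    names += ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    names += [a.name for a in t.atoms if a.name.startswith(("HC", "F"))]
    return [t.index_of(n) for n in names]


def _set_torsion(t: MonomerTemplate, quad: tuple[str, ...], value: float, moving: list[int]):
    """Rotate ``moving`` atoms about the quad's central bond to set a torsion."""
    from .geometry import torsion_angle

    p = [t.atoms[t.index_of(n)].reference_position for n in quad]
    current = torsion_angle(*p)
    axis_origin = p[1]
    axis = p[2] - p[1]
    rot = rotation_about_axis(axis, value - current)
    for i in moving:
        a = t.atoms[i]
        newpos = axis_origin + rot @ (a.reference_position - axis_origin)
        t.atoms[i] = AtomSpec(a.name, a.element, a.vdw_radius, a.moiety, newpos)


def _lattice_counts(n: int, extent: np.ndarray) -> tuple[int, int, int]:
    """Find the integer lattice (na, nb, nc) with equal spacing per axis."""
    best = None
    for na in range(1, n + 1):
        if n % na:
            continue
        for nb in range(1, n // na + 1):
            if (n // na) % nb:
                continue
            nc = n // (na * nb)
            counts = (na, nb, nc)
            spacings = []
            ok = True
            for cnt, ext in zip(counts, extent):
                if cnt == 1:
                    if abs(ext) > 1e-9:
                        ok = False
                    continue
                spacings.append(ext / (cnt - 1))
            if not ok or (spacings and np.ptp(spacings) > 1e-6 * max(spacings)):
                continue
            best = counts
            break
        if best:
            break
    if best is None:
        # identify the axis that cannot host an integer count
        raise ValueError(
            f"no integer lattice of {n} monomers fits extents {tuple(extent)} "
            "with equal spacing (check the x-axis extent first)"
        )
    return best


def build_grid_system(
    template: MonomerTemplate,
    n_monomers: int,
    grid_extent,
    box,
    seed: int,
) -> SystemFrame:
    """Place ``n_monomers`` template copies on a regular lattice in the box.

    Monomer geometric centres sit on the lattice; orientations are drawn
    as uniform random rotations from a generator seeded with ``seed``, so
    the same seed reproduces the system bit for bit.
    """
    from .geometry import random_rotation

    grid_extent = np.asarray(grid_extent, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(grid_extent > box + 1e-9):
        raise ValueError("grid extent exceeds the box")
    counts = _lattice_counts(n_monomers, grid_extent)

    axes_pts = []
    for cnt, ext, b in zip(counts, grid_extent, box):
        start = (b - ext) / 2.0
        axes_pts.append(start + (np.linspace(0, ext, cnt) if cnt > 1 else np.array([0.0])))
    centers = np.array(
        [(x, y, zz) for x in axes_pts[0] for y in axes_pts[1] for zz in axes_pts[2]]
    )

    rng = np.random.default_rng(seed)
    local = template.coords
    local = local - local.mean(axis=0)
    coords = np.empty((n_monomers, template.n_atoms, 3))
    for m in range(n_monomers):
        rot = random_rotation(rng)
        coords[m] = centers[m] + local @ rot.T
    return SystemFrame(frame_index=0, time_ns=0.0, box=box, coords=coords)
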