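"""Low-level vector geometry shared by the analysis modules.

Everything here operates on plain ``numpy`` arrays in Ångström.  Periodic
boxes are orthorhombic (the simulated systems use a cubic water box), so
the minimum-image convention reduces to a componentwise wrap.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "minimum_image",
    "pairwise_min_distance",
    "random_rotation",
    "rotation_about_axis",
    "fit_plane",
    "ring_centroid_normal",
    "torsion_angle",
    "fibonacci_sphere",
]


def minimum_image(dvec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image cell of an
    orthorhombic box.  ``box is None`` means a non-periodic system."""
    if box is None:
        return dvec
    box = np.asarray(box, dtype=float)
    return dvec - box * np.round(dvec / box)


def pairwise_min_distance(
    xyz_a: np.ndarray, xyz_b: np.ndarray, box: np.ndarray | None = None
) -> float:
    """Minimum distance between two atom sets under minimum image.

    Brute force over all pairs; the selections handled here are small
    (tens of atoms), so an O(n*m) broadcast is both exact and fast.
    """
    a = np.asarray(xyz_a, dtype=float)
    b = np.asarray(xyz_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty atom selection in distance computation")
    d = minimum_image(a[:, None, :] - b[None, :, :], box)
    return float(np.sqrt(np.min(np.einsum("ijk,ijk->ij", d, d))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (Shoemake quaternion method)."""
    u1, u2, u3 = rng.random(3)
    q = np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )
    x, y, z, w = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-fit plane through a point set.

    Returns ``(centroid, unit_normal, rms_out_of_plane)``.  The normal is
    the singular vector of the centred coordinates with the smallest
    singular value.  Raises for degenerate (collinear) input.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-8:
        raise ValueError("degenerate ring: points are collinear")
    normal = vt[2]
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return centroid, normal, rms


def ring_centroid_normal(points: np.ndarray, max_rms: float = 0.2):
    """Centroid and plane normal of an aromatic ring, enforcing planarity."""
    centroid, normal, rms = fit_plane(points)
    if rms > max_rms:
        raise ValueError(f"ring not planar: RMS out-of-plane {rms:.3f} Å > {max_rms}")
    return centroid, normal


def torsion_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in degrees, IUPAC convention, (−180, 180].

    Positive when, looking from p2 towards p3, the far bond p3→p4 is
    rotated clockwise from the near bond p2→p1.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("torsion undefined: three consecutive points collinear")
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly to +180 so the range is (-180, 180]
    if ang <= -180.0 + 1e-12:
        ang += 360.0
    return float(ang)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
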