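"""Contact-graph clusters, radius of gyration and β-sheet-like motifs.

A set of monomers forms a cluster when each member is within the uniform
4.0 Å heavy-atom distance criterion of at least one other member, i.e.
clusters are the connected components of the monomer contact graph.
Components of size one are tracked separately as singletons.

The per-cluster radius of gyration is the plain (unweighted) RMS
deviation of the member heavy atoms from their geometric centre,

    Rg = sqrt( (1/N) Σ_k |r_k − r̄|² ),

computed after unwrapping the cluster across periodic boundaries so the
deviation is measured on a contiguous image of the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .core_model import MonomerTemplate, SystemFrame
from .geometry import minimum_image
from .interactions import (
    CUTOFF,
    classify_stacking,
    detect_hbond,
    min_heavy_atom_distance,
)

__all__ = [
    "ClusterAssignment",
    "find_clusters",
    "unwrap_cluster",
    "cluster_rg",
    "radius_of_gyration",
    "rg_vs_size_profile",
    "classify_dimer_motif",
    "contact_graph",
]


@dataclass
class ClusterAssignment:
    """Per-frame partition into contact-connected clusters and singletons."""

    frame_index: int
    clusters: list[list[int]] = field(default_factory=list)
    singletons: list[int] = field(default_factory=list)
    graph: nx.Graph | None = None

    def partition_sets(self) -> set[frozenset]:
        return {frozenset(c) for c in self.clusters}

    def validate(self, n_monomers: int) -> None:
        seen = [m for c in self.clusters for m in c] + list(self.singletons)
        if sorted(seen) != list(range(n_monomers)):
            raise ValueError("clusters and singletons must partition the monomers")


def contact_graph(
    frame: SystemFrame, template: MonomerTemplate, cutoff: float = CUTOFF
) -> nx.Graph:
    """Monomer contact graph: edge iff min heavy-atom distance ≤ cutoff."""
    heavy = template.heavy_indices
    xyz = frame.coords[:, heavy, :]
    centers = xyz.mean(axis=1)
    radii = np.linalg.norm(xyz - centers[:, None, :], axis=2).max(axis=1)
    g = nx.Graph()
    g.add_nodes_from(range(frame.n_monomers))
    for i, j in combinations(range(frame.n_monomers), 2):
        dc = np.linalg.norm(minimum_image(centers[j] - centers[i], frame.box))
        if dc > cutoff + radii[i] + radii[j]:
            continue
        d = min_heavy_atom_distance(frame, i, j, heavy, heavy)
        if d <= cutoff:
            g.add_edge(i, j, distance=d)
    return g


def find_clusters(
    frame: SystemFrame, template: MonomerTemplate, cutoff: float = CUTOFF
) -> ClusterAssignment:
    """Connected components of the contact graph; size-1 components are
    reported as singletons, not clusters."""
    g = contact_graph(frame, template, cutoff)
    clusters, singles = [], []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            clusters.append(sorted(comp))
        else:
            singles.extend(comp)
    clusters.sort()
    assignment = ClusterAssignment(
        frame_index=frame.frame_index,
        clusters=clusters,
        singletons=sorted(singles),
        graph=g,
    )
    assignment.validate(frame.n_monomers)
    return assignment


def unwrap_cluster(
    frame: SystemFrame,
    template: MonomerTemplate,
    cluster: list[int],
    graph: nx.Graph | None = None,
) -> np.ndarray:
    """Coordinates of a cluster's monomers on one contiguous periodic image.

    Walks the cluster's contact graph breadth-first, translating each
    monomer by the lattice vector that brings it to the minimum image of
    its already-placed neighbour.  Returns ``coords[len(cluster), n_atoms, 3]``.
    """
    if graph is None:
        sub_frame_graph = contact_graph(frame, template)
    else:
        sub_frame_graph = graph
    sub = sub_frame_graph.subgraph(cluster)
    heavy = template.heavy_indices
    # make each monomer whole first: atoms rejoined to the minimum image
    # of their own first atom (files may store atom-wise wrapped coords)
    whole = frame.coords.copy()
    anchors = whole[:, 0:1, :]
    whole = anchors + minimum_image(whole - anchors, frame.box)
    centers = whole[:, heavy, :].mean(axis=1)
    shift: dict[int, np.ndarray] = {}
    root = cluster[0]
    shift[root] = np.zeros(3)
    for parent, child in nx.bfs_edges(sub, root):
        d = centers[child] - (centers[parent] + shift[parent])
        wrapped = minimum_image(d, frame.box)
        shift[child] = wrapped - d + shift[parent]
    out = np.empty((len(cluster), template.n_atoms, 3))
    for k, m in enumerate(cluster):
        out[k] = whole[m] + shift.get(m, np.zeros(3))
    return out


def radius_of_gyration(points: np.ndarray) -> float:
    """Unweighted Rg of a point set about its geometric centre."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty point set")
    centred = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", centred, centred))))


def cluster_rg(
    frame: SystemFrame,
    template: MonomerTemplate,
    cluster: list[int],
    heavy_only: bool = True,
    graph: nx.Graph | None = None,
) -> float:
    """Radius of gyration of a cluster's member monomers (heavy atoms by
    default; set ``heavy_only=False`` to include hydrogens)."""
    if not cluster:
        raise ValueError("empty cluster")
    coords = unwrap_cluster(frame, template, cluster, graph)
    if heavy_only:
        coords = coords[:, template.heavy_indices, :]
    return radius_of_gyration(coords.reshape(-1, 3))


def rg_vs_size_profile(
    trajectory, cutoff: float = CUTOFF, heavy_only: bool = True
) -> pd.DataFrame:
    """Cluster-size → Rg profile over a trajectory.

    One row per observed cluster size with the mean and SD of Rg and the
    number of (frame, cluster) observations.
    """
    template = trajectory.template
    records: dict[int, list[float]] = {}
    for frame in trajectory.frames:
        assignment = find_clusters(frame, template, cutoff)
        for cl in assignment.clusters:
            rg = cluster_rg(frame, template, cl, heavy_only, assignment.graph)
            records.setdefault(len(cl), []).append(rg)
    rows = []
    for size in sorted(records):
        vals = np.array(records[size])
        rows.append(
            {
                "size": size,
                "mean_rg": float(vals.mean()),
                "sd_rg": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n_obs": int(vals.size),
            }
        )
    return pd.DataFrame(rows, columns=["size", "mean_rg", "sd_rg", "n_obs"])


def classify_dimer_motif(
    frame: SystemFrame,
    template: MonomerTemplate,
    i: int,
    j: int,
) -> str:
    """β-sheet-like dimer motif classification.

    The motif requires BOTH (a) a backbone hydrogen bond — amide N–H of
    one monomer to a carbonyl oxygen (carbamate or carboxyl C=O) of the
    other — and (b) a face-to-face aromatic stack between the monomers'
    Fmoc ring systems or their Phe rings.  Parallel vs antiparallel is
    the sign of the dot product of the two backbone direction vectors
    (carbamate C → carboxyl C).  Returns ``'parallel_beta_like'``,
    ``'antiparallel_beta_like'`` or ``'none'``.
    """
    bm = template.backbone_map
    box = frame.box

    hbond = False
    for a, b in ((i, j), (j, i)):
        for acc in (bm["carbamate_O"], bm["carboxyl_O1"]):
            ok, _ = detect_hbond(
                frame.coords[a, bm["amide_N"]],
                frame.coords[a, bm["amide_H"]],
                frame.coords[b, acc],
                box,
            )
            if ok:
                hbond = True
                break
        if hbond:
            break
    if not hbond:
        return "none"

    fmoc_rings = [template.rings["FMOC_RING_A"], template.rings["FMOC_RING_B"]]
    phe_ring = [template.rings["PHE_RING"]]
    stacked = False
    for rings in (fmoc_rings, phe_ring):
        for ra in rings:
            for rb in rings:
                cls, _ = classify_stacking(
                    frame.coords[i, ra], frame.coords[j, rb], box
                )
                if cls == "face_to_face":
                    stacked = True
                    break
            if stacked:
                break
        if stacked:
            break
    if not stacked:
        return "none"

    v_i = minimum_image(
        frame.coords[i, bm["carboxyl_C"]] - frame.coords[i, bm["carbamate_C"]], None
    )
    v_j = frame.coords[j, bm["carboxyl_C"]] - frame.coords[j, bm["carbamate_C"]]
    return "parallel_beta_like" if float(v_i @ v_j) >= 0 else "antiparallel_beta_like"
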