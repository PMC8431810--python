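"""Pairwise inter-monomer interaction detection and classification.

A uniform 4.0 Å heavy-atom distance criterion (minimum image) defines
when two atom groups interact.  On top of that cutoff the taxonomy
distinguishes aromatic stacking (with a face-to-face vs offset/edge
classification from ring-centroid distance and interplanar angle),
fluorine contacts, and hydrogen bonds (donor–acceptor distance plus
D–H···A angle).  The percent-frequency statistic normalizes interaction
counts per replicate — each label's count divided by the total number of
interactions observed in that replicate — and aggregates mean and SD
across replicates.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import yaml

from .core_model import Moiety, MonomerTemplate, SystemFrame
from .geometry import minimum_image, pairwise_min_distance, ring_centroid_normal

__all__ = [
    "Rule",
    "InteractionSpec",
    "InteractionEvent",
    "default_taxonomy",
    "load_taxonomy",
    "min_heavy_atom_distance",
    "classify_stacking",
    "detect_hbond",
    "enumerate_interactions",
    "percent_frequency",
    "CUTOFF",
    "D_STACK",
    "THETA_FACE",
    "HBOND_DA_MAX",
    "HBOND_ANGLE_MIN",
    "CHF_DA_MAX",
    "CHF_ANGLE_MIN",
]

logger = logging.getLogger(__name__)

# module defaults; every threshold is also settable per taxonomy entry
CUTOFF = 4.0  # Å, uniform interaction criterion
D_STACK = 5.5  # Å, ring centroid-centroid gate for stack labels
THETA_FACE = 30.0  # deg, interplanar angle for face-to-face
HBOND_DA_MAX = 3.5  # Å, donor...acceptor for N/O donors
HBOND_ANGLE_MIN = 120.0  # deg
CHF_DA_MAX = 3.7  # Å, weak C-H...F
CHF_ANGLE_MIN = 110.0  # deg


class Rule(str, enum.Enum):
    CUTOFF_CONTACT = "CUTOFF_CONTACT"
    STACKING = "STACKING"
    HBOND = "HBOND"


@dataclass(frozen=True)
class InteractionSpec:
    """One taxonomy entry: a label, its atom-group selectors and rule.

    ``group_a``/``group_b`` are selector expressions resolved against the
    template: ``moiety:NAME[+NAME...]``, ``ring:NAME[|NAME...]`` (STACKING),
    ``atoms:NAME,NAME`` or ``donor:D-H`` / ``acceptor:NAME,...`` (HBOND).
    """

    label: str
    rule: Rule
    group_a: str
    group_b: str
    params: dict = field(default_factory=dict)


def default_taxonomy() -> list[InteractionSpec]:
    """The interaction taxonomy tracked for all variants.

    Fluorine entries resolve to empty groups on the unfluorinated parent
    and simply never fire there, so the same set can be tracked for every
    system.
    """
    return [
        InteractionSpec("FMOC_FMOC_STACK", Rule.STACKING, "ring:FMOC_RING_A|FMOC_RING_B", "ring:FMOC_RING_A|FMOC_RING_B"),
        InteractionSpec("PHE_PHE_STACK", Rule.STACKING, "ring:PHE_RING", "ring:PHE_RING"),
        InteractionSpec("FMOC_PHE_STACK", Rule.STACKING, "ring:FMOC_RING_A|FMOC_RING_B", "ring:PHE_RING"),
        InteractionSpec("F_F", Rule.CUTOFF_CONTACT, "moiety:FLUORINE", "moiety:FLUORINE"),
        InteractionSpec("F_FMOC", Rule.CUTOFF_CONTACT, "moiety:FLUORINE", "moiety:FMOC"),
        InteractionSpec("F_PHE", Rule.CUTOFF_CONTACT, "moiety:FLUORINE", "ring:PHE_RING"),
        InteractionSpec("F_TERMINAL_O", Rule.CUTOFF_CONTACT, "moiety:FLUORINE", "atoms:O1,O2"),
        InteractionSpec(
            "COOH_COOH_HBOND", Rule.HBOND, "donor:O2-HO2", "acceptor:O1,O2",
        ),
        InteractionSpec(
            "BACKBONE_HBOND", Rule.HBOND, "donor:N-HN", "acceptor:O4,O1",
        ),
    ]


def load_taxonomy(path) -> list[InteractionSpec]:
    """Read a taxonomy from YAML (list of label/rule/group_a/group_b maps)."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    specs = [
        InteractionSpec(
            e["label"], Rule(e["rule"]), e["group_a"], e["group_b"],
            e.get("params", {}),
        )
        for e in entries
    ]
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("taxonomy labels must be unique")
    return specs


def resolve_selector(template: MonomerTemplate, expr: str):
    """Resolve a selector expression to atom indices on the template.

    Returns an int array for plain groups, a list of ring-name index
    lists for ``ring:`` under STACKING, or ``(D, H)`` pairs for donors.
    """
    kind, _, arg = expr.partition(":")
    if kind == "moiety":
        moieties = [Moiety(m) for m in arg.split("+")]
        return template.moiety_indices(*moieties)
    if kind == "ring":
        return [list(template.rings[name]) for name in arg.split("|")]
    if kind == "atoms" or kind == "acceptor":
        return np.array([template.index_of(n) for n in arg.split(",")], dtype=int)
    if kind == "donor":
        pairs = []
        for token in arg.split(","):
            d, h = token.split("-")
            pairs.append((template.index_of(d), template.index_of(h)))
        return pairs
    raise ValueError(f"unknown selector expression {expr!r}")


def _flat_ring_atoms(template: MonomerTemplate, expr: str) -> np.ndarray:
    rings = resolve_selector(template, expr)
    return np.unique(np.concatenate(rings))


@dataclass
class InteractionEvent:
    """One detected (frame, monomer pair, label) interaction."""

    frame_index: int
    i: int
    j: int
    label: str
    min_distance: float
    replicate_id: int = 0
    geometry: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-interaction event")
        if self.i > self.j:
            self.i, self.j = self.j, self.i


def min_heavy_atom_distance(
    frame: SystemFrame,
    i: int,
    j: int,
    sel_i: np.ndarray,
    sel_j: np.ndarray,
) -> float:
    """Minimum-image minimum distance between selected atoms of monomers
    ``i`` and ``j``.  Selections index into the monomer's atom table."""
    sel_i = np.asarray(sel_i, dtype=int)
    sel_j = np.asarray(sel_j, dtype=int)
    if sel_i.size == 0 or sel_j.size == 0:
        raise ValueError("empty atom selection")
    return pairwise_min_distance(
        frame.coords[i, sel_i], frame.coords[j, sel_j], frame.box
    )


def classify_stacking(
    ring_a_xyz: np.ndarray,
    ring_b_xyz: np.ndarray,
    box: np.ndarray | None = None,
    d_stack: float = D_STACK,
    theta_face: float = THETA_FACE,
) -> tuple[str, dict]:
    """Classify a ring pair as face_to_face / offset_or_edge / none.

    Face-to-face requires centroid separation ≤ ``d_stack`` and an
    interplanar angle ≤ ``theta_face``; within ``d_stack`` but tilted is
    offset_or_edge; beyond ``d_stack`` is none.  Raises for non-planar or
    degenerate rings.
    """
    ca, na = ring_centroid_normal(ring_a_xyz)
    cb, nb = ring_centroid_normal(ring_b_xyz)
    dvec = minimum_image(cb - ca, box)
    d = float(np.linalg.norm(dvec))
    cosang = abs(float(na @ nb))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    geom = {"centroid_distance": d, "interplanar_angle": angle}
    if d > d_stack:
        return "none", geom
    if angle <= theta_face:
        return "face_to_face", geom
    return "offset_or_edge", geom


def detect_hbond(
    donor_xyz: np.ndarray,
    h_xyz: np.ndarray | None,
    acceptor_xyz: np.ndarray,
    box: np.ndarray | None = None,
    da_max: float = HBOND_DA_MAX,
    angle_min: float = HBOND_ANGLE_MIN,
) -> tuple[bool, dict]:
    """Hydrogen-bond test: D···A ≤ ``da_max`` and ∠(D–H···A) ≥ ``angle_min``.

    The donor hydrogen must be supplied explicitly; geometric H placement
    is the caller's job (see crystal module) — a missing H raises.
    """
    if h_xyz is None:
        raise ValueError(
            "hydrogen bond test requires an explicit donor H; place hydrogens first"
        )
    donor_xyz = np.asarray(donor_xyz, float)
    h_xyz = np.asarray(h_xyz, float)
    acceptor_xyz = np.asarray(acceptor_xyz, float)
    da = float(np.linalg.norm(minimum_image(acceptor_xyz - donor_xyz, box)))
    v_hd = minimum_image(donor_xyz - h_xyz, box)
    v_ha = minimum_image(acceptor_xyz - h_xyz, box)
    cosang = float(
        v_hd @ v_ha / (np.linalg.norm(v_hd) * np.linalg.norm(v_ha))
    )
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    geom = {"da_distance": da, "dha_angle": angle}
    return (da <= da_max and angle >= angle_min), geom


def _monomer_bounding_radius(template: MonomerTemplate) -> float:
    xyz = template.coords[template.heavy_indices]
    c = xyz.mean(axis=0)
    return float(np.max(np.linalg.norm(xyz - c, axis=1)))


def enumerate_interactions(
    trajectory,
    specs: list[InteractionSpec] | None = None,
    cutoff: float = CUTOFF,
    counting: str = "pair",
) -> list[InteractionEvent]:
    """Detect all taxonomy interactions in a trajectory.

    ``counting='pair'`` emits at most one event per (frame, monomer pair,
    label); ``counting='atom_pair'`` counts every satisfying atom pair for
    CUTOFF_CONTACT entries.  Stack labels additionally require the ring
    centroids within the stacking gate; hydrogen-bond labels apply their
    distance/angle criteria (looser for C–H···F donors).
    """
    if counting not in ("pair", "atom_pair"):
        raise ValueError("counting must be 'pair' or 'atom_pair'")
    template = trajectory.template
    specs = default_taxonomy() if specs is None else specs
    resolved = []
    for spec in specs:
        ga = resolve_selector(template, spec.group_a)
        gb = resolve_selector(template, spec.group_b)
        resolved.append((spec, ga, gb))

    heavy = template.heavy_indices
    r_bound = _monomer_bounding_radius(template)
    prefilter = max(cutoff, D_STACK, HBOND_DA_MAX, CHF_DA_MAX) + 2 * r_bound + 0.5

    events: list[InteractionEvent] = []
    for frame in trajectory.frames:
        centers = frame.coords[:, heavy, :].mean(axis=1)
        for i, j in combinations(range(frame.n_monomers), 2):
            dc = np.linalg.norm(minimum_image(centers[j] - centers[i], frame.box))
            if dc > prefilter:
                continue
            for spec, ga, gb in resolved:
                events.extend(
                    _apply_spec(
                        frame, i, j, spec, ga, gb, template, cutoff, counting,
                        trajectory.replicate_id,
                    )
                )
    return events


def _apply_spec(frame, i, j, spec, ga, gb, template, cutoff, counting, replicate):
    out = []
    if spec.rule is Rule.CUTOFF_CONTACT:
        ga = _flatten_group(ga)
        gb = _flatten_group(gb)
        for (a, b, mi, mj) in _sym_orders(ga, gb, i, j):
            if counting == "atom_pair":
                xa = frame.coords[mi, a]
                xb = frame.coords[mj, b]
                d = minimum_image(xa[:, None, :] - xb[None, :, :], frame.box)
                dist = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
                for ai, bi in zip(*np.nonzero(dist <= cutoff)):
                    out.append(
                        InteractionEvent(
                            frame.frame_index, mi, mj, spec.label,
                            float(dist[ai, bi]), replicate,
                            {"atom_a": int(a[ai]), "atom_b": int(b[bi])},
                        )
                    )
            else:
                dmin = min_heavy_atom_distance(frame, mi, mj, a, b)
                if dmin <= cutoff:
                    out.append(
                        InteractionEvent(
                            frame.frame_index, mi, mj, spec.label, dmin, replicate
                        )
                    )
                    break
    elif spec.rule is Rule.STACKING:
        d_stack = spec.params.get("d_stack", D_STACK)
        theta = spec.params.get("theta_face", THETA_FACE)
        best = None
        for rings_a, rings_b, mi, mj in _sym_orders(ga, gb, i, j, flat=False):
            for ra in rings_a:
                for rb in rings_b:
                    dmin = min_heavy_atom_distance(frame, mi, mj, ra, rb)
                    if dmin > cutoff:
                        continue
                    cls, geom = classify_stacking(
                        frame.coords[mi, ra], frame.coords[mj, rb],
                        frame.box, d_stack, theta,
                    )
                    if cls == "none":
                        continue
                    geom["classification"] = cls
                    cand = InteractionEvent(
                        frame.frame_index, mi, mj, spec.label, dmin, replicate, geom
                    )
                    if best is None or geom["centroid_distance"] < best.geometry["centroid_distance"]:
                        best = cand
        if best is not None:
            out.append(best)
    elif spec.rule is Rule.HBOND:
        da_max = spec.params.get("da_max", HBOND_DA_MAX)
        angle_min = spec.params.get("angle_min", HBOND_ANGLE_MIN)
        found = None
        for donors, acceptors, mi, mj in _sym_orders(ga, gb, i, j, flat=False):
            for d_idx, h_idx in donors:
                for a_idx in np.atleast_1d(acceptors):
                    ok, geom = detect_hbond(
                        frame.coords[mi, d_idx], frame.coords[mi, h_idx],
                        frame.coords[mj, int(a_idx)], frame.box, da_max, angle_min,
                    )
                    if ok and (found is None or geom["da_distance"] < found.geometry["da_distance"]):
                        found = InteractionEvent(
                            frame.frame_index, mi, mj, spec.label,
                            geom["da_distance"], replicate, geom,
                        )
        if found is not None:
            out.append(found)
    return out


def _flatten_group(g) -> np.ndarray:
    """Ring selectors resolve to per-ring index lists; contact rules see
    the union of their atoms."""
    if isinstance(g, np.ndarray):
        return g
    return np.unique(np.concatenate([np.atleast_1d(x) for x in g]))


def _sym_orders(ga, gb, i, j, flat=True):
    """Yield both (group_a on i, group_b on j) and the swapped assignment,
    skipping the duplicate when both groups are identical."""
    if isinstance(ga, np.ndarray) or isinstance(gb, np.ndarray):
        same = (
            isinstance(ga, np.ndarray)
            and isinstance(gb, np.ndarray)
            and np.array_equal(ga, gb)
        )
    else:
        same = ga == gb
    yield ga, gb, i, j
    if not same:
        yield ga, gb, j, i


def percent_frequency(
    events: list[InteractionEvent],
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Percent-frequency table: per replicate, each label's share of all
    interactions observed in that replicate, plus across-replicate mean
    and sample SD per label.

    Returns a tidy DataFrame with columns ``label, replicate, count,
    percent`` plus aggregate rows (``replicate = 'mean'|'sd'``).
    Replicates with zero events are reported as missing and excluded
    from the aggregates with a logged warning.
    """
    if labels is None:
        labels = sorted({e.label for e in events})
    replicates = sorted({e.replicate_id for e in events})
    rows = []
    per_label = {lab: [] for lab in labels}
    for rep in replicates:
        rep_events = [e for e in events if e.replicate_id == rep]
        total = len(rep_events)
        if total == 0:
            logger.warning("replicate %s has zero events; percents undefined", rep)
            continue
        for lab in labels:
            count = sum(1 for e in rep_events if e.label == lab)
            pct = 100.0 * count / total
            per_label[lab].append(pct)
            rows.append({"label": lab, "replicate": rep, "count": count, "percent": pct})
    for lab in labels:
        vals = np.array(per_label[lab], dtype=float)
        mean = float(vals.mean()) if vals.size else float("nan")
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append({"label": lab, "replicate": "mean", "count": np.nan, "percent": mean})
        rows.append({"label": lab, "replicate": "sd", "count": np.nan, "percent": sd})
    return pd.DataFrame(rows)
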