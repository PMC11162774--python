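"""Nucleobase centroid/plane geometry and intercalation calls.

A 16S rRNA base (A1503, optionally C1397) is classified against the mRNA
as *intercalated* (inserted face-on between two adjacent mRNA bases),
*stacked* (face-on over a single mRNA base), *retracted* (out of stacking
range of every mRNA base) or *unresolved* (required geometry missing).

The screen works on base centroids (mean of ring atoms) and least-squares
base planes. A base j is a stacking partner of the query when all three
hold:

  d_j     <= d_stack   centroid-centroid distance
  alpha_j <= alpha_max acute angle between the two base planes
  omega_j <= omega_max acute angle between the centroid-centroid vector
                       and the query's plane normal (face-on, not edge-on)

Intercalation additionally requires the two partners to sit at adjacent
mRNA positions with the query centroid between their planes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryUnresolvedError
from .structure_io import RibosomeStructure, base_letter

PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


@dataclass
class BaseGeometry:
    """Centroid and plane of one nucleobase."""

    residue: tuple  # (chain_id, residue_number, insertion_code)
    base_type: str  # {"purine", "pyrimidine", "unknown"}
    centroid: np.ndarray
    normal: np.ndarray  # unit vector
    ring_atom_count: int


@dataclass(frozen=True)
class ContactThresholds:
    """Stacking-geometry cutoffs, recorded into every report."""

    d_stack: float = 4.5     # A, max centroid distance for a partner
    alpha_max: float = 30.0  # deg, max inter-plane angle
    omega_max: float = 40.0  # deg, max off-normal angle (face-on test)
    d_retract: float = 6.0   # A, beyond this the query is out of range
    tie_tol: float = 0.01    # A, partner distance tie tolerance


@dataclass
class ContactCall:
    call: str                 # {"intercalated", "stacked", "retracted", "unresolved"}
    partners: tuple = ()      # mRNA paper-convention positions, 5'-most first
    centroid_distances: dict = field(default_factory=dict)  # position -> A
    plane_angles: dict = field(default_factory=dict)        # position -> deg
    warnings: tuple = ()
    thresholds: ContactThresholds = field(default_factory=ContactThresholds)


def _ring_set_for(residue_name: str, present: set) -> tuple:
    letter = base_letter(residue_name)
    if letter in ("A", "G"):
        return PURINE_RING, "purine"
    if letter in ("C", "U"):
        return PYRIMIDINE_RING, "pyrimidine"
    # unknown/modified: prefer the set with better coverage
    n_pur = sum(1 for n in PURINE_RING if n in present)
    n_pyr = sum(1 for n in PYRIMIDINE_RING if n in present)
    return (PURINE_RING, "unknown") if n_pur > n_pyr else (PYRIMIDINE_RING, "unknown")


def base_geometry(s: RibosomeStructure, chain_id: str, residue_number: int,
                  insertion_code: str = "",
                  five_prime_centroid: np.ndarray | None = None) -> BaseGeometry:
    """Centroid and least-squares plane normal of a base's ring atoms.

    The normal sign points toward the 5' neighbour's centroid when given;
    otherwise the sign is arbitrary but deterministic. Fewer than 5 ring
    atoms raises :class:`GeometryUnresolvedError`.
    """
    atoms = s.residue_atoms(chain_id, residue_number, insertion_code)
    name = s.residue_name(chain_id, residue_number, insertion_code) or ""
    ring, btype = _ring_set_for(name, set(atoms))
    pts = np.array([atoms[n] for n in ring if n in atoms], float)
    if len(pts) < 5:
        raise GeometryUnresolvedError(
            f"{chain_id}/{residue_number}{insertion_code}: only {len(pts)} ring atoms")
    centroid = pts.mean(axis=0)
    # plane normal = smallest-variance axis of the ring-atom cloud
    _, _, vt = np.linalg.svd(pts - centroid)
    normal = vt[-1]
    if five_prime_centroid is not None:
        if np.dot(normal, np.asarray(five_prime_centroid) - centroid) < 0:
            normal = -normal
    elif normal[np.argmax(np.abs(normal))] < 0:  # deterministic sign
        normal = -normal
    return BaseGeometry((chain_id, residue_number, insertion_code),
                        btype, centroid, normal / np.linalg.norm(normal), len(pts))


def _acute_deg(cos_val: float) -> float:
    return float(np.degrees(np.arccos(np.clip(abs(cos_val), 0.0, 1.0))))


def positions_adjacent(a: int, b: int) -> bool:
    """Adjacent mRNA positions; the register skips 0, so -1 and +1 touch."""
    lo, hi = min(a, b), max(a, b)
    return hi - lo == 1 or (lo == -1 and hi == 1)


def classify_contact(query: BaseGeometry,
                     mrna: list,
                     thresholds: ContactThresholds | None = None) -> ContactCall:
    """Classify the query base against mRNA bases.

    ``mrna`` is a list of (paper position, BaseGeometry-or-None) pairs,
    ordered 5'->3'. Positions with None geometry are skipped (and noted).
    """
    th = thresholds or ContactThresholds()
    if not mrna:
        raise ValueError("empty mRNA base list")

    warnings = []
    valid = [(pos, g) for pos, g in mrna if g is not None]
    if len(valid) < 2:
        return ContactCall("unresolved", warnings=("mrna_coverage",), thresholds=th)

    dists, angles, omegas = {}, {}, {}
    for pos, g in valid:
        v = g.centroid - query.centroid
        d = float(np.linalg.norm(v))
        dists[pos] = d
        angles[pos] = _acute_deg(float(np.dot(query.normal, g.normal)))
        omegas[pos] = _acute_deg(float(np.dot(v / d, query.normal))) if d > 1e-9 else 0.0

    partners = [pos for pos in dists
                if dists[pos] <= th.d_stack
                and angles[pos] <= th.alpha_max
                and omegas[pos] <= th.omega_max]
    # nearest first; distance ties broken toward the more 5' position
    partners.sort(key=lambda p: (round(dists[p] / th.tie_tol), p))

    if not partners:
        return ContactCall("retracted", (), dists, angles, tuple(warnings), th)

    if len(partners) >= 2:
        a, b = partners[0], partners[1]
        if len(partners) > 2:
            warnings.append("extra_partners_ignored")
        if positions_adjacent(a, b):
            ga = dict(valid)[a]
            gb = dict(valid)[b]
            nb = gb.normal if np.dot(ga.normal, gb.normal) >= 0 else -gb.normal
            mean_n = ga.normal + nb
            mean_n /= np.linalg.norm(mean_n)
            sa = float(np.dot(query.centroid - ga.centroid, mean_n))
            sb = float(np.dot(query.centroid - gb.centroid, mean_n))
            if sa * sb < 0:
                pair = tuple(sorted((a, b)))
                return ContactCall("intercalated", pair, dists, angles,
                                   tuple(warnings), th)
            warnings.append("partners_same_side")
        else:
            warnings.append("nonconsecutive_partners")
        return ContactCall("stacked", (partners[0],), dists, angles,
                           tuple(warnings), th)

    return ContactCall("stacked", (partners[0],), dists, angles, tuple(warnings), th)
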