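"""30S body/head rotation measurement and conformational-state calls.

The ribosome's conformational state is read from two rigid-body angles
measured against a non-rotated (classical-state) reference:

* body rotation — rotation of the 30S body domain relative to the 50S
  (23S rRNA core) frame;
* head rotation — swivel of the 30S head domain relative to the 30S body.

Both are obtained by a two-stage least-squares superposition (Kabsch) of
phosphorus atoms followed by an axis-angle (Euler-Rodrigues) decomposition
of the residual rotation matrix. State windows: chimeric-hybrid for head
rotation in [15, 21] deg, hybrid for body rotation in [6, 10] deg,
classical for body <= 3 deg and head <= 6 deg, otherwise unassigned;
precedence chimeric > hybrid > classical.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateFitError, MeasurementUnresolvedError
from .structure_io import ChainMap, RibosomeStructure

# Community-standard 30S head boundary (E. coli 16S numbering) and 23S
# mobile elements excluded from the 50S frame (L1 stalk, A-site finger).
DEFAULT_HEAD_16S = ((930, 1381),)
DEFAULT_23S_EXCLUDE = ((880, 898), (2093, 2196))


@dataclass(frozen=True)
class DomainDefinition:
    """Residue ranges defining the rigid domains used for the fits."""

    head_16S: tuple = DEFAULT_HEAD_16S
    body_16S: tuple | None = None   # None = all 16S residues not in head
    core_23S: tuple | None = None   # None = all 23S residues minus excludes
    core_23S_exclude: tuple = DEFAULT_23S_EXCLUDE
    atom_selector: str = "P"
    min_paired_atoms: int = 20
    body_forward_axis: tuple | None = None  # reference handedness, optional
    head_forward_axis: tuple | None = None


@dataclass
class RotationMeasurement:
    body_angle: float            # deg, magnitude
    head_angle: float            # deg, magnitude
    body_axis: np.ndarray
    head_axis: np.ndarray
    body_sign: str = "forward"   # {"forward", "reverse"}
    head_sign: str = "forward"
    fit_rmsd_core: float = 0.0
    fit_rmsd_body: float = 0.0
    fit_rmsd_head: float = 0.0
    n_atoms_core: int = 0
    n_atoms_body: int = 0
    n_atoms_head: int = 0
    frame_fallback: bool = False  # True when 23S absent and body used as frame


@dataclass(frozen=True)
class StateWindows:
    """Angle windows for the conformational-state call (degrees)."""

    hybrid_body: tuple = (6.0, 10.0)
    chimeric_head: tuple = (15.0, 21.0)
    classical_body_max: float = 3.0
    classical_head_max: float = 6.0


@dataclass
class StateCall:
    state: str  # {"classical", "hybrid", "chimeric_hybrid", "unassigned"}
    windows: StateWindows = field(default_factory=StateWindows)


# ---------------------------------------------------------------------------
# Rigid superposition and axis-angle extraction

def superpose(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares rigid superposition (Kabsch).

    Returns (R, t, rmsd) with fixed ~= moving @ R.T + t and det(R) = +1.
    Raises :class:`DegenerateFitError` for n < 3 or (near-)collinear sets.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = len(moving)
    if n < 3:
        raise DegenerateFitError(f"need >= 3 points, got {n}")
    cm, cf = moving.mean(0), fixed.mean(0)
    A, B = moving - cm, fixed - cf
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    scale = S[0] if S[0] > 0 else 1.0
    if S[1] / scale < 1e-8:
        raise DegenerateFitError("collinear point set, rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    diff = (moving @ R.T + t) - fixed
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> None:
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R @ R.T, np.eye(3), atol=tol) or abs(np.linalg.det(R) - 1) > tol:
        raise ValueError("input is not a proper rotation matrix")


def axis_angle(R: np.ndarray):
    """Axis-angle (Euler-Rodrigues) decomposition of a rotation matrix.

    Uses the Euler-Rodrigues (unit quaternion) parameters via Shepperd's
    stable branch selection, so both theta -> 0 and theta -> 180 deg are
    well conditioned. Returns (theta in degrees in [0, 180], unit axis).
    """
    R = np.asarray(R, float)
    _check_rotation(R)
    tr = np.trace(R)
    # pick the largest of (1+tr, 1+2*R00-tr, ...) for numerical stability
    choices = [tr, R[0, 0], R[1, 1], R[2, 2]]
    k = int(np.argmax(choices))
    if k == 0:
        w = 0.5 * np.sqrt(max(1.0 + tr, 0.0))
        v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]) / (4 * w)
    else:
        i = k - 1
        j, l = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(max(1.0 + R[i, i] - R[j, j] - R[l, l], 0.0))
        v = np.empty(3)
        v[i] = 0.5 * s
        w = (R[l, j] - R[j, l]) / (2 * s)
        v[j] = (R[j, i] + R[i, j]) / (2 * s)
        v[l] = (R[l, i] + R[i, l]) / (2 * s)
    if w < 0:  # canonical hemisphere: theta in [0, 180]
        w, v = -w, -v
    norm_v = np.linalg.norm(v)
    theta = float(np.degrees(2.0 * np.arctan2(norm_v, w)))
    axis = v / norm_v if norm_v > 1e-12 else np.array([0.0, 0.0, 1.0])
    return theta, axis


def rotation_from_axis_angle(theta_deg: float, axis) -> np.ndarray:
    """Rodrigues' formula; inverse of :func:`axis_angle` on (0, 180) deg."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.radians(theta_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


# ---------------------------------------------------------------------------
# Domain atom selection and the two-stage measurement

def _in_ranges(num: int, ranges) -> bool:
    return any(lo <= num <= hi for lo, hi in ranges)


def _paired_coords(s: RibosomeStructure, ref: RibosomeStructure,
                   chain_s: str, chain_ref: str,
                   ranges, exclude, complement_of,
                   selector: str,
                   offset_s: int = 0, offset_ref: int = 0):
    """Coordinates of `selector` atoms paired across structures by E. coli number."""
    def eligible(st, chain, offset):
        out = {}
        for (num, icode) in st.chain_residues(chain):
            if icode:
                continue
            ecoli = num - offset
            if ranges is not None and not _in_ranges(ecoli, ranges):
                continue
            if complement_of is not None and _in_ranges(ecoli, complement_of):
                continue
            if exclude and _in_ranges(ecoli, exclude):
                continue
            atoms = st.residue_atoms(chain, num)
            if selector in atoms:
                out[ecoli] = atoms[selector]
        return out

    a = eligible(s, chain_s, offset_s)
    b = eligible(ref, chain_ref, offset_ref)
    common = sorted(set(a) & set(b))
    return (np.array([a[k] for k in common]) if common else np.empty((0, 3)),
            np.array([b[k] for k in common]) if common else np.empty((0, 3)))


def measure_rotations(s: RibosomeStructure, ref: RibosomeStructure,
                      cm_s: ChainMap, cm_ref: ChainMap,
                      dd: DomainDefinition | None = None) -> RotationMeasurement:
    """Measure 30S body and head rotation of `s` relative to `ref`.

    Stage 1 superposes the 23S core (50S frame); stage 2 reads the body
    angle from the residual body-domain rotation; stage 3 aligns body
    frames and reads the head angle from the residual head rotation.
    """
    dd = dd or DomainDefinition()
    off_s, off_ref = cm_s.numbering_offset_16S, cm_ref.numbering_offset_16S

    def require(mov, fix, stage):
        if len(mov) < dd.min_paired_atoms:
            raise MeasurementUnresolvedError(
                f"{s.pdb_id}: only {len(mov)} paired atoms in {stage} fit "
                f"(minimum {dd.min_paired_atoms})")
        return superpose(mov, fix)

    frame_fallback = not (cm_s.rrna23S and cm_ref.rrna23S)
    body_mov, body_fix = _paired_coords(
        s, ref, cm_s.rrna16S, cm_ref.rrna16S,
        dd.body_16S, None, dd.head_16S if dd.body_16S is None else None,
        dd.atom_selector, off_s, off_ref)
    head_mov, head_fix = _paired_coords(
        s, ref, cm_s.rrna16S, cm_ref.rrna16S,
        dd.head_16S, None, None, dd.atom_selector, off_s, off_ref)

    if frame_fallback:
        core_mov, core_fix = body_mov, body_fix
        n_core = 0
        R1, t1, rmsd_core = require(core_mov, core_fix, "frame (16S body fallback)")
    else:
        core_mov, core_fix = _paired_coords(
            s, ref, cm_s.rrna23S, cm_ref.rrna23S,
            dd.core_23S, dd.core_23S_exclude, None, dd.atom_selector)
        n_core = len(core_mov)
        R1, t1, rmsd_core = require(core_mov, core_fix, "23S core")

    body_mov1 = body_mov @ R1.T + t1
    head_mov1 = head_mov @ R1.T + t1

    Rb, tb, rmsd_body = require(body_mov1, body_fix, "16S body")
    body_angle, body_axis = axis_angle(Rb)

    head_mov2 = head_mov1 @ Rb.T + tb
    Rh, th_, rmsd_head = require(head_mov2, head_fix, "16S head")
    head_angle, head_axis = axis_angle(Rh)

    def sign_of(axis, forward):
        if forward is None:
            return "forward"
        return "forward" if float(np.dot(axis, np.asarray(forward, float))) >= 0 else "reverse"

    return RotationMeasurement(
        body_angle=body_angle, head_angle=head_angle,
        body_axis=body_axis, head_axis=head_axis,
        body_sign=sign_of(body_axis, dd.body_forward_axis),
        head_sign=sign_of(head_axis, dd.head_forward_axis),
        fit_rmsd_core=rmsd_core, fit_rmsd_body=rmsd_body, fit_rmsd_head=rmsd_head,
        n_atoms_core=n_core, n_atoms_body=len(body_mov), n_atoms_head=len(head_mov),
        frame_fallback=frame_fallback,
    )


def classify_state(m: RotationMeasurement,
                   windows: StateWindows | None = None) -> StateCall:
    """Assign classical / hybrid / chimeric-hybrid / unassigned.

    Precedence chimeric > hybrid > classical; magnitudes are compared (the
    windows are defined on unsigned angles), hybrid additionally requires
    the forward rotation sense when a reference handedness was recorded.
    """
    w = windows or StateWindows()
    if w.chimeric_head[0] <= m.head_angle <= w.chimeric_head[1]:
        return StateCall("chimeric_hybrid", w)
    if w.hybrid_body[0] <= m.body_angle <= w.hybrid_body[1] and m.body_sign == "forward":
        return StateCall("hybrid", w)
    if m.body_angle <= w.classical_body_max and m.head_angle <= w.classical_head_max:
        return StateCall("classical", w)
    return StateCall("unassigned", w)
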