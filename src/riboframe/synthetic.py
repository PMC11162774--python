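"""Labeled synthetic fixtures: base-stack scenes and two-domain subunits.

Every stage of the pipeline is testable without downloading deposited
structures. Two families of fixtures are generated, each carrying its
truth label by construction (never computed by the classifier under test):

* mRNA base stacks with an insertable query base, realising intercalated /
  stacked / retracted scenes with a controllable margin beyond the
  classifier thresholds;
* two-domain rigid bodies (16S body + head point clouds against a 23S
  core frame) with known injected rotation angles and optional isotropic
  Gaussian coordinate noise.

Ring-atom templates are idealized planar base geometries (1.39 A bonds);
absolute bond lengths only need to be plausible since classification uses
centroids and planes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ContactThresholds
from .rotation import rotation_from_axis_angle
from .structure_io import Atom, ChainMap, MRNARegister, RibosomeStructure

_BOND = 1.39  # A, aromatic ring bond length used for the templates


def _hexagon() -> dict:
    """Planar six-membered ring N1,C2,...,C6, centroid at the origin."""
    names = ("N1", "C2", "N3", "C4", "C5", "C6")
    r = _BOND  # circumradius of a regular hexagon equals its side
    return {n: np.array([r * math.cos(math.radians(90 - 60 * k)),
                         r * math.sin(math.radians(90 - 60 * k)), 0.0])
            for k, n in enumerate(names)}


def _purine_template() -> dict:
    """Hexagon with a fused five-ring (N7, C8, N9) sharing the C4-C5 edge."""
    atoms = _hexagon()
    a, b = atoms["C5"], atoms["C4"]
    edge = b - a
    L = np.linalg.norm(edge)
    mid = (a + b) / 2
    out = mid / np.linalg.norm(mid)  # outward from hexagon centre
    # regular pentagon on the shared edge: apothem and vertex geometry
    r_c = L / (2 * math.sin(math.pi / 5))          # circumradius
    centre = mid + out * (r_c * math.cos(math.pi / 5))
    # vertex angles measured from pentagon centre; shared vertices at +-36 deg
    ang0 = math.atan2(*(a - centre)[[1, 0]])
    step = 2 * math.pi / 5
    # walk away from the shared edge; pick direction giving outward vertices
    cand = [centre + r_c * np.array([math.cos(ang0 + s * step * k),
                                     math.sin(ang0 + s * step * k), 0.0])
            for s in (+1, -1) for k in (1, 2, 3)]
    fwd = cand[:3] if np.linalg.norm(cand[0] - b) > 1e-6 else cand[3:]
    atoms["N7"], atoms["C8"], atoms["N9"] = fwd
    # recentre so the 9-atom ring centroid is at the origin
    c = np.mean(list(atoms.values()), axis=0)
    return {n: p - c for n, p in atoms.items()}


_PYRIMIDINE = _hexagon()
_PURINE = _purine_template()


def base_template(residue_name: str) -> dict:
    """Idealized planar ring atoms (centroid at origin, normal +z)."""
    return dict(_PURINE if residue_name in ("A", "G") else _PYRIMIDINE)


def _place_base(residue_name: str, chain_id: str, resnum: int,
                R: np.ndarray | None = None, t: np.ndarray | None = None) -> list:
    R = np.eye(3) if R is None else R
    t = np.zeros(3) if t is None else np.asarray(t, float)
    return [Atom(chain_id, resnum, "", residue_name, name, tuple(R @ p + t))
            for name, p in base_template(residue_name).items()]


def _noisy(atoms: list, noise_sd: float, rng: np.random.Generator) -> list:
    if noise_sd <= 0:
        return list(atoms)
    out = []
    for a in atoms:
        out.append(a._replace(xyz=tuple(np.asarray(a.xyz) + rng.normal(0, noise_sd, 3))))
    return out


# ---------------------------------------------------------------------------
# mRNA stacks and contact scenes

def make_mrna_stack(n_bases: int, rise: float = 3.4, twist: float = 0.0,
                    seed: int = 0, noise_sd: float = 0.0,
                    chain_id: str = "M", start_resnum: int = 8,
                    sequence: str | None = None) -> list:
    """Idealized single-strand base stack along +z; returns Atom list.

    Residue numbers increase 5'->3' so the P-codon register convention is
    constructible on top of it.
    """
    if n_bases < 2:
        raise ValueError("need at least 2 bases")
    rng = np.random.default_rng(seed)
    seq = (sequence or ("ACGU" * n_bases))[:n_bases]
    atoms = []
    for i, letter in enumerate(seq):
        Rz = rotation_from_axis_angle(twist * i, (0, 0, 1))
        atoms += _place_base(letter, chain_id, start_resnum + i,
                             Rz, np.array([0.0, 0.0, rise * i]))
    return _noisy(atoms, noise_sd, rng)


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one labeled contact scene."""

    kind: str                      # {"intercalated", "stacked", "retracted"}
    rise: float = 3.4              # A, stacking rise
    gap_position: tuple = (-2, -1)  # adjacent mRNA positions flanking the query
    tilt: float = 0.0              # deg, query plane tilt
    noise_sd: float = 0.0          # A, isotropic Gaussian per atom
    seed: int = 0
    margin: float = 0.5            # A, label margin beyond thresholds
    positions: tuple = (-4, -3, -2, -1, 1, 2, 3)
    p_codon_start_resnum: int = 12
    query_chain: str = "S"
    query_resnum: int = 1503
    mrna_chain: str = "M"

    def __post_init__(self):
        if self.kind not in ("intercalated", "stacked", "retracted"):
            raise ValueError(f"unknown scene kind {self.kind!r}")
        if self.noise_sd < 0 or self.rise <= 0:
            raise ValueError("noise_sd must be >= 0 and rise > 0")


@dataclass
class SceneTruth:
    kind: str
    partners: tuple           # mRNA positions, 5'-most first; () for retracted
    register: MRNARegister
    query: tuple              # (chain_id, residue_number)


def _scene_register(spec: SceneSpec) -> MRNARegister:
    return MRNARegister(spec.mrna_chain, spec.p_codon_start_resnum, 1,
                        (min(spec.positions), max(spec.positions)))


def _scene_atoms(spec: SceneSpec):
    """Deterministic noise-free scene layout plus the query placement."""
    reg = _scene_register(spec)
    positions = sorted(spec.positions)
    z_of = {}
    z = 0.0
    lo_gap, hi_gap = sorted(spec.gap_position)
    for i, pos in enumerate(positions):
        if i > 0:
            prev = positions[i - 1]
            widen = (spec.kind == "intercalated" and prev == lo_gap and pos == hi_gap)
            z += 2 * spec.rise if widen else spec.rise
        z_of[pos] = z

    seq = "AUGCAUGCAU"
    atoms = []
    for i, pos in enumerate(positions):
        atoms += _place_base(seq[i % len(seq)], spec.mrna_chain,
                             reg.residue_number(pos), None,
                             np.array([0.0, 0.0, z_of[pos]]))

    Rtilt = rotation_from_axis_angle(spec.tilt, (1, 0, 0))
    if spec.kind == "intercalated":
        zq = (z_of[lo_gap] + z_of[hi_gap]) / 2
        tq = np.array([0.0, 0.0, zq])
        partners = (lo_gap, hi_gap)
    elif spec.kind == "stacked":
        top = positions[-1]
        tq = np.array([0.0, 0.0, z_of[top] + spec.rise])
        partners = (top,)
    else:
        top = positions[-1]
        tq = np.array([14.0, 0.0, z_of[top] / 2])
        partners = ()
    atoms += _place_base("A", spec.query_chain, spec.query_resnum, Rtilt, tq)
    return atoms, partners, reg


def _centroid(atoms: list, chain: str, resnum: int) -> np.ndarray:
    pts = [np.asarray(a.xyz) for a in atoms
           if a.chain_id == chain and a.residue_number == resnum]
    return np.mean(pts, axis=0)


def _margins_ok(atoms: list, spec: SceneSpec, partners: tuple,
                reg: MRNARegister, th: ContactThresholds) -> bool:
    """Verify the constructed label still holds with margin after noise.

    Uses only centroid distances (independent bookkeeping, not the
    classifier): partners must sit clearly inside d_stack, every other
    base clearly outside d_retract-relevant ranges.
    """
    qc = _centroid(atoms, spec.query_chain, spec.query_resnum)
    for pos in spec.positions:
        d = float(np.linalg.norm(_centroid(atoms, spec.mrna_chain,
                                           reg.residue_number(pos)) - qc))
        if pos in partners:
            if d > th.d_stack - spec.margin:
                return False
        elif spec.kind == "retracted":
            if d < th.d_retract + spec.margin:
                return False
        else:
            if d < th.d_stack + spec.margin:
                return False
    return True


def make_contact_scene(spec: SceneSpec,
                       thresholds: ContactThresholds | None = None,
                       max_attempts: int = 20):
    """Build one labeled scene; returns (RibosomeStructure, SceneTruth).

    With noise the scene is redrawn (new sub-seed) until the label margin
    survives; exceeding ``max_attempts`` raises RuntimeError.
    """
    th = thresholds or ContactThresholds()
    base_atoms, partners, reg = _scene_atoms(spec)
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_attempts):
        atoms = _noisy(base_atoms, spec.noise_sd, rng)
        if _margins_ok(atoms, spec, partners, reg, th):
            rs = RibosomeStructure(
                pdb_id=f"SYN-{spec.kind.upper()[:5]}-{spec.seed}",
                atoms=atoms, resolution=3.0, method="cryoem")
            return rs, SceneTruth(spec.kind, partners, reg,
                                  (spec.query_chain, spec.query_resnum))
    raise RuntimeError(
        f"could not satisfy label margin after {max_attempts} draws "
        f"(noise_sd={spec.noise_sd} too large for margin={spec.margin})")


# ---------------------------------------------------------------------------
# Two-domain rotated subunits

@dataclass(frozen=True)
class SubunitSpec:
    """Recipe for a reference/rotated pair of two-domain point clouds."""

    body_angle: float = 0.0        # deg
    head_angle: float = 0.0        # deg
    body_axis: tuple | None = None  # None = random unit vector (seeded)
    head_axis: tuple | None = None
    n_body: int = 200
    n_head: int = 150
    n_core: int = 150
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.body_angle <= 30 and 0 <= self.head_angle <= 30):
            raise ValueError("angles must lie in [0, 30] deg")
        if min(self.n_body, self.n_head, self.n_core) < 50:
            raise ValueError("need >= 50 residues per domain")


@dataclass
class SubunitTruth:
    body_angle: float
    head_angle: float
    body_axis: np.ndarray
    head_axis: np.ndarray


def _p_atoms(coords: np.ndarray, chain: str, start: int) -> list:
    return [Atom(chain, start + i, "", "A", "P", tuple(p))
            for i, p in enumerate(coords)]


def subunit_chain_map() -> ChainMap:
    return ChainMap(rrna16S="S", mrna=None, rrna23S="L")


def make_rotated_subunit(spec: SubunitSpec):
    """Reference and rotated two-domain subunits with known angles.

    Returns (reference, rotated, SubunitTruth). Chains: "S" holds 16S body
    (residues 1..n_body) and head (930..) phosphorus pseudo-atoms, "L" the
    23S core frame. The rotated copy applies the body rotation to body+head
    about the body centroid, then the head rotation about the head
    centroid; noise perturbs the rotated copy only, so truth stays exact.
    """
    rng = np.random.default_rng(spec.seed)
    body = rng.normal(0, 25, (spec.n_body, 3))
    head = rng.normal(0, 15, (spec.n_head, 3)) + np.array([0.0, 0.0, 60.0])
    core = rng.normal(0, 25, (spec.n_core, 3)) + np.array([70.0, 0.0, 0.0])

    def unit(v):
        v = np.asarray(v, float)
        return v / np.linalg.norm(v)

    b_axis = unit(spec.body_axis if spec.body_axis is not None
                  else rng.normal(size=3))
    h_axis = unit(spec.head_axis if spec.head_axis is not None
                  else rng.normal(size=3))

    Rb = rotation_from_axis_angle(spec.body_angle, b_axis)
    Rh = rotation_from_axis_angle(spec.head_angle, h_axis)

    bc = body.mean(0)
    body_r = (body - bc) @ Rb.T + bc
    head_r = (head - bc) @ Rb.T + bc
    hc = head_r.mean(0)
    head_r = (head_r - hc) @ Rh.T + hc

    if spec.noise_sd > 0:
        body_r = body_r + rng.normal(0, spec.noise_sd, body_r.shape)
        head_r = head_r + rng.normal(0, spec.noise_sd, head_r.shape)
        core_r = core + rng.normal(0, spec.noise_sd, core.shape)
    else:
        core_r = core

    head_start = 930  # inside the default head window (930-1381)

    def build(body_c, head_c, core_c, tag):
        atoms = (_p_atoms(body_c, "S", 1) + _p_atoms(head_c, "S", head_start)
                 + _p_atoms(core_c, "L", 1))
        return RibosomeStructure(pdb_id=tag, atoms=atoms,
                                 resolution=3.0, method="cryoem")

    ref = build(body, head, core, f"SYNREF-{spec.seed}")
    rot = build(body_r, head_r, core_r, f"SYNROT-{spec.seed}")
    return ref, rot, SubunitTruth(spec.body_angle, spec.head_angle, b_axis, h_axis)


# ---------------------------------------------------------------------------
# Full survey fixtures (contact scene + tRNA + rotation domains)

_STATE_ANGLES = {
    "classical": (1.0, 2.0),
    "hybrid": (8.0, 2.0),
    "chimeric_hybrid": (2.0, 18.0),
}


def make_survey_structure(contact_kind: str, state: str, seed: int = 0,
                          noise_sd: float = 0.0, resolution: float = 3.0,
                          drop_ring_atoms_at: tuple = (),
                          subunit_seed: int | None = None,
                          gap_position: tuple = (-2, -1)):
    """Compose a survey-ready structure with known contact and state labels.

    The fixture carries: an mRNA stack (chain M) with query base 1503 in
    chain S arranged per ``contact_kind``; a P-site tRNA anticodon (chain
    T, residues 34-36) paired to mRNA codon +1..+3 so the register is
    detectable; 16S body/head and 23S core pseudo-atom clouds rotated per
    ``state``. ``drop_ring_atoms_at`` removes ring atoms at the given mRNA
    paper positions (for confidence-filter tests). Structures meant to be
    measured against one shared classical reference must share a
    ``subunit_seed`` (defaults to ``seed``) so the underlying domain point
    clouds are identical across the batch.

    Returns (structure, reference_structure, truth dict, hints dict).
    """
    if state not in _STATE_ANGLES:
        raise ValueError(f"unknown state {state!r}")
    scene_spec = SceneSpec(kind=contact_kind, seed=seed, noise_sd=noise_sd,
                           gap_position=gap_position)
    scene, truth = make_contact_scene(scene_spec)
    reg = truth.register

    # anticodon bases: in-plane translated copies of the codon bases so the
    # Watson-Crick edge contact is within the pairing cutoff
    t_atoms = []
    for i, pos in enumerate((1, 2, 3)):
        resnum = reg.residue_number(pos)
        for a in scene.atoms:
            if a.chain_id == scene_spec.mrna_chain and a.residue_number == resnum:
                t_atoms.append(Atom("T", 36 - i, "", a.residue_name, a.atom_name,
                                    (a.xyz[0] + 2.9, a.xyz[1], a.xyz[2])))

    body_angle, head_angle = _STATE_ANGLES[state]
    sub_spec = SubunitSpec(body_angle=body_angle, head_angle=head_angle,
                           body_axis=(0, 0, 1), head_axis=(1, 0, 0),
                           seed=seed if subunit_seed is None else subunit_seed,
                           noise_sd=noise_sd)
    sub_ref, sub_rot, _ = make_rotated_subunit(sub_spec)

    far = np.array([150.0, 0.0, 0.0])  # keep domains clear of the scene

    def shift(atoms):
        return [a._replace(xyz=tuple(np.asarray(a.xyz) + far)) for a in atoms]

    drop_resnums = {reg.residue_number(p) for p in drop_ring_atoms_at}
    scene_atoms = [a for a in scene.atoms
                   if not (a.chain_id == scene_spec.mrna_chain
                           and a.residue_number in drop_resnums)]

    atoms = scene_atoms + t_atoms + shift(sub_rot.atoms)
    ref_atoms = scene_atoms + t_atoms + shift(sub_ref.atoms)

    tag = f"SYN-{contact_kind[:5].upper()}-{state[:4].upper()}-{seed}"
    structure = RibosomeStructure(tag, atoms, resolution, "cryoem")
    reference = RibosomeStructure(tag + "-REF", ref_atoms, resolution, "cryoem")
    hints = {"rrna16S": "S", "rrna23S": "L", "mrna": "M", "trnas": [("T", "P")]}
    truth_d = {"contact": contact_kind, "partners": truth.partners,
               "state": state, "p_codon_start": reg.p_codon_start}
    return structure, reference, truth_d, hints
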