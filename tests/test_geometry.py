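"""Base geometry and the intercalated/stacked/retracted classifier."""
import numpy as np
import pytest

from conftest import random_rigid_motion, transform_structure
from riboframe import geometry, synthetic
from riboframe.errors import GeometryUnresolvedError
from riboframe.geometry import ContactThresholds
from riboframe.rotation import rotation_from_axis_angle
from riboframe.structure_io import Atom, RibosomeStructure


def _base_structure(name="G", R=None, t=None, chain="Q", resnum=1, drop=()):
    tmpl = synthetic.base_template(name)
    R = np.eye(3) if R is None else R
    t = np.zeros(3) if t is None else np.asarray(t)
    atoms = [Atom(chain, resnum, "", name, an, tuple(R @ p + t))
             for an, p in tmpl.items() if an not in drop]
    return RibosomeStructure("T", atoms)


def test_flat_base_centroid_and_normal():
    s = _base_structure("G")
    g = geometry.base_geometry(s, "Q", 1)
    assert np.allclose(g.centroid, 0, atol=1e-9)
    assert abs(abs(g.normal[2]) - 1) < 1e-9
    assert g.base_type == "purine" and g.ring_atom_count == 9


def test_rigid_motion_transforms_centroid_and_normal_consistently():
    rng = np.random.default_rng(11)
    R, t = random_rigid_motion(rng)
    g0 = geometry.base_geometry(_base_structure("C"), "Q", 1)
    g1 = geometry.base_geometry(_base_structure("C", R, t), "Q", 1)
    assert np.allclose(g1.centroid, R @ g0.centroid + t, atol=1e-9)
    assert abs(abs(np.dot(g1.normal, R @ g0.normal)) - 1) < 1e-9


def test_puckered_ring_normal_close_to_flat_normal():
    rng = np.random.default_rng(4)
    tmpl = synthetic.base_template("A")
    atoms = [Atom("Q", 1, "", "A", an, (p[0], p[1], p[2] + rng.uniform(-0.2, 0.2)))
             for an, p in tmpl.items()]
    g = geometry.base_geometry(RibosomeStructure("T", atoms), "Q", 1)
    angle = np.degrees(np.arccos(abs(g.normal[2])))
    assert angle < 5.0


def test_too_few_ring_atoms_is_unresolved():
    s = _base_structure("C", drop=("N1", "C2"))  # 4 of 6 left
    with pytest.raises(GeometryUnresolvedError):
        geometry.base_geometry(s, "Q", 1)


# ---------------------------------------------------------------------------
# classifier

def _geoms_from_scene(rs, truth, positions=(-4, -3, -2, -1, 1, 2, 3)):
    q = geometry.base_geometry(rs, truth.query[0], truth.query[1])
    mrna = []
    for pos in positions:
        try:
            g = geometry.base_geometry(rs, truth.register.chain_id,
                                       truth.register.residue_number(pos))
        except GeometryUnresolvedError:
            g = None
        mrna.append((pos, g))
    return q, mrna


@pytest.mark.parametrize("kind", ["intercalated", "stacked", "retracted"])
def test_constructed_scenes_classified_as_built(kind, scene_factory):
    rs, truth = scene_factory(kind, seed=2)
    q, mrna = _geoms_from_scene(rs, truth)
    call = geometry.classify_contact(q, mrna)
    assert call.call == kind
    assert call.partners == truth.partners


def test_call_is_exactly_one_of_four(scene_factory):
    for kind in ("intercalated", "stacked", "retracted"):
        rs, truth = scene_factory(kind, seed=9, noise_sd=0.1)
        q, mrna = _geoms_from_scene(rs, truth)
        call = geometry.classify_contact(q, mrna)
        assert call.call in {"intercalated", "stacked", "retracted", "unresolved"}


def test_rigid_motion_invariance_of_calls(scene_factory):
    rng = np.random.default_rng(21)
    for kind in ("intercalated", "stacked", "retracted"):
        rs, truth = scene_factory(kind, seed=5)
        q0, m0 = _geoms_from_scene(rs, truth)
        ref = geometry.classify_contact(q0, m0)
        for _ in range(12):
            R, t = random_rigid_motion(rng)
            rs2 = transform_structure(rs, R, t)
            q, m = _geoms_from_scene(rs2, truth)
            call = geometry.classify_contact(q, m)
            assert (call.call, call.partners) == (ref.call, ref.partners)


def test_increasing_d_stack_never_demotes_call(scene_factory):
    """Sweep d_stack upward on a fixed scene: calls may only move along
    retracted -> stacked -> intercalated."""
    order = {"retracted": 0, "stacked": 1, "intercalated": 2}
    rs, truth = scene_factory("intercalated", seed=13)
    q, mrna = _geoms_from_scene(rs, truth)
    prev = -1
    for d_stack in np.linspace(2.0, 8.0, 25):
        th = ContactThresholds(d_stack=float(d_stack),
                               d_retract=max(6.0, float(d_stack) + 1.0))
        call = geometry.classify_contact(q, mrna, th)
        assert order[call.call] >= prev
        prev = order[call.call]


def test_oracle_equivalence_on_seeded_scenes(scene_factory):
    for kind in ("intercalated", "stacked", "retracted"):
        for seed in range(20):
            rs, truth = scene_factory(kind, seed=seed, noise_sd=0.08)
            q, mrna = _geoms_from_scene(rs, truth)
            assert geometry.classify_contact(q, mrna).call == kind


def test_edge_on_contact_is_not_stacking():
    """A base approaching in-plane (edge contact) fails the face-on test."""
    sA = _base_structure("A", t=(0, 0, 0))
    # edge-on neighbour: same plane, 4 A lateral offset
    tmpl = synthetic.base_template("U")
    atoms = sA.atoms + [Atom("M", 10, "", "U", an, (p[0] + 4.0, p[1], p[2]))
                        for an, p in tmpl.items()]
    rs = RibosomeStructure("T", atoms)
    q = geometry.base_geometry(rs, "Q", 1)
    g = geometry.base_geometry(rs, "M", 10)
    call = geometry.classify_contact(q, [(-1, g), (-2, None), (1, g)])
    assert call.call != "stacked" or call.partners == ()


def test_nonconsecutive_partners_fall_back_to_stacked():
    """Two face-on partners at non-adjacent positions -> stacked + warning."""
    tmpl = synthetic.base_template("A")
    atoms = []
    for pos, resnum, z in ((-3, 9, -3.3), (1, 12, 3.3)):
        atoms += [Atom("M", resnum, "", "A", an, (p[0], p[1], p[2] + z))
                  for an, p in tmpl.items()]
    atoms += [Atom("Q", 1503, "", "A", an, tuple(p)) for an, p in tmpl.items()]
    rs = RibosomeStructure("T", atoms)
    q = geometry.base_geometry(rs, "Q", 1503)
    m = [(-3, geometry.base_geometry(rs, "M", 9)),
         (-2, None), (-1, None),
         (1, geometry.base_geometry(rs, "M", 12))]
    call = geometry.classify_contact(q, m)
    assert call.call == "stacked"
    assert len(call.partners) == 1
    assert "nonconsecutive_partners" in call.warnings


def test_partner_tie_breaks_toward_five_prime():
    tmpl = synthetic.base_template("A")
    atoms = []
    for pos, resnum, z in ((-3, 9, -3.4), (-1, 11, 3.4)):
        atoms += [Atom("M", resnum, "", "A", an, (p[0], p[1], p[2] + z))
                  for an, p in tmpl.items()]
    atoms += [Atom("Q", 1503, "", "A", an, tuple(p)) for an, p in tmpl.items()]
    rs = RibosomeStructure("T", atoms)
    q = geometry.base_geometry(rs, "Q", 1503)
    m = [(-3, geometry.base_geometry(rs, "M", 9)),
         (-2, None),
         (-1, geometry.base_geometry(rs, "M", 11))]
    call = geometry.classify_contact(q, m)  # equidistant, non-adjacent
    assert call.call == "stacked" and call.partners == (-3,)


def test_empty_mrna_list_rejected():
    q = geometry.base_geometry(_base_structure("A"), "Q", 1)
    with pytest.raises(ValueError):
        geometry.classify_contact(q, [])
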