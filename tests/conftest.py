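import numpy as np
import pytest

from riboframe import structure_io, synthetic


@pytest.fixture
def scene_factory():
    def make(kind, seed=0, **kw):
        spec = synthetic.SceneSpec(kind=kind, seed=seed, **kw)
        return synthetic.make_contact_scene(spec)
    return make


@pytest.fixture
def subunit_cm():
    return synthetic.subunit_chain_map()


@pytest.fixture
def survey_batch():
    """Small labeled batch sharing one classical reference."""
    from riboframe import survey

    combos = [
        ("intercalated", "chimeric_hybrid", (-2, -1)),
        ("intercalated", "classical", (-4, -3)),
        ("stacked", "classical", (-2, -1)),
        ("retracted", "classical", (-2, -1)),
        ("retracted", "hybrid", (-2, -1)),
        ("intercalated", "chimeric_hybrid", (-2, -1)),
    ]
    cfg = survey.SurveyConfig()
    structures, truths = {}, {}
    hints = None
    reference = None
    for i, (ck, st, gap) in enumerate(combos):
        s, r, truth, hints = synthetic.make_survey_structure(
            ck, st, seed=100 + i, subunit_seed=7, gap_position=gap)
        structures[s.pdb_id] = s
        truths[s.pdb_id] = truth
        cfg.per_structure[s.pdb_id] = {"chains": hints}
        if reference is None:
            reference = r
    cm_ref = structure_io.identify_chains(reference, hints=hints)
    return dict(cfg=cfg, structures=structures, truths=truths,
                reference=reference, cm_ref=cm_ref, hints=hints)


def random_rigid_motion(rng):
    """Uniformly random proper rotation plus a bounded translation."""
    from riboframe.rotation import rotation_from_axis_angle

    axis = rng.normal(size=3)
    theta = rng.uniform(0, 180)
    R = rotation_from_axis_angle(theta, axis)
    t = rng.uniform(-50, 50, 3)
    return R, t


def transform_structure(rs, R, t):
    atoms = [a._replace(xyz=tuple(R @ np.asarray(a.xyz) + t)) for a in rs.atoms]
    return structure_io.RibosomeStructure(rs.pdb_id, atoms, rs.resolution,
                                          rs.method, rs.model_number)
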