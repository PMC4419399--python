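import numpy as np
import pytest
from hypothesis import settings

from classfrag import synthetic
from classfrag.geometry import TorsionTriple, build_backbone_from_torsions
from classfrag.synthetic import SSSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def angle_diff(a: float, b: float) -> float:
    """Smallest absolute angular difference in degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


@pytest.fixture(scope="session")
def ideal_helix():
    """30-residue chain at phi=-57, psi=-47 (alpha helix)."""
    tors = [TorsionTriple(i + 1, -57.0, -47.0, 180.0) for i in range(30)]
    return build_backbone_from_torsions("A" * 30, tors, structure_id="helix30")


@pytest.fixture(scope="session")
def antiparallel_pair():
    return synthetic.make_strand_pair(8, parallel=False, seed=2)


@pytest.fixture(scope="session")
def parallel_pair():
    return synthetic.make_strand_pair(8, parallel=True, seed=2)


@pytest.fixture(scope="session")
def mixed_db():
    """Small class-annotated synthetic template DB with ground truth."""
    return synthetic.make_template_db(
        {"mainly_alpha": 5, "mainly_beta": 5}, lengths=(50, 70), seed=3)


@pytest.fixture(scope="session")
def toy():
    """12-residue mainly-alpha target vs 5 mixed-class synthetic templates."""
    db, _ = synthetic.make_template_db(
        {"mainly_alpha": 3, "mainly_beta": 2}, lengths=(20, 30), seed=9)
    rng = np.random.default_rng(12)
    spec = synthetic.class_spec("mainly_alpha", 12, rng)
    native = synthetic.make_ideal_structure(spec, seed=12)
    profile, pred = synthetic.make_profile_and_ss(
        native.sequence, spec.letters, sharpness=0.7, seed=12)
    return db, native, spec, profile, pred


@pytest.fixture(scope="session")
def alpha_native():
    """Mainly-alpha native with its blueprint, profile and SS prediction."""
    rng = np.random.default_rng(7)
    spec = synthetic.class_spec("mainly_alpha", 30, rng)
    native = synthetic.make_ideal_structure(spec, seed=7, structure_id="native")
    profile, pred = synthetic.make_profile_and_ss(
        native.sequence, spec.letters, sharpness=0.9, seed=7)
    return native, spec, profile, pred
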