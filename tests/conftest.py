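import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from idpbem.backbone import build_backbone_from_torsions, uniform_profile
from idpbem.model import PeptideSequence, TorsionProfile, UVR8_C27_WT, UVR8_C27_OFFSET

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wt_sequence() -> PeptideSequence:
    return PeptideSequence(UVR8_C27_WT, UVR8_C27_OFFSET)


@pytest.fixture(scope="session")
def ala_sequence() -> PeptideSequence:
    return PeptideSequence("A" * 27)


@pytest.fixture(scope="session")
def helix(wt_sequence):
    """27-residue ideal alpha helix of the wild-type sequence."""
    return build_backbone_from_torsions(wt_sequence, uniform_profile(27, -57.8, -47.0))


@pytest.fixture(scope="session")
def ala_helix(ala_sequence):
    return build_backbone_from_torsions(ala_sequence, uniform_profile(27, -57.8, -47.0))


@pytest.fixture(scope="session")
def extended(wt_sequence):
    """Fully extended chain (phi = -180, psi = 180)."""
    return build_backbone_from_torsions(wt_sequence, uniform_profile(27, -180.0, 180.0))


@pytest.fixture(scope="session")
def ppii_chain(wt_sequence):
    return build_backbone_from_torsions(wt_sequence, uniform_profile(27, -75.0, 145.0))


def random_conformations(sequence, n, seed=0, compact=False):
    """Self-avoidance is not enforced; these exercise pure geometry."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        L = len(sequence)
        lo, hi = ((-100.0, 0.0) if compact else (-180.0, 0.0))
        phi = rng.uniform(lo, hi, L)
        psi = rng.uniform(-180.0, 180.0, L)
        chi = np.column_stack(
            [rng.uniform(-180.0, 180.0, L), rng.uniform(-180.0, 180.0, L)]
        )
        out.append(
            build_backbone_from_torsions(
                sequence, TorsionProfile(phi=phi, psi=psi), chi=chi
            )
        )
    return out


@pytest.fixture(scope="session")
def random_frames(wt_sequence):
    return random_conformations(wt_sequence, 20, seed=11)
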