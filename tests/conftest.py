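import numpy as np
import pytest

from mesodemog.simulate import (
    DemographicModel,
    PopulationScenario,
    SimulationConfig,
    make_study_fixture,
)

BASES = "ACGT"


def random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Random unaligned-noise sequences for oracle tests."""
    return ["".join(rng.choice(list(BASES), size=length)) for _ in range(n)]


def mutate(reference: str, variants: dict[int, str]) -> str:
    """Apply {1-based position: base} substitutions to a sequence."""
    seq = list(reference)
    for pos, base in variants.items():
        seq[pos - 1] = base
    return "".join(seq)


@pytest.fixture(scope="session")
def small_fixture():
    """Two-population study fixture with planted haplogroups (session-cached)."""
    pops = [
        PopulationScenario(
            name="Alpha", n=25, mixture={"A2": 0.5, "B2": 0.3, "C1": 0.2},
            model=DemographicModel(sizes=(1500.0,)), region="Maya",
            language="Mayan", lat=20.5, lon=-89.0,
        ),
        PopulationScenario(
            name="Beta", n=20, mixture={"A2": 0.4, "D1": 0.4, "D4h3a": 0.2},
            model=DemographicModel(sizes=(1200.0,)), region="West",
            language="Uto-Aztecan", lat=22.0, lon=-104.3,
        ),
    ]
    return make_study_fixture(pops, seed=11)


@pytest.fixture(scope="session")
def low_rate_fixture():
    """Fixture evolved at a low mutation rate: motifs survive essentially intact."""
    cfg = SimulationConfig(mu=3.0e-8)
    pops = [
        PopulationScenario(
            name="Gamma", n=40, mixture={"A2": 0.4, "B2": 0.3, "C1": 0.2, "X2a": 0.1},
            model=DemographicModel(sizes=(1500.0,)),
        ),
    ]
    return make_study_fixture(pops, seed=5, cfg=cfg)
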