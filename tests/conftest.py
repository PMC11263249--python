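import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

SMALL_TREE = ("((S_sanghuang:0.04,(S_vaninii:0.02,P_gilvus:0.02):0.03):0.06,"
              "(I_hispidus:0.05,I_obliquus:0.05):0.06,F_palustris:0.12);")

TRIO = ("S_sanghuang", "S_vaninii", "P_gilvus")


@pytest.fixture(scope="session")
def small_cohort():
    """Six-genome synthetic cohort with full ground truth (session-cached)."""
    from mitocomp.simulate import SimulationSpec, make_cohort
    return make_cohort(SimulationSpec(seed=11, tree=SMALL_TREE))


@pytest.fixture(scope="session")
def full_cohort():
    """The default 16-genome cohort (session-cached)."""
    from mitocomp.simulate import SimulationSpec, make_cohort
    return make_cohort(SimulationSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n, freqs=None):
    p = None
    if freqs:
        p = np.array([freqs[b] for b in "ACGT"], dtype=float)
        p /= p.sum()
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
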