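import numpy as np
import pytest

from deltapwm import PFM, PWM, SimulationConfig, pfm_to_pwm, write_fixture_tree


def random_pfm(rng: np.random.Generator, length: int, concentration: float = 0.5,
               motif_id: str = "rand") -> PFM:
    return PFM(motif_id, rng.dirichlet(np.full(4, concentration), size=length))


def random_pwm(rng: np.random.Generator, length: int, motif_id: str = "rand") -> PWM:
    return pfm_to_pwm(random_pfm(rng, length, motif_id=motif_id))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small but complete synthetic fixture tree (2 TFs x 150 SNVs)."""
    out = tmp_path_factory.mktemp("fixture") / "tree"
    cfg = SimulationConfig(n_tfs=2, n_snvs_per_tf=150, seed=11)
    write_fixture_tree(out, cfg)
    return out, cfg
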