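import warnings

import numpy as np
import pytest

from imtrial import DesignConfig, GeneratorConfig, TrialDataset
from imtrial.synthetic import generate_participant, generate_week4

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_gen():
    return GeneratorConfig()


@pytest.fixture
def default_design():
    return DesignConfig()


def make_randomised_dataset(
    n: int,
    gen: GeneratorConfig,
    rng: np.random.Generator,
    n_immediate: int | None = None,
) -> TrialDataset:
    """Eligible participants with arms assigned by shuffle (not minimisation).

    Test helper for stages downstream of randomisation, where the exact
    allocation mechanism is irrelevant.
    """
    n_imm = n // 2 if n_immediate is None else n_immediate
    arms = ["immediate"] * n_imm + ["delayed"] * (n - n_imm)
    rng.shuffle(arms)
    recs = []
    i = 0
    while len(recs) < n:
        rec = generate_participant(gen, rng, enrollment_index=i)
        i += 1
        if not rec.eligible:
            continue
        rec.arm = arms[len(recs)]
        generate_week4(gen, rec, rng)
        recs.append(rec)
    return TrialDataset(recs)


@pytest.fixture
def small_effect_dataset(rng):
    """36/39 split with the trial's calibrated treatment effect."""
    return make_randomised_dataset(75, GeneratorConfig(), rng, n_immediate=36)
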