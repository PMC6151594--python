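import warnings

import pytest

from vinomics.quant import quantify_batch
from vinomics.simulate import (
    BatchDesign,
    InstrumentParams,
    MethodEffectParams,
    generate_truth,
    simulate_batch,
)

SEED = 42


@pytest.fixture(scope="session")
def truth():
    return generate_truth(SEED)


@pytest.fixture(scope="session")
def noise_free_batch(truth):
    return simulate_batch(
        BatchDesign(),
        truth,
        MethodEffectParams.noise_free(),
        InstrumentParams.noise_free(),
        seed=SEED,
    )


@pytest.fixture(scope="session")
def noise_free_quant(noise_free_batch):
    return quantify_batch(noise_free_batch)


@pytest.fixture(scope="session")
def noisy_quant(truth):
    """Default study conditions: contamination, filtration loss, method CVs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        batch = simulate_batch(
            BatchDesign(),
            truth,
            MethodEffectParams.default(),
            InstrumentParams(),
            seed=SEED + 1,
        )
        return quantify_batch(batch)
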