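import random

import pytest
from hypothesis import settings

import sdrfkit as sk
from sdrfkit.design import DesignSpec, QuantMethod, generate_design

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cv_store():
    return sk.load_default_cv()


@pytest.fixture(scope="session")
def fig1_spec():
    """Label-free design: two biological x two technical replicates,
    no fractionation."""
    return DesignSpec(
        quant_method=QuantMethod.LABEL_FREE,
        n_biological=2,
        n_technical=2,
        n_fractions=1,
    )


@pytest.fixture(scope="session")
def fig2_spec():
    """TMT design: three multiplexed samples, three fractions."""
    return DesignSpec(
        quant_method=QuantMethod.TMT10,
        n_biological=3,
        n_technical=1,
        n_fractions=3,
    )


@pytest.fixture()
def fig1_table(fig1_spec):
    return generate_design(fig1_spec)


@pytest.fixture()
def fig2_table(fig2_spec):
    return generate_design(fig2_spec)


def random_design_specs(n, seed=20210915, max_size=5):
    """Deterministic stream of valid randomized DesignSpecs (S,T,F <= max_size)."""
    rng = random.Random(seed)
    methods = list(QuantMethod)
    specs = []
    for _ in range(n):
        method = rng.choice(methods)
        s = rng.randint(1, max_size)
        if method.requires_full_plex:
            s = method.plex * rng.randint(1, max(1, max_size // method.plex))
        specs.append(
            DesignSpec(
                quant_method=method,
                n_biological=s,
                n_technical=rng.randint(1, max_size),
                n_fractions=rng.randint(1, max_size),
                factor_levels=tuple(f"level {i}" for i in range(1, rng.randint(2, 4))),
            )
        )
    return specs
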