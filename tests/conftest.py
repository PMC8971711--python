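import numpy as np
import pytest

from lcanova.phantom import (
    EffectSpec,
    PhantomSpec,
    make_phantom,
    null_cohort,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def geometry(phantom_spec):
    return make_phantom(phantom_spec)


@pytest.fixture(scope="session")
def effect_spec():
    return EffectSpec()


@pytest.fixture(scope="session")
def planted_db(geometry, phantom_spec, effect_spec):
    """Cohort with a +20% SDF effect planted in the EPT group."""
    db, truth = simulate_cohort(geometry, phantom_spec, effect_spec, rng=7)
    return db, truth


@pytest.fixture(scope="session")
def null_db(geometry, phantom_spec):
    return null_cohort(geometry, phantom_spec, rng=11)


@pytest.fixture(scope="session")
def single_bundle():
    """A single straight x-aligned bundle on a small grid, with geometry."""
    from lcanova.phantom import Bundle

    spec = PhantomSpec(
        dims=(40, 20, 20),
        voxel_size=2.0,
        bundles=[Bundle(start=(0.0, 10.0, 10.0), end=(40.0, 10.0, 10.0), radius=2.0, sdf=0.6)],
    )
    return spec, make_phantom(spec)
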