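import numpy as np
import pytest

from olivenir import GeneratorConfig, InstrumentGrid, SpectraBlock, generate_dataset

SMALL_GRIDS = (
    InstrumentGrid("sphere", "cm-1", 3600.0, 12500.0, 301, gain=1.0),
    InstrumentGrid("probe", "cm-1", 3600.0, 12500.0, 301, gain=1.3),
    InstrumentGrid("portable", "nm", 500.0, 1000.0, 201, gain=1.0),
)


@pytest.fixture
def small_config():
    """Compact campaign: 24 units, coarse grids, default noise."""
    return GeneratorConfig(n_units=24, seed=11, grids=SMALL_GRIDS)


@pytest.fixture
def noise_free_config():
    """Same campaign without any noise source (exact Beer-Lambert mixing)."""
    return GeneratorConfig(
        n_units=24,
        seed=11,
        grids=SMALL_GRIDS,
        scatter_sd=0.0,
        baseline_sd=0.0,
        noise_sd=0.0,
        replicate_chem_cv=0.0,
    )


@pytest.fixture
def small_dataset(small_config):
    return generate_dataset(small_config)


def make_block(A, axis=None, unit_ids=None, replicates=None, name="test", unit="cm-1"):
    """Convenience SpectraBlock constructor for hand-written matrices."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n, p = A.shape
    axis = np.arange(p, dtype=float) if axis is None else np.asarray(axis, float)
    unit_ids = (
        np.array([f"U{i:03d}" for i in range(n)]) if unit_ids is None else np.asarray(unit_ids)
    )
    replicates = np.ones(n, dtype=int) if replicates is None else np.asarray(replicates)
    return SpectraBlock(
        instrument_name=name,
        axis=axis,
        axis_unit=unit,
        unit_ids=unit_ids,
        replicates=replicates,
        A=A,
    )
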