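import numpy as np
import pytest

from ocplsnir import (
    GeneratorConfig,
    RunConfig,
    SampleMeta,
    SpectraSet,
    WavenumberGrid,
    run_study,
)


@pytest.fixture(scope="session")
def small_grid() -> WavenumberGrid:
    return WavenumberGrid(np.linspace(4000.0, 5000.0, 40))


@pytest.fixture(scope="session")
def tiny_generator(small_grid) -> GeneratorConfig:
    """Reduced-design generator for fast I/O and pipeline tests."""
    return GeneratorConfig(
        grid=small_grid,
        seed=3,
        n_pure_per_batch=(6, 6, 6),
        adulterant_design=(
            ("A1", 0.01, 3),
            ("A1", 0.05, 3),
            ("A2", 0.02, 3),
            ("A3", 0.02, 3),
        ),
    )


@pytest.fixture(scope="session")
def default_study():
    """The full frozen-seed study (60 pure + 197 adulterated, 3 models).

    Session-scoped: several regression tests read different aspects of the
    same run.
    """
    return run_study(RunConfig(seed=0))


def make_set(matrix, grid=None, pure=True) -> SpectraSet:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if grid is None:
        grid = WavenumberGrid(4000.0 + 10.0 * np.arange(matrix.shape[1]))
    meta = [
        SampleMeta(f"S{i:03d}", "pure", "A0", 0.0, "B1")
        if pure
        else SampleMeta(f"S{i:03d}", "adulterated", "A1", 0.02, "B1")
        for i in range(matrix.shape[0])
    ]
    return SpectraSet(grid, matrix, meta)
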