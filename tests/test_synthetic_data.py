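"""The synthetic-spectra generator: design counts, determinism, dose response."""

import dataclasses

import numpy as np
import pytest

from ocplsnir import (
    GeneratorConfig,
    VariationParams,
    generate_adulterated,
    generate_pure,
    generate_study,
    make_water_reference,
    op_project,
    read_spectra_csv,
    write_spectra_csv,
)
from ocplsnir.exceptions import ConfigError, GridError
from ocplsnir.spectra_io import Spectrum, default_study_grid


def zero_variation(**overrides) -> VariationParams:
    fields = {f.name: 0.0 for f in dataclasses.fields(VariationParams)}
    fields.update(overrides)
    return VariationParams(**fields)


class TestDesignCounts:
    def test_full_study_matches_reference_design(self):
        pure, adulterated, reference, truth = generate_study(GeneratorConfig(seed=7))
        assert pure.n_samples == 60  # 17 + 25 + 18
        assert adulterated.n_samples == 197  # sum of the 16 design rows
        assert len(truth.records) == 257
        assert np.linalg.norm(reference.absorbance) > 0
        # batch composition of the pure set
        batches = [m.batch for m in pure.meta]
        assert [batches.count(b) for b in ("B1", "B2", "B3")] == [17, 25, 18]
        # per-(adulterant, level) counts
        per_adulterant = {"A1": 0, "A2": 0, "A3": 0}
        for m in adulterated.meta:
            per_adulterant[m.adulterant] += 1
        assert per_adulterant == {"A1": 83, "A2": 63, "A3": 51}

    def test_seed_changes_values_not_shapes(self):
        a = generate_study(GeneratorConfig(seed=1))
        b = generate_study(GeneratorConfig(seed=2))
        assert a[0].matrix.shape == b[0].matrix.shape
        assert not np.array_equal(a[0].matrix, b[0].matrix)


class TestDeterminism:
    def test_same_seed_bit_identical(self, tiny_generator):
        p1, a1 = _study_pair(tiny_generator)
        p2, a2 = _study_pair(tiny_generator)
        assert np.array_equal(p1.matrix, p2.matrix)
        assert np.array_equal(a1.matrix, a2.matrix)

    def test_water_reference_deterministic_and_nonnegative(self, small_grid):
        r1 = make_water_reference(small_grid, seed=1)
        r2 = make_water_reference(small_grid, seed=1)
        assert np.array_equal(r1.absorbance, r2.absorbance)
        assert np.all(r1.absorbance >= 0)
        assert np.trapezoid(r1.absorbance, small_grid.values) > 0


def _study_pair(config):
    pure, _ = generate_pure(config)
    adulterated, _ = generate_adulterated(config, pure)
    return pure, adulterated


class TestVariationStructure:
    def test_zero_variation_collapses_batches(self, small_grid):
        config = GeneratorConfig(
            grid=small_grid, seed=2, n_pure_per_batch=(4, 3),
            variation=zero_variation(),
        )
        pure, _ = generate_pure(config)
        assert np.all(pure.matrix == pure.matrix[0])

    def test_zero_dose_equals_source_spectrum_plus_noise_only(self, small_grid):
        config = GeneratorConfig(
            grid=small_grid, seed=4, n_pure_per_batch=(5,),
            adulterant_design=(("A1", 0.0, 4),),
            variation=zero_variation(),
        )
        pure, _ = generate_pure(config)
        adulterated, truth = generate_adulterated(config, pure)
        # signature term vanishes at zero dose: rows equal pure rows exactly
        assert np.allclose(adulterated.matrix, pure.matrix[0], atol=1e-12)
        assert np.all(truth.records["adulterant_norm"] == 0)

    def test_signature_contribution_grows_with_dose(self):
        config = GeneratorConfig(seed=5)
        pure, _ = generate_pure(config)
        adulterated, truth = generate_adulterated(config, pure)
        norms = truth.records["adulterant_norm"].to_numpy()
        levels = np.array([m.doping_level for m in adulterated.meta])
        kinds = np.array([m.adulterant for m in adulterated.meta])
        a1 = kinds == "A1"
        mean_at = lambda lvl: norms[a1 & (levels == lvl)].mean()
        assert mean_at(0.08) > mean_at(0.01)

    def test_orthogonal_signature_component_monotone_in_dose(self, small_grid):
        """After projecting out the water reference, the residual adulterant
        contribution grows strictly with doping level (noise off)."""
        levels = (0.01, 0.02, 0.04, 0.08)
        config = GeneratorConfig(
            grid=small_grid, seed=6, n_pure_per_batch=(3,),
            adulterant_design=tuple(("A1", lvl, 1) for lvl in levels),
            variation=zero_variation(),
            reference_noise_sd=0.0,
        )
        pure, _ = generate_pure(config)
        adulterated, _ = generate_adulterated(config, pure)
        ref = make_water_reference(small_grid, seed=6, noise_sd=0.0)
        base = op_project(Spectrum(small_grid, pure.matrix[0]), ref).absorbance
        norms = [
            np.linalg.norm(
                op_project(Spectrum(small_grid, row), ref).absorbance - base
            )
            for row in adulterated.matrix
        ]
        assert all(n2 > n1 for n1, n2 in zip(norms, norms[1:]))


class TestValidationAndIO:
    def test_generated_sets_round_trip_csv(self, tmp_path, tiny_generator):
        pure, adulterated = _study_pair(tiny_generator)
        for name, data in (("pure", pure), ("adulterated", adulterated)):
            path = tmp_path / f"{name}.csv"
            write_spectra_csv(data, path)
            back = read_spectra_csv(path)
            assert np.array_equal(back.matrix, data.matrix)
            assert back.meta == data.meta

    def test_grid_mismatch_between_config_and_base_rejected(self, small_grid):
        pure, _ = generate_pure(GeneratorConfig(grid=small_grid, seed=0,
                                                n_pure_per_batch=(4,)))
        other = GeneratorConfig(grid=default_study_grid(), seed=0)
        with pytest.raises(GridError):
            generate_adulterated(other, pure)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_pure_per_batch": (-1, 5)},
            {"adulterant_design": (("A1", 0.9, 3),)},  # level > 0.5
            {"adulterant_design": (("A7", 0.01, 3),)},  # unknown code
            {"water_bands": ()},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            GeneratorConfig(**kwargs)

    def test_negative_band_width_rejected(self):
        from ocplsnir import Band

        with pytest.raises(ConfigError):
            Band(5000.0, 0.0, 1.0)
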