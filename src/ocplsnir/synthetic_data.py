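"""Synthetic NIR spectra with the statistical structure of a yogurt study.

No public spectral data set accompanies this kind of benchtop study, so the
package ships a generator that emulates the ingredients the analysis relies
on, at the sample counts of the original design:

* a water-dominated absorbance profile over 4000-12000 cm^-1, built from
  Gaussian bands at the classic water combination/overtone regions
  (~5150, ~6900, ~10300 cm^-1);
* a weaker "yogurt solids" profile (C-H / N-H / carbohydrate bands);
* within-class nuisance variation of pure yogurt: a random water-amplitude
  coefficient, independent per-band amplitude and position jitter of the
  water and solids bands (a many-dimensional shape nuisance), multiplicative
  scatter, additive baseline offset and slope, a small per-batch shift, and
  i.i.d. measurement noise;
* additive adulterant signatures (2-3 Gaussian bands each, placed in the
  protein/gelatin C-H / N-H regions) scaling linearly with doping level,
  with the two weaker adulterants deliberately fainter per unit dose than
  edible gelatin.

A pure spectrum is

    x = (c_w * water + solids + batch_shift) * m + b0 + b1 (w - w_mid) + eps,

with c_w ~ N(1, water_scale_sd), m ~ N(1, mult_scatter_sd), b0, b1 and eps
Gaussian, and `water`/`solids` rebuilt per sample from jittered bands.  An adulterated spectrum blends a randomly chosen pure-style
spectrum with an adulterant solution whose spectrum is mostly water
(signature + make-up water term), mirroring how thickness is kept constant
in practice:

    x = (1 - L) * x_pure + L * (signature_A + c_sol * water) + eps.

Band placements and variation magnitudes are modelling choices (the real
signatures are not characterised quantitatively anywhere); they were
calibrated once so that raw-spectrum class overlap is substantial while
orthogonal projection against the water reference separates the classes,
then frozen.  A :class:`SyntheticTruth` sidecar records every latent draw so
tests can check parameter recovery and dose monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .spectra_io import (
    ReferenceSpectrum,
    SampleMeta,
    SpectraSet,
    WavenumberGrid,
    default_study_grid,
)

__all__ = [
    "Band",
    "VariationParams",
    "GeneratorConfig",
    "SyntheticTruth",
    "make_water_reference",
    "generate_pure",
    "generate_adulterated",
    "generate_study",
    "DEFAULT_ADULTERANT_DESIGN",
]


@dataclass(frozen=True)
class Band:
    """A Gaussian absorbance band: center/width in cm^-1, amplitude in AU."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"band width must be > 0, got {self.width}")


def _band_sum(grid: WavenumberGrid, bands: tuple[Band, ...]) -> np.ndarray:
    w = grid.values
    out = np.zeros_like(w)
    for b in bands:
        out += b.amplitude * np.exp(-0.5 * ((w - b.center) / b.width) ** 2)
    return out


@dataclass(frozen=True)
class VariationParams:
    """Within-class nuisance magnitudes for pure yogurt.

    All standard deviations; units are absorbance units unless noted.  The
    water *amplitude* of pure yogurt is kept fairly stable (its water content
    is controlled during production) while the water band *shape* wanders
    sample to sample through independent per-band amplitude and position
    jitter — a many-dimensional nuisance no small latent-variable budget can
    fully model.  Together with the make-up water added to adulterated
    samples, this is what separates the three preprocessing variants: a raw
    model leans on the water signal itself and is fooled by the make-up
    water, SNV removes the scale-type part of the variation, and projecting
    out the water spectrum removes the water direction entirely.
    """

    water_scale_sd: float = 0.01  # relative sd of the common water amplitude
    water_band_jitter_sd: float = 0.03  # relative per-band amplitude jitter
    solids_band_jitter_sd: float = 0.04  # relative per-band amplitude jitter
    band_center_jitter_sd: float = 2.0  # cm^-1 per-band position jitter
    mult_scatter_sd: float = 0.035  # multiplicative factor around 1
    baseline_offset_sd: float = 0.01
    baseline_slope_sd: float = 2e-6  # AU per cm^-1
    noise_sd: float = 0.002
    batch_shift_sd: float = 0.004

    def __post_init__(self) -> None:
        for name in (
            "water_scale_sd",
            "water_band_jitter_sd",
            "solids_band_jitter_sd",
            "band_center_jitter_sd",
            "mult_scatter_sd",
            "baseline_offset_sd",
            "baseline_slope_sd",
            "noise_sd",
            "batch_shift_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


#: (adulterant, doping level w/w, sample count) rows of the default design.
DEFAULT_ADULTERANT_DESIGN: tuple[tuple[str, float, int], ...] = (
    ("A1", 0.01, 12),
    ("A1", 0.02, 14),
    ("A1", 0.03, 14),
    ("A1", 0.04, 15),
    ("A1", 0.06, 15),
    ("A1", 0.08, 13),
    ("A2", 0.005, 14),
    ("A2", 0.01, 9),
    ("A2", 0.02, 12),
    ("A2", 0.03, 13),
    ("A2", 0.05, 15),
    ("A3", 0.005, 10),
    ("A3", 0.01, 10),
    ("A3", 0.02, 10),
    ("A3", 0.03, 10),
    ("A3", 0.05, 11),
)

_DEFAULT_WATER_BANDS = (
    Band(5150.0, 180.0, 1.00),  # O-H combination
    Band(6900.0, 230.0, 0.70),  # O-H first overtone
    Band(10300.0, 300.0, 0.22),  # O-H second overtone
)

_DEFAULT_YOGURT_BANDS = (
    Band(4330.0, 90.0, 0.060),  # C-H combination (fat)
    Band(4760.0, 110.0, 0.050),  # carbohydrate / protein combination
    Band(5680.0, 120.0, 0.040),  # C-H first overtone
    Band(6550.0, 150.0, 0.020),  # N-H first overtone
    Band(8250.0, 200.0, 0.012),  # C-H second overtone
)

# Amplitudes are per unit mass fraction of adulterant.  A1 (edible gelatin)
# is deliberately the strongest per dose so the synthetic detection limits
# qualitatively echo the easier detectability of edible gelatin.
_DEFAULT_ADULTERANT_BANDS: dict[str, tuple[Band, ...]] = {
    "A1": (
        Band(4590.0, 80.0, 7.00),
        Band(5770.0, 100.0, 3.94),
        Band(6480.0, 120.0, 3.06),
    ),
    "A2": (
        Band(4620.0, 85.0, 2.80),
        Band(5745.0, 100.0, 1.58),
        Band(6510.0, 130.0, 1.22),
    ),
    "A3": (
        Band(4560.0, 95.0, 2.80),
        Band(5695.0, 110.0, 1.75),
        Band(6840.0, 140.0, 1.05),
    ),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of the synthetic study design.

    Defaults reproduce the reference design: three pure batches of
    17/25/18 samples (60 total) and 197 adulterated samples across three
    adulterants at the listed dose levels.
    """

    grid: WavenumberGrid = field(default_factory=default_study_grid)
    seed: int = 0
    n_pure_per_batch: tuple[int, ...] = (17, 25, 18)
    adulterant_design: tuple[tuple[str, float, int], ...] = DEFAULT_ADULTERANT_DESIGN
    water_bands: tuple[Band, ...] = _DEFAULT_WATER_BANDS
    yogurt_bands: tuple[Band, ...] = _DEFAULT_YOGURT_BANDS
    adulterant_bands: dict[str, tuple[Band, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_ADULTERANT_BANDS)
    )
    variation: VariationParams = field(default_factory=VariationParams)
    solution_water_coeff: float = 1.0  # water make-up per unit dose
    reference_noise_sd: float = 2e-5  # per replicate water measurement

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.n_pure_per_batch):
            raise ConfigError("pure batch counts must be >= 0")
        for adulterant, level, count in self.adulterant_design:
            if adulterant not in self.adulterant_bands:
                raise ConfigError(f"no band definition for adulterant {adulterant!r}")
            if not 0 <= level <= 0.5:
                raise ConfigError(f"doping level {level} outside [0, 0.5]")
            if count < 0:
                raise ConfigError("design sample counts must be >= 0")
        if not self.water_bands:
            raise ConfigError("at least one water band is required")

    @property
    def water_band_centers(self) -> tuple[float, ...]:
        return tuple(b.center for b in self.water_bands)

    @property
    def water_band_widths(self) -> tuple[float, ...]:
        return tuple(b.width for b in self.water_bands)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-sample latent draws behind a generated SpectraSet."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "water_coeff", "scatter", "baseline_offset"}
        if not required <= set(self.records.columns):
            raise ConfigError("truth records missing required columns")


def _rng_streams(seed: int) -> tuple[np.random.Generator, ...]:
    """Independent streams for (reference, pure, adulterated) from one seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def make_water_reference(
    grid: WavenumberGrid, seed: int = 0, noise_sd: float | None = None
) -> ReferenceSpectrum:
    """Pure-water reference: five noisy replicate 'measurements', averaged.

    The underlying profile is the sum of the default water Gaussian bands;
    replicate noise is tiny (override with `noise_sd`, 0 for the ideal
    profile), so the average is smooth, and the result is clipped at zero to
    stay a physical absorbance.  Deterministic per seed.
    """
    cfg = GeneratorConfig(grid=grid, seed=seed)
    if noise_sd is not None:
        cfg = replace(cfg, reference_noise_sd=noise_sd)
    rng, _, _ = _rng_streams(seed)
    return _water_reference(cfg, rng)


def _water_reference(
    config: GeneratorConfig, rng: np.random.Generator
) -> ReferenceSpectrum:
    profile = _band_sum(config.grid, config.water_bands)
    reps = profile + rng.normal(
        0.0, config.reference_noise_sd, size=(5, config.grid.n_points)
    )
    return ReferenceSpectrum(config.grid, np.clip(reps.mean(axis=0), 0.0, None))


def _jittered_band_sum(
    grid: WavenumberGrid,
    bands: tuple[Band, ...],
    rng: np.random.Generator,
    amp_sd: float,
    center_sd: float,
) -> np.ndarray:
    """Band sum with independent per-band amplitude and position jitter."""
    w = grid.values
    out = np.zeros_like(w)
    for b in bands:
        center = b.center + (rng.normal(0.0, center_sd) if center_sd > 0 else 0.0)
        amp = b.amplitude * (1.0 + (rng.normal(0.0, amp_sd) if amp_sd > 0 else 0.0))
        out += amp * np.exp(-0.5 * ((w - center) / b.width) ** 2)
    return out


def _pure_style_spectrum(
    config: GeneratorConfig,
    rng: np.random.Generator,
    batch_shift: float,
) -> tuple[np.ndarray, dict[str, float]]:
    v = config.variation
    w = config.grid.values
    mid = 0.5 * (w[0] + w[-1])
    c_w = rng.normal(1.0, v.water_scale_sd)
    water = _jittered_band_sum(
        config.grid, config.water_bands, rng,
        v.water_band_jitter_sd, v.band_center_jitter_sd,
    )
    solids = _jittered_band_sum(
        config.grid, config.yogurt_bands, rng,
        v.solids_band_jitter_sd, v.band_center_jitter_sd,
    )
    m = rng.normal(1.0, v.mult_scatter_sd)
    b0 = rng.normal(0.0, v.baseline_offset_sd)
    b1 = rng.normal(0.0, v.baseline_slope_sd)
    eps = rng.normal(0.0, v.noise_sd, size=w.size) if v.noise_sd > 0 else 0.0
    x = (c_w * water + solids + batch_shift) * m
    x = x + b0 + b1 * (w - mid) + eps
    latents = {
        "water_coeff": c_w,
        "scatter": m,
        "baseline_offset": b0,
        "baseline_slope": b1,
        "batch_shift": batch_shift,
    }
    return x, latents


def generate_pure(config: GeneratorConfig) -> tuple[SpectraSet, SyntheticTruth]:
    """Generate the pure-class samples, batch by batch."""
    _, rng, _ = _rng_streams(config.seed)
    v = config.variation
    rows, meta, recs = [], [], []
    sample_no = 0
    for batch_idx, count in enumerate(config.n_pure_per_batch):
        shift = rng.normal(0.0, v.batch_shift_sd) if v.batch_shift_sd > 0 else 0.0
        batch = f"B{batch_idx + 1}"
        for _ in range(count):
            sample_no += 1
            sid = f"P{sample_no:03d}"
            x, latents = _pure_style_spectrum(config, rng, shift)
            rows.append(x)
            meta.append(SampleMeta(sid, "pure", "A0", 0.0, batch))
            recs.append({"sample_id": sid, "batch": batch, **latents,
                         "adulterant_norm": 0.0, "source_id": ""})
    matrix = np.array(rows) if rows else np.empty((0, config.grid.n_points))
    return (
        SpectraSet(config.grid, matrix, meta),
        SyntheticTruth(pd.DataFrame(recs, columns=_TRUTH_COLUMNS)),
    )


_TRUTH_COLUMNS = [
    "sample_id",
    "batch",
    "water_coeff",
    "scatter",
    "baseline_offset",
    "baseline_slope",
    "batch_shift",
    "adulterant_norm",
    "source_id",
]


def generate_adulterated(
    config: GeneratorConfig, pure_base: SpectraSet
) -> tuple[SpectraSet, SyntheticTruth]:
    """Generate adulterated samples by doping randomly chosen pure spectra.

    Each sample blends ``(1 - L)`` of a pure-base spectrum with ``L`` of an
    adulterant 'solution' (Gaussian signature plus make-up water along the
    water profile), then adds fresh measurement noise.
    """
    config.grid.require_match(pure_base.grid, "generator and pure-base grids")
    if pure_base.n_samples == 0:
        raise ConfigError("pure_base must contain at least one spectrum")
    _, _, rng = _rng_streams(config.seed)
    water = _band_sum(config.grid, config.water_bands)
    v = config.variation
    rows, meta, recs = [], [], []
    sample_no = 0
    for adulterant, level, count in config.adulterant_design:
        signature = _band_sum(config.grid, config.adulterant_bands[adulterant])
        for _ in range(count):
            sample_no += 1
            sid = f"D{sample_no:03d}"
            src = int(rng.integers(pure_base.n_samples))
            eps = rng.normal(0.0, v.noise_sd, size=config.grid.n_points) \
                if v.noise_sd > 0 else 0.0
            solution = signature + config.solution_water_coeff * water
            x = (1.0 - level) * pure_base.matrix[src] + level * solution + eps
            rows.append(x)
            # a zero-dose design row contains no adulterant at all: its
            # samples are labelled pure, honouring the metadata invariant
            if level == 0.0:
                meta.append(SampleMeta(sid, "pure", "A0", 0.0,
                                       pure_base.meta[src].batch))
            else:
                meta.append(SampleMeta(sid, "adulterated", adulterant, level,
                                       pure_base.meta[src].batch))
            recs.append({
                "sample_id": sid,
                "batch": pure_base.meta[src].batch,
                "water_coeff": np.nan,
                "scatter": np.nan,
                "baseline_offset": np.nan,
                "baseline_slope": np.nan,
                "batch_shift": np.nan,
                "adulterant_norm": level * float(np.linalg.norm(signature)),
                "source_id": pure_base.meta[src].sample_id,
            })
    matrix = np.array(rows) if rows else np.empty((0, config.grid.n_points))
    return (
        SpectraSet(config.grid, matrix, meta),
        SyntheticTruth(pd.DataFrame(recs, columns=_TRUTH_COLUMNS)),
    )


def generate_study(
    config: GeneratorConfig | None = None,
) -> tuple[SpectraSet, SpectraSet, ReferenceSpectrum, SyntheticTruth]:
    """One-call fixture for the full design.

    Returns (pure, adulterated, water reference, truth); with the default
    config the sample counts are 60 pure and 197 adulterated.
    """
    if config is None:
        config = GeneratorConfig()
    ref_rng, _, _ = _rng_streams(config.seed)
    reference = _water_reference(config, ref_rng)
    pure, truth_p = generate_pure(config)
    adulterated, truth_a = generate_adulterated(config, pure)
    truth = SyntheticTruth(
        pd.concat([truth_p.records, truth_a.records], ignore_index=True)
    )
    return pure, adulterated, reference, truth
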