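"""End-to-end study runner.

One call reproduces the whole analysis protocol:

1. generate (or load) pure and adulterated spectra plus the water reference;
2. DUPLEX-split the pure samples once, on the raw spectra, into training and
   test subsets; every adulterated sample goes to the test set as a negative;
3. for each requested preprocessing variant (raw / SNV / OP), apply the
   transform to training and test spectra, fit an independent OCPLS model on
   the preprocessed training set, predict the test set, and evaluate.

The split is computed once on raw spectra and reused across variants so the
three evaluation rows share an identical test composition.  Two RNG concerns
(data generation, MCCV resampling) get independent streams derived from the
master seed, so changing the number of MCCV repeats never perturbs the
synthetic data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluate import EvaluationReport, evaluate_predictions
from .exceptions import ConfigError
from .ocpls import MCCVConfig, fit_ocpls, predict
from .preprocess import METHODS, PreprocessSpec, apply_preprocess
from .spectra_io import ReferenceSpectrum, SpectraSet, write_spectra_csv
from .split import DuplexSplit, duplex_split
from .synthetic_data import GeneratorConfig, generate_study

logger = logging.getLogger("ocplsnir")

__all__ = ["RunConfig", "StudyResult", "run_study"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full study run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    methods: tuple[str, ...] = ("raw", "snv", "op")
    n_test: int = 20
    mccv: MCCVConfig = field(default_factory=MCCVConfig)
    alpha: float = 0.05
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.methods:
            raise ConfigError("at least one preprocessing method is required")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ConfigError(f"unknown preprocessing methods: {unknown}")
        if not 0 < self.alpha < 0.5:
            raise ConfigError("alpha must be in (0, 0.5)")

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "methods": list(self.methods),
                "n_test": self.n_test,
                "alpha": self.alpha,
                "seed": self.seed,
                "mccv": [
                    self.mccv.leave_out_fraction,
                    self.mccv.n_repeats,
                    self.mccv.max_components,
                ],
                "generator_seed": self.generator.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class StudyResult:
    """Outputs of :func:`run_study`, keyed by preprocessing method."""

    reports: dict[str, EvaluationReport]
    split: DuplexSplit
    pure: SpectraSet
    adulterated: SpectraSet
    reference: ReferenceSpectrum
    seed: int
    config_hash: str


def _derive_seeds(master_seed: int) -> tuple[int, int]:
    """(generation seed, MCCV seed): one stream per concern, < 2**31."""
    ss = np.random.SeedSequence(master_seed)
    gen_s, mccv_s = ss.spawn(2)
    return (
        int(gen_s.generate_state(1)[0] % (2**31)),
        int(mccv_s.generate_state(1)[0] % (2**31)),
    )


def run_study(config: RunConfig | None = None) -> StudyResult:
    """Run the full generate → split → preprocess → fit → evaluate protocol."""
    if config is None:
        config = RunConfig()
    gen_seed, mccv_seed = _derive_seeds(config.seed)
    generator = config.generator.with_seed(gen_seed)
    t0 = time.perf_counter()
    pure, adulterated, reference, truth = generate_study(generator)
    logger.info(
        "generated %d pure + %d adulterated spectra on %d points (%.2fs)",
        pure.n_samples, adulterated.n_samples, pure.grid.n_points,
        time.perf_counter() - t0,
    )

    split = duplex_split(pure, config.n_test)
    logger.info("DUPLEX split: %d train / %d test", split.n_train, split.n_test)
    train_raw = pure.subset(split.train_indices)
    test_raw = pure.subset(split.test_indices).concat(adulterated)

    reports: dict[str, EvaluationReport] = {}
    models = {}
    for method in config.methods:
        spec = PreprocessSpec(
            method=method, reference=reference if method == "op" else None
        )
        train = apply_preprocess(train_raw, spec)
        test = apply_preprocess(test_raw, spec)
        mccv_cfg = MCCVConfig(
            leave_out_fraction=config.mccv.leave_out_fraction,
            n_repeats=config.mccv.n_repeats,
            max_components=config.mccv.max_components,
            rng_seed=mccv_seed,
        )
        t1 = time.perf_counter()
        model = fit_ocpls(
            train, mccv_cfg, alpha=config.alpha, preprocessing=method
        )
        results = predict(model, test)
        reports[method] = evaluate_predictions(results, test.meta, model)
        models[method] = model
        logger.info(
            "%s: %d LVs, sens %.3f, spec %.3f (%.2fs)", method,
            model.n_components, reports[method].sensitivity,
            reports[method].specificity, time.perf_counter() - t1,
        )

    result = StudyResult(
        reports=reports,
        split=split,
        pure=pure,
        adulterated=adulterated,
        reference=reference,
        seed=config.seed,
        config_hash=config.config_hash(),
    )
    if config.output_dir is not None:
        _write_artifacts(config, result, models, truth)
    return result


def _write_artifacts(config: RunConfig, result: StudyResult, models, truth) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_spectra_csv(result.pure, out / "pure.csv")
    write_spectra_csv(result.adulterated, out / "adulterated.csv")
    truth.records.to_csv(out / "truth.csv", index=False)
    split_rows = [
        (result.pure.meta[i].sample_id, subset)
        for subset, idx in (
            ("train", result.split.train_indices),
            ("test", result.split.test_indices),
        )
        for i in idx
    ]
    with open(out / "split.csv", "w") as fh:
        fh.write("sample_id,subset\n")
        for sid, subset in split_rows:
            fh.write(f"{sid},{subset}\n")
    summary_rows = []
    for method, report in result.reports.items():
        models[method].to_json(out / f"model_{method}.json")
        (out / f"report_{method}.txt").write_text(report.to_text() + "\n")
        summary_rows.append(report.to_frame())
    import pandas as pd

    pd.concat(summary_rows, ignore_index=True).to_csv(
        out / "summary.csv", index=False
    )
    (out / "run.json").write_text(
        json.dumps({"seed": result.seed, "config_hash": result.config_hash})
    )
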