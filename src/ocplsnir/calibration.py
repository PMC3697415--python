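"""Type-I-error (false-rejection) calibration study.

Repeatedly simulates the full modelling protocol on in-class data only:
each replicate draws a fresh homogeneous population of pure spectra, splits
it at random into a training set and a held-out set, fits the one-class
model, and records the fraction of held-out pure samples the acceptance
interval rejects.  If the interval is calibrated, that fraction averages
close to the significance level alpha.

A note on what "close" means: sigma is estimated from the n training
samples, so sigma_hat carries chi-square noise with ~n-1 degrees of freedom,
and the rejection probability is convex in sigma_hat; by Jensen's inequality
the expected rejection rate sits slightly above alpha at small n (about
0.0556 rather than 0.0500 at n = 40, alpha = 0.05).  Replicates share one
model per batch of held-out predictions, so the Monte-Carlo uncertainty of
the mean is governed by the replicate-level spread, not the pooled
prediction count.
"""

from __future__ import annotations

import numpy as np

from .ocpls import MCCVConfig, fit_ocpls, predict
from .preprocess import PreprocessSpec, apply_preprocess
from .synthetic_data import GeneratorConfig, generate_pure, make_water_reference

__all__ = ["type_i_error_study"]


def type_i_error_study(
    master_seed: int,
    n_replicates: int = 20,
    n_train: int = 40,
    n_heldout: int = 100,
    alpha: float = 0.05,
    method: str = "op",
    mccv: MCCVConfig | None = None,
) -> np.ndarray:
    """Per-replicate held-out rejection fractions of in-class samples.

    Each replicate generates ``n_train + n_heldout`` pure spectra from the
    default generator (single batch — the calibration question is about the
    interval, not batch structure), preprocesses them with `method`
    (default: orthogonal projection against the water reference, the
    protocol's headline model), fits OCPLS on a random ``n_train`` subset
    and predicts the rest.  All randomness derives from `master_seed`.
    """
    if mccv is None:
        mccv = MCCVConfig()
    master = np.random.SeedSequence(master_seed)
    gen_ss, mccv_ss, split_ss = master.spawn(3)
    gen_seeds = [int(s.generate_state(1)[0] % 2**31) for s in gen_ss.spawn(n_replicates)]
    mccv_seeds = [int(s.generate_state(1)[0] % 2**31) for s in mccv_ss.spawn(n_replicates)]
    split_rngs = [np.random.default_rng(s) for s in split_ss.spawn(n_replicates)]
    n_total = n_train + n_heldout
    fracs = np.empty(n_replicates)
    for rep in range(n_replicates):
        cfg = GeneratorConfig(seed=gen_seeds[rep], n_pure_per_batch=(n_total,))
        pure, _ = generate_pure(cfg)
        reference = make_water_reference(cfg.grid, seed=gen_seeds[rep])
        spec = PreprocessSpec(method, reference if method == "op" else None)
        data = apply_preprocess(pure, spec)
        idx = split_rngs[rep].permutation(n_total)
        model = fit_ocpls(
            data.subset(idx[:n_train]),
            MCCVConfig(
                leave_out_fraction=mccv.leave_out_fraction,
                n_repeats=mccv.n_repeats,
                max_components=mccv.max_components,
                rng_seed=mccv_seeds[rep],
            ),
            alpha=alpha,
            preprocessing=method,
        )
        results = predict(model, data.subset(idx[n_train:]))
        fracs[rep] = np.mean([not r.accepted for r in results])
    return fracs
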