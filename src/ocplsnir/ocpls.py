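"""One-class PLS (OCPLS) class modelling.

The model regresses an all-ones response on the *uncentered* training
spectra of the target class,

    1 = X b + e,

using NIPALS PLS1.  Column centering is forbidden here: centering makes
every predictor column orthogonal to the constant response, so the regression
would have nothing to fit.  The residual dispersion of the class is estimated
by Monte-Carlo cross-validation (MCCV): repeated random leave-out rounds
yield held-out prediction errors e = 1 - y_hat whose pooled mean and sample
standard deviation (mu_e, sigma_e) parameterise a normal-theory acceptance
interval at significance level alpha:

    ( 1 - mu_e - z_{1-alpha/2} sigma_e ,  1 - mu_e + z_{1-alpha/2} sigma_e ).

A new spectrum is accepted as in-class when its predicted response falls in
the (closed) interval.  The number of latent variables is chosen from the
MCCV PRESS curve: the smallest count whose PRESS is within a small relative
tolerance of the curve minimum ("more components cannot reduce PRESS
significantly").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .exceptions import (
    ConfigError,
    ContaminationError,
    DegenerateModelError,
    DimensionError,
    RankError,
)
from .spectra_io import SpectraSet, WavenumberGrid

__all__ = [
    "MCCVConfig",
    "OCPLSModel",
    "PredictionResult",
    "fit_uncentered_pls",
    "mccv",
    "select_components",
    "fit_ocpls",
    "predict",
]

# Component extraction fails when the deflated matrix is numerically zero
# along the extracted direction.  The weight norm itself decays geometrically
# on smooth low-noise spectra while the scores stay well-conditioned, so the
# rank check is on the score norm: exact rank deficiency drives t't to
# (machine eps)^2 of the data scale, many orders below any legitimate
# component.
_RANK_TOL = 1e3 * np.finfo(float).eps


@dataclass(frozen=True)
class MCCVConfig:
    """Monte-Carlo cross-validation settings.

    Defaults follow common practice for one-class PLS model selection:
    10% of the training samples left out per round, 100 rounds.
    """

    leave_out_fraction: float = 0.10
    n_repeats: int = 100
    max_components: int = 15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.leave_out_fraction < 0.5:
            raise ConfigError("leave_out_fraction must be in (0, 0.5)")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if self.max_components < 1:
            raise ConfigError("max_components must be >= 1")


@dataclass(frozen=True)
class PredictionResult:
    """Per-sample OCPLS verdict."""

    sample_id: str
    y_hat: float
    accepted: bool
    z_score: float


@dataclass
class OCPLSModel:
    """Fitted OCPLS model: coefficients, MCCV statistics, acceptance interval."""

    b: np.ndarray
    n_components: int
    mu_e: float
    sigma_e: float
    alpha: float
    z_crit: float
    interval: tuple[float, float]
    press_curve: np.ndarray
    grid: WavenumberGrid | None = None
    preprocessing: str = "raw"
    mccv_config: MCCVConfig = field(default_factory=MCCVConfig)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "b": self.b.tolist(),
            "n_components": self.n_components,
            "mu_e": self.mu_e,
            "sigma_e": self.sigma_e,
            "alpha": self.alpha,
            "z_crit": self.z_crit,
            "interval": list(self.interval),
            "press_curve": self.press_curve.tolist(),
            "grid": None if self.grid is None else self.grid.values.tolist(),
            "preprocessing": self.preprocessing,
            "mccv": {
                "leave_out_fraction": self.mccv_config.leave_out_fraction,
                "n_repeats": self.mccv_config.n_repeats,
                "max_components": self.mccv_config.max_components,
                "rng_seed": self.mccv_config.rng_seed,
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "OCPLSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            b=np.array(d["b"]),
            n_components=d["n_components"],
            mu_e=d["mu_e"],
            sigma_e=d["sigma_e"],
            alpha=d["alpha"],
            z_crit=d["z_crit"],
            interval=tuple(d["interval"]),
            press_curve=np.array(d["press_curve"]),
            grid=None if d["grid"] is None else WavenumberGrid(np.array(d["grid"])),
            preprocessing=d["preprocessing"],
            mccv_config=MCCVConfig(**d["mccv"]),
        )


def _nipals_pls1_ones(X: np.ndarray, n_components: int) -> np.ndarray:
    """Uncentered NIPALS PLS1 against the all-ones response.

    Returns an array B of shape (p, n_components) whose a-th column is the
    coefficient vector of the model truncated at a+1 latent variables, so a
    single pass serves every candidate component count.  Uses the standard
    X-only deflation; the coefficient recursion r_a = w_a - sum_j (p_j.w_a) r_j
    avoids forming W (P'W)^-1 q explicitly.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n, p):
        raise RankError(
            f"{n_components} components requested, at most {min(n, p)} possible"
        )
    y = np.ones(n)
    Xd = X.copy()
    scale = np.linalg.norm(X) + 1.0
    B = np.zeros((p, n_components))
    R = np.zeros((p, n_components))  # r_a vectors
    P = np.zeros((p, n_components))
    b = np.zeros(p)
    for a in range(n_components):
        w = Xd.T @ y
        wn = np.linalg.norm(w)
        if wn == 0.0:
            raise RankError(f"component {a + 1}: zero weight vector (rank)")
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (_RANK_TOL * scale) ** 2:
            raise RankError(f"component {a + 1}: score vector underflow (rank)")
        pa = Xd.T @ t / tt
        qa = float(y @ t) / tt
        Xd -= np.outer(t, pa)
        r = w - R[:, :a] @ (P[:, :a].T @ w)
        R[:, a] = r
        P[:, a] = pa
        b = b + qa * r
        B[:, a] = b
    return B


def fit_uncentered_pls(X: np.ndarray, n_components: int) -> np.ndarray:
    """Coefficient vector b of the uncentered PLS1 fit of 1 on X.

    Predictions are ``y_hat = X @ b`` with exactly `n_components` latent
    variables; no intercept, no centering, no scaling.
    """
    return _nipals_pls1_ones(X, n_components)[:, n_components - 1]


def mccv(X: np.ndarray, config: MCCVConfig) -> tuple[np.ndarray, np.ndarray]:
    """MCCV PRESS curve and pooled held-out errors per component count.

    Each round leaves out ``round(n * leave_out_fraction)`` samples (at least
    one) drawn uniformly without replacement, fits the uncentered PLS1 model
    on the remainder for every component count up to ``max_components``, and
    records held-out errors ``e = 1 - y_hat``.

    Returns
    -------
    press_curve : (max_components,) array, PRESS(a) = sum of squared held-out
        errors over all rounds at a components.
    errors : (max_components, n_repeats * k) array of pooled held-out errors.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k = max(1, round(n * config.leave_out_fraction))
    if n - k < config.max_components + 1:
        raise ConfigError(
            f"training remainder {n - k} too small for "
            f"{config.max_components} components"
        )
    rng = np.random.default_rng(config.rng_seed)
    A = config.max_components
    errors = np.empty((A, config.n_repeats * k))
    for rep in range(config.n_repeats):
        out = rng.choice(n, size=k, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out] = False
        B = _nipals_pls1_ones(X[mask], A)
        yhat = X[out] @ B  # (k, A)
        errors[:, rep * k : (rep + 1) * k] = (1.0 - yhat).T
    press = (errors**2).sum(axis=1)
    return press, errors


def select_components(press_curve: np.ndarray, rel_tol: float = 0.02) -> int:
    """Smallest component count within `rel_tol` of the PRESS minimum.

    Operationalises the elbow rule "low PRESS, and more components cannot
    reduce PRESS significantly" deterministically.
    """
    press = np.asarray(press_curve, dtype=float)
    if press.size == 0 or not np.all(np.isfinite(press)):
        raise ConfigError("press_curve must be nonempty and finite")
    threshold = (1.0 + rel_tol) * press.min()
    return int(np.flatnonzero(press <= threshold)[0]) + 1


def fit_ocpls(
    train: SpectraSet,
    mccv_config: MCCVConfig | None = None,
    alpha: float = 0.05,
    rel_tol: float = 0.02,
    preprocessing: str = "raw",
) -> OCPLSModel:
    """Fit the one-class model on pure-class training spectra.

    Runs MCCV, picks the latent-variable count from the PRESS curve, refits
    on the full training set, and derives the acceptance interval from the
    pooled MCCV errors at the chosen count.  `train` must contain only
    pure-class samples; the caller is responsible for having applied the same
    preprocessing that prediction data will receive (recorded in
    ``preprocessing`` for provenance).
    """
    if mccv_config is None:
        mccv_config = MCCVConfig()
    if not 0 < alpha < 0.5:
        raise ConfigError("alpha must be in (0, 0.5)")
    impure = [m.sample_id for m in train.meta if not m.is_pure]
    if impure:
        raise ContaminationError(
            f"one-class training set contains non-pure samples: {impure[:5]}"
        )
    if train.n_samples < 10:
        raise ConfigError("at least 10 training samples are required")
    press, errors = mccv(train.matrix, mccv_config)
    a = select_components(press, rel_tol=rel_tol)
    e = errors[a - 1]
    mu_e = float(e.mean())
    sigma_e = float(e.std(ddof=1))
    if sigma_e == 0.0:
        raise DegenerateModelError("MCCV errors have zero dispersion")
    z_crit = float(norm.ppf(1.0 - alpha / 2.0))
    interval = (1.0 - mu_e - z_crit * sigma_e, 1.0 - mu_e + z_crit * sigma_e)
    b = fit_uncentered_pls(train.matrix, a)
    return OCPLSModel(
        b=b,
        n_components=a,
        mu_e=mu_e,
        sigma_e=sigma_e,
        alpha=alpha,
        z_crit=z_crit,
        interval=interval,
        press_curve=press,
        grid=train.grid,
        preprocessing=preprocessing,
        mccv_config=mccv_config,
    )


def predict(model: OCPLSModel, data: SpectraSet) -> list[PredictionResult]:
    """Classify spectra against the model's acceptance interval.

    `data` must be on the model's grid and preprocessed identically to the
    training spectra.  The interval is closed: a predicted response exactly
    on a bound is accepted.
    """
    if data.matrix.shape[1] != model.b.size:
        raise DimensionError(
            f"data has {data.matrix.shape[1]} wavenumbers, model expects {model.b.size}"
        )
    if model.grid is not None:
        model.grid.require_match(data.grid, "model and data grids")
    y_hat = data.matrix @ model.b
    lower, upper = model.interval
    center = 1.0 - model.mu_e
    return [
        PredictionResult(
            sample_id=m.sample_id,
            y_hat=float(y),
            accepted=bool(lower <= y <= upper),
            z_score=float((y - center) / model.sigma_e),
        )
        for y, m in zip(y_hat, data.meta)
    ]
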