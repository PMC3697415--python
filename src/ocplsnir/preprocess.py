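"""Spectral preprocessing: raw passthrough, SNV, orthogonal projection.

Water dominates NIR absorbance of high-moisture foods, so ordinary
within-class water variation (content, temperature, path length) swamps the
small signals adulterants add.  Two corrections are offered:

* **OP** — orthogonal projection onto the complement of a nuisance direction
  ``s`` (the pure-water spectrum): ``x_new = (I - s s+) x_raw`` where ``s+``
  is the Moore-Penrose pseudoinverse.  For a single column vector
  ``s+ = s^T / (s^T s)``, so the projector collapses to the rank-one update
  ``x - s (s.x)/(s.s)`` — O(p) memory, no p x p matrix is ever formed.
* **SNV** — standard normal variate: per-spectrum standardisation
  ``(x - mean(x)) / sd(x)``, removing multiplicative scatter and additive
  offsets.  The sample (n-1) standard deviation is used by default; the
  choice is configurable and immaterial downstream thanks to SNV's affine
  invariance.

OP and SNV are alternative single transforms, never chained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSpectrumError, ReferenceError_
from .spectra_io import ReferenceSpectrum, SpectraSet, Spectrum

__all__ = ["PreprocessSpec", "op_project", "snv", "apply_preprocess", "METHODS"]

METHODS = ("raw", "snv", "op")


@dataclass(frozen=True)
class PreprocessSpec:
    """Which transform to apply; ``op`` requires a reference spectrum."""

    method: str = "raw"
    reference: ReferenceSpectrum | None = None
    snv_ddof: int = 1

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if self.method == "op" and self.reference is None:
            raise ReferenceError_("method 'op' requires a reference spectrum")


def op_project(x: Spectrum, s: ReferenceSpectrum) -> Spectrum:
    """Project ``x`` onto the orthogonal complement of ``s``.

    Returns ``x - s (s.x)/(s.s)``; the result is orthogonal to ``s`` to
    numerical precision.  Raises if the grids differ or ``s`` has zero norm.
    """
    x.grid.require_match(s.grid, "spectrum and reference grids")
    sv = s.absorbance
    ss = float(sv @ sv)
    if ss == 0.0:
        raise ReferenceError_("reference spectrum has zero norm")
    out = x.absorbance - sv * (float(sv @ x.absorbance) / ss)
    return Spectrum(x.grid, out)


def snv(x: Spectrum, ddof: int = 1) -> Spectrum:
    """Standard normal variate transform of a single spectrum."""
    a = x.absorbance
    if a.size < 2:
        raise DegenerateSpectrumError("SNV needs at least 2 points")
    sd = a.std(ddof=ddof)
    if sd == 0.0:
        raise DegenerateSpectrumError("constant spectrum: SNV undefined (sd = 0)")
    return Spectrum(x.grid, (a - a.mean()) / sd)


def apply_preprocess(data: SpectraSet, spec: PreprocessSpec) -> SpectraSet:
    """Apply the transform row-wise; metadata passes through untouched."""
    if spec.method == "raw":
        return SpectraSet(data.grid, data.matrix.copy(), data.meta)
    if spec.method == "op":
        ref = spec.reference
        assert ref is not None
        data.grid.require_match(ref.grid, "data and reference grids")
        sv = ref.absorbance
        ss = float(sv @ sv)
        if ss == 0.0:
            raise ReferenceError_("reference spectrum has zero norm")
        coef = data.matrix @ sv / ss
        return SpectraSet(data.grid, data.matrix - np.outer(coef, sv), data.meta)
    # snv
    if data.grid.n_points < 2:
        raise DegenerateSpectrumError("SNV needs at least 2 points per spectrum")
    mean = data.matrix.mean(axis=1, keepdims=True)
    sd = data.matrix.std(axis=1, ddof=spec.snv_ddof, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0.0)
    if flat.size:
        bad = ", ".join(data.meta[i].sample_id for i in flat[:5])
        raise DegenerateSpectrumError(f"constant spectra (sd = 0): {bad}")
    return SpectraSet(data.grid, (data.matrix - mean) / sd, data.meta)
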