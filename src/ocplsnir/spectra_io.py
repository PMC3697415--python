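"""Spectral containers and file I/O.

The central object is :class:`SpectraSet`: a samples x wavenumbers absorbance
matrix on a shared :class:`WavenumberGrid` with one :class:`SampleMeta` record
per row.  All algebra elsewhere in the package assumes the single internal
grid convention established here: wavenumbers in cm^-1, strictly ascending.
FT-IR instruments often emit descending grids; readers normalise on the way
in.

On-disk formats
---------------
* Wide CSV, one sample per row: five metadata columns
  (``sample_id, class_label, adulterant, doping_level, batch``) followed by
  one column per wavenumber, header carrying the wavenumbers themselves.
  Floats are written with Python's shortest ``repr`` so a write/read cycle is
  bit-lossless.
* JCAMP-DX (read-only, AFFN-encoded ``XYDATA``/``XYPOINTS``) for single
  reference spectra such as the pure-water spectrum.

Grids must match exactly between a data set and its reference spectrum;
interpolation between mismatched grids is deliberately out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import GridError, MetadataError, SpectraFormatError

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "ReferenceSpectrum",
    "SampleMeta",
    "SpectraSet",
    "default_study_grid",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_reference_jcampdx",
    "read_reference_csv",
    "write_reference_csv",
    "META_COLUMNS",
    "ADULTERANT_CODES",
]

META_COLUMNS = ("sample_id", "class_label", "adulterant", "doping_level", "batch")
ADULTERANT_CODES = ("A0", "A1", "A2", "A3")
CLASS_LABELS = ("pure", "adulterated")

#: Default study grid: 2074 points from 4000 cm^-1 at 3.857 cm^-1 spacing
#: (end ~ 11995.6 cm^-1).  The nominal 4000-12000 cm^-1 range and this point
#: count are not exactly consistent with inclusive endpoints; the point count
#: is the operative dimension for every model, so it wins.
STUDY_GRID_START = 4000.0
STUDY_GRID_STEP = 3.857
STUDY_GRID_POINTS = 2074


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly ascending wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise GridError("grid must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(values)):
            raise GridError("grid contains non-finite wavenumbers")
        if np.any(values <= 0):
            raise GridError("wavenumbers must be positive")
        if np.any(np.diff(values) <= 0):
            raise GridError("grid must be strictly ascending with no duplicates")

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    def matches(self, other: "WavenumberGrid") -> bool:
        return self.n_points == other.n_points and np.array_equal(
            self.values, other.values
        )

    def require_match(self, other: "WavenumberGrid", what: str = "grids") -> None:
        if not self.matches(other):
            raise GridError(f"{what} do not match; identical grids are required")


def default_study_grid() -> WavenumberGrid:
    """The 2074-point 4000 cm^-1 / 3.857 cm^-1 acquisition grid."""
    values = STUDY_GRID_START + STUDY_GRID_STEP * np.arange(STUDY_GRID_POINTS)
    return WavenumberGrid(values)


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum on a grid."""

    grid: WavenumberGrid
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", a)
        if a.ndim != 1 or a.size != self.grid.n_points:
            raise GridError(
                f"absorbance length {a.size} != grid length {self.grid.n_points}"
            )
        if not np.all(np.isfinite(a)):
            raise SpectraFormatError("absorbance contains non-finite values")


class ReferenceSpectrum(Spectrum):
    """A nuisance-direction spectrum (here: pure water) used for projection.

    Same contract as :class:`Spectrum` plus a nonzero norm, enforced where it
    matters (``preprocess.op_project``) rather than at construction, so that
    an all-zero file can still be inspected.
    """


@dataclass(frozen=True)
class SampleMeta:
    """Identity, class, adulterant code (A0-A3) and doping level of a sample.

    Invariant: ``adulterant == "A0"`` iff ``class_label == "pure"`` iff
    ``doping_level == 0``.
    """

    sample_id: str
    class_label: str
    adulterant: str
    doping_level: float
    batch: str = ""

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise MetadataError(
                f"{self.sample_id}: unknown class_label {self.class_label!r}"
            )
        if self.adulterant not in ADULTERANT_CODES:
            raise MetadataError(
                f"{self.sample_id}: unknown adulterant code {self.adulterant!r}"
            )
        if not 0 <= self.doping_level < 1:
            raise MetadataError(
                f"{self.sample_id}: doping_level {self.doping_level} not in [0, 1)"
            )
        is_pure = self.class_label == "pure"
        if is_pure != (self.adulterant == "A0") or is_pure != (self.doping_level == 0):
            raise MetadataError(
                f"{self.sample_id}: class/adulterant/doping_level inconsistent "
                f"({self.class_label}, {self.adulterant}, {self.doping_level})"
            )

    @property
    def is_pure(self) -> bool:
        return self.class_label == "pure"


@dataclass(frozen=True)
class SpectraSet:
    """Absorbance matrix (samples x wavenumbers) plus per-row metadata."""

    grid: WavenumberGrid
    matrix: np.ndarray
    meta: tuple[SampleMeta, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "meta", tuple(self.meta))
        if m.size == 0 and len(self.meta) == 0:
            # allow a genuinely empty set (0 x p)
            m = m.reshape(0, self.grid.n_points)
            object.__setattr__(self, "matrix", m)
        if m.shape[1] != self.grid.n_points:
            raise GridError(
                f"matrix has {m.shape[1]} columns, grid has {self.grid.n_points} points"
            )
        if m.shape[0] != len(self.meta):
            raise MetadataError(
                f"{m.shape[0]} spectra but {len(self.meta)} metadata records"
            )
        if m.size and not np.all(np.isfinite(m)):
            raise SpectraFormatError("spectra matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(self.grid, self.matrix[idx], [self.meta[i] for i in idx])

    def concat(self, other: "SpectraSet") -> "SpectraSet":
        self.grid.require_match(other.grid)
        return SpectraSet(
            self.grid,
            np.vstack([self.matrix, other.matrix]),
            list(self.meta) + list(other.meta),
        )

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (m.sample_id, m.class_label, m.adulterant, m.doping_level, m.batch)
                for m in self.meta
            ],
            columns=list(META_COLUMNS),
        )


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def write_spectra_csv(data: SpectraSet, path: str | Path) -> None:
    """Write a :class:`SpectraSet` as wide CSV (lossless round trip)."""
    spectral = pd.DataFrame(
        data.matrix, columns=[repr(float(w)) for w in data.grid.values]
    )
    pd.concat([data.meta_frame(), spectral], axis=1).to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read a wide-format spectra CSV written by :func:`write_spectra_csv`.

    The header's trailing columns are parsed as the wavenumber grid and must
    be strictly ascending.  Metadata is validated row by row.
    """
    try:
        frame = pd.read_csv(
            path,
            dtype={c: str for c in ("sample_id", "batch")},
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise SpectraFormatError(f"{path}: {exc}") from exc
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise SpectraFormatError(f"{path}: missing metadata columns {missing}")
    wn_cols = [c for c in frame.columns if c not in META_COLUMNS]
    try:
        wavenumbers = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavenumber header") from exc
    grid = WavenumberGrid(wavenumbers)
    matrix = frame[wn_cols].to_numpy(dtype=float) if wn_cols else np.empty((len(frame), 0))
    if matrix.size and not np.all(np.isfinite(matrix)):
        raise SpectraFormatError(f"{path}: ragged or non-numeric spectral rows")
    meta = [
        SampleMeta(
            sample_id=str(row.sample_id),
            class_label=str(row.class_label),
            adulterant=str(row.adulterant),
            doping_level=float(row.doping_level),
            batch="" if pd.isna(row.batch) else str(row.batch),
        )
        for row in frame[list(META_COLUMNS)].itertuples(index=False)
    ]
    return SpectraSet(grid, matrix.reshape(len(meta), grid.n_points), meta)


def write_reference_csv(ref: ReferenceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavenumber": ref.grid.values, "absorbance": ref.absorbance}
    ).to_csv(path, index=False)


def read_reference_csv(path: str | Path) -> ReferenceSpectrum:
    """Two-column (wavenumber, absorbance) reference spectrum reader."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if not {"wavenumber", "absorbance"} <= set(frame.columns):
        raise SpectraFormatError(f"{path}: expected wavenumber/absorbance columns")
    order = np.argsort(frame["wavenumber"].to_numpy())
    return ReferenceSpectrum(
        WavenumberGrid(frame["wavenumber"].to_numpy(dtype=float)[order]),
        frame["absorbance"].to_numpy(dtype=float)[order],
    )


# ---------------------------------------------------------------------------
# JCAMP-DX (minimal, AFFN only)
# ---------------------------------------------------------------------------

_LDR = re.compile(r"^\s*##\s*([^=]+?)\s*=\s*(.*)$")
_NUM = re.compile(r"[+-]?\d+(?:\.\d*)?(?:[eE][+-]?\d+)?")


def read_reference_jcampdx(path: str | Path) -> ReferenceSpectrum:
    """Read a single-block JCAMP-DX spectrum as a :class:`ReferenceSpectrum`.

    Supports AFFN-encoded ``##XYDATA=(X++(Y..Y))`` (with XFACTOR/YFACTOR)
    and ``##XYPOINTS=(XY..XY)`` records; compressed (SQZ/DIF/DUP) encodings
    are not supported.  Descending files are flipped to the ascending
    internal convention.
    """
    text = Path(path).read_text().splitlines()
    headers: dict[str, str] = {}
    data_lines: list[str] = []
    mode = None  # None | "xydata" | "xypoints"
    for line in text:
        line = line.split("$$")[0]  # strip comments
        m = _LDR.match(line)
        if m:
            key = m.group(1).upper().replace(" ", "").replace("-", "").replace("_", "")
            val = m.group(2).strip()
            if key == "XYDATA":
                mode = "xydata"
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "END":
                break
            else:
                if mode is not None:
                    mode = None  # a new LDR terminates the data record
                headers[key] = val
            continue
        if mode is not None and line.strip():
            data_lines.append(line.strip())
    if not data_lines or mode is None:
        raise SpectraFormatError(f"{path}: no XYDATA/XYPOINTS record found")

    if mode == "xypoints":
        nums = [float(t) for ln in data_lines for t in _NUM.findall(ln)]
        if len(nums) % 2:
            raise SpectraFormatError(f"{path}: odd token count in XYPOINTS")
        x = np.array(nums[0::2])
        y = np.array(nums[1::2])
    else:
        xfac = float(headers.get("XFACTOR", 1.0))
        yfac = float(headers.get("YFACTOR", 1.0))
        xs: list[float] = []
        ys: list[float] = []
        for ln in data_lines:
            toks = [float(t) for t in _NUM.findall(ln)]
            if len(toks) < 2:
                raise SpectraFormatError(f"{path}: XYDATA line with <2 numbers")
            x0, yvals = toks[0], toks[1:]
            # per-line abscissa start; spacing from FIRSTX/LASTX/NPOINTS
            npts = int(float(headers.get("NPOINTS", 0)))
            firstx = float(headers.get("FIRSTX", x0))
            lastx = float(headers.get("LASTX", x0))
            dx = (lastx - firstx) / (npts - 1) if npts > 1 else 0.0
            for k, yv in enumerate(yvals):
                xs.append((x0 + k * dx / (xfac if xfac else 1.0)) * xfac)
                ys.append(yv * yfac)
        x = np.array(xs)
        y = np.array(ys)

    if x.size < 2:
        raise SpectraFormatError(f"{path}: fewer than 2 data points")
    if x[0] > x[-1]:  # descending file -> ascending convention
        x, y = x[::-1], y[::-1]
    return ReferenceSpectrum(WavenumberGrid(x), y)
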