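"""Domain types and file I/O for 1-D Raman/SERS spectra.

Spectra live on a wavenumber (Raman shift) axis in cm^-1, strictly
ascending, with unitless intensity counts.  Two on-disk formats are
supported:

* two-column ASCII text (shift, intensity), whitespace- or
  comma-delimited, ``#`` comment/header lines allowed -- the format
  portable Raman instruments export;
* a CSV matrix with an ``id`` column and numeric wavenumber headers,
  one spectrum per row, for whole cohorts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AxisError",
    "ExtrapolationError",
    "SpectrumParseError",
    "WavenumberAxis",
    "Spectrum",
    "SpectrumSet",
    "default_axis",
    "parse_filename_metadata",
    "read_two_column_ascii",
    "write_two_column_ascii",
    "read_matrix_csv",
    "write_matrix_csv",
    "resample_to_common_axis",
]


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed."""


class AxisError(ValueError):
    """A wavenumber axis violates its invariants."""


class ExtrapolationError(ValueError):
    """A resampling target extends beyond the source axis."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise AxisError("axis must be 1-D with at least 2 points")
        if not np.all(np.isfinite(values)):
            raise AxisError("axis contains non-finite values")
        if not np.all(np.diff(values) > 0):
            raise AxisError("axis must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def nearest_index(self, shift: float) -> int:
        """Index of the grid point closest to ``shift``."""
        return int(np.argmin(np.abs(self.values - shift)))


def default_axis(lo: float = 400.0, hi: float = 1800.0, step: float = 1.0) -> WavenumberAxis:
    """The default analysis axis: 400-1800 cm^-1 at 1 cm^-1 spacing."""
    n = int(round((hi - lo) / step)) + 1
    return WavenumberAxis(lo + step * np.arange(n))


@dataclass
class Spectrum:
    """One measured or synthetic spectrum with free-text metadata."""

    axis: WavenumberAxis
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        intensity = np.asarray(self.intensity, dtype=float)
        if intensity.shape != (len(self.axis),):
            raise ValueError(
                f"intensity length {intensity.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensity contains non-finite values")
        self.intensity = intensity

    def with_intensity(self, intensity: np.ndarray, **meta_updates) -> "Spectrum":
        meta = {**self.meta, **meta_updates}
        return Spectrum(self.axis, np.asarray(intensity, dtype=float), meta)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.intensity))


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one common axis."""

    spectra: list[Spectrum]
    common_axis: WavenumberAxis

    def __post_init__(self) -> None:
        for i, s in enumerate(self.spectra):
            if s.axis != self.common_axis:
                raise AxisError(f"spectrum {i} is not on the common axis")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectrumSet":
        if not spectra:
            raise ValueError("cannot build a SpectrumSet from no spectra")
        return cls(list(spectra), spectra[0].axis)

    def ids(self) -> list[str]:
        return [str(s.meta.get("sample", i)) for i, s in enumerate(self.spectra)]

    def to_matrix(self) -> np.ndarray:
        """Stack intensities into an (n_spectra, n_points) array."""
        return np.vstack([s.intensity for s in self.spectra]) if self.spectra else np.empty(
            (0, len(self.common_axis))
        )

    def map(self, fn) -> "SpectrumSet":
        out = [fn(s) for s in self.spectra]
        axis = out[0].axis if out else self.common_axis
        return SpectrumSet(out, axis)


def parse_filename_metadata(path: str | Path, pattern: str | None) -> dict:
    """Extract sample/replicate/group metadata from a filename.

    ``pattern`` is a regular expression with named groups (``sample``,
    ``replicate``, ``group``) matched against the file stem.  Unmatched
    filenames yield empty metadata with a logged warning, never an error.
    """
    stem = Path(path).stem
    meta: dict = {"filename": Path(path).name}
    if pattern is None:
        return meta
    m = re.search(pattern, stem)
    if m is None:
        logger.warning("filename %r does not match metadata pattern %r", stem, pattern)
        return meta
    meta.update({k: v for k, v in m.groupdict().items() if v is not None})
    return meta


def read_two_column_ascii(
    path: str | Path,
    metadata_pattern: str | None = None,
) -> Spectrum:
    """Read a two-column (shift, intensity) ASCII spectrum file.

    Lines starting with ``#`` are skipped; columns may be separated by
    whitespace or commas.  Raises :class:`SpectrumParseError` (naming
    the offending line) on non-numeric rows and :class:`AxisError` if
    the shift column is not strictly increasing.
    """
    path = Path(path)
    shifts: list[float] = []
    intensities: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}: line {lineno}: expected >= 2 columns")
            try:
                shifts.append(float(parts[0]))
                intensities.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric value in {parts[:2]}"
                ) from exc
    if len(shifts) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    try:
        axis = WavenumberAxis(np.asarray(shifts))
    except AxisError as exc:
        raise AxisError(f"{path}: {exc}") from exc
    meta = parse_filename_metadata(path, metadata_pattern)
    return Spectrum(axis, np.asarray(intensities), meta)


def write_two_column_ascii(spectrum: Spectrum, path: str | Path, fmt: str = "%.10g") -> None:
    """Write a spectrum as two-column ASCII (round-trips with the reader)."""
    data = np.column_stack([spectrum.axis.values, spectrum.intensity])
    np.savetxt(path, data, fmt=fmt, delimiter="\t")


def read_matrix_csv(path: str | Path) -> SpectrumSet:
    """Read a sample x wavenumber CSV matrix (first column ``id``)."""
    path = Path(path)
    try:
        # correctly-rounded float parsing makes the write/read cycle
        # bitwise lossless at full repr precision
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 3 or df.columns[0] != "id":
        raise SpectrumParseError(
            f"{path}: expected an 'id' column followed by >= 2 wavenumber columns"
        )
    try:
        wavenumbers = np.asarray([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectrumParseError(f"{path}: non-numeric wavenumber header") from exc
    axis = WavenumberAxis(wavenumbers)
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise SpectrumParseError(f"{path}: non-finite or missing intensity values")
    spectra = [
        Spectrum(axis, row, {"sample": str(sid)}) for sid, row in zip(df["id"], values)
    ]
    return SpectrumSet(spectra, axis)


def write_matrix_csv(sset: SpectrumSet, path: str | Path, float_format: str | None = None) -> None:
    """Write a SpectrumSet as a sample x wavenumber CSV matrix.

    With the default ``float_format=None`` the round trip through
    :func:`read_matrix_csv` is bitwise lossless (pandas writes full
    ``repr`` precision).
    """
    df = pd.DataFrame(
        sset.to_matrix(), columns=[repr(float(v)) for v in sset.common_axis.values]
    )
    df.insert(0, "id", sset.ids())
    df.to_csv(path, index=False, float_format=float_format)


def resample_to_common_axis(
    spectra: Iterable[Spectrum], axis: WavenumberAxis
) -> SpectrumSet:
    """Linearly interpolate spectra onto a shared target axis.

    The target axis must lie within every source spectrum's span;
    extrapolation raises :class:`ExtrapolationError`.  Values at grid
    points shared with the source axis are unchanged.
    """
    out: list[Spectrum] = []
    for i, s in enumerate(spectra):
        if axis.lo < s.axis.lo or axis.hi > s.axis.hi:
            raise ExtrapolationError(
                f"spectrum {i}: target axis [{axis.lo}, {axis.hi}] exceeds source span "
                f"[{s.axis.lo}, {s.axis.hi}]"
            )
        y = np.interp(axis.values, s.axis.values, s.intensity)
        out.append(Spectrum(axis, y, dict(s.meta)))
    return SpectrumSet(out, axis)
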