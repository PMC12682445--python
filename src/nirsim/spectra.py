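"""Core spectral data types and CSV I/O.

A dataset is a sample x wavenumber absorbance matrix on a shared axis.  The
canonical on-disk format is a wide CSV, one row per sample::

    sample_id,class,10000,9992,...
    c01_s01,class_01,0.412,0.409,...

The ``class`` column may be empty (unlabeled samples are legal; grid
evaluation then becomes unavailable while pairwise similarity still works).
The wavenumber axis comes from the header and must be strictly monotone; by
convention it is stored descending (10,000 -> 4,000 cm^-1, matching
instrument scan order).  Non-monotone axes are rejected, never reordered.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import FormatError, InputError, ParseError

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "SpectralDataset",
    "read_dataset",
    "write_dataset",
]


def _fmt(v: float) -> str:
    """Full-precision, compact decimal rendering (round-trips float64)."""
    return format(float(v), ".17g")


@dataclass(frozen=True, eq=False)
class WavenumberAxis:
    """A strictly monotone wavenumber axis in cm^-1."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 3:
            raise InputError("axis needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise InputError("axis contains non-finite values")
        d = np.diff(pts)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InputError("axis must be strictly monotone")
        pts.flags.writeable = False
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return int(self.points.size)

    @property
    def descending(self) -> bool:
        return bool(self.points[0] > self.points[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return np.array_equal(self.points, other.points)

    def __hash__(self) -> int:  # frozen dataclass convenience
        return hash(self.points.tobytes())


@dataclass(frozen=True, eq=False)
class Spectrum:
    """One sample's absorbance vector (unitless intensities)."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise InputError(f"spectrum {self.sample_id!r}: values must be 1-D")
        if not np.all(np.isfinite(vals)):
            raise InputError(f"spectrum {self.sample_id!r}: non-finite values")
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class SpectralDataset:
    """An ordered collection of spectra on a shared axis, with optional
    class labels (free text) keyed by sample id."""

    axis: WavenumberAxis
    spectra: list[Spectrum]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)
        n = len(self.axis)
        ids = [s.sample_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sample_id(s): {dup}")
        for s in self.spectra:
            if len(s) != n:
                raise InputError(
                    f"spectrum {s.sample_id!r} has {len(s)} points, axis has {n}"
                )
        unknown = set(self.labels) - set(ids)
        if unknown:
            raise InputError(f"labels reference unknown sample_id(s): {sorted(unknown)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]

    @property
    def n_samples(self) -> int:
        return len(self.spectra)

    def values_matrix(self) -> np.ndarray:
        """Samples x wavenumbers float matrix (a copy)."""
        return np.array([s.values for s in self.spectra], dtype=float)

    def with_values(self, matrix: np.ndarray) -> "SpectralDataset":
        """Same ids, labels and axis, new values (same shape)."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (self.n_samples, len(self.axis)):
            raise InputError(
                f"matrix shape {matrix.shape} != ({self.n_samples}, {len(self.axis)})"
            )
        spectra = [
            Spectrum(s.sample_id, matrix[i]) for i, s in enumerate(self.spectra)
        ]
        return SpectralDataset(self.axis, spectra, dict(self.labels))

    def get(self, sample_id: str) -> Spectrum:
        for s in self.spectra:
            if s.sample_id == sample_id:
                return s
        raise InputError(f"unknown sample_id {sample_id!r}")

    def allclose(self, other: "SpectralDataset", atol: float = 1e-12) -> bool:
        return (
            self.axis == other.axis
            and self.sample_ids == other.sample_ids
            and self.labels == other.labels
            and np.allclose(self.values_matrix(), other.values_matrix(), atol=atol, rtol=0.0)
        )

    @classmethod
    def from_matrix(
        cls,
        axis: WavenumberAxis,
        sample_ids: Sequence[str],
        matrix: np.ndarray,
        labels: Mapping[str, str] | None = None,
    ) -> "SpectralDataset":
        matrix = np.asarray(matrix, dtype=float)
        spectra = [Spectrum(sid, matrix[i]) for i, sid in enumerate(sample_ids)]
        return cls(axis, spectra, dict(labels or {}))


def read_dataset(path: str | Path, dialect: str = "excel") -> SpectralDataset:
    """Read a wide-format spectral CSV.

    Header must be ``sample_id,class,<wavenumbers...>``; each row is one
    sample.  Raises :class:`FormatError` for a malformed header or ragged
    rows, :class:`ParseError` (naming row and column) for non-numeric cells.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, dialect=dialect)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if len(header) < 5 or header[0] != "sample_id" or header[1] != "class":
            raise FormatError(
                f"{path}: header must start with 'sample_id,class' followed by "
                "at least 3 wavenumber columns"
            )
        try:
            axis_points = [float(tok) for tok in header[2:]]
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric wavenumber in header: {exc}") from None
        axis = WavenumberAxis(np.asarray(axis_points))

        spectra: list[Spectrum] = []
        labels: dict[str, str] = {}
        width = len(header)
        for rownum, row in enumerate(reader, start=2):
            if not row:
                continue  # ignore trailing blank line
            if len(row) != width:
                raise FormatError(
                    f"{path}: row {rownum} has {len(row)} fields, expected {width}"
                )
            sid, cls_label = row[0], row[1]
            vals = np.empty(width - 2)
            for j, tok in enumerate(row[2:]):
                try:
                    vals[j] = float(tok)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {tok!r} at row {rownum}, "
                        f"column {header[2 + j]!r}"
                    ) from None
            spectra.append(Spectrum(sid, vals))
            if cls_label != "":
                labels[sid] = cls_label
    return SpectralDataset(axis, spectra, labels)


def write_dataset(dataset: SpectralDataset, path: str | Path) -> None:
    """Write a dataset as wide CSV at full float precision.

    ``read_dataset(write_dataset(d)) == d`` within 1e-12 (exactly, in fact:
    values are rendered with 17 significant digits)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "class"] + [_fmt(w) for w in dataset.axis.points])
        for s in dataset.spectra:
            label = dataset.labels.get(s.sample_id, "")
            writer.writerow([s.sample_id, label] + [_fmt(v) for v in s.values])
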