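"""Labeled reflectance-pixel tables.

A *pixel table* holds one row per 1-km MODIS coastal pixel with 14
reflectance attributes — surface reflectance (``rhos``) and
top-of-atmosphere reflectance (``rhot``) at seven wavelengths — plus a
binary *Sargassum* presence label and optional latitude/longitude/date
metadata.  This module reads and writes that table as delimited text,
validates it, and computes the descriptive statistics (class counts,
per-class band means) used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Nominal MODIS band center wavelengths used as classifier features, in nm.
BAND_WAVELENGTHS: tuple[int, ...] = (412, 469, 555, 645, 859, 1240, 2130)

RHOS_COLUMNS: tuple[str, ...] = tuple(f"rhos_{w}" for w in BAND_WAVELENGTHS)
RHOT_COLUMNS: tuple[str, ...] = tuple(f"rhot_{w}" for w in BAND_WAVELENGTHS)
REFLECTANCE_COLUMNS: tuple[str, ...] = RHOS_COLUMNS + RHOT_COLUMNS
LABEL_COLUMN = "label"
METADATA_COLUMNS: tuple[str, ...] = ("lat", "lon", "date")

#: Accepted spellings of the binary label, normalized to {0, 1}.
_LABEL_ALIASES: dict[object, int] = {
    0: 0, 1: 1,
    "0": 0, "1": 1,
    False: 0, True: 1,
    "false": 0, "true": 1,
    "without": 0, "with": 1,
}


class SchemaError(ValueError):
    """A required column is missing or the schema mapping is malformed."""


class ValidationError(ValueError):
    """A row holds a value outside the table's domain (non-finite
    reflectance, unknown label)."""

    def __init__(self, message: str, rows: Sequence[int] = ()) -> None:
        super().__init__(message)
        self.rows = tuple(rows)


class NoDataError(ValueError):
    """An operation that needs at least one observation received none."""


@dataclass(frozen=True)
class PixelSpectrum:
    """A single coastal pixel: 7 rhos + 7 rhot reflectances and a label.

    Reflectances are dimensionless and ordered by wavelength (412 →
    2130 nm), identically for both families.  ``label`` is 1 when
    *Sargassum* is present, 0 when absent.
    """

    rhos: np.ndarray
    rhot: np.ndarray
    label: int
    lat: float | None = None
    lon: float | None = None
    date: str | None = None

    def __post_init__(self) -> None:
        rhos = np.asarray(self.rhos, dtype=float)
        rhot = np.asarray(self.rhot, dtype=float)
        if rhos.shape != (7,) or rhot.shape != (7,):
            raise ValidationError(
                f"expected 7 rhos and 7 rhot values, got {rhos.shape} and {rhot.shape}"
            )
        if not (np.isfinite(rhos).all() and np.isfinite(rhot).all()):
            raise ValidationError("reflectances must be finite")
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label!r}")
        object.__setattr__(self, "rhos", rhos)
        object.__setattr__(self, "rhot", rhot)

    @property
    def features(self) -> np.ndarray:
        """The 14-vector [rhos 412→2130, rhot 412→2130]."""
        return np.concatenate([self.rhos, self.rhot])


class SpectralDataset:
    """An ordered collection of labeled reflectance pixels.

    Internally a :class:`pandas.DataFrame` with canonical columns
    ``rhos_412 … rhos_2130``, ``rhot_412 … rhot_2130``, ``label`` and
    optional ``lat``/``lon``/``date``.  Row order is preserved by every
    operation in this module.  Construction only checks that the
    canonical columns exist; strict per-cell validation belongs to
    :func:`read_dataset` (on ingest) and :func:`validate_dataset`
    (report-only), so that a dataset carrying injected faults can still
    be inspected.
    """

    band_wavelengths = BAND_WAVELENGTHS

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in REFLECTANCE_COLUMNS + (LABEL_COLUMN,) if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required columns: {', '.join(missing)}")
        keep = [c for c in frame.columns if c in REFLECTANCE_COLUMNS + (LABEL_COLUMN,) + METADATA_COLUMNS]
        self._frame = frame.loc[:, keep].reset_index(drop=True)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[PixelSpectrum]:
        for i in range(len(self)):
            yield self.pixel(i)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        return self._frame.equals(other._frame)

    def pixel(self, i: int) -> PixelSpectrum:
        row = self._frame.iloc[i]
        meta = {k: (row[k] if k in self._frame.columns and pd.notna(row[k]) else None)
                for k in METADATA_COLUMNS}
        return PixelSpectrum(
            rhos=row[list(RHOS_COLUMNS)].to_numpy(dtype=float),
            rhot=row[list(RHOT_COLUMNS)].to_numpy(dtype=float),
            label=int(row[LABEL_COLUMN]),
            lat=meta["lat"], lon=meta["lon"],
            date=None if meta["date"] is None else str(meta["date"]),
        )

    # -- array views --------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """A defensive copy of the underlying table."""
        return self._frame.copy()

    @property
    def labels(self) -> np.ndarray:
        return self._frame[LABEL_COLUMN].to_numpy(dtype=int)

    def features(self) -> np.ndarray:
        """(n, 14) float array ordered [rhos 412→2130, rhot 412→2130]."""
        return self._frame[list(REFLECTANCE_COLUMNS)].to_numpy(dtype=float)

    def reflectances(self, band_family: str) -> np.ndarray:
        """(n, 7) array for one family, columns ordered by wavelength."""
        cols = _family_columns(band_family)
        return self._frame[list(cols)].to_numpy(dtype=float)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "SpectralDataset":
        """New dataset with the selected rows, preserving their order."""
        return SpectralDataset(self._frame.iloc[np.asarray(indices)].reset_index(drop=True))

    def class_subset(self, label: int) -> "SpectralDataset":
        return self.subset(np.flatnonzero(self.labels == label))


@dataclass(frozen=True)
class BandSummary:
    """Per-band mean reflectance of one class for one band family."""

    band_family: str
    class_label: int
    per_band_mean: np.ndarray
    wavelengths: tuple[int, ...] = BAND_WAVELENGTHS

    def __post_init__(self) -> None:
        mean = np.asarray(self.per_band_mean, dtype=float)
        if mean.shape != (len(self.wavelengths),):
            raise ValueError("per_band_mean must align with the band wavelengths")
        object.__setattr__(self, "per_band_mean", mean)

    def mean_at(self, wavelength: int) -> float:
        return float(self.per_band_mean[self.wavelengths.index(wavelength)])


def _family_columns(band_family: str) -> tuple[str, ...]:
    if band_family == "rhos":
        return RHOS_COLUMNS
    if band_family == "rhot":
        return RHOT_COLUMNS
    raise ValueError(f"band_family must be 'rhos' or 'rhot', got {band_family!r}")


def _normalize_label(value: object, row: int) -> int:
    key = value.strip().lower() if isinstance(value, str) else value
    if isinstance(key, float):
        if not np.isfinite(key) or key != int(key):
            raise ValidationError(f"row {row}: unknown label value {value!r}", rows=[row])
        key = int(key)
    try:
        hash(key)
    except TypeError:
        raise ValidationError(f"row {row}: unknown label value {value!r}", rows=[row]) from None
    if key not in _LABEL_ALIASES:
        raise ValidationError(f"row {row}: unknown label value {value!r}", rows=[row])
    return _LABEL_ALIASES[key]


def read_dataset(
    path,
    schema: Mapping[str, object] | None = None,
    sep: str | None = None,
) -> SpectralDataset:
    """Read a delimited-text pixel table into a :class:`SpectralDataset`.

    Parameters
    ----------
    path
        Delimited text file, UTF-8, header row required.  Comma is the
        default delimiter; tab is detected automatically (or force one
        via ``sep``).
    schema
        Optional remapping for files whose headers differ from the
        canonical names.  Two keys are recognized: ``"columns"``, a
        mapping from canonical names (``rhos_412`` … ``label`` …) to the
        file's actual headers, and ``"label_values"``, a mapping from
        the file's label spellings to 0/1.  Unmapped canonical names
        are looked up verbatim.
    sep
        Explicit delimiter; ``None`` sniffs between comma and tab.

    Raises
    ------
    SchemaError
        A mapped or required column is absent (the message names it).
    ValidationError
        A reflectance cell is non-numeric or non-finite, or a label
        value is not recognized; the offending row index is reported.
    """
    schema = dict(schema or {})
    column_map: Mapping[str, str] = dict(schema.get("columns", {}))
    label_values: Mapping[object, object] = dict(schema.get("label_values", {}))

    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    raw = pd.read_csv(path, sep=sep, encoding="utf-8")
    raw.columns = [str(c).strip() for c in raw.columns]

    def source(canonical: str) -> str:
        return str(column_map.get(canonical, canonical))

    data: dict[str, object] = {}
    for canonical in REFLECTANCE_COLUMNS + (LABEL_COLUMN,):
        actual = source(canonical)
        if actual not in raw.columns:
            raise SchemaError(f"missing column {actual!r} (for {canonical!r})")
        data[canonical] = raw[actual]
    for canonical in METADATA_COLUMNS:
        actual = source(canonical)
        if actual in raw.columns:
            data[canonical] = raw[actual]

    frame = pd.DataFrame(data)

    for col in REFLECTANCE_COLUMNS:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(values.to_numpy(dtype=float)))
        if bad.size:
            raise ValidationError(
                f"row {bad[0]}: column {col!r} is non-numeric or non-finite",
                rows=bad.tolist(),
            )
        frame[col] = values.astype(float)

    if label_values:
        mapped = frame[LABEL_COLUMN].map(
            lambda v: label_values.get(v, label_values.get(str(v), v))
        )
    else:
        mapped = frame[LABEL_COLUMN]
    frame[LABEL_COLUMN] = [
        _normalize_label(v, i) for i, v in enumerate(mapped.tolist())
    ]
    return SpectralDataset(frame)


def write_dataset(ds: SpectralDataset, path, sep: str = ",") -> None:
    """Write the canonical delimited-text form (UTF-8, header row)."""
    ds.frame.to_csv(path, sep=sep, index=False, encoding="utf-8")


def class_counts(ds: SpectralDataset) -> tuple[int, int]:
    """(pixels with *Sargassum*, pixels without); sums to ``len(ds)``."""
    labels = ds.labels
    n_with = int(np.sum(labels == 1))
    return n_with, len(ds) - n_with


def band_means(ds: SpectralDataset, class_label: int, band_family: str) -> BandSummary:
    """Arithmetic per-band mean reflectance over pixels of one class.

    Raises :class:`NoDataError` when the class is empty — an empty class
    must surface explicitly, never as silent zeros.
    """
    if class_label not in (0, 1):
        raise ValueError(f"class_label must be 0 or 1, got {class_label!r}")
    values = ds.reflectances(band_family)[ds.labels == class_label]
    if values.shape[0] == 0:
        raise NoDataError(f"no pixels with label {class_label}")
    return BandSummary(band_family=band_family, class_label=class_label,
                       per_band_mean=values.mean(axis=0))


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    offending_rows: tuple[int, ...] = ()


@dataclass(frozen=True)
class ValidationReport:
    """Per-invariant pass/fail with offending row indices; report-only."""

    checks: tuple[CheckResult, ...] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def n_offenders(self) -> int:
        return len({r for c in self.checks for r in c.offending_rows})

    def check(self, name: str) -> CheckResult:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def validate_dataset(ds: SpectralDataset) -> ValidationReport:
    """Audit a dataset against the pixel-table invariants.

    The dataset is left unchanged; failures are reported, not raised.
    Checks: every reflectance finite (per family), every label in
    {0, 1}.
    """
    checks = []
    for family in ("rhos", "rhot"):
        values = ds.reflectances(family)
        bad = np.flatnonzero(~np.isfinite(values).all(axis=1)) if len(ds) else np.array([], int)
        checks.append(CheckResult(f"{family}_finite", bad.size == 0, tuple(bad.tolist())))
    labels = ds._frame[LABEL_COLUMN].to_numpy()
    bad = np.flatnonzero(~np.isin(labels, (0, 1))) if len(ds) else np.array([], int)
    checks.append(CheckResult("label_domain", bad.size == 0, tuple(bad.tolist())))
    return ValidationReport(checks=tuple(checks))
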