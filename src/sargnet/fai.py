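"""Floating Algae Index (FAI).

FAI measures how far the near-infrared reflectance of a pixel rises
above a linear baseline interpolated between the red and shortwave
infrared bands::

    FAI = R_nir - [R_red + (R_swir - R_red) * (l_nir - l_red) / (l_swir - l_red)]

Floating vegetation has a pronounced NIR red-edge, so FAI is elevated
over algal mats and near zero over clear water.  With the MODIS triple
(645, 859, 1240 nm) the interpolation factor is 214/595.  The index is
used descriptively here — per-class summary statistics, not a
classification threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sargnet.dataset import NoDataError, SpectralDataset

#: Nominal MODIS center wavelengths of the red/NIR/SWIR triple, nm.
FAI_WAVELENGTHS: tuple[float, float, float] = (645.0, 859.0, 1240.0)


@dataclass(frozen=True)
class FAIBandTriple:
    """Reflectances of one pixel at the red/NIR/SWIR FAI bands."""

    red: float
    nir: float
    swir: float
    wavelengths: tuple[float, float, float] = FAI_WAVELENGTHS

    def __post_init__(self) -> None:
        red, nir, swir = self.wavelengths
        if not red < nir < swir:
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite([self.red, self.nir, self.swir])):
            raise ValueError("band reflectances must be finite")


@dataclass(frozen=True)
class FAISummary:
    """Location/spread statistics of a set of FAI values (dimensionless)."""

    n_pixels: int
    mean: float
    std: float
    min: float
    q25: float
    median: float
    q75: float
    max: float
    class_label: int | None = None

    def __post_init__(self) -> None:
        if not (self.min <= self.q25 <= self.median <= self.q75 <= self.max):
            raise ValueError("order statistics must be monotone")
        if self.std < 0:
            raise ValueError("std must be >= 0")

    def as_row(self) -> dict[str, float]:
        return {
            "pixels": self.n_pixels, "mean": self.mean, "std": self.std,
            "min": self.min, "25%": self.q25, "50%": self.median,
            "75%": self.q75, "max": self.max,
        }


def _fai(red, nir, swir, wavelengths=FAI_WAVELENGTHS):
    l_red, l_nir, l_swir = wavelengths
    factor = (l_nir - l_red) / (l_swir - l_red)
    return nir - (red + (swir - red) * factor)


def fai_pixel(bands: FAIBandTriple) -> float:
    """FAI of a single pixel: NIR minus the red→SWIR linear baseline."""
    return float(_fai(bands.red, bands.nir, bands.swir, bands.wavelengths))


def fai_dataset(ds: SpectralDataset, band_family: str = "rhos") -> np.ndarray:
    """Per-pixel FAI values, order-preserving, one per dataset row.

    Uses the requested reflectance family's 645/859/1240 nm bands.
    ``rhos`` (surface reflectance) is the default: it is the
    atmospherically corrected quantity the index is conventionally
    computed from.
    """
    if len(ds) == 0:
        raise NoDataError("dataset is empty")
    bands = ds.reflectances(band_family)
    wl = list(ds.band_wavelengths)
    red = bands[:, wl.index(645)]
    nir = bands[:, wl.index(859)]
    swir = bands[:, wl.index(1240)]
    return _fai(red, nir, swir)


def fai_summary(values, class_label: int | None = None) -> FAISummary:
    """Summarize FAI values: mean, sample std (n−1 denominator), and the
    min/quartile/median/max order statistics with linear interpolation
    between order statistics.  A single value has std 0 by convention.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise NoDataError("no FAI values to summarize")
    q25, median, q75 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return FAISummary(
        n_pixels=int(values.size),
        mean=float(values.mean()),
        std=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        min=float(values.min()),
        q25=float(q25),
        median=float(median),
        q75=float(q75),
        max=float(values.max()),
        class_label=class_label,
    )


def fai_class_summaries(ds: SpectralDataset, band_family: str = "rhos") -> dict[int, FAISummary]:
    """One :class:`FAISummary` per class present in the dataset,
    keyed by label (1 = with *Sargassum* first)."""
    values = fai_dataset(ds, band_family)
    labels = ds.labels
    out: dict[int, FAISummary] = {}
    for label in (1, 0):
        mask = labels == label
        if mask.any():
            out[label] = fai_summary(values[mask], class_label=label)
    return out
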