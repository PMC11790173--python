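"""Pattern quantification: binarization, motif counting, DFT spectra.

Motif counting follows the prominence-based local-maxima idea (the "find
maxima" detector of common image software): a motif is a connected set of
maxima whose height above its surrounding saddle exceeds a noise tolerance.
For binary images motifs are simply connected foreground components.

Spectra are centred 2D DFT magnitude tables with the processing conventions
used for periodic colour patterns: log10, normalization by a maximum (the
image's own or a series-wide one) and a hard threshold at 1/20 or 1/100 of
the maximum to keep only the dominant frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from skimage.measure import label
from skimage.morphology import h_maxima

from .engine import FIXED_POINT, MAX_A, MIN_A

__all__ = [
    "BinaryImage",
    "Spectrum",
    "binarize",
    "count_motifs",
    "dft_magnitude_spectrum",
    "postprocess_spectrum",
    "radial_band_set",
]


@dataclass(frozen=True)
class BinaryImage:
    """A {0,1} image plus the threshold that produced it."""

    values: np.ndarray
    threshold: float

    def __post_init__(self):
        vals = np.unique(self.values)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary image must contain only 0 and 1")

    @property
    def foreground_fraction(self) -> float:
        return float(self.values.mean())


SpectrumState = Literal["raw", "log10", "normalized", "thresholded"]


@dataclass(frozen=True)
class Spectrum:
    """Centred 2D DFT magnitude table and its processing state."""

    magnitude: np.ndarray
    state: SpectrumState = "raw"
    normalization: float | None = None
    threshold_fraction: float | None = None


def _default_threshold(image: np.ndarray) -> float:
    """Activator fixed point mapped into the image's units.

    Raw concentration fields are thresholded at the fixed point a = 4;
    integer images at the same relative position of their dtype range,
    unit-scaled floats at 4/4.4.
    """
    rel = (FIXED_POINT[0] - MIN_A) / (MAX_A - MIN_A)
    if np.issubdtype(image.dtype, np.integer):
        return rel * float(np.iinfo(image.dtype).max)
    if image.size and float(image.max()) <= 1.0:
        return rel
    return FIXED_POINT[0]


def binarize(image: np.ndarray, threshold: float | None = None) -> BinaryImage:
    """Threshold a greyscale image: pixel = 1 iff value > threshold."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D greyscale image")
    if threshold is None:
        threshold = _default_threshold(image)
    return BinaryImage((image > threshold).astype(np.uint8), float(threshold))


def count_motifs(image: np.ndarray | BinaryImage, noise_tolerance: float | None = None) -> int:
    """Number of distinct motifs in an image.

    Binary input: 8-connected foreground components.  Greyscale input: local
    maxima with prominence above ``noise_tolerance`` (default 10% of the
    image's value range), maxima merged when connected at the tolerance
    level.  Deterministic; an empty or flat image counts 0.
    """
    if isinstance(image, BinaryImage):
        values = image.values
        return int(label(values, connectivity=2).max())
    values = np.asarray(image, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2D image")
    if values.size == 0:
        return 0
    vrange = float(values.max() - values.min())
    if vrange == 0:
        return 0
    binary_like = np.isin(np.unique(values), (0.0, 1.0)).all()
    if binary_like:
        return int(label(values.astype(np.uint8), connectivity=2).max())
    if noise_tolerance is None:
        noise_tolerance = 0.1 * vrange
    peaks = h_maxima(values, noise_tolerance)
    return int(label(peaks, connectivity=2).max())


def dft_magnitude_spectrum(image: np.ndarray | BinaryImage) -> Spectrum:
    """Centred magnitude of the 2D DFT (modulus of each complex coefficient;
    zero frequency moved to the array centre)."""
    if isinstance(image, BinaryImage):
        image = image.values
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    mag = np.abs(np.fft.fftshift(np.fft.fft2(image)))
    return Spectrum(magnitude=mag, state="raw")


def postprocess_spectrum(
    spec: Spectrum,
    log: bool = True,
    normalize_by: Literal["own_max", "series_max"] = "own_max",
    series_max: float | None = None,
    threshold_fraction: float | None = None,
) -> Spectrum:
    """Apply the display conventions: log10, max-normalization, threshold.

    ``threshold_fraction`` keeps only bins >= fraction * maximum (typically
    1/20 or 1/100); others are zeroed.  With ``normalize_by='series_max'``
    the caller supplies the largest (already log-scaled, if ``log``)
    magnitude of the whole picture series.
    """
    if threshold_fraction is not None and not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if spec.state == "thresholded":
        raise ValueError("spectrum already thresholded")
    mag = spec.magnitude.astype(float)
    h, w = mag.shape
    dc = (h // 2, w // 2)
    if log and spec.state == "raw":
        pos = mag > 0
        if not pos.any():
            raise ValueError("spectrum is identically zero")
        floor = mag[pos].min()
        # zero bins mapped to the smallest positive magnitude before the log
        mag = np.log10(np.where(pos, mag, floor))
        mag -= mag.min()  # shift so magnitudes stay >= 0 on the log scale
    if normalize_by == "series_max":
        if series_max is None or series_max <= 0:
            raise ValueError("series_max must be supplied and positive")
        ref = float(series_max)
    else:
        # the DC bin is the image mean, not a periodicity: the reference
        # maximum is taken over the off-centre bins (DC saturates at 1)
        off_dc = mag.copy()
        off_dc[dc] = -np.inf
        ref = float(off_dc.max())
    if ref > 0:
        mag = np.minimum(mag / ref, 1.0)
    state: SpectrumState = "normalized"
    if threshold_fraction is not None:
        mag = np.where(mag >= threshold_fraction, mag, 0.0)
        state = "thresholded"
    return Spectrum(magnitude=mag, state=state, normalization=ref,
                    threshold_fraction=threshold_fraction)


def log_shift(spec: Spectrum) -> Spectrum:
    """Shifted log10 of a raw spectrum, without normalizing (helper for
    series normalization: take the max of these over the series)."""
    out = postprocess_spectrum(spec, log=True, normalize_by="own_max")
    return replace(out, magnitude=out.magnitude * out.normalization, state="log10")


def radial_band_set(spec: Spectrum, n_bands: int = 10) -> tuple[set[int], float]:
    """Which concentric frequency annuli contain surviving power.

    Partitions the off-DC frequency plane into ``n_bands`` annuli of equal
    radial width and returns the set of annulus indices holding at least one
    non-zero bin, plus a richness score (fraction of occupied annuli).
    Intended for thresholded spectra, where 'surviving' is meaningful.
    """
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    mag = spec.magnitude
    h, w = mag.shape
    cy, cx = h // 2, w // 2
    yy, xx = np.ogrid[:h, :w]
    radius = np.hypot(yy - cy, xx - cx)
    rmax = radius.max()
    bands = np.minimum((radius / rmax * n_bands).astype(int), n_bands - 1)
    occupied = set()
    nonzero = mag > 0
    nonzero[cy, cx] = False  # the DC bin carries no periodicity
    for k in range(n_bands):
        if nonzero[bands == k].any():
            occupied.add(k)
    return occupied, len(occupied) / n_bands


def spectral_energy(spec: Spectrum) -> float:
    """Total raw spectral energy sum(|F|^2); equals N * image energy
    (Parseval) for a raw spectrum."""
    if spec.state != "raw":
        raise ValueError("energy is only meaningful for raw spectra")
    return float((spec.magnitude ** 2).sum())
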