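"""Luminance conversion and spectral (FFT) estimation of image contrast.

The image is treated as a realisation of a wide-sense-stationary 2-D random
process.  Its second-order structure is estimated through the autocovariance
function, computed either through the Fourier route (squared modulus of the
2-D FFT, inverted back to lag space) or by explicit lag-wise summation, which
serves as an independent oracle for the FFT path.  The autocovariance at lag
(0, 0) is the average normalised power of the mean-centred luminance field;
we report it both on the variance scale and on its square-root (RMS) scale.

Conventions
-----------
* Luminance is ``(0.299 R + 0.587 G + 0.114 B) / 255``, in ``[0, 1]``.
* The field is mean-centred before the spectral step, so lag 0 is the
  plug-in variance rather than being dominated by the squared mean.
* ``circular`` mode uses the FFT-native periodic estimate with ``1/N``
  normalisation at every lag (exact Parseval identity); ``linear_unbiased``
  zero-pads and divides each lag by its overlap count.
* Lag (0, 0) sits at index ``[0, 0]``; negative lags wrap to the end of each
  axis, as in the raw FFT layout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .image_io import RGBImage

#: Rec.601-style luma weights applied to stored (gamma-encoded) 8-bit values.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class AcfMode(str, enum.Enum):
    CIRCULAR = "circular"
    LINEAR_UNBIASED = "linear_unbiased"


@dataclass(frozen=True)
class LuminanceField:
    """An ``H x W`` real-valued brightness field with entries in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 2 or vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValidationError(
                f"LuminanceField requires a 2-D H x W array, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise ValidationError("LuminanceField contains non-finite values")
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValidationError(
                f"luminance values must lie in [0, 1], got range "
                f"[{vals.min()}, {vals.max()}]"
            )
        object.__setattr__(self, "values", vals)

    @property
    def mean_luminance(self) -> float:
        return float(self.values.mean())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class AutocorrelationField:
    """Lag-indexed autocovariance estimate; lag (0, 0) at index [0, 0]."""

    values: np.ndarray
    mode: AcfMode
    n_pixels: int

    @property
    def at_origin(self) -> float:
        return float(self.values[0, 0])


@dataclass(frozen=True)
class ContrastResult:
    """Scalar contrast of one image on both reporting scales."""

    variance_contrast: float
    rms_contrast: float
    image_id: str = ""
    config_digest: str = ""

    def __post_init__(self) -> None:
        if self.variance_contrast < 0:
            raise ValidationError("variance_contrast must be non-negative")


def rgb_to_luminance(img: RGBImage, linearize_srgb: bool = False) -> LuminanceField:
    """Convert an RGB image to a luminance field in [0, 1].

    Per pixel ``L = (0.299 R + 0.587 G + 0.114 B) / 255``.  By default the
    weights are applied to the stored (gamma-encoded) channel values; with
    ``linearize_srgb`` the channels are first decoded from sRGB to linear
    light (a sensitivity-analysis option, off by default).
    """
    channels = img.pixels.astype(np.float64) / 255.0
    if linearize_srgb:
        channels = _srgb_to_linear(channels)
    values = channels @ LUMA_WEIGHTS
    return LuminanceField(values=np.clip(values, 0.0, 1.0))


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def mean_center(field: LuminanceField) -> np.ndarray:
    """Subtract the arithmetic mean; the result has mean 0 (to ~1e-12)."""
    return field.values - field.values.mean()


def autocorrelation_fft(
    centered: np.ndarray, mode: AcfMode = AcfMode.CIRCULAR
) -> AutocorrelationField:
    """Autocovariance of a mean-centred field through the Fourier route.

    ``circular``: inverse 2-D FFT of the squared FFT modulus, divided by the
    pixel count, so lag (0, 0) equals the mean of squares (the biased,
    Parseval-exact estimate).  ``linear_unbiased``: the field is zero-padded
    to ``(2H-1) x (2W-1)`` and each lag is divided by its overlap count.
    """
    centered = np.asarray(centered, dtype=np.float64)
    if centered.ndim != 2:
        raise ValidationError("expected a 2-D array")
    if not np.all(np.isfinite(centered)):
        raise ValidationError("non-finite values in input field")
    h, w = centered.shape
    n = h * w
    mode = AcfMode(mode)
    if mode is AcfMode.CIRCULAR:
        spec = np.fft.fft2(centered)
        acf = np.fft.ifft2(np.abs(spec) ** 2).real / n
    else:
        spec = np.fft.fft2(centered, s=(2 * h - 1, 2 * w - 1))
        raw = np.fft.ifft2(np.abs(spec) ** 2).real
        counts = _overlap_counts(h, w)
        acf = raw / counts
    return AutocorrelationField(values=acf, mode=mode, n_pixels=n)


def _overlap_counts(h: int, w: int) -> np.ndarray:
    """Overlap count per lag in the (2h-1, 2w-1) zero-padded FFT layout."""
    da = np.minimum(np.arange(2 * h - 1), np.arange(2 * h - 1, 0, -1))
    db = np.minimum(np.arange(2 * w - 1), np.arange(2 * w - 1, 0, -1))
    ca = h - np.abs(np.where(da < h, da, da - (2 * h - 1)))
    cb = w - np.abs(np.where(db < w, db, db - (2 * w - 1)))
    return np.outer(ca, cb)


def autocorrelation_direct(
    centered: np.ndarray, max_lag: int, mode: AcfMode = AcfMode.CIRCULAR
) -> AutocorrelationField:
    """Brute-force lag-wise autocovariance: the oracle for the FFT path.

    Computes lags ``0..max_lag`` along each axis by explicit double
    summation — circular (wraparound) indexing in ``circular`` mode,
    overlap-normalised truncated sums in ``linear_unbiased`` mode.  Agrees
    with :func:`autocorrelation_fft` on all shared lags to ~1e-10.
    """
    centered = np.asarray(centered, dtype=np.float64)
    if centered.ndim != 2:
        raise ValidationError("expected a 2-D array")
    h, w = centered.shape
    if not 0 <= max_lag < min(h, w):
        raise ValidationError(
            f"max_lag must satisfy 0 <= max_lag < min(H, W)={min(h, w)}, "
            f"got {max_lag}"
        )
    mode = AcfMode(mode)
    out = np.zeros((max_lag + 1, max_lag + 1))
    for da in range(max_lag + 1):
        for db in range(max_lag + 1):
            if mode is AcfMode.CIRCULAR:
                shifted = np.roll(np.roll(centered, -da, axis=0), -db, axis=1)
                out[da, db] = float(np.sum(centered * shifted)) / (h * w)
            else:
                a = centered[: h - da, : w - db]
                b = centered[da:, db:]
                out[da, db] = float(np.sum(a * b)) / ((h - da) * (w - db))
    return AutocorrelationField(values=out, mode=mode, n_pixels=h * w)


def image_contrast(
    field: LuminanceField, image_id: str = "", config_digest: str = ""
) -> ContrastResult:
    """Average image contrast: the autocovariance at lag (0, 0).

    The luminance field is mean-centred, taken through the spectral route,
    and the value at the origin is reported as ``variance_contrast`` together
    with its square root ``rms_contrast``.
    """
    if field.values.size < 2:
        raise ValidationError("contrast is undefined for a single-pixel image")
    if field.values.min() == field.values.max():
        return ContrastResult(  # constant field: zero by definition, exactly
            variance_contrast=0.0,
            rms_contrast=0.0,
            image_id=image_id,
            config_digest=config_digest,
        )
    acf = autocorrelation_fft(mean_center(field), AcfMode.CIRCULAR)
    var = max(acf.at_origin, 0.0)  # clip FFT round-off below zero
    return ContrastResult(
        variance_contrast=var,
        rms_contrast=float(np.sqrt(var)),
        image_id=image_id,
        config_digest=config_digest,
    )


def radial_acf_profile(
    acf: AutocorrelationField, n_bins: int
) -> np.ndarray:
    """Radially averaged autocovariance profile.

    Lags are mapped to signed offsets (shortest wraparound displacement in
    circular mode), binned by Euclidean radius into ``n_bins`` bins, and each
    bin's mean autocovariance is reported.  Bin 0 contains only lag (0, 0),
    so ``profile[0, 1]`` equals the variance contrast exactly.

    Returns an ``(n_bins, 2)`` array of ``(mean radius, mean autocovariance)``
    rows; empty bins carry NaN.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    vals = acf.values
    h, w = vals.shape
    la = np.fft.fftfreq(h, d=1.0 / h)  # signed lags: 0..h/2, -h/2..-1
    lb = np.fft.fftfreq(w, d=1.0 / w)
    radius = np.hypot(*np.meshgrid(la, lb, indexing="ij"))
    rmax = radius.max()
    # bin 0 is exactly radius 0; the rest partition (0, rmax]
    bins = np.zeros(radius.shape, dtype=int)
    positive = radius > 0
    if rmax > 0:
        bins[positive] = 1 + np.minimum(
            ((radius[positive] / rmax) * (n_bins - 1)).astype(int), n_bins - 2
        )
    out = np.full((n_bins, 2), np.nan)
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            out[b, 0] = radius[mask].mean()
            out[b, 1] = vals[mask].mean()
    return out
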