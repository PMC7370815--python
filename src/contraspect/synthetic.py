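"""Synthetic images of known contrast and synthetic two-condition cohorts.

Every generator is deterministic given its spec (the seed lives inside the
spec), emits luminance values in [0, 1], and reports the contrast of what it
generated: analytically for the uniform / checkerboard / grating /
two-tone kinds, empirically (realised pre-quantisation plug-in variance) for
Gaussian random fields.  Grayscale images are replicated across the three
RGB channels so they round-trip losslessly through the 8-bit pipeline.

Quantisation to 8 bits is part of the contract: deterministic rounding for
the piecewise-constant/analytic kinds, seeded uniform dithering for the
stochastic and two-tone kinds so that the realised contrast varies
continuously with the target (no grid-induced ties between cohort images).
The perturbation of the contrast is below 1e-3 in all cases.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .contrast import LuminanceField
from .errors import ValidationError
from .image_io import CatalogRecord, Condition, RGBImage, write_catalog

#: canonical high-condition chronological ranks of the 28-item reference design
REFERENCE_HIGH_RANKS = frozenset({9, 10, 11, 12, 21, 22, 23, 27, 28})

#: Gaussian-field sigma cap keeping the [0,1]-clipping fraction below 1e-3
MAX_GAUSSIAN_SIGMA = 0.15


class ImageKind(str, enum.Enum):
    UNIFORM = "uniform"
    CHECKERBOARD = "checkerboard"
    GRATING = "grating"
    GAUSSIAN_FIELD = "gaussian_field"
    TWO_TONE_PATCHES = "two_tone_patches"


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for one synthetic image.

    ``params`` is kind-specific:

    * uniform: ``level``
    * checkerboard: ``tile``, ``level_lo``, ``level_hi``
    * grating: ``amplitude``, ``frequency`` (integer cycles across width),
      ``level`` (mean, default 0.5)
    * gaussian_field: ``sigma``, ``corr_length``
    * two_tone_patches: ``fraction``, ``level_lo``, ``level_hi``
    """

    kind: ImageKind
    height: int
    width: int
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValidationError("image dimensions must be positive")
        object.__setattr__(self, "kind", ImageKind(self.kind))


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Recipe for a two-condition cohort of synthetic images."""

    n_low: int
    n_high: int
    contrast_low: float
    contrast_high: float
    within_sd: float
    image_spec_template: SyntheticImageSpec
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_low + self.n_high < 2:
            raise ValidationError("cohort needs at least 2 images")
        for t in (self.contrast_low, self.contrast_high):
            if not 0.0 <= t <= 0.5:
                raise ValidationError("target RMS contrast must lie in [0, 0.5]")
        if self.within_sd < 0:
            raise ValidationError("within_sd must be non-negative")


def _require_level(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name}={value} outside [0, 1]")
    return value


def _quantize_round(values: np.ndarray) -> np.ndarray:
    return np.clip(np.round(values * 255.0), 0, 255).astype(np.uint8)


def _quantize_dither(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform-dither quantisation: unbiased per pixel, keeps the realised
    contrast a continuous function of the target."""
    jittered = np.floor(values * 255.0 + rng.random(values.shape))
    return np.clip(jittered, 0, 255).astype(np.uint8)


def _to_rgb(gray: np.ndarray, source_id: str) -> RGBImage:
    return RGBImage(pixels=np.repeat(gray[:, :, None], 3, axis=2), source_id=source_id)


def generate_gaussian_field(
    height: int,
    width: int,
    sigma: float,
    corr_length: float,
    seed: int,
) -> LuminanceField:
    """Stationary Gaussian random field around mean 0.5, clipped to [0, 1].

    White Gaussian noise is filtered in Fourier space with a Gaussian
    transfer function of spatial scale ``corr_length``, normalised so the
    output standard deviation is ``sigma`` in expectation, shifted to mean
    0.5 and clipped.  Under ``sigma <= 0.15`` the clipped fraction is
    negligible (< 1e-3).  Deterministic per seed.
    """
    if sigma < 0:
        raise ValidationError("sigma must be non-negative")
    if sigma > MAX_GAUSSIAN_SIGMA:
        raise ValidationError(
            f"sigma={sigma} exceeds {MAX_GAUSSIAN_SIGMA}; larger values clip "
            "more than 1e-3 of pixels against [0, 1]"
        )
    if corr_length < 0:
        raise ValidationError("corr_length must be non-negative")
    if sigma == 0.0:
        return LuminanceField(values=np.full((height, width), 0.5))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((height, width))
    if corr_length > 0:
        fy = np.fft.fftfreq(height)[:, None]
        fx = np.fft.fftfreq(width)[None, :]
        transfer = np.exp(-2.0 * np.pi**2 * corr_length**2 * (fx**2 + fy**2))
        filtered = np.fft.ifft2(np.fft.fft2(noise) * transfer).real
        # white noise through |G|^2 has output variance mean(G^2)
        filtered /= np.sqrt(np.mean(transfer**2))
    else:
        filtered = noise
    values = 0.5 + sigma * filtered
    return LuminanceField(values=np.clip(values, 0.0, 1.0))


def generate_image(spec: SyntheticImageSpec) -> tuple[RGBImage, float]:
    """Generate one image; return it with its known variance contrast.

    The returned contrast refers to the pre-quantisation field: exact for
    the analytic kinds, the realised plug-in variance for Gaussian fields.
    8-bit quantisation perturbs the measured contrast by < 1e-3.
    """
    h, w = spec.height, spec.width
    p = spec.params
    rng = np.random.default_rng(spec.seed)
    source_id = f"synthetic-{spec.kind.value}-{spec.seed}"

    if spec.kind is ImageKind.UNIFORM:
        level = _require_level("level", p.get("level", 0.5))
        gray = _quantize_round(np.full((h, w), level))
        return _to_rgb(gray, source_id), 0.0

    if spec.kind is ImageKind.CHECKERBOARD:
        tile = int(p.get("tile", 1))
        if tile < 1:
            raise ValidationError("tile must be >= 1")
        lo = _require_level("level_lo", p.get("level_lo", 0.0))
        hi = _require_level("level_hi", p.get("level_hi", 1.0))
        ii, jj = np.meshgrid(np.arange(h) // tile, np.arange(w) // tile, indexing="ij")
        mask = (ii + jj) % 2 == 1
        values = np.where(mask, hi, lo)
        frac = mask.mean()
        known = float(frac * (1 - frac) * (hi - lo) ** 2)
        return _to_rgb(_quantize_round(values), source_id), known

    if spec.kind is ImageKind.GRATING:
        amp = float(p.get("amplitude", 0.25))
        k = int(p.get("frequency", 4))
        level = _require_level("level", p.get("level", 0.5))
        if amp < 0 or level - amp < 0 or level + amp > 1:
            raise ValidationError(
                f"grating level={level} amplitude={amp} leaves [0, 1]"
            )
        if not 1 <= k < w / 2:
            raise ValidationError(f"frequency must satisfy 1 <= k < W/2, got {k}")
        x = np.arange(w)
        row = level + amp * np.sin(2.0 * np.pi * k * x / w)
        values = np.tile(row, (h, 1))
        # discrete sum of sin^2 over whole periods is exactly W/2
        known = float(amp**2 / 2.0)
        return _to_rgb(_quantize_round(values), source_id), known

    if spec.kind is ImageKind.GAUSSIAN_FIELD:
        sigma = float(p.get("sigma", 0.1))
        ell = float(p.get("corr_length", 0.0))
        fld = generate_gaussian_field(h, w, sigma, ell, spec.seed)
        known = float(np.mean((fld.values - fld.values.mean()) ** 2))
        return _to_rgb(_quantize_dither(fld.values, rng), source_id), known

    if spec.kind is ImageKind.TWO_TONE_PATCHES:
        frac = float(p.get("fraction", 0.5))
        lo = _require_level("level_lo", p.get("level_lo", 0.25))
        hi = _require_level("level_hi", p.get("level_hi", 0.75))
        if not 0.0 <= frac <= 1.0:
            raise ValidationError("fraction must lie in [0, 1]")
        n = h * w
        n_hi = int(round(frac * n))
        flat = np.full(n, lo)
        flat[rng.permutation(n)[:n_hi]] = hi
        values = flat.reshape(h, w)
        gray = _quantize_dither(values, rng)
        # known contrast is the exact variance of the emitted 8-bit field,
        # ~f(1-f)(hi-lo)^2 up to the O(1e-6) dither contribution
        lum = gray.astype(np.float64) / 255.0
        known = float(np.mean((lum - lum.mean()) ** 2))
        return _to_rgb(gray, source_id), known

    raise ValidationError(f"unknown image kind {spec.kind}")  # pragma: no cover


def _spec_for_target(
    template: SyntheticImageSpec, target_rms: float, seed: int
) -> SyntheticImageSpec:
    """Specialise the template so its contrast parameter hits ``target_rms``."""
    kind = template.kind
    params = dict(template.params)
    if kind is ImageKind.TWO_TONE_PATCHES:
        params.setdefault("fraction", 0.5)
        f = params["fraction"]
        delta = target_rms / np.sqrt(f * (1 - f)) if target_rms > 0 else 0.0
        if delta > 1.0:
            raise ValidationError(
                f"target rms {target_rms} unreachable at fraction {f}"
            )
        params["level_lo"] = 0.5 - delta / 2
        params["level_hi"] = 0.5 + delta / 2
    elif kind is ImageKind.GRATING:
        amp = target_rms * np.sqrt(2.0)
        if amp > 0.5:
            raise ValidationError(
                f"target rms {target_rms} exceeds the grating maximum 0.3535"
            )
        params["amplitude"] = amp
        params.setdefault("frequency", 4)
        params.setdefault("level", 0.5)
    elif kind is ImageKind.GAUSSIAN_FIELD:
        if target_rms > MAX_GAUSSIAN_SIGMA:
            raise ValidationError(
                f"target rms {target_rms} exceeds the Gaussian-field cap "
                f"{MAX_GAUSSIAN_SIGMA}"
            )
        params["sigma"] = target_rms
    elif kind is ImageKind.CHECKERBOARD:
        params["level_lo"] = 0.5 - target_rms
        params["level_hi"] = 0.5 + target_rms
        if not 0.0 <= target_rms <= 0.5:
            raise ValidationError("checkerboard target rms must lie in [0, 0.5]")
    else:
        raise ValidationError(
            f"kind {kind.value} cannot realise an arbitrary target contrast"
        )
    return replace(template, params=params, seed=seed)


def _draw_targets(spec: SyntheticCohortSpec, rng: np.random.Generator) -> np.ndarray:
    means = np.concatenate(
        [
            np.full(spec.n_low, spec.contrast_low),
            np.full(spec.n_high, spec.contrast_high),
        ]
    )
    targets = means + spec.within_sd * rng.standard_normal(means.size)
    return np.clip(targets, 0.0, 0.5)


def _condition_layout(n_low: int, n_high: int) -> list[Condition]:
    """Condition per chronological rank; the 19/9 design uses the canonical
    high-rank placement, other sizes place the high block at the end."""
    n = n_low + n_high
    if (n_low, n_high) == (19, 9):
        return [
            Condition.HIGH if i in REFERENCE_HIGH_RANKS else Condition.LOW
            for i in range(1, n + 1)
        ]
    return [Condition.LOW] * n_low + [Condition.HIGH] * n_high


def generate_cohort_arrays(
    spec: SyntheticCohortSpec,
) -> tuple[list[CatalogRecord], list[RGBImage], pd.DataFrame]:
    """In-memory cohort: catalog records, images, and the truth table.

    Per-image target RMS contrasts are drawn per condition from
    ``Normal(contrast_*, within_sd)`` truncated to [0, 0.5]; the template
    spec is specialised per image to realise each target.  The truth table
    records the drawn target and the generator's known realised contrast.
    """
    rng = np.random.default_rng(spec.seed)
    targets = _draw_targets(spec, rng)
    conditions = _condition_layout(spec.n_low, spec.n_high)
    # map condition blocks onto the chronological layout
    low_targets = iter(targets[: spec.n_low])
    high_targets = iter(targets[spec.n_low :])

    records, images, truth = [], [], []
    for rank, cond in enumerate(conditions, start=1):
        target = float(next(low_targets if cond is Condition.LOW else high_targets))
        child_seed = int(rng.integers(0, 2**31 - 1))
        img_spec = _spec_for_target(spec.image_spec_template, target, child_seed)
        image, known = generate_image(img_spec)
        image_id = f"synth{rank:03d}"
        records.append(
            CatalogRecord(
                image_id=image_id,
                order_index=rank,
                date_label=f"t{rank:03d}",
                condition=cond,
                path=f"{image_id}.png",
            )
        )
        images.append(image)
        truth.append(
            {
                "image_id": image_id,
                "order_index": rank,
                "condition": cond.value,
                "target_rms_contrast": target,
                "known_variance_contrast": known,
                "known_rms_contrast": float(np.sqrt(known)),
                "seed": child_seed,
            }
        )
    return records, images, pd.DataFrame(truth)


def cohort_rank_test_pvalues(spec: SyntheticCohortSpec) -> tuple[float, float]:
    """Run one synthetic cohort through the full pipeline and its oracle.

    Returns ``(p_pipeline, p_truth)``: the two-sided rank-test p-value from
    the measured image contrasts (generate -> luminance -> spectral contrast
    -> timeline -> test) and from a direct rank test on the drawn truth
    targets.  Since PNG is lossless for 8-bit data the in-memory pipeline is
    identical to the on-disk one.
    """
    from .cohort import assemble_timeline, compare_conditions, mann_whitney_u
    from .contrast import image_contrast, rgb_to_luminance

    records, images, truth = generate_cohort_arrays(spec)
    results = [
        image_contrast(rgb_to_luminance(img), image_id=rec.image_id)
        for rec, img in zip(records, images)
    ]
    table = assemble_timeline(records, results)
    p_pipeline = compare_conditions(table).p_value

    targets = truth.set_index("condition")["target_rms_contrast"]
    p_truth = mann_whitney_u(
        targets.loc[[Condition.LOW.value]].to_numpy(),
        targets.loc[[Condition.HIGH.value]].to_numpy(),
    ).p_value
    return p_pipeline, p_truth


def generate_cohort(
    spec: SyntheticCohortSpec, out_dir
) -> tuple[Path, Path]:
    """Write a cohort to disk: PNG images, ``catalog.csv``, ``truth.csv``.

    Returns the catalog and truth-table paths.  PNG being lossless for
    8-bit data, the on-disk cohort is pixel-identical to
    :func:`generate_cohort_arrays` with the same spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, images, truth = generate_cohort_arrays(spec)
    fixed = []
    for rec, img in zip(records, images):
        img_path = out_dir / rec.path
        iio.imwrite(img_path, img.pixels, extension=".png")
        fixed.append(
            CatalogRecord(
                image_id=rec.image_id,
                order_index=rec.order_index,
                date_label=rec.date_label,
                condition=rec.condition,
                path=str(img_path),
            )
        )
    catalog_path = out_dir / "catalog.csv"
    truth_path = out_dir / "truth.csv"
    write_catalog(fixed, catalog_path)
    truth.to_csv(truth_path, index=False)
    return catalog_path, truth_path
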