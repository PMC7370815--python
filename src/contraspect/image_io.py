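"""Raster-image and cohort-catalog loading.

Images of any supported format (PNG/JPEG/TIFF, 8- or 16-bit, with or without
alpha, grayscale or colour) are normalised into an :class:`RGBImage`: an
``H x W x 3`` uint8 array in fixed R, G, B channel order.  The catalog is a
UTF-8 CSV with header columns ``image_id, order_index, date_label, condition,
path`` describing an ordered two-condition cohort.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import CatalogError, ValidationError

PathLike = Union[str, Path]

CATALOG_COLUMNS = ("image_id", "order_index", "date_label", "condition", "path")


class Condition(str, enum.Enum):
    """Exposure condition of a cohort record."""

    LOW = "low"
    HIGH = "high"

    @classmethod
    def parse(cls, raw: str) -> "Condition":
        try:
            return cls(str(raw).strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown condition {raw!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit three-channel raster.

    Attributes
    ----------
    pixels:
        ``(H, W, 3)`` uint8 array, channels ordered R, G, B.
    source_id:
        Free-text identifier (usually the originating file name).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"RGBImage requires an (H, W, 3) array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("zero-area image")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class CatalogRecord:
    """One row of the cohort catalog."""

    image_id: str
    order_index: int
    date_label: str
    condition: Condition
    path: str

    def __post_init__(self) -> None:
        if int(self.order_index) < 1:
            raise ValidationError(
                f"order_index must be a positive integer, got {self.order_index}"
            )
        object.__setattr__(self, "order_index", int(self.order_index))
        if not isinstance(self.condition, Condition):
            object.__setattr__(self, "condition", Condition.parse(self.condition))


def _normalize_pixels(arr: np.ndarray, path: PathLike) -> np.ndarray:
    """Coerce a decoded array to (H, W, 3) uint8: strip alpha, replicate gray,
    rescale 16-bit sources by integer division."""
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValidationError(f"{path}: unsupported image dimensionality {arr.ndim}")
    if arr.shape[2] == 2:  # gray + alpha
        arr = arr[:, :, :1]
    elif arr.shape[2] == 4:  # RGBA
        arr = arr[:, :, :3]
    if arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    if arr.shape[2] != 3:
        raise ValidationError(f"{path}: cannot normalise {arr.shape[2]} channels")
    if arr.dtype == np.uint16:
        arr = (arr // 256).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    return arr


def load_image(path: PathLike) -> RGBImage:
    """Read a PNG/JPEG/TIFF file into an :class:`RGBImage`.

    16-bit sources are rescaled to 0-255 by integer division (``v // 256``),
    alpha channels are dropped and grayscale data is replicated across the
    three channels.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder-specific error zoo
        raise OSError(f"cannot decode image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"{path}: zero-area image")
    return RGBImage(pixels=_normalize_pixels(arr, path), source_id=path.name)


def load_catalog(path: PathLike) -> list[CatalogRecord]:
    """Read the cohort catalog CSV, returning records sorted by order_index.

    Raises :class:`CatalogError` on a missing/short header, duplicate
    ``order_index`` values, or an unrecognised condition string.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CatalogError(f"{path}: empty catalog file") from None
    missing = [c for c in CATALOG_COLUMNS if c not in frame.columns]
    if missing:
        raise CatalogError(f"{path}: missing catalog columns {missing}")
    if len(frame) == 0:
        raise CatalogError(f"{path}: catalog has no rows")

    records = []
    for i, row in frame.iterrows():
        try:
            order = int(row["order_index"])
        except ValueError:
            raise CatalogError(
                f"{path} row {i}: non-integer order_index {row['order_index']!r}"
            ) from None
        try:
            cond = Condition.parse(row["condition"])
        except ValidationError as exc:
            raise CatalogError(f"{path} row {i}: {exc}") from None
        records.append(
            CatalogRecord(
                image_id=row["image_id"],
                order_index=order,
                date_label=row["date_label"],
                condition=cond,
                path=row["path"],
            )
        )

    orders = [r.order_index for r in records]
    if len(set(orders)) != len(orders):
        dupes = sorted({o for o in orders if orders.count(o) > 1})
        raise CatalogError(f"{path}: duplicate order_index values {dupes}")
    return sorted(records, key=lambda r: r.order_index)


def write_catalog(records: Iterable[CatalogRecord], path: PathLike) -> None:
    """Write catalog records as CSV (inverse of :func:`load_catalog`)."""
    frame = pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "order_index": r.order_index,
                "date_label": r.date_label,
                "condition": r.condition.value,
                "path": r.path,
            }
            for r in records
        ],
        columns=list(CATALOG_COLUMNS),
    )
    frame.to_csv(path, index=False)


def fixture_catalog_path() -> Path:
    """Path of the packaged 28-row two-condition fixture catalog."""
    return Path(resources.files("contraspect").joinpath("data/cohort28.csv"))


def load_fixture_catalog() -> list[CatalogRecord]:
    """Load the packaged 28-row fixture catalog (19 low / 9 high)."""
    return load_catalog(fixture_catalog_path())
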