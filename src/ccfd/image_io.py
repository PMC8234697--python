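"""Reading and writing en face slab images and cohort tables.

All unit and coordinate conventions live here.  An en face slab is a 2-D
grayscale projection of an OCTA volume over a thin depth interval; the
package works on pairs of co-registered slabs (a *flow* slab carrying the
decorrelation signal and a *structure* slab carrying reflectivity) of a
3 x 3 mm macular scan.

Conventions
-----------
* Intensities are normalized to [0, 1] at load time: ``raw / (2**bits - 1)``.
* Coordinates are row-major, origin top-left, 0-based; masks share the
  image grid exactly.
* The default geometry is a 512 x 512 raster over 3 x 3 mm, i.e. a pixel
  pitch of 3000/512 ~= 5.859 um.  This is the unique pitch consistent with
  the standard printed pixel->micron window-radius conversions (see
  :func:`ccfd.fd_quantification.radius_px_to_um`) and is configurable.
* Physical metadata (pitch, modality, eye id) travels in a sidecar record
  rather than TIFF tags, keeping the raster formats dialect-free.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .fd_quantification import FDMetrics

__all__ = [
    "DEFAULT_SCAN_WIDTH_UM",
    "DEFAULT_SIZE_PX",
    "DEFAULT_PITCH_UM",
    "EnFaceImage",
    "EyeRecord",
    "CohortTable",
    "CohortSchemaError",
    "read_enface",
    "write_enface",
    "write_mask",
    "read_mask",
    "read_cohort",
    "write_cohort",
]

DEFAULT_SCAN_WIDTH_UM = 3000.0
DEFAULT_SIZE_PX = 512
#: Default physical pixel pitch (um) for a 3 x 3 mm scan at 512 x 512.
DEFAULT_PITCH_UM = DEFAULT_SCAN_WIDTH_UM / DEFAULT_SIZE_PX

MODALITIES = ("flow", "structure")
GROUPS = ("non_neovascular", "neovascular")

FLAG_COLUMNS = ("small_drusen", "large_drusen", "drusenoid_ped", "rpd", "atrophy")
REQUIRED_COHORT_COLUMNS = (
    "eye_id",
    "group",
    "age_years",
    "bcva_logmar",
    "cmt_um",
    "ct_um",
) + FLAG_COLUMNS
METRIC_COLUMNS = ("fd_percent", "n_fd", "mean_fd_size_um2", "total_fd_area_mm2")


class CohortSchemaError(ValueError):
    """Raised when a cohort CSV violates the expected schema."""


@dataclass
class EnFaceImage:
    """One grayscale en face slab with its physical pixel pitch.

    ``pixels`` is an H x W float array with intensities in [0, 1].
    """

    pixels: np.ndarray
    pixel_pitch_um: float = DEFAULT_PITCH_UM
    modality: str = "flow"
    eye_id: str = ""
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"en face image must be 2-D, got {self.pixels.ndim} dimensions"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError(f"empty image of shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities outside [0, 1]: range [{lo}, {hi}]")
        if self.pixel_pitch_um <= 0:
            raise ValueError(f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.source_bit_depth not in (8, 16):
            raise ValueError(f"source_bit_depth must be 8 or 16, got {self.source_bit_depth}")

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def physical_width_um(self) -> float:
        return self.width_px * self.pixel_pitch_um

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        """Copy of this image with new pixel data, metadata preserved."""
        return replace(self, pixels=pixels)


def _bit_depth_of(arr: np.ndarray, path: Path) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ValueError(
        f"{path}: unsupported dtype {arr.dtype}; expected 8- or 16-bit unsigned raster"
    )


def read_enface(
    path: str | Path,
    *,
    pixel_pitch_um: float = DEFAULT_PITCH_UM,
    modality: str = "flow",
    eye_id: str = "",
) -> EnFaceImage:
    """Read a single-channel 8/16-bit TIFF or PNG as a normalized slab.

    Intensity normalization is ``raw / (2**bits - 1)`` so that the full
    scale of either bit depth maps onto [0, 1].
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            from PIL import Image

            with Image.open(path) as im:
                arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3:
        raise ValueError(
            f"{path}: expected single-channel image, got {arr.shape[-1]} channels"
        )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected 2-D raster, got shape {arr.shape}")
    bits = _bit_depth_of(arr, path)
    pixels = arr.astype(np.float64) / float(2**bits - 1)
    return EnFaceImage(
        pixels=pixels,
        pixel_pitch_um=pixel_pitch_um,
        modality=modality,
        eye_id=eye_id,
        source_bit_depth=bits,
    )


def write_enface(image: EnFaceImage, path: str | Path, *, bit_depth: int | None = None) -> None:
    """Write a slab as a single-channel TIFF/PNG at 8 or 16 bits.

    Quantizes by rounding ``v * (2**bits - 1)``; round-trips 8-bit input
    rasters bit-exactly.
    """
    path = Path(path)
    bits = bit_depth if bit_depth is not None else image.source_bit_depth
    if bits not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bits}")
    full = 2**bits - 1
    raw = np.rint(np.clip(image.pixels, 0.0, 1.0) * full).astype(
        np.uint8 if bits == 8 else np.uint16
    )
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, raw)
    else:
        from PIL import Image

        Image.fromarray(raw).save(path)


def write_mask(mask, path: str | Path) -> None:
    """Write a binary flow-deficit mask as an 8-bit raster.

    Deficit pixels are written as 0 (black) and flow pixels as 255
    (white), so deficits appear as contiguous black areas, the display
    convention used throughout the field.
    """
    path = Path(path)
    arr = np.where(np.asarray(mask.mask, dtype=bool), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
    else:
        from PIL import Image

        Image.fromarray(arr).save(path)


def read_mask(path: str | Path, *, pixel_pitch_um: float = DEFAULT_PITCH_UM, eye_id: str = ""):
    """Read a mask raster written by :func:`write_mask` (0 = deficit)."""
    from .binarization import BinaryFDMask

    img = read_enface(path, pixel_pitch_um=pixel_pitch_um, modality="flow", eye_id=eye_id)
    return BinaryFDMask(mask=img.pixels < 0.5, pixel_pitch_um=pixel_pitch_um, eye_id=eye_id)


@dataclass
class EyeRecord:
    """Per-eye clinical covariates, optionally with computed FD metrics."""

    eye_id: str
    group: str
    age_years: float
    bcva_logmar: float
    cmt_um: float
    ct_um: float
    small_drusen: bool
    large_drusen: bool
    drusenoid_ped: bool
    rpd: bool
    atrophy: bool
    sex: str | None = None
    metrics: "FDMetrics | None" = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.age_years > 0:
            raise ValueError(f"age_years must be > 0, got {self.age_years}")
        if not self.cmt_um > 0:
            raise ValueError(f"cmt_um must be > 0, got {self.cmt_um}")
        if not self.ct_um > 0:
            raise ValueError(f"ct_um must be > 0, got {self.ct_um}")

    @property
    def flags(self) -> dict[str, bool]:
        return {name: bool(getattr(self, name)) for name in FLAG_COLUMNS}


class CohortTable:
    """Ordered collection of :class:`EyeRecord` with unique eye ids."""

    def __init__(self, records: Iterable[EyeRecord]):
        self.records: list[EyeRecord] = list(records)
        ids = [r.eye_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CohortSchemaError(f"duplicate eye_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EyeRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> EyeRecord:
        return self.records[i]

    def group_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in GROUPS}
        for r in self.records:
            counts[r.group] += 1
        return counts

    def subset(self, group: str) -> "CohortTable":
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return CohortTable(r for r in self.records if r.group == group)

    def extend(self, other: "CohortTable") -> "CohortTable":
        return CohortTable(list(self.records) + list(other.records))

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a DataFrame (metrics columns included when present)."""
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "eye_id": r.eye_id,
                "group": r.group,
                "sex": r.sex,
                "age_years": r.age_years,
                "bcva_logmar": r.bcva_logmar,
                "cmt_um": r.cmt_um,
                "ct_um": r.ct_um,
            }
            row.update({k: int(v) for k, v in r.flags.items()})
            if r.metrics is not None:
                row["fd_percent"] = r.metrics.fd_percent
                row["n_fd"] = r.metrics.n_fd
                row["mean_fd_size_um2"] = r.metrics.mean_fd_size_um2
                row["total_fd_area_mm2"] = r.metrics.total_fd_area_mm2
            rows.append(row)
        df = pd.DataFrame(rows)
        if df["sex"].isna().all():
            df = df.drop(columns=["sex"])
        return df


def _parse_flag(value: object, column: str, eye_id: str) -> bool:
    try:
        ivalue = int(str(value).strip())
    except ValueError:
        raise CohortSchemaError(
            f"eye {eye_id!r}: flag column {column!r} must be 0 or 1, got {value!r}"
        ) from None
    if ivalue not in (0, 1):
        raise CohortSchemaError(
            f"eye {eye_id!r}: flag column {column!r} must be 0 or 1, got {value!r}"
        )
    return bool(ivalue)


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV (one eye per row, flags coded 0/1)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing required column(s) {missing}")
    records = []
    from .fd_quantification import FDMetrics

    has_metrics = all(c in df.columns for c in METRIC_COLUMNS)
    for _, row in df.iterrows():
        eye_id = str(row["eye_id"])
        metrics = None
        if has_metrics and not pd.isna(row["fd_percent"]):
            n_fd = int(float(row["n_fd"]))
            metrics = FDMetrics(
                fd_percent=float(row["fd_percent"]),
                n_fd=n_fd,
                mean_fd_size_um2=float(row["mean_fd_size_um2"]),
                total_fd_area_mm2=float(row["total_fd_area_mm2"]),
                component_sizes_px=None,
                eye_id=eye_id,
            )
        records.append(
            EyeRecord(
                eye_id=eye_id,
                group=str(row["group"]),
                age_years=float(row["age_years"]),
                bcva_logmar=float(row["bcva_logmar"]),
                cmt_um=float(row["cmt_um"]),
                ct_um=float(row["ct_um"]),
                sex=(None if "sex" not in df.columns or pd.isna(row["sex"]) else str(row["sex"])),
                metrics=metrics,
                **{c: _parse_flag(row[c], c, eye_id) for c in FLAG_COLUMNS},
            )
        )
    return CohortTable(records)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort table back to CSV (round-trips through read_cohort)."""
    df = cohort.to_frame()
    for c in FLAG_COLUMNS:
        df[c] = df[c].astype(int)
    df.to_csv(path, index=False)
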