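"""Configuration parsing, image reading, results-table and overlay writing.

The pipeline is driven by a flat 14-key configuration. Five keys are
mandatory — ``input_path``, ``trim_factor``, ``pixel_length_um``,
``y_pixels`` and ``x_pixels`` — and the remaining nine tune individual
stages and default sensibly. Configurations may come from a ``key = value``
text file or from any mapping (e.g. CLI flags).
"""

from __future__ import annotations

import dataclasses
import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.morphology import dilation, disk

logger = logging.getLogger("veindensity")

__all__ = [
    "ConfigError",
    "ImageReadError",
    "PipelineConfig",
    "load_config",
    "read_image",
    "write_results_table",
    "read_results_table",
    "write_overlay",
    "RESULT_COLUMNS",
]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class ImageReadError(IOError):
    """An input raster could not be read."""


#: The five keys that must always be supplied.
NECESSARY_KEYS = ("input_path", "trim_factor", "pixel_length_um", "y_pixels", "x_pixels")

#: Defaults for the nine optional keys (14 recognised keys in total).
OPTIONAL_DEFAULTS: dict[str, Any] = {
    "mode": "auto",
    "monocot_branch_length_to_keep": 0.0,
    "blur_w": 20,
    "clahe_clip_limit": 0.01,
    "clahe_tile_grid": (8, 8),
    "threshold_override": None,
    "invert_foreground": True,
    "auto_trim_trigger_fraction": 0.15,
    "output_dir": "output",
}

RECOGNISED_KEYS = NECESSARY_KEYS + tuple(OPTIONAL_DEFAULTS)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    Parameters
    ----------
    input_path : str
        Image file or directory of images to process.
    trim_factor : int
        Spur branches strictly shorter than this many pixels are deleted
        from the skeleton.
    pixel_length_um : float
        Physical side length of one pixel in micrometres (the image scale).
    y_pixels, x_pixels : int
        Expected image height and width; a mismatch with the file flags the
        image but does not abort processing.
    mode : {"auto", "monocot"}
        ``monocot`` additionally removes commissural veins (short transverse
        connections between parallel longitudinal veins).
    monocot_branch_length_to_keep : float
        In monocot mode, branch-point-to-branch-point edges whose terminal
        Euclidean span is strictly below this many pixels are removed;
        0 disables removal.
    blur_w : int
        Mean-filter half-width ``w``; the kernel is ``(2w+1) x (2w+1)``.
    clahe_clip_limit : float
        CLAHE clipping limit (fraction of tile pixel count).
    clahe_tile_grid : (int, int)
        CLAHE tile grid as (rows, cols).
    threshold_override : float or None
        Fixed binarization threshold in [0, 1]; ``None`` selects Otsu.
    invert_foreground : bool
        Complement the binary mask so dark-stained veins become foreground.
    auto_trim_trigger_fraction : float
        Spur-pixel fraction of the skeleton above which the trim factor is
        derived automatically from the modal spur length.
    output_dir : str
        Directory receiving the results table and overlay images.
    """

    input_path: str
    trim_factor: int
    pixel_length_um: float
    y_pixels: int
    x_pixels: int
    mode: str = "auto"
    monocot_branch_length_to_keep: float = 0.0
    blur_w: int = 20
    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    threshold_override: float | None = None
    invert_foreground: bool = True
    auto_trim_trigger_fraction: float = 0.15
    output_dir: str = "output"

    def __post_init__(self) -> None:
        if self.pixel_length_um <= 0:
            raise ConfigError("pixel_length_um must be > 0")
        if self.x_pixels < 16 or self.y_pixels < 16:
            raise ConfigError("x_pixels and y_pixels must be >= 16")
        if self.trim_factor < 0:
            raise ConfigError("trim_factor must be >= 0")
        if self.mode not in ("auto", "monocot"):
            raise ConfigError(f"mode must be 'auto' or 'monocot', got {self.mode!r}")
        if self.monocot_branch_length_to_keep < 0:
            raise ConfigError("monocot_branch_length_to_keep must be >= 0")
        if self.blur_w < 1:
            raise ConfigError("blur_w must be >= 1")
        if self.clahe_clip_limit <= 0:
            raise ConfigError("clahe_clip_limit must be > 0")
        rows, cols = self.clahe_tile_grid
        if rows < 1 or cols < 1:
            raise ConfigError("clahe_tile_grid entries must be >= 1")
        if self.threshold_override is not None and not (0.0 <= self.threshold_override <= 1.0):
            raise ConfigError("threshold_override must lie in [0, 1]")
        if not (0.0 <= self.auto_trim_trigger_fraction <= 1.0):
            raise ConfigError("auto_trim_trigger_fraction must lie in [0, 1]")

    def to_mapping(self) -> dict[str, Any]:
        """Serialize to a flat mapping accepted by :func:`load_config`."""
        d = dataclasses.asdict(self)
        d["clahe_tile_grid"] = f"{self.clahe_tile_grid[0]},{self.clahe_tile_grid[1]}"
        return d


def _coerce(key: str, value: Any) -> Any:
    """Coerce a raw (possibly string) config value to its typed form."""
    if key in ("input_path", "output_dir"):
        return str(value)
    if key in ("trim_factor", "blur_w", "y_pixels", "x_pixels"):
        return int(value)
    if key in ("pixel_length_um", "monocot_branch_length_to_keep",
               "clahe_clip_limit", "auto_trim_trigger_fraction"):
        return float(value)
    if key == "threshold_override":
        if value is None or (isinstance(value, str) and value.strip().lower() in ("", "none")):
            return None
        return float(value)
    if key == "invert_foreground":
        if isinstance(value, bool):
            return value
        s = str(value).strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        raise ConfigError(f"invert_foreground: cannot interpret {value!r} as boolean")
    if key == "mode":
        return str(value).strip().lower()
    if key == "clahe_tile_grid":
        if isinstance(value, (tuple, list)):
            rows, cols = value
        elif isinstance(value, int):
            rows = cols = value
        else:
            parts = str(value).replace("x", ",").split(",")
            if len(parts) == 1:
                rows = cols = int(parts[0])
            else:
                rows, cols = (int(p) for p in parts)
        return (int(rows), int(cols))
    raise ConfigError(f"unrecognised configuration key: {key!r}")


def _parse_config_file(path: Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", ";", "[")):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        mapping[key.strip()] = value.strip().strip('"').strip("'")
    return mapping


def load_config(source: Mapping[str, Any] | str | os.PathLike) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a mapping or file.

    Unknown keys are rejected; missing mandatory keys raise a
    :class:`ConfigError` naming the key.
    """
    if isinstance(source, (str, os.PathLike)):
        source = _parse_config_file(Path(source))
    unknown = set(source) - set(RECOGNISED_KEYS)
    if unknown:
        raise ConfigError(f"unrecognised configuration keys: {sorted(unknown)}")
    for key in NECESSARY_KEYS:
        if key not in source or source[key] is None:
            raise ConfigError(f"{key} required")
    kwargs = {k: _coerce(k, v) for k, v in source.items()}
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# Image reading
# ---------------------------------------------------------------------------

IMAGE_EXTENSIONS = (".tif", ".tiff", ".png", ".jpg", ".jpeg")


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a raster image as float64 in [0, 1].

    8-bit images are scaled by 255. Deeper integer images (e.g. 16-bit
    microscope captures, which rarely fill their nominal range) are
    min-max rescaled to [0, 1]. Float images outside [0, 1] are min-max
    rescaled; float images already inside pass through. RGB(A) rasters
    keep their channel axis (alpha is dropped); greyscale returns 2-D.
    """
    path = Path(path)
    if not path.exists():
        raise ImageReadError(f"no such image: {path}")
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise ConfigError(f"zero-size image: {path}")
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3):
        raise ImageReadError(f"unsupported raster shape {arr.shape} in {path}")

    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        return np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if lo < 0.0 or hi > 1.0:
        return np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    return arr


# ---------------------------------------------------------------------------
# Results table
# ---------------------------------------------------------------------------

#: Fixed column order of the results CSV.
RESULT_COLUMNS = [
    "image_id",
    "vein_density_um_per_mm2",
    "vein_length_um",
    "area_mm2",
    "skeleton_pixel_count",
    "auto_trim_used",
    "effective_trim_factor",
    "flagged",
]


def write_results_table(results: Iterable, path: str | os.PathLike, append: bool = False) -> Path:
    """Write density results to CSV in the fixed column order.

    Without ``append`` an existing file is replaced atomically (write to a
    temporary file, then rename); with ``append`` rows are added below the
    existing ones, keeping a single header.
    """
    rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r) for r in results]
    if not rows:
        raise ValueError("results must be non-empty")
    extra = [c for c in rows[0] if c not in RESULT_COLUMNS]
    df = pd.DataFrame(rows)[RESULT_COLUMNS + extra]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if append and path.exists():
        df.to_csv(path, mode="a", header=False, index=False)
        return path
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".csv.tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results_table`.

    Uses round-trip float parsing so every numeric field is recovered to
    full precision.
    """
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Overlay writing
# ---------------------------------------------------------------------------

def write_overlay(original: np.ndarray, skeleton: np.ndarray,
                  path: str | os.PathLike, dilation_radius: int = 2) -> Path:
    """Render the skeleton, dilated for visibility, in red over the greyscale
    original and write it as an 8-bit image file."""
    original = np.asarray(original, dtype=np.float64)
    skeleton = np.asarray(skeleton).astype(bool)
    if original.shape != skeleton.shape:
        raise ValueError(
            f"dimension mismatch: original {original.shape} vs skeleton {skeleton.shape}")
    grey = np.clip(original, 0.0, 1.0)
    rgb = np.repeat((grey * 255.0).astype(np.uint8)[:, :, None], 3, axis=2)
    if skeleton.any():
        thick = dilation(skeleton, disk(dilation_radius))
        rgb[thick] = (220, 20, 20)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb)
    return path
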