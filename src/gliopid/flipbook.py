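"""Digital flipbook rendering from co-registered volumetric image series.

Serial MRI changes are easier to spot when co-registered timepoints are
viewed in rapid succession (exploiting visual motion perception) than
side by side.  This module renders each timepoint's volume into a fixed
axial mosaic (default 6 columns x 4 rows, one slice every 3 mm from
inferior to superior) and binds the frames into a multipage PDF, an
animated GIF, or a directory of images — one page/frame per timepoint,
with the frame index and label burned into a corner.

Spatial preprocessing (DICOM conversion, rigid registration, skull
stripping, bias-field correction) is deliberately out of scope: it belongs
to dedicated external tools (dcm2niix, FSL flirt/bet2/fast), and this
module only *checks* that the inputs look co-registered by comparing affine
headers, warning on mismatch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
from PIL import Image, ImageDraw

from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger("gliopid")


@dataclass(frozen=True)
class MosaicSpec:
    """Layout of one mosaic frame."""

    columns: int = 6
    rows: int = 4
    slice_spacing: float = 3.0  # mm between displayed slices
    orientation: str = "axial"
    intensity_window: tuple[float, float] = (2.0, 98.0)  # percentiles

    def __post_init__(self):
        if self.columns < 1 or self.rows < 1:
            raise ConfigurationError("columns and rows must be >= 1")
        if self.slice_spacing <= 0:
            raise ConfigurationError("slice_spacing must be > 0")
        if self.orientation != "axial":
            raise ConfigurationError("only axial mosaics are supported")
        lo, hi = self.intensity_window
        if not (0 <= lo < hi <= 100):
            raise ConfigurationError("intensity_window must be percentiles lo < hi")


def _volume_and_spacing(volume) -> tuple[np.ndarray, float]:
    """Accept a nibabel image or (array, z-spacing-mm); return data + z step."""
    if isinstance(volume, tuple):
        data, z_mm = volume
        data = np.asarray(data)
    else:
        img = volume
        data = np.asanyarray(img.dataobj)
        z_mm = float(img.header.get_zooms()[2])
    if data.ndim != 3:
        raise ValidationError(f"expected a 3-D volume, got {data.ndim}-D")
    if z_mm <= 0:
        raise ValidationError("volume lacks a positive slice spacing")
    return data.astype(float), z_mm


def _window(data: np.ndarray, percentiles: tuple[float, float]) -> np.ndarray:
    """Percentile intensity windowing to [0, 1]; degenerate windows widen."""
    lo, hi = np.percentile(data, percentiles)
    if hi <= lo:  # constant or near-constant volume
        lo, hi = float(data.min()), float(data.min()) + 1.0
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0)


def make_mosaic(volume, spec: MosaicSpec = MosaicSpec()) -> np.ndarray:
    """Render one timepoint into a uint8 2-D mosaic frame.

    Takes ``rows * columns`` axial slices at ``slice_spacing`` mm intervals
    from inferior to superior, windows intensities by the percentile pair,
    and tiles the slices row-major; positions beyond the volume extent are
    rendered black.
    """
    data, z_mm = _volume_and_spacing(volume)
    windowed = _window(data, spec.intensity_window)
    step = max(1, int(round(spec.slice_spacing / z_mm)))
    n_tiles = spec.rows * spec.columns
    nz = data.shape[2]
    slice_indices = np.arange(n_tiles) * step  # from inferior (index 0) upward

    h, w = data.shape[0], data.shape[1]
    frame = np.zeros((spec.rows * h, spec.columns * w), dtype=np.uint8)
    for tile, k in enumerate(slice_indices):
        if k >= nz:
            continue  # padded black
        r, c = divmod(tile, spec.columns)
        tile_img = np.round(windowed[:, :, k] * 255).astype(np.uint8)
        frame[r * h : (r + 1) * h, c * w : (c + 1) * w] = tile_img
    return frame


def check_coregistration(images: Sequence[nib.spatialimages.SpatialImage]) -> bool:
    """Warn (and return False) unless all images share shape and affine."""
    ref = images[0]
    ok = True
    for img in images[1:]:
        if img.shape != ref.shape or not np.allclose(img.affine, ref.affine, atol=1e-3):
            warnings.warn(
                "input volumes have mismatched shapes/affines; flipbook frames "
                "assume co-registered inputs (register externally, e.g. FSL flirt)",
                stacklevel=2,
            )
            ok = False
            break
    return ok


def _burn_label(frame: np.ndarray, text: str) -> Image.Image:
    img = Image.fromarray(frame, mode="L")
    draw = ImageDraw.Draw(img)
    draw.rectangle([2, 2, 10 + 7 * len(text), 16], fill=0)
    draw.text((5, 4), text, fill=255)
    return img


def export_flipbook(
    frames: Sequence[np.ndarray],
    out: Union[str, Path],
    format: str = "multipage-pdf",
    labels: Optional[Sequence[str]] = None,
) -> list[Path]:
    """Bind mosaic frames into a flipbook; returns the written paths.

    ``format`` is one of multipage-pdf, animated-gif, image-directory.  One
    page/frame per timepoint in the given (acquisition) order, with
    "<index>: <label>" burned into the top-left corner.
    """
    if len(frames) == 0:
        raise ValidationError("flipbook needs at least one frame")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValidationError("all frames must share the same dimensions")
    if labels is None:
        labels = [f"t{i}" for i in range(len(frames))]
    if len(labels) != len(frames):
        raise ValidationError("labels must match frames one-to-one")

    pages = [
        _burn_label(np.asarray(f, dtype=np.uint8), f"{i}: {lab}")
        for i, (f, lab) in enumerate(zip(frames, labels))
    ]
    out = Path(out)
    if format == "multipage-pdf":
        out.parent.mkdir(parents=True, exist_ok=True)
        pages[0].save(out, format="PDF", save_all=True, append_images=pages[1:])
        written = [out]
    elif format == "animated-gif":
        out.parent.mkdir(parents=True, exist_ok=True)
        pages[0].save(
            out, format="GIF", save_all=True, append_images=pages[1:],
            duration=500, loop=0,
        )
        written = [out]
    elif format == "image-directory":
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for i, page in enumerate(pages):
            p = out / f"frame_{i:03d}.png"
            page.save(p)
            written.append(p)
    else:
        raise ConfigurationError(
            "format must be multipage-pdf, animated-gif, or image-directory"
        )
    logger.info("flipbook: wrote %d frame(s) to %s", len(frames), out)
    return written
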