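"""Frame and sequence I/O for fundus fluorescein angiography (FFA) time series.

An FFA frame is a single-channel fluorescence intensity image with an
approximately circular bright field of view (the ROI) on a dark camera frame.
This module loads frames, detects the ROI, and carries the shared image types
used by every other stage of the pipeline.

Coordinate convention (shared package-wide): pixel coordinates are
``(row, col)``, 0-based, row increasing downward.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "FFAImage",
    "FFASequence",
    "NoFieldOfViewError",
    "FormatError",
    "detect_roi",
    "load_image",
    "load_sequence",
    "save_image",
    "roi_to_rle",
    "rle_to_roi",
]


class NoFieldOfViewError(ValueError):
    """Raised when no illuminated field of view can be found in a frame."""


class FormatError(ValueError):
    """Raised for images that are not single-channel grayscale."""


@dataclass
class FFAImage:
    """One grayscale FFA frame plus its field-of-view mask.

    Parameters
    ----------
    pixels : ndarray of float
        2-D nonnegative intensity grid in arbitrary fluorescence units.
        Integer inputs are converted to float without rescaling.
    roi : ndarray of bool
        Same-shape mask, True inside the illuminated field of view.
    time_min : float
        Acquisition time in minutes since fluorescein injection.
    meta : dict
        Free-form metadata (e.g. source path, original bit depth).
    """

    pixels: np.ndarray
    roi: np.ndarray
    time_min: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.pixels.ndim != 2:
            raise FormatError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.pixels.shape != self.roi.shape:
            raise ValueError(
                f"pixels {self.pixels.shape} and roi {self.roi.shape} differ in shape"
            )
        if not self.roi.any():
            raise ValueError("roi has no interior pixel")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixel values must be finite")
        if (self.pixels < 0).any():
            raise ValueError("pixel values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FFASequence:
    """Time-ordered FFA frames from one eye."""

    frames: list[FFAImage]
    eye_id: str = ""

    def __post_init__(self) -> None:
        times = [f.time_min for f in self.frames]
        if len(set(times)) != len(times):
            raise ValueError(f"duplicate acquisition times: {sorted(times)}")
        self.frames = sorted(self.frames, key=lambda f: f.time_min)
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mismatched shapes: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_min for f in self.frames], dtype=float)


def detect_roi(pixels: np.ndarray, full_frame_fraction: float = 0.98) -> np.ndarray:
    """Detect the circular illuminated field of view of a fundus camera frame.

    The field of view is the dominant bright region on a dark frame, so it is
    found as the largest connected component above an Otsu threshold (clipped
    to at least 1 % of the frame maximum), morphologically closed and
    hole-filled.  A component covering ``full_frame_fraction`` of the frame or
    more means there is no dark frame at all and the whole image is returned.

    Raises
    ------
    NoFieldOfViewError
        If the image is identically zero.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2:
        raise FormatError("detect_roi expects a 2-D grid")
    vmax = pixels.max()
    if vmax <= 0:
        raise NoFieldOfViewError("no field of view detected: image is all zero")
    if pixels.min() == vmax:
        # Constant nonzero frame: nothing dark to separate from.
        return np.ones(pixels.shape, dtype=bool)
    t = max(threshold_otsu(pixels), 0.01 * vmax)
    mask = pixels > t
    if not mask.any():
        raise NoFieldOfViewError("no field of view detected: nothing above threshold")
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    mask = morphology.closing(mask, morphology.disk(5))
    mask = ndi.binary_fill_holes(mask)
    if mask.sum() >= full_frame_fraction * mask.size:
        return np.ones(pixels.shape, dtype=bool)
    return mask


def _read_grayscale(path: Path) -> tuple[np.ndarray, int]:
    """Read a TIFF/PNG frame, collapsing identical RGB channels; returns (array, itemsize_bits)."""
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"could not read image {path}: {exc}") from exc
    bits = arr.dtype.itemsize * 8
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop a fully opaque alpha channel
            if (arr[..., 3] == arr[..., 3].ravel()[0]).all():
                arr = arr[..., :3]
        if arr.ndim == 3 and all(
            np.array_equal(arr[..., 0], arr[..., c]) for c in range(1, arr.shape[2])
        ):
            arr = arr[..., 0]
        else:
            raise FormatError(f"multi-channel image with non-identical channels: {path}")
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D single-channel image, got {arr.shape}: {path}")
    return np.asarray(arr, dtype=float), bits


def load_image(path, time_min: float) -> FFAImage:
    """Load one FFA frame and detect its ROI.

    Values are converted to float without rescaling, so a 16-bit TIFF with a
    maximum of 65535 loads with ``pixels.max() == 65535.0``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"file not found: {path}")
    arr, bits = _read_grayscale(path)
    roi = detect_roi(arr)
    return FFAImage(arr, roi, float(time_min), meta={"path": str(path), "bit_depth": bits})


def load_sequence(manifest, eye_id: str = "") -> FFASequence:
    """Load a sequence from a manifest.

    ``manifest`` is either a CSV path with header columns ``path,time_min``
    (paths resolved relative to the CSV location) or an iterable of
    ``(path, time_min)`` pairs.  At least two frames with distinct times are
    required.
    """
    if isinstance(manifest, (str, Path)):
        mpath = Path(manifest)
        df = pd.read_csv(mpath)
        if not {"path", "time_min"}.issubset(df.columns):
            raise ValueError("manifest CSV must have columns: path,time_min")
        entries = [
            (mpath.parent / p if not Path(p).is_absolute() else Path(p), t)
            for p, t in zip(df["path"], df["time_min"])
        ]
    else:
        entries = [(Path(p), t) for p, t in manifest]
    if len(entries) < 2:
        raise ValueError("a sequence needs at least 2 frames")
    frames = [load_image(p, t) for p, t in entries]
    return FFASequence(frames, eye_id=eye_id)


def roi_to_rle(roi: np.ndarray) -> list[int]:
    """Run-length encode a boolean mask (row-major, starting with a zero run)."""
    flat = np.asarray(roi, dtype=bool).ravel()
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    bounds = np.concatenate(([0], changes + 1, [flat.size]))
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_to_roi(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for r in runs:
        if val:
            flat[pos : pos + r] = True
        pos += r
        val = not val
    return flat.reshape(shape)


def save_image(image: FFAImage, path) -> None:
    """Write a frame as TIFF plus a JSON sidecar carrying time and ROI."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.float32))
    sidecar = {
        "time_min": image.time_min,
        "shape": list(image.shape),
        "roi_rle": roi_to_rle(image.roi),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_saved_image(path) -> FFAImage:
    """Read back a frame written by :func:`save_image`."""
    import tifffile

    path = Path(path)
    arr = np.asarray(tifffile.imread(path), dtype=float)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    roi = rle_to_roi(sidecar["roi_rle"], tuple(sidecar["shape"]))
    return FFAImage(arr, roi, sidecar["time_min"], meta={"path": str(path)})
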