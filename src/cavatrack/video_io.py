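"""Cine-loop input/output and the package-wide coordinate convention.

All geometry in cavatrack uses 0-based ``(row, col)`` coordinates with the
row index increasing with imaging depth.  Sub-pixel positions are
real-valued in the same grid.  Every downstream module consumes a
:class:`VideoSequence`; nothing else re-reads files.

Supported containers: a directory of lexicographically ordered PNG/TIFF
frames, a multi-page TIFF, an AVI/MP4 file (when an FFMPEG-capable imageio
backend is present), and uncompressed multi-frame grayscale DICOM.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, FormatError, InputError

# ITU-R BT.601 luma weights for RGB -> grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])

_FRAME_EXTENSIONS = {".png", ".tif", ".tiff"}


@dataclass
class VideoSequence:
    """An ordered stack of 8-bit grayscale frames with a frame rate.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``, dtype uint8.
    fps
        Frame rate in Hz; must be positive.
    pixel_spacing
        Physical size of a pixel in mm as ``(row, col)``, or None when
        unknown (geometry is then reported in pixels).
    """

    frames: np.ndarray
    fps: float
    pixel_spacing: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"expected a (n_frames, rows, cols) stack, got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise FormatError("a cine loop needs at least 2 frames")
        if self.frames.dtype != np.uint8:
            self.frames = np.clip(np.rint(self.frames), 0, 255).astype(np.uint8)
        if not self.fps > 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of every frame."""
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame_index / fps)."""
        return np.arange(self.n_frames) / self.fps

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]


def _to_gray_u8(arr: np.ndarray) -> np.ndarray:
    """Convert one frame (or a stack) to 8-bit grayscale via luma weights."""
    arr = np.asarray(arr)
    if arr.ndim >= 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].astype(np.float64) @ _LUMA
    if arr.dtype != np.uint8:
        arr = np.asarray(arr, dtype=np.float64)
        if arr.size and arr.max() > 255:  # e.g. 16-bit DICOM — rescale
            lo, hi = float(arr.min()), float(arr.max())
            arr = (arr - lo) / (hi - lo) * 255.0 if hi > lo else np.zeros_like(arr)
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return arr


def _load_frame_directory(path: Path) -> list[np.ndarray]:
    import imageio.v3 as iio

    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
    )
    if not files:
        raise FormatError(f"no PNG/TIFF frames found in directory {path}")
    return [_to_gray_u8(iio.imread(f)) for f in files]


def _load_dicom(path: Path) -> tuple[list[np.ndarray], Optional[float], Optional[tuple[float, float]]]:
    import pydicom

    ds = pydicom.dcmread(str(path))
    syntax = getattr(getattr(ds, "file_meta", None), "TransferSyntaxUID", None)
    if syntax is not None and getattr(syntax, "is_compressed", False):
        raise FormatError(
            "only uncompressed multi-frame grayscale DICOM is supported; "
            f"got transfer syntax {syntax}"
        )
    arr = ds.pixel_array
    if arr.ndim == 2:
        raise FormatError("DICOM file holds a single frame, not a cine loop")
    frames = [_to_gray_u8(fr) for fr in arr]
    fps = None
    if getattr(ds, "CineRate", None):
        fps = float(ds.CineRate)
    elif getattr(ds, "FrameTime", None):  # ms per frame
        fps = 1000.0 / float(ds.FrameTime)
    spacing = None
    if getattr(ds, "PixelSpacing", None):
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return frames, fps, spacing


def load_video(path: str | Path, fps_override: Optional[float] = None) -> VideoSequence:
    """Read a cine loop from disk.

    ``fps_override`` wins over any frame rate found in container metadata.
    Raises :class:`InputError` for a missing path, :class:`ConfigError`
    when no frame rate is available from any source, and
    :class:`FormatError` for unreadable or inconsistent content.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file or directory: {path}")

    fps_meta: Optional[float] = None
    spacing: Optional[tuple[float, float]] = None

    if path.is_dir():
        frames = _load_frame_directory(path)
    elif path.suffix.lower() == ".dcm" or _looks_like_dicom(path):
        frames, fps_meta, spacing = _load_dicom(path)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(str(path))
        if arr.ndim == 2:
            raise FormatError(f"{path} holds a single frame, not a cine loop")
        frames = [_to_gray_u8(fr) for fr in arr]
    elif path.suffix.lower() in {".avi", ".mp4", ".mov"}:
        frames, fps_meta = _load_movie(path)
    else:
        raise FormatError(f"unrecognized cine container: {path}")

    shapes = {fr.shape for fr in frames}
    if len(shapes) != 1:
        raise FormatError(f"frames of mixed size: {sorted(shapes)}")

    fps = fps_override if fps_override is not None else fps_meta
    if fps is None:
        raise ConfigError(
            "no frame rate in container metadata; pass fps_override (or --fps)"
        )
    return VideoSequence(np.stack(frames), float(fps), spacing)


def _looks_like_dicom(path: Path) -> bool:
    if not path.is_file() or path.stat().st_size < 132:
        return False
    with open(path, "rb") as fh:
        fh.seek(128)
        return fh.read(4) == b"DICM"


def _load_movie(path: Path) -> tuple[list[np.ndarray], Optional[float]]:
    import imageio.v3 as iio

    try:
        arr = iio.imread(str(path))
        meta = iio.immeta(str(path))
    except Exception as exc:  # no codec backend available, or corrupt file
        raise FormatError(f"cannot decode movie {path}: {exc}") from exc
    fps = meta.get("fps")
    return [_to_gray_u8(fr) for fr in arr], float(fps) if fps else None


def save_video(video: VideoSequence, path: str | Path) -> None:
    """Write a cine loop losslessly.

    A ``.tif``/``.tiff`` target becomes a multi-page TIFF; a directory
    target becomes numbered PNG frames.  Both round-trip pixel values
    exactly through :func:`load_video`.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(str(path), video.frames, photometric="minisblack")
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(video.n_frames)))
        for i, frame in enumerate(video.frames):
            iio.imwrite(path / f"frame_{i:0{width}d}.png", frame)


def save_measurements(
    per_frame: dict[str, Sequence[float]],
    report: dict,
    csv_path: str | Path,
    json_path: str | Path,
    fps: float,
) -> None:
    """Write per-frame measurements as CSV and scalar indices as JSON.

    ``per_frame`` maps column names to per-frame sequences of equal length;
    the CSV gains mandatory ``frame`` and ``time_s`` columns with
    ``time_s = frame_index / fps``.  ``report`` is serialized verbatim
    (numpy scalars/arrays are converted to plain Python types).
    """
    lengths = {len(v) for v in per_frame.values()}
    if len(lengths) > 1:
        raise InputError(f"per-frame columns of unequal length: {lengths}")
    n = lengths.pop() if lengths else 0

    csv_path, json_path = Path(csv_path), Path(json_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    json_path.parent.mkdir(parents=True, exist_ok=True)

    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "time_s", *per_frame.keys()])
        for i in range(n):
            writer.writerow(
                [i, repr(i / fps), *(repr(float(per_frame[k][i])) for k in per_frame)]
            )

    with open(json_path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
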