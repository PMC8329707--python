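"""Loading, temporal subsampling and preprocessing of behavior recordings.

Raw open-field recordings (30 frames/s) are reduced to analysis clips by
keeping every ``subsample_step``-th frame (default 10, i.e. 3 frames/s)
and windowing to ``n_frames`` frames (default 150, i.e. 50 s) starting
at a per-trial offset that skips the experimenter's hand releasing the
animal.  Frames are optionally center-cropped to the arena bounding box
and resized to the analysis resolution (default 400 x 350).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import downscale_local_mean, resize

__all__ = ["ClipSpec", "FrameSequence", "ClipLengthError", "load_clip", "preprocess"]


class ClipLengthError(ValueError):
    """Recording is too short to satisfy the requested clip window."""


@dataclass(frozen=True)
class ClipSpec:
    """How a raw recording is turned into a fixed-length analysis clip.

    ``start_offset_frames`` is indexed in the *subsampled* stream: the
    clip is ``subsampled[start : start + n_frames]``.
    """

    subsample_step: int = 10
    n_frames: int = 150
    start_offset_frames: int = 0
    target_size: tuple[int, int] = (400, 350)  # (width, height)

    def __post_init__(self) -> None:
        if self.subsample_step < 1:
            raise ValueError("subsample_step must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.start_offset_frames < 0:
            raise ValueError("start_offset_frames must be >= 0")
        if min(self.target_size) < 16:
            raise ValueError("target dimensions must be >= 16 px")

    def raw_indices(self) -> np.ndarray:
        """Raw-stream indices of the clip frames."""
        start = self.start_offset_frames
        return (start + np.arange(self.n_frames)) * self.subsample_step


@dataclass
class FrameSequence:
    """A fixed-length analysis clip: frames plus its effective frame rate."""

    frames: np.ndarray  # (n_frames, H, W) or (n_frames, H, W, C)
    fps_effective: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, H, W) or (T, H, W, C)")
        if self.fps_effective <= 0:
            raise ValueError("fps_effective must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_seconds(self) -> float:
        return self.n_frames / self.fps_effective


_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(p: Path) -> tuple:
    # "frame_2.png" sorts before "frame_10.png"
    return tuple(int(s) if s.isdigit() else s for s in _NUM_RE.split(p.stem))


def _list_frame_files(directory: Path) -> list[Path]:
    exts = {".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp"}
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in exts),
        key=_numeric_key,
    )
    if not files:
        raise OSError(f"no image frames found in directory {directory}")
    return files


def load_clip(source_path, clip_spec: ClipSpec, fps_raw: float = 30.0) -> FrameSequence:
    """Read a recording and window it into a fixed-length analysis clip.

    ``source_path`` is either a directory of numbered image frames or a
    video file (the latter requires an imageio video plugin).  Exactly
    ``clip_spec.n_frames`` frames are returned, taken every
    ``subsample_step``-th raw frame after the subsampled-stream offset.
    """
    import imageio.v3 as iio

    source = Path(source_path)
    indices = clip_spec.raw_indices()
    required = int(indices[-1]) + 1

    if source.is_dir():
        files = _list_frame_files(source)
        if len(files) < required:
            raise ClipLengthError(
                f"{source}: clip needs {required} raw frames "
                f"(offset {clip_spec.start_offset_frames}, step "
                f"{clip_spec.subsample_step}, {clip_spec.n_frames} frames) "
                f"but only {len(files)} are available"
            )
        frames = np.stack([iio.imread(files[i]) for i in indices])
    else:
        if not source.exists():
            raise OSError(f"recording {source} does not exist")
        try:
            all_frames = iio.imread(source, index=None)
        except Exception as exc:  # no suitable plugin for the container
            raise OSError(
                f"cannot read video container {source}: {exc}. "
                "Install an imageio video plugin or convert the recording "
                "to a directory of numbered PNG frames."
            ) from exc
        if all_frames.shape[0] < required:
            raise ClipLengthError(
                f"{source}: clip needs {required} raw frames but only "
                f"{all_frames.shape[0]} are available"
            )
        frames = all_frames[indices]

    return FrameSequence(
        frames=frames,
        fps_effective=fps_raw / clip_spec.subsample_step,
        provenance={"source": str(source), "clip_spec": clip_spec, "fps_raw": fps_raw},
    )


def _to_luminance(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 3:
        return frames
    if frames.shape[-1] == 1:
        return frames[..., 0]
    # ITU-R 601 luma weights on the first three channels
    w = np.array([0.299, 0.587, 0.114], dtype=np.float64)
    lum = frames[..., :3].astype(np.float64) @ w
    if np.issubdtype(frames.dtype, np.integer):
        lum = np.clip(np.rint(lum), 0, np.iinfo(frames.dtype).max).astype(frames.dtype)
    return lum


def preprocess(
    frames,
    target_size: tuple[int, int] | None = (400, 350),
    normalization: str | None = None,
    crop_box: tuple[int, int, int, int] | None = None,
    interpolation: str = "bilinear",
    fps_effective: float | None = None,
) -> FrameSequence:
    """Crop, resize and normalize a stack of frames.

    ``crop_box`` is ``(x0, y0, width, height)`` — the arena bounding box
    cut out before resizing (cropping preserves the arena's aspect ratio
    instead of distorting it).  ``interpolation`` is ``"bilinear"`` or
    ``"area"`` (block averaging; requires an integer downscale factor).
    ``normalization`` is ``None`` (keep pixel range) or ``"unit"``
    (float32 in [0, 1]).  With no cropping, no resizing and no
    normalization the input passes through bit-identically.
    """
    if isinstance(frames, FrameSequence):
        if fps_effective is None:
            fps_effective = frames.fps_effective
        frames = frames.frames
    arr = np.asarray(frames)
    if arr.ndim not in (3, 4) or arr.shape[0] == 0:
        raise ValueError("expected a non-empty (T, H, W[, C]) frame stack")
    if fps_effective is None:
        fps_effective = 1.0

    orig_int_max = (
        float(np.iinfo(arr.dtype).max) if np.issubdtype(arr.dtype, np.integer) else None
    )
    arr = _to_luminance(arr)

    if crop_box is not None:
        x0, y0, w, h = crop_box
        if w <= 0 or h <= 0 or y0 + h > arr.shape[1] or x0 + w > arr.shape[2]:
            raise ValueError(f"crop_box {crop_box} exceeds frame size {arr.shape[1:3]}")
        arr = arr[:, y0 : y0 + h, x0 : x0 + w]

    if target_size is not None and (arr.shape[2], arr.shape[1]) != tuple(target_size):
        tw, th = target_size
        if interpolation == "area":
            fy, fx = arr.shape[1] / th, arr.shape[2] / tw
            if fy != int(fy) or fx != int(fx):
                raise ValueError(
                    "area interpolation requires integer downscale factors; "
                    f"got {arr.shape[1:3]} -> {(th, tw)}"
                )
            out = downscale_local_mean(
                arr.astype(np.float64), (1, int(fy), int(fx))
            )
        elif interpolation == "bilinear":
            out = resize(
                arr.astype(np.float64),
                (arr.shape[0], th, tw),
                order=1,
                anti_aliasing=False,
                preserve_range=True,
            )
        else:
            raise ValueError(f"unknown interpolation {interpolation!r}")
        if np.issubdtype(arr.dtype, np.integer) and normalization is None:
            arr = np.clip(np.rint(out), 0, np.iinfo(arr.dtype).max).astype(arr.dtype)
        else:
            arr = out

    if normalization == "unit":
        arr = arr.astype(np.float32)
        if orig_int_max is not None:
            arr = arr / orig_int_max
    elif normalization is not None:
        raise ValueError(f"unknown normalization {normalization!r}")

    return FrameSequence(frames=arr, fps_effective=fps_effective)
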