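"""Per-frame feature extraction.

Each frame of a clip is reduced to a fixed-length feature vector and the
clip becomes a features x frames matrix — the input of the sequence
classifier.  Two backends share this contract:

* ``patch`` (default, deterministic, no weights): the frame is tiled
  into a grid of patches and each patch contributes its mean intensity
  and its mean gradient magnitude.
* ``pretrained``: the 2,048-feature global-average-pool layer of a
  pretrained image-classification convolutional network.  It requires a
  deep-learning framework plus downloaded weights and is therefore only
  a declared backend here; calling it without those raises an actionable
  error.

Swapping backends changes only ``n_features``, never the downstream
data contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .video_io import FrameSequence

__all__ = [
    "FeatureBackendSpec",
    "FeatureMatrix",
    "PatchFeatureBackend",
    "PretrainedBackend",
    "get_backend",
    "extract_features",
    "save_features",
    "load_features",
]


@dataclass(frozen=True)
class FeatureBackendSpec:
    name: str
    n_features: int
    deterministic: bool
    requires_pretrained_weights: bool

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")


@dataclass
class FeatureMatrix:
    """Features x frames array for one trial."""

    values: np.ndarray  # (n_features, n_frames)
    backend: FeatureBackendSpec
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_features, n_frames)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if self.values.shape[0] != self.backend.n_features:
            raise ValueError(
                f"row count {self.values.shape[0]} does not match backend "
                f"n_features {self.backend.n_features}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


class PatchFeatureBackend:
    """Deterministic grid-patch features: mean intensity + mean |gradient|.

    The frame is divided into ``grid_shape`` (rows x cols) patches,
    edge-padding the bottom/right so the grid divides the frame.  Frames
    are scaled to [0, 1] before feature computation, so an all-black
    frame yields an all-zero column.  Feature order: the ``rows*cols``
    patch mean intensities (row-major), then the patch mean gradient
    magnitudes.
    """

    def __init__(self, grid_shape: tuple[int, int] = (10, 10)):
        self.grid_shape = tuple(grid_shape)
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape entries must be >= 1")

    @property
    def spec(self) -> FeatureBackendSpec:
        r, c = self.grid_shape
        return FeatureBackendSpec(
            name=f"patch{r}x{c}",
            n_features=2 * r * c,
            deterministic=True,
            requires_pretrained_weights=False,
        )

    def _patch_reduce(self, img: np.ndarray) -> np.ndarray:
        gr, gc = self.grid_shape
        H, W = img.shape
        ph, pw = -(-H // gr), -(-W // gc)  # ceil
        pad_h, pad_w = ph * gr - H, pw * gc - W
        if pad_h or pad_w:
            img = np.pad(img, ((0, pad_h), (0, pad_w)), mode="edge")
        return img.reshape(gr, ph, gc, pw).mean(axis=(1, 3)).ravel()

    def frame_features(self, frame: np.ndarray) -> np.ndarray:
        img = np.asarray(frame, dtype=np.float64)
        if img.ndim == 3:
            img = img.mean(axis=-1)
        if np.issubdtype(np.asarray(frame).dtype, np.integer):
            img = img / float(np.iinfo(np.asarray(frame).dtype).max)
        gy, gx = np.gradient(img)
        grad_mag = np.hypot(gy, gx)
        return np.concatenate([self._patch_reduce(img), self._patch_reduce(grad_mag)])

    def extract(self, frames: np.ndarray) -> np.ndarray:
        cols = [self.frame_features(f) for f in frames]
        return np.stack(cols, axis=1)

    def patch_mask(self, feature_index: int, frame_shape: tuple[int, int]) -> np.ndarray:
        """Boolean pixel mask of the patch a feature index belongs to."""
        gr, gc = self.grid_shape
        idx = feature_index % (gr * gc)
        r, c = divmod(idx, gc)
        H, W = frame_shape
        ph, pw = -(-H // gr), -(-W // gc)
        mask = np.zeros((H, W), dtype=bool)
        mask[r * ph : min((r + 1) * ph, H), c * pw : min((c + 1) * pw, W)] = True
        return mask


class PretrainedBackend:
    """Declared 2,048-feature pretrained convolutional backend.

    The backend contract (feature count, determinism) is declared so
    pipelines can be configured against it, but extraction needs a
    deep-learning framework and downloaded weights.
    """

    @property
    def spec(self) -> FeatureBackendSpec:
        return FeatureBackendSpec(
            name="pretrained",
            n_features=2048,
            deterministic=True,
            requires_pretrained_weights=True,
        )

    def extract(self, frames: np.ndarray) -> np.ndarray:
        raise RuntimeError(
            "the pretrained convolutional backend requires a deep-learning "
            "framework and its downloaded weights, neither of which is "
            "available. Either fetch the weights in an environment with such "
            "a framework installed, or use the deterministic 'patch' backend."
        )


def get_backend(name: str, **kwargs):
    if name == "patch":
        return PatchFeatureBackend(**kwargs)
    if name == "pretrained":
        return PretrainedBackend(**kwargs)
    raise ValueError(f"unknown feature backend {name!r} (expected 'patch' or 'pretrained')")


def extract_features(clip, backend=None, trial_id: str = "") -> FeatureMatrix:
    """Convert a clip into its features x frames matrix.

    Column ``t`` depends only on frame ``t`` (no cross-frame leakage),
    so permuting frames permutes columns identically.
    """
    if backend is None:
        backend = PatchFeatureBackend()
    if isinstance(backend, str):
        backend = get_backend(backend)
    frames = clip.frames if isinstance(clip, FrameSequence) else np.asarray(clip)
    values = backend.extract(frames)
    return FeatureMatrix(values=values, backend=backend.spec, trial_id=trial_id)


def save_features(path, matrices: dict[str, FeatureMatrix]) -> None:
    """Store per-trial feature matrices in an HDF5 file (one dataset each)."""
    import h5py

    with h5py.File(path, "w") as f:
        for trial_id, fm in matrices.items():
            ds = f.create_dataset(trial_id, data=fm.values)
            ds.attrs["backend"] = fm.backend.name
            ds.attrs["n_features"] = fm.backend.n_features
            ds.attrs["deterministic"] = fm.backend.deterministic
            ds.attrs["requires_pretrained_weights"] = fm.backend.requires_pretrained_weights


def load_features(path) -> dict[str, FeatureMatrix]:
    import h5py

    out: dict[str, FeatureMatrix] = {}
    with h5py.File(path, "r") as f:
        for trial_id in f:
            ds = f[trial_id]
            spec = FeatureBackendSpec(
                name=str(ds.attrs["backend"]),
                n_features=int(ds.attrs["n_features"]),
                deterministic=bool(ds.attrs["deterministic"]),
                requires_pretrained_weights=bool(ds.attrs["requires_pretrained_weights"]),
            )
            out[trial_id] = FeatureMatrix(values=ds[()], backend=spec, trial_id=trial_id)
    return out
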