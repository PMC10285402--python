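"""Reading, writing and cropping of EM volumes and instance-label volumes.

Axis order is fixed to (z, y, x) everywhere in the package; z is the
serial-section axis.  On disk, volumes live either in HDF5 files with a
single named 3D dataset (default name ``"main"``, the de-facto
connectomics convention) or in multipage TIFF stacks with one page per
section.  Coordinates are 0-based and ranges half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import tifffile

DEFAULT_DATASET = "main"

_H5_SUFFIXES = {".h5", ".hdf5", ".hdf"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class Volume:
    """A 3D grayscale image, values in [0, 1], axes (z, y, x)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] | None = None  # (z_nm, y_nm, x_nm)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3 dimensions (z, y, x), got {self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"volume values outside [0, 1]: min={lo}, max={hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """A 3D non-negative integer instance map; 0 is background."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(
                f"expected 3 dimensions (z, y, x), got {data.ndim}"
            )
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"labels must be integers, got dtype {data.dtype}")
        if data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = data.astype(np.int64, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def ids(self) -> np.ndarray:
        """Instance ids present, background excluded."""
        u = np.unique(self.data)
        return u[u > 0]


def _read_array(path: Path, dataset_key: str) -> np.ndarray:
    if path.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(path, "r") as f:
            if dataset_key not in f:
                raise KeyError(
                    f"dataset {dataset_key!r} not found in {path} "
                    f"(available: {sorted(f.keys())})"
                )
            return f[dataset_key][()]
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return tifffile.imread(path)
    raise ValueError(f"unsupported container suffix {path.suffix!r} for {path}")


def read_volume(
    path: str | Path,
    dataset_key: str = DEFAULT_DATASET,
    labels: bool = False,
) -> Volume | LabelVolume:
    """Read a 3D volume from an HDF5 file or a multipage TIFF stack.

    Grayscale integer input is rescaled by its dtype maximum to [0, 1] for
    image volumes and left as integers when ``labels=True``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    arr = _read_array(path, dataset_key)
    if arr.ndim != 3:
        raise ValueError(
            f"expected 3 dimensions (z, y, x) in {path}, got {arr.ndim}"
        )
    if labels:
        return LabelVolume(arr)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = arr.astype(np.float32) / float(info.max)
    return Volume(arr)


def write_volume(
    vol: Volume | LabelVolume,
    path: str | Path,
    dataset_key: str = DEFAULT_DATASET,
) -> Path:
    """Write a volume; container chosen by suffix (.h5/.hdf5 or .tif/.tiff).

    Image volumes are stored as float32, labels as uint32 (uint64 when the
    id range requires it).  HDF5 datasets are written without timestamps so
    regeneration with the same data is byte-identical.
    """
    path = Path(path)
    if isinstance(vol, LabelVolume):
        maxid = int(vol.data.max()) if vol.data.size else 0
        dtype = np.uint64 if maxid > np.iinfo(np.uint32).max else np.uint32
        data = vol.data.astype(dtype)
    else:
        data = vol.data.astype(np.float32)
    if path.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(path, "w", libver="earliest") as f:
            f.create_dataset(dataset_key, data=data, track_times=False)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        raise ValueError(f"unsupported container suffix {path.suffix!r} for {path}")
    return path


def sample_subvolume(
    vol: Volume,
    labels: LabelVolume | None,
    size: tuple[int, int, int] = (6, 96, 96),
    rng: np.random.Generator | None = None,
) -> tuple[Volume, LabelVolume | None]:
    """Randomly crop a training sub-volume (and the paired label crop).

    The crop corner is uniform over all valid positions; paired crops share
    the same corner, and repeated calls with the same generator state yield
    identical crops.
    """
    rng = np.random.default_rng() if rng is None else rng
    shape = vol.shape
    bad = [
        f"axis {'zyx'[a]}: size {size[a]} > volume {shape[a]}"
        for a in range(3)
        if size[a] > shape[a]
    ]
    if bad:
        raise ValueError("subvolume does not fit: " + "; ".join(bad))
    if labels is not None and labels.shape != shape:
        raise ValueError(
            f"label shape {labels.shape} does not match volume shape {shape}"
        )
    corner = tuple(int(rng.integers(0, shape[a] - size[a] + 1)) for a in range(3))
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    crop = Volume(vol.data[sl].copy(), voxel_size=vol.voxel_size)
    lcrop = LabelVolume(labels.data[sl].copy()) if labels is not None else None
    return crop, lcrop
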