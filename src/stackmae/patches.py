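"""Anisotropic patch tokenization and 3D sin-cos positional embeddings.

Volumes are divided into a regular grid of non-overlapping blocks; the
default block is (1, 16, 16) voxels — full z-resolution, 16x16 in-plane —
so a 6x96x96 input yields a 6x6x6 token grid, 216 tokens.  Token order is
the raster flattening of the grid, z-major, then y, then x; mask plans
index into exactly this order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import Volume

DEFAULT_PATCH = (1, 16, 16)


@dataclass(frozen=True)
class PatchGrid:
    """Geometry of a patch tokenization: block size and token-grid shape."""

    patch_size: tuple[int, int, int]
    grid_shape: tuple[int, int, int]

    @property
    def n_tokens(self) -> int:
        gz, gy, gx = self.grid_shape
        return gz * gy * gx

    @property
    def patch_dim(self) -> int:
        pz, py, px = self.patch_size
        return pz * py * px

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return tuple(g * p for g, p in zip(self.grid_shape, self.patch_size))  # type: ignore[return-value]


def grid_for(shape: tuple[int, int, int], patch_size: tuple[int, int, int]) -> PatchGrid:
    for ax, name in enumerate("zyx"):
        if shape[ax] % patch_size[ax] != 0:
            raise ValueError(
                f"axis {name}: volume extent {shape[ax]} not divisible by "
                f"patch extent {patch_size[ax]}"
            )
    grid = tuple(s // p for s, p in zip(shape, patch_size))
    return PatchGrid(tuple(patch_size), grid)  # type: ignore[arg-type]


def patchify(
    vol: Volume | np.ndarray, patch_size: tuple[int, int, int] = DEFAULT_PATCH
) -> tuple[np.ndarray, PatchGrid]:
    """Cut a volume (or batch of volumes) into flattened patch rows.

    Returns ``(patches, grid)`` where ``patches`` has shape
    ``(..., n_tokens, patch_dim)``; row ``i`` holds the raster-flattened
    voxels of grid cell ``i``.
    """
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if data.ndim < 3:
        raise ValueError("need at least 3 dimensions (z, y, x)")
    shape = data.shape[-3:]
    grid = grid_for(shape, patch_size)  # type: ignore[arg-type]
    (gz, gy, gx), (pz, py, px) = grid.grid_shape, grid.patch_size
    lead = data.shape[:-3]
    nl = len(lead)
    x = data.reshape(*lead, gz, pz, gy, py, gx, px)
    # (gz, pz, gy, py, gx, px) -> (gz, gy, gx, pz, py, px)
    x = x.transpose(*range(nl), *(nl + i for i in (0, 2, 4, 1, 3, 5)))
    patches = x.reshape(*lead, grid.n_tokens, grid.patch_dim)
    return np.ascontiguousarray(patches), grid


def unpatchify(patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Exact inverse of :func:`patchify` (returns the raw array)."""
    patches = np.asarray(patches)
    if patches.shape[-2:] != (grid.n_tokens, grid.patch_dim):
        raise ValueError(
            f"patch matrix shape {patches.shape[-2:]} does not match grid "
            f"({grid.n_tokens} tokens x {grid.patch_dim} values)"
        )
    (gz, gy, gx), (pz, py, px) = grid.grid_shape, grid.patch_size
    lead = patches.shape[:-2]
    nl = len(lead)
    x = patches.reshape(*lead, gz, gy, gx, pz, py, px)
    # (gz, gy, gx, pz, py, px) -> (gz, pz, gy, py, gx, px)
    x = x.transpose(*range(nl), *(nl + i for i in (0, 3, 1, 4, 2, 5)))
    return np.ascontiguousarray(x.reshape(*lead, gz * pz, gy * py, gx * px))


def _axis_dims(embed_dim: int) -> tuple[int, int, int]:
    # three near-equal even blocks (sin+cos halves per axis) summing to embed_dim
    if embed_dim < 6 or embed_dim % 2 != 0:
        raise ValueError(
            f"embed_dim must be an even number >= 6 for a 3-axis sin-cos "
            f"table, got {embed_dim}"
        )
    base = 2 * (embed_dim // 6)
    dims = [base, base, base]
    rest = embed_dim - 3 * base
    i = 1
    while rest > 0:
        dims[i] += 2
        rest -= 2
        i = (i % 2) + 1
    return tuple(dims)  # type: ignore[return-value]


def _sincos_1d(n_pos: int, dim: int) -> np.ndarray:
    half = dim // 2
    omega = 1.0 / (10000.0 ** (np.arange(half, dtype=np.float64) / half))
    ang = np.arange(n_pos, dtype=np.float64)[:, None] * omega[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1)


def posembed_3d(grid: PatchGrid, embed_dim: int) -> np.ndarray:
    """Fixed (non-learned) 3D sin-cos positional table, one row per token.

    Built as the concatenation of three 1D sin-cos embeddings — one per
    grid axis, each over the token's absolute index on that axis — with
    near-equal even per-axis widths.  Rows for distinct grid coordinates
    are pairwise distinct.
    """
    dz, dy, dx = _axis_dims(embed_dim)
    gz, gy, gx = grid.grid_shape
    ez = _sincos_1d(gz, dz)
    ey = _sincos_1d(gy, dy)
    ex = _sincos_1d(gx, dx)
    zz, yy, xx = np.meshgrid(np.arange(gz), np.arange(gy), np.arange(gx), indexing="ij")
    table = np.concatenate(
        [ez[zz.ravel()], ey[yy.ravel()], ex[xx.ravel()]], axis=1
    )
    return table.astype(np.float32)


def normalize_patches(patches: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Per-patch normalization used for reconstruction targets.

    Each row is centered by its mean and divided by its (biased) standard
    deviation plus ``eps``.
    """
    patches = np.asarray(patches, dtype=np.float32)
    mean = patches.mean(axis=-1, keepdims=True)
    std = patches.std(axis=-1, keepdims=True)  # biased (ddof=0)
    return (patches - mean) / (std + eps)
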