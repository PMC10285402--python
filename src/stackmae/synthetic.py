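"""Synthetic serial-section EM volumes with paired instance labels.

The generator emulates the two structure classes that matter for the
downstream tasks: neurite-like *tubes* (random-walk trajectories stamped
with an anisotropic brush) and mitochondria-like *ellipsoids*.  Objects are
deliberately flatter in z than in xy so the stacks look like serial
sections (z-resolution coarser than xy).  Rendering paints bright textured
interiors separated by dark membranes, adds Gaussian noise and clips to
[0, 1].  Everything is driven by one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, Volume, write_volume

# 6-connectivity structuring element
_STRUCT6 = ndimage.generate_binary_structure(3, 1)
# in-plane (xy) cross for anisotropy-aware dilation
_STRUCT_XY = np.zeros((1, 3, 3), dtype=bool)
_STRUCT_XY[0] = [[False, True, False], [True, True, True], [False, True, False]]

Z_FLATTEN = 0.4  # z semi-axis as a fraction of the xy radius


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    rz, ry, rx = radii
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _stamp_tube(shape, rng, min_radius, max_radius) -> np.ndarray:
    """Random-walk tube: mostly in-plane steps with occasional z drift."""
    mask = np.zeros(shape, dtype=bool)
    r = float(rng.uniform(min_radius, max_radius))
    rz = max(1.0, r * Z_FLATTEN)
    pos = np.array(
        [rng.uniform(1, shape[0] - 1), rng.uniform(r, shape[1] - r), rng.uniform(r, shape[2] - r)]
    )
    direction = rng.normal(size=3)
    direction[0] *= 0.3  # keep trajectories mostly in-plane
    direction /= np.linalg.norm(direction) + 1e-9
    n_steps = int(rng.integers(8, 24))
    step_len = max(1.5, r * 0.8)
    for _ in range(n_steps):
        center = np.clip(pos, 0, np.array(shape) - 1)
        mask |= _ellipsoid_mask(shape, center, (rz, r, r))
        turn = rng.normal(scale=0.35, size=3)
        turn[0] *= 0.5
        direction = direction + turn
        direction /= np.linalg.norm(direction) + 1e-9
        pos = pos + direction * step_len
        pos = np.clip(pos, [0, 0, 0], np.array(shape) - 1)
    return mask


def _stamp_ellipsoid(shape, rng, min_radius, max_radius) -> np.ndarray:
    r = float(rng.uniform(min_radius, max_radius))
    rz = max(1.0, r * Z_FLATTEN)
    ry = r * float(rng.uniform(0.7, 1.3))
    rx = r * float(rng.uniform(0.7, 1.3))
    center = (
        rng.uniform(1, shape[0] - 1),
        rng.uniform(ry, shape[1] - ry),
        rng.uniform(rx, shape[2] - rx),
    )
    return _ellipsoid_mask(shape, center, (rz, ry, rx))


def make_instances(
    shape: tuple[int, int, int],
    n_objects: int = 60,
    min_radius: float = 5,
    max_radius: float = 12,
    rng: np.random.Generator | None = None,
    tube_fraction: float = 0.6,
    max_retries: int = 8,
    gap: int = 0,
) -> LabelVolume:
    """Pack non-overlapping, 6-connected instances into a volume.

    Labels are consecutive integers starting at 1.  Each placed instance is
    a single 6-connected component spanning at least two z-sections.  By
    default instances may touch (neurite-like packing); ``gap`` keeps at
    least that many background voxels between instances (mitochondria-like
    isolation).  Raises when not a single object can be placed within the
    retry budget.
    """
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    labels = np.zeros(shape, dtype=np.int64)
    next_id = 1
    for _ in range(n_objects):
        placed = False
        for _ in range(max_retries):
            if rng.random() < tube_fraction:
                cand = _stamp_tube(shape, rng, min_radius, max_radius)
            else:
                cand = _stamp_ellipsoid(shape, rng, min_radius, max_radius)
            stamped = int(cand.sum())
            occupied = labels > 0
            if gap > 0:
                occupied = ndimage.binary_dilation(
                    occupied, structure=_STRUCT6, iterations=gap
                )
            cand &= ~occupied
            if not cand.any():
                continue
            # keep only the largest 6-connected piece of what survived
            cc, n = ndimage.label(cand, structure=_STRUCT6)
            if n == 0:
                continue
            sizes = ndimage.sum_labels(cand, cc, index=np.arange(1, n + 1))
            best = int(np.argmax(sizes)) + 1
            piece = cc == best
            # reject stamps that earlier objects carved down to slivers:
            # heavily carved remnants have thin necks that no longer look
            # like cell bodies
            if piece.sum() < 0.6 * stamped:
                continue
            zs = np.any(piece, axis=(1, 2))
            if zs.sum() < 2 or piece.sum() < 8:
                continue
            labels[piece] = next_id
            next_id += 1
            placed = True
            break
        if not placed and next_id == 1:
            raise RuntimeError(
                f"could not place any instance in shape {shape} "
                f"(placed 0 of {n_objects})"
            )
    return LabelVolume(labels)


def render_em(
    labels: LabelVolume,
    membrane_width: int = 1,
    interior_mean: float = 0.75,
    membrane_mean: float = 0.15,
    noise_sigma: float = 0.05,
    rng: np.random.Generator | None = None,
    texture_sigma: float = 0.06,
) -> Volume:
    """Render a label volume as a serial-section-EM-like grayscale stack.

    Voxels on an inter-instance or instance/background interface (detected
    by in-volume 6-neighbor comparison, then dilated in-plane to
    ``membrane_width``) are drawn dark around ``membrane_mean``; instance
    interiors bright around ``interior_mean``, modulated by a smooth
    low-frequency texture field; unclaimed background stays dark.  The
    result depends only on the label *geometry* — permuting instance ids
    leaves the image unchanged.
    """
    if not (0.0 <= membrane_mean < interior_mean <= 1.0):
        raise ValueError(
            f"need 0 <= membrane_mean < interior_mean <= 1, got "
            f"{membrane_mean} and {interior_mean}"
        )
    if membrane_width < 1:
        raise ValueError("membrane_width must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    lab = labels.data
    fg = lab > 0

    boundary = np.zeros(lab.shape, dtype=bool)
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(1, None)
        b[axis] = slice(None, -1)
        diff = lab[tuple(a)] != lab[tuple(b)]
        boundary[tuple(a)] |= diff
        boundary[tuple(b)] |= diff
    boundary &= fg | ndimage.binary_dilation(fg, structure=_STRUCT6)
    if membrane_width > 1:
        boundary = ndimage.binary_dilation(
            boundary, structure=_STRUCT_XY, iterations=membrane_width - 1
        )

    img = np.full(lab.shape, membrane_mean, dtype=np.float32)
    interior = fg & ~boundary
    # smooth texture field gives interiors a cell-plasm-like mottle;
    # drawn over the whole volume so it never depends on label values
    texture = ndimage.gaussian_filter(
        rng.normal(scale=1.0, size=lab.shape).astype(np.float32), sigma=(1, 4, 4)
    )
    texture *= texture_sigma / (texture.std() + 1e-9)
    img[interior] = interior_mean + texture[interior]
    if noise_sigma > 0:
        img += rng.normal(scale=noise_sigma, size=lab.shape).astype(np.float32)
    return Volume(np.clip(img, 0.0, 1.0))


@dataclass
class SynthConfig:
    """Configuration for a synthetic dataset written to disk."""

    out_dir: str | Path = "synthetic_data"
    n_volumes: int = 2
    shape: tuple[int, int, int] = (20, 128, 128)
    n_objects: int = 60
    min_radius: float = 5
    max_radius: float = 12
    membrane_width: int = 2
    interior_mean: float = 0.75
    membrane_mean: float = 0.15
    noise_sigma: float = 0.05
    seed: int = 0
    container: str = "h5"  # "h5" or "tif"
    extra: dict = field(default_factory=dict)


def make_volume_pair(
    shape: tuple[int, int, int],
    rng: np.random.Generator,
    n_objects: int = 60,
    min_radius: float = 5,
    max_radius: float = 12,
    tube_fraction: float = 0.6,
    gap: int = 0,
    **render_kwargs,
) -> tuple[Volume, LabelVolume]:
    """Convenience: instances + rendering in one call (in memory)."""
    labels = make_instances(
        shape,
        n_objects=n_objects,
        min_radius=min_radius,
        max_radius=max_radius,
        rng=rng,
        tube_fraction=tube_fraction,
        gap=gap,
    )
    vol = render_em(labels, rng=rng, **render_kwargs)
    return vol, labels


def make_dataset(config: SynthConfig) -> list[tuple[Path, Path]]:
    """Write paired image/label containers readable by :mod:`stackmae.volumes`.

    Returns the list of (image_path, label_path) pairs.  Regenerating with
    the same seed yields byte-identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = {"h5": ".h5", "tif": ".tif"}[config.container]
    rng = np.random.default_rng(config.seed)
    pairs: list[tuple[Path, Path]] = []
    for i in range(config.n_volumes):
        vol, labels = make_volume_pair(
            config.shape,
            rng,
            n_objects=config.n_objects,
            min_radius=config.min_radius,
            max_radius=config.max_radius,
            membrane_width=config.membrane_width,
            interior_mean=config.interior_mean,
            membrane_mean=config.membrane_mean,
            noise_sigma=config.noise_sigma,
        )
        img_path = out / f"vol_{i:03d}{suffix}"
        lab_path = out / f"vol_{i:03d}_labels{suffix}"
        write_volume(vol, img_path)
        write_volume(labels, lab_path)
        pairs.append((img_path, lab_path))
    return pairs
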