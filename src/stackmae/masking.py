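"""Mask-sampling strategies for volumetric token grids.

Three strategies are supported:

* ``random`` — uniform sampling of tokens without replacement, independent
  of spatial structure; the visible count is ``floor((1 - ratio) * N)``
  (the convention that makes 216 tokens at ratio 0.90 leave 21 visible).
* ``space_only`` — a set of xy-columns is kept; kept columns are visible in
  *every* z-section, everything else is masked.
* ``section_only`` — whole z-sections of tokens are kept or masked.

Column/section strategies take integer keep-counts because their feasible
ratios are quantized; :func:`ratio_to_count` converts a requested ratio to
the nearest feasible count, ties broken toward more masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patches import PatchGrid

STRATEGIES = ("random", "space_only", "section_only")


@dataclass
class MaskPlan:
    """Per-token visibility assignment plus strategy/ratio metadata."""

    visible_idx: np.ndarray  # sorted token indices
    masked_idx: np.ndarray  # sorted complement
    ratio_requested: float
    strategy: str
    n_tokens: int

    @property
    def ratio_effective(self) -> float:
        return len(self.masked_idx) / self.n_tokens

    def __post_init__(self) -> None:
        self.visible_idx = np.sort(np.asarray(self.visible_idx, dtype=np.int64))
        self.masked_idx = np.sort(np.asarray(self.masked_idx, dtype=np.int64))
        if len(self.visible_idx) < 1:
            raise ValueError("a mask plan must leave at least one visible token")
        union = np.union1d(self.visible_idx, self.masked_idx)
        if len(self.visible_idx) + len(self.masked_idx) != self.n_tokens or not np.array_equal(
            union, np.arange(self.n_tokens)
        ):
            raise ValueError("visible and masked indices must partition the token set")


def _plan(visible: np.ndarray, n_tokens: int, ratio: float, strategy: str) -> MaskPlan:
    visible = np.sort(np.asarray(visible, dtype=np.int64))
    mask = np.ones(n_tokens, dtype=bool)
    mask[visible] = False
    return MaskPlan(visible, np.flatnonzero(mask), ratio, strategy, n_tokens)


def plan_random(n_tokens: int, ratio: float, rng: np.random.Generator) -> MaskPlan:
    """Uniform token masking without replacement at the requested ratio."""
    if not 0.0 <= ratio < 1.0:
        raise ValueError(f"masking ratio must be in [0, 1), got {ratio}")
    n_visible = max(1, int(np.floor((1.0 - ratio) * n_tokens)))
    visible = rng.choice(n_tokens, size=n_visible, replace=False)
    return _plan(visible, n_tokens, ratio, "random")


def plan_space_only(grid: PatchGrid, keep_columns: int, rng: np.random.Generator) -> MaskPlan:
    """Keep ``keep_columns`` random xy-columns visible across all sections."""
    gz, gy, gx = grid.grid_shape
    n_cols = gy * gx
    if not 1 <= keep_columns <= n_cols:
        raise ValueError(f"keep_columns must be in [1, {n_cols}], got {keep_columns}")
    cols = rng.choice(n_cols, size=keep_columns, replace=False)
    visible = (np.arange(gz)[:, None] * n_cols + cols[None, :]).ravel()
    ratio = 1.0 - keep_columns / n_cols
    return _plan(visible, grid.n_tokens, ratio, "space_only")


def plan_section_only(grid: PatchGrid, keep_sections: int, rng: np.random.Generator) -> MaskPlan:
    """Keep ``keep_sections`` random whole z-sections visible."""
    gz, gy, gx = grid.grid_shape
    if not 1 <= keep_sections <= gz:
        raise ValueError(f"keep_sections must be in [1, {gz}], got {keep_sections}")
    secs = rng.choice(gz, size=keep_sections, replace=False)
    per_section = gy * gx
    visible = (secs[:, None] * per_section + np.arange(per_section)[None, :]).ravel()
    ratio = 1.0 - keep_sections / gz
    return _plan(visible, grid.n_tokens, ratio, "section_only")


def ratio_to_count(grid: PatchGrid, strategy: str, ratio: float) -> int:
    """Nearest feasible keep-count for a requested structured-masking ratio.

    Ties are broken toward more masking (the smaller keep-count).
    """
    if not 0.0 <= ratio < 1.0:
        raise ValueError(f"masking ratio must be in [0, 1), got {ratio}")
    gz, gy, gx = grid.grid_shape
    n_units = gy * gx if strategy == "space_only" else gz
    if strategy not in ("space_only", "section_only"):
        raise ValueError(f"no keep-count conversion for strategy {strategy!r}")
    target = (1.0 - ratio) * n_units
    lo = max(1, int(np.floor(target)))
    hi = min(n_units, int(np.ceil(target)))
    # tie toward more masking = fewer kept units
    return lo if abs(lo - target) <= abs(hi - target) else hi


def make_plan(
    grid: PatchGrid,
    strategy: str,
    rng: np.random.Generator,
    ratio: float | None = None,
    keep_columns: int | None = None,
    keep_sections: int | None = None,
) -> MaskPlan:
    """Dispatch helper used by config-driven code paths."""
    if strategy == "random":
        if ratio is None:
            raise ValueError("random strategy requires a ratio")
        return plan_random(grid.n_tokens, ratio, rng)
    if strategy == "space_only":
        if keep_columns is None:
            keep_columns = ratio_to_count(grid, strategy, float(ratio))  # type: ignore[arg-type]
        return plan_space_only(grid, keep_columns, rng)
    if strategy == "section_only":
        if keep_sections is None:
            keep_sections = ratio_to_count(grid, strategy, float(ratio))  # type: ignore[arg-type]
        return plan_section_only(grid, keep_sections, rng)
    raise ValueError(f"unknown masking strategy {strategy!r} (choose from {STRATEGIES})")
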