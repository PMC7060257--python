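"""Effective-rank estimation for SVD map analysis.

The effective rank n_e is the number of SVD components that carry real
signal.  Two lines of evidence are combined per component i:

* the relative singular weight ``W_ii / sum(W)`` must clear a floor, and
* the V_i-map must show spatial structure, which is quantified as Moran's I
  under 4-neighbor (rook) contiguity on the pixel grid, with a one-sided
  permutation p-value against the spatially-random null.

A component with a large weight but a structureless (noise-like) V_i-map is
rejected: spatial structure dominates the weight evidence.  Components must
pass as a consecutive prefix (all j <= i), so n_e is the length of the
leading run of accepted components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .map_io import ScalarMap
from .svd_engine import SVDResult, relative_weights, v_map

__all__ = [
    "RankReport",
    "grid_shape",
    "structure_score",
    "structure_pvalue",
    "effective_rank",
]


@dataclass
class RankReport:
    """Per-component evidence and the chosen effective rank n_e."""

    weights: np.ndarray  # W_ii for the evaluated components
    relative_weights: np.ndarray
    structure_scores: np.ndarray  # Moran's I of each V_i-map
    structure_pvalues: np.ndarray
    n_e: int
    weight_floor: float
    alpha: float
    n_perm: int
    seed: int
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def n_evaluated(self) -> int:
        return self.weights.size

    def to_rows(self) -> list[dict]:
        rows = []
        for i in range(self.n_evaluated):
            rows.append(
                {
                    "component": i + 1,
                    "weight": float(self.weights[i]),
                    "relative_weight": float(self.relative_weights[i]),
                    "structure_score": float(self.structure_scores[i]),
                    "structure_pvalue": float(self.structure_pvalues[i]),
                    "significant": i < self.n_e,
                }
            )
        return rows


def grid_shape(smap: ScalarMap) -> tuple[np.ndarray, tuple[int, int]]:
    """Recover the rectangular pixel grid behind a scalar map.

    Returns the values reshaped (ny, nx) in row-major (y, x) order.  Raises
    if the points do not form a complete rectangular grid.
    """
    xs = np.unique(smap.coords[:, 0])
    ys = np.unique(smap.coords[:, 1])
    ny, nx = ys.size, xs.size
    if nx * ny != smap.n_points:
        raise ValueError("map points do not form a complete rectangular grid")
    order = np.lexsort((smap.coords[:, 0], smap.coords[:, 1]))
    sorted_coords = smap.coords[order]
    expected_x = np.tile(xs, ny)
    expected_y = np.repeat(ys, nx)
    if not (
        np.array_equal(sorted_coords[:, 0], expected_x)
        and np.array_equal(sorted_coords[:, 1], expected_y)
    ):
        raise ValueError("map points do not form a complete rectangular grid")
    return smap.values[order].reshape(ny, nx), (ny, nx)


def _moran_grid(Z: np.ndarray) -> np.ndarray:
    """Rook-contiguity Moran's I for one grid (ny, nx) or a stack (k, ny, nx).

    Returns 0 for constant grids (degenerate case).
    """
    single = Z.ndim == 2
    if single:
        Z = Z[None]
    k, ny, nx = Z.shape
    n = ny * nx
    zbar = Z.mean(axis=(1, 2), keepdims=True)
    Zc = Z - zbar
    ss = (Zc**2).sum(axis=(1, 2))
    # undirected rook edges, each counted once
    num = (Zc[:, :, :-1] * Zc[:, :, 1:]).sum(axis=(1, 2)) + (
        Zc[:, :-1, :] * Zc[:, 1:, :]
    ).sum(axis=(1, 2))
    n_edges = ny * (nx - 1) + nx * (ny - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        I = (n / (2.0 * n_edges)) * (2.0 * num / ss)
    I = np.where(ss > 0, I, 0.0)
    return I[0] if single else I


def structure_score(smap: ScalarMap) -> float:
    """Moran's I of the map under rook contiguity.

    Near 0 for spatially random maps, approaching 1 for smooth structured
    maps, -1 for a perfectly alternating checkerboard.  A constant map scores
    0 (degenerate).
    """
    if smap.n_points < 16:
        raise ValueError("need at least 16 points for a structure score")
    Z, _ = grid_shape(smap)
    return float(_moran_grid(Z))


def is_degenerate(smap: ScalarMap) -> bool:
    """True when the map is constant (no spatial information at all)."""
    return bool(np.all(smap.values == smap.values[0]))


def structure_pvalue(smap: ScalarMap, n_perm: int = 499, seed: int | None = None) -> float:
    """One-sided permutation p-value for spatial structure.

    Values are shuffled across grid positions; p = (1 + #{I_perm >= I_obs})
    / (n_perm + 1).  A degenerate (constant) map gets p = 1.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if seed is None:
        raise ValueError("structure_pvalue requires an explicit seed")
    if is_degenerate(smap):
        return 1.0
    Z, (ny, nx) = grid_shape(smap)
    obs = _moran_grid(Z)
    rng = np.random.default_rng(seed)
    flat = np.tile(Z.ravel(), (n_perm, 1))
    flat = rng.permuted(flat, axis=1)
    perm = _moran_grid(flat.reshape(n_perm, ny, nx))
    return float((1 + int((perm >= obs).sum())) / (n_perm + 1))


def effective_rank(
    result: SVDResult,
    weight_floor: float = 1e-4,
    alpha: float = 0.01,
    n_perm: int = 499,
    seed: int | None = None,
    max_components: int | None = None,
) -> RankReport:
    """Estimate the effective rank n_e of a decomposed map.

    Component i is significant when its relative weight is >= ``weight_floor``
    AND its V_i-map rejects the spatial-randomness null at level ``alpha``.
    n_e is the largest i such that all components j <= i are significant
    (consecutive-prefix rule).  Evaluation stops at the first failure; the
    report carries the evidence for every evaluated component.
    """
    if seed is None:
        raise ValueError("effective_rank requires an explicit seed")
    relw = relative_weights(result)
    limit = result.rank if max_components is None else min(max_components, result.rank)
    scores: list[float] = []
    pvals: list[float] = []
    degen: list[bool] = []
    n_e = 0
    for i in range(1, limit + 1):
        vm = v_map(result, i)
        degen.append(is_degenerate(vm))
        scores.append(structure_score(vm))
        pvals.append(structure_pvalue(vm, n_perm=n_perm, seed=seed + i))
        ok = (relw[i - 1] >= weight_floor) and (pvals[-1] <= alpha)
        if ok:
            n_e = i
        else:
            break
    k = len(scores)
    return RankReport(
        weights=result.weights[:k].copy(),
        relative_weights=relw[:k].copy(),
        structure_scores=np.array(scores),
        structure_pvalues=np.array(pvals),
        n_e=n_e,
        weight_floor=weight_floor,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        degenerate=np.array(degen, dtype=bool),
    )
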