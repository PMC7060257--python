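"""Singular value decomposition of spectral maps.

The data matrix D is assembled channels x points (one column per map point,
one row per spectral channel) and factorized as ``D = U W V^T`` with no
centering or scaling.  On uncentered non-negative data the first basis
spectrum U1 is proportional to the map's average spectral shape, and the
higher U_i are successive orthogonal deviations from it; the rows of V^T
("amplitude vectors") carry one value per map point and, re-spatialized onto
the grid, form the V_i-maps.  Because no centering is applied this is an SVD
analysis proper, not PCA.

SVD leaves the sign of each (U_i, V_i) pair free; decompose() fixes it by
flipping each pair so the entry of U_i with the largest absolute value is
positive, which makes results bit-reproducible and lets band signs be
asserted directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .map_io import ScalarMap
from .spectral_model import HyperMap, SpectralAxis

__all__ = ["SVDResult", "assemble_matrix", "decompose", "relative_weights", "v_map", "reconstruct"]


@dataclass(eq=False)
class SVDResult:
    """Thin SVD of a map's data matrix, with spatial bookkeeping.

    ``basis_spectra`` holds the U_i in its columns (n_channels x r),
    ``weights`` the singular values W_ii in non-increasing order, and
    ``amplitudes`` the rows V_i of V^T (r x n_points).  ``coords`` maps
    amplitude columns back onto (x, y) positions.  Component indices in the
    API are 1-based, mirroring the U1/V1 naming convention.
    """

    axis: SpectralAxis
    coords: np.ndarray  # (n_points, 2)
    basis_spectra: np.ndarray  # (n_channels, r)
    weights: np.ndarray  # (r,)
    amplitudes: np.ndarray  # (r, n_points)
    sign_canonicalized: bool = True

    @property
    def rank(self) -> int:
        return self.weights.size

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    # method aliases for the module-level operations
    def relative_weights(self) -> np.ndarray:
        return relative_weights(self)

    def v_map(self, i: int) -> ScalarMap:
        return v_map(self, i)

    def reconstruct(self, rank: int) -> np.ndarray:
        return reconstruct(self, rank)


def assemble_matrix(hmap: HyperMap) -> tuple[np.ndarray, np.ndarray]:
    """Build the channels x points data matrix D and its column coordinates.

    Column order equals the map's canonical point order.  No centering and no
    scaling are applied.
    """
    if hmap.n_points < 2 or hmap.n_channels < 2:
        raise ValueError("need at least 2 points and 2 channels")
    if not np.all(np.isfinite(hmap.spectra)):
        raise ValueError("spectra contain non-finite entries")
    return hmap.spectra.T.copy(), hmap.coords.copy()


def _canonicalize_signs(U: np.ndarray, Vt: np.ndarray) -> None:
    """Flip each (U_i, V_i) pair so U_i's largest-|.| entry is positive."""
    for i in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] *= -1.0
            Vt[i, :] *= -1.0


def decompose(hmap: HyperMap) -> SVDResult:
    """Thin SVD of the map with deterministic sign canonicalization."""
    D, coords = assemble_matrix(hmap)
    U, W, Vt = np.linalg.svd(D, full_matrices=False)
    _canonicalize_signs(U, Vt)
    return SVDResult(
        axis=hmap.axis,
        coords=coords,
        basis_spectra=U,
        weights=W,
        amplitudes=Vt,
    )


def relative_weights(result: SVDResult) -> np.ndarray:
    """W_ii / sum(W_jj); sums to 1."""
    total = result.weights.sum()
    if not (total > 0):
        raise ValueError("all singular values are zero")
    return result.weights / total


def v_map(result: SVDResult, i: int) -> ScalarMap:
    """Re-spatialize amplitude vector V_i (1-based) onto the map grid."""
    if not (1 <= i <= result.rank):
        raise ValueError(f"component index {i} out of range 1..{result.rank}")
    return ScalarMap(
        coords=result.coords.copy(),
        values=result.amplitudes[i - 1].copy(),
        name=f"V{i}",
    )


def reconstruct(result: SVDResult, rank: int) -> np.ndarray:
    """Rank-truncated (noise-filtered) reconstruction of D.

    Returns ``sum_{i<=rank} W_ii U_i V_i^T``.  By the Eckart-Young theorem
    the Frobenius error of the truncation equals
    ``sqrt(sum_{i>rank} W_ii^2)``.
    """
    if not (1 <= rank <= result.rank):
        raise ValueError(f"rank {rank} out of range 1..{result.rank}")
    U = result.basis_spectra[:, :rank]
    W = result.weights[:rank]
    Vt = result.amplitudes[:rank]
    return (U * W) @ Vt
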