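"""Patch-based PCA denoising with Marchenko-Pastur automatic rank selection.

A sliding spatial window turns the CSI grid into Casorati matrices (rows =
voxels in the patch, columns = spectral points).  Under i.i.d. noise the
eigenvalue spectrum of a pure-noise Casorati matrix follows the
Marchenko-Pastur (MP) law; signal components stick out above the MP bulk edge.
For each candidate signal rank ``p`` the discarded eigenvalues yield two noise
variance estimates — their mean, and their spread mapped through the MP bulk
width ``4 sigma^2 sqrt(gamma)`` — and the selected rank is the smallest ``p``
for which the spread-based estimate does not exceed the mean-based one,
i.e. the tail is consistent with pure noise.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field

from .containers import SpectralGrid


class PatchConfig(BaseModel):
    """Sliding-window configuration for Casorati patch extraction."""

    patch_shape: tuple[int, int, int] = (3, 3, 3)
    stride: tuple[int, int, int] = (1, 1, 1)
    #: rows = voxels, columns = spectral points (transposed internally if the
    #: spectral dimension is the shorter one for the eigen-decomposition)
    casorati_voxel_rows: bool = True

    model_config = {"frozen": True}

    def n_patch_voxels(self) -> int:
        n = int(np.prod(self.patch_shape))
        if n < 2:
            raise ValueError("patch must contain at least 2 voxels")
        return n


def mp_rank_select(
    singular_values: np.ndarray, n_rows: int, n_cols: int
) -> tuple[int, float]:
    """Automatic rank selection against the Marchenko-Pastur null.

    ``singular_values`` are those of an ``n_rows x n_cols`` (complex) matrix,
    sorted descending.  Returns ``(rank, noise_variance)`` where the noise
    variance is per complex matrix entry (sum of the real and imaginary
    component variances).
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 singular values")
    if np.any(np.diff(s) > 1e-12 * max(s[0], 1.0)) or np.any(s < 0):
        raise ValueError("singular values must be sorted descending and non-negative")
    n = min(n_rows, n_cols)
    m = max(n_rows, n_cols)
    lam = s**2 / m  # eigenvalues of X X^H / m, descending
    # candidate p = number of retained (signal) components
    for p in range(n - 1):
        tail = lam[p:]
        gamma = (n - p) / m
        sigma2_mean = float(tail.mean())
        sigma2_spread = float((tail[0] - tail[-1]) / (4.0 * np.sqrt(gamma)))
        if sigma2_spread <= sigma2_mean:
            return p, sigma2_mean
    return n - 1, float(lam[-1])


def _denoise_casorati(x: np.ndarray) -> tuple[np.ndarray, int, float]:
    """Truncate one Casorati matrix at the MP-selected rank.

    The SVD is taken via the eigendecomposition of the small Gram matrix
    X X^H (rows << columns here), which is substantially faster than a full
    SVD of the wide matrix.
    """
    rows, cols = x.shape
    if rows <= cols:
        gram = x @ x.conj().T
        evals, evecs = np.linalg.eigh(gram)  # ascending
        evals = np.maximum(evals[::-1], 0.0)
        u = evecs[:, ::-1]
        s = np.sqrt(evals)
    else:
        return _denoise_casorati_t(x)
    rank, sigma2 = mp_rank_select(s, rows, cols)
    if rank == 0:
        return np.zeros_like(x), 0, sigma2
    ur = u[:, :rank]
    xd = ur @ (ur.conj().T @ x)
    return xd, rank, sigma2


def _denoise_casorati_t(x: np.ndarray) -> tuple[np.ndarray, int, float]:
    xd, rank, sigma2 = _denoise_casorati(x.T)
    return xd.T, rank, sigma2


def denoise_grid(
    grid: SpectralGrid, cfg: PatchConfig | None = None, return_info: bool = False
):
    """MP-PCA denoise a CSI grid with overlapping patches.

    Overlapping estimates are uniformly averaged.  Output shape equals input
    shape.  With ``return_info=True`` also returns a dict with the per-patch
    rank map and noise-variance map (on the patch-origin grid).
    """
    cfg = cfg or PatchConfig()
    cfg.n_patch_voxels()
    shape = grid.spatial_shape
    pw = cfg.patch_shape
    if any(p > n for p, n in zip(pw, shape)):
        raise ValueError(f"patch {pw} larger than grid {shape}")
    nt = grid.data.shape[-1]

    acc = np.zeros_like(grid.data)
    weight = np.zeros(shape)
    starts = [
        range(0, shape[ax] - pw[ax] + 1, cfg.stride[ax]) for ax in range(3)
    ]
    # make sure the trailing edge is covered when the stride skips it
    starts = [
        sorted(set(list(r) + [shape[ax] - pw[ax]])) for ax, r in enumerate(starts)
    ]
    ranks = np.full(shape, -1, dtype=int)
    sigma2s = np.full(shape, np.nan)
    for i0 in starts[0]:
        for j0 in starts[1]:
            for k0 in starts[2]:
                sl = (slice(i0, i0 + pw[0]), slice(j0, j0 + pw[1]), slice(k0, k0 + pw[2]))
                patch = grid.data[sl].reshape(-1, nt)
                if not cfg.casorati_voxel_rows:
                    xd, rank, sigma2 = _denoise_casorati(patch.T)
                    xd = xd.T
                else:
                    xd, rank, sigma2 = _denoise_casorati(patch)
                acc[sl] += xd.reshape(pw + (nt,))
                weight[sl] += 1.0
                ranks[i0, j0, k0] = rank
                sigma2s[i0, j0, k0] = sigma2
    out = SpectralGrid(acc / weight[..., None], grid.acq, dict(grid.meta))
    out.meta["denoised"] = {"patch_shape": list(pw), "stride": list(cfg.stride)}
    if return_info:
        return out, {"rank_map": ranks, "noise_variance_map": sigma2s}
    return out
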