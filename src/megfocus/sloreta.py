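"""sLORETA inverse: regularized minimum norm with per-voxel standardization.

The minimum-norm estimate is computed in noise-whitened sensor space,

    W = L~' (L~ L~' + lambda^2 I)^{-1},      L~ = C^{-1/2} L,

with the regularization set from a target signal-to-noise ratio,
``lambda^2 = trace(L~ L~') / (n_channels * snr^2)``.  sLORETA standardizes
the 3-vector estimate at each voxel by the corresponding 3x3 diagonal
block of the resolution matrix R = W L~:

    power_v = j_v' (R_vv + eps I)^{-1} j_v .

In a spherical conductor the radial source direction is silent, so R_vv is
rank 2; the small eps ridge (1e-12 of the mean block trace) makes the
standardization well defined without disturbing the observable subspace.
Standardized power is dimensionless and non-negative, and is invariant to
rescaling the noise covariance by any positive scalar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .head_model import LeadField


@dataclass(frozen=True)
class NoiseModel:
    """Sensor noise covariance (tesla^2) pooled from baseline windows."""

    covariance: np.ndarray
    source_windows: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(c, c.T, rtol=0.0, atol=1e-12 * np.abs(c).max()):
            raise ValueError("covariance must be symmetric")


@dataclass(frozen=True)
class InverseKernel:
    """Whitened minimum-norm kernel plus sLORETA resolution blocks."""

    kernel: np.ndarray             # (3V, n_channels), applies to whitened data
    lam: float                     # regularization lambda^2 (dimensionless rule)
    resolution_blocks: np.ndarray  # (V, 3, 3)
    whitener: np.ndarray           # (n_channels, n_channels) C^{-1/2}

    @property
    def n_voxels(self) -> int:
        return self.kernel.shape[0] // 3

    @property
    def n_channels(self) -> int:
        return self.kernel.shape[1]


@dataclass(frozen=True)
class CurrentMap:
    """Per-voxel standardized power: (V, T) time series or (V,) average."""

    values: np.ndarray
    kind: str = "IED"       # {"IED", "BL"}
    window_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v < 0):
            raise ValueError("standardized power must be non-negative")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]


def estimate_noise_covariance(
    bl_windows: Sequence[np.ndarray], shrinkage: float = 0.1
) -> NoiseModel:
    """Pooled sample covariance of baseline windows, shrunk toward its diagonal.

    Each window is (n_channels, T); windows are demeaned individually and the
    covariance is pooled over all windows.  ``shrinkage`` s maps
    C <- (1-s) C + s diag(C).
    """
    if len(bl_windows) < 2:
        raise ValueError("need at least 2 baseline windows for a noise estimate")
    if not (0.0 <= shrinkage <= 1.0):
        raise ValueError("shrinkage must lie in [0, 1]")
    acc = None
    dof = 0
    for w in bl_windows:
        w = np.asarray(w, dtype=float)
        x = w - w.mean(axis=1, keepdims=True)
        acc = x @ x.T if acc is None else acc + x @ x.T
        dof += w.shape[1] - 1
    cov = acc / dof
    var = np.diag(cov)
    dead = np.flatnonzero(var <= 0)
    if dead.size:
        raise ValueError(f"zero-variance channel(s): {dead.tolist()}")
    cov = (1.0 - shrinkage) * cov + shrinkage * np.diag(var)
    return NoiseModel(cov, source_windows=f"{len(bl_windows)} baseline windows")


def compute_inverse_kernel(
    leadfield: LeadField, noise: NoiseModel, snr: float = 3.0
) -> InverseKernel:
    """Whitened, SNR-regularized minimum-norm kernel with resolution blocks."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    cov = noise.covariance
    n_ch = leadfield.n_channels
    if cov.shape[0] != n_ch:
        raise ValueError("noise covariance does not match lead field channels")
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 0 or evals.min() < 1e-15 * evals.max():
        raise ValueError("noise covariance is singular; cannot whiten")
    whitener = (evecs / np.sqrt(evals)) @ evecs.T
    lw = whitener @ leadfield.matrix                     # (n_ch, 3V)
    gram = lw @ lw.T
    lam2 = np.trace(gram) / (n_ch * snr**2)
    kernel = lw.T @ np.linalg.inv(gram + lam2 * np.eye(n_ch))  # (3V, n_ch)
    v = leadfield.n_voxels
    blocks = np.einsum(
        "vak,kvb->vab", kernel.reshape(v, 3, n_ch), lw.reshape(n_ch, v, 3)
    )
    blocks = 0.5 * (blocks + blocks.transpose(0, 2, 1))
    return InverseKernel(kernel=kernel, lam=float(lam2), resolution_blocks=blocks, whitener=whitener)


def _standardizers(kernel: InverseKernel) -> np.ndarray:
    """(V, 3, 3) inverses of (R_vv + eps I)."""
    blocks = kernel.resolution_blocks
    eps = 1e-12 * float(np.trace(blocks.mean(axis=0)) / 3.0)
    eye = np.eye(3)[None]
    return np.linalg.inv(blocks + eps * eye)


def apply_sloreta(
    kernel: InverseKernel, window: np.ndarray, kind: str = "IED", window_id: str = ""
) -> CurrentMap:
    """sLORETA standardized power time series for one sensor window.

    ``window`` is (n_channels, T); the result holds a (V, T) array of the
    quadratic form j' (R_vv + eps I)^{-1} j at each voxel and sample.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[:, None]
    if window.shape[0] != kernel.n_channels:
        raise ValueError(
            f"window has {window.shape[0]} channels, kernel expects {kernel.n_channels}"
        )
    j = (kernel.kernel @ (kernel.whitener @ window)).reshape(kernel.n_voxels, 3, -1)
    binv = _standardizers(kernel)
    power = np.einsum("vat,vab,vbt->vt", j, binv, j)
    return CurrentMap(np.maximum(power, 0.0), kind=kind, window_id=window_id)


def time_average_map(series: CurrentMap) -> CurrentMap:
    """Arithmetic mean of a standardized-power time series over time."""
    vals = series.values
    if vals.ndim == 1:
        vals = vals[:, None]
    if vals.shape[1] < 1:
        raise ValueError("cannot average an empty time series")
    return CurrentMap(vals.mean(axis=1), kind=series.kind, window_id=series.window_id)
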