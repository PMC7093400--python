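"""Combined distributed-source (cDS) focus diagnosis.

Pipeline: band-pass the raw recording to the spike band (10-50 Hz),
extract the annotated interictal-discharge (IED) windows and 100-ms
baseline (BL) windows, compute the time-averaged sLORETA map of every
window, contrast IED vs. BL maps voxelwise with a label-permutation test
(1,000 randomizations by default), adjust the p-map with the
Benjamini-Hochberg false-discovery rate, and then raise the statistical
threshold along a fixed ladder until the surviving voxels fall inside a
single sublobar region.  The region containing the maximum-intensity
voxel — the peak of the studentized IED-vs-BL contrast restricted to the
surviving mask — is reported as the epileptogenic-focus diagnosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt
from statsmodels.stats.multitest import multipletests

from .head_model import LeadField, SourceGrid
from .sloreta import (
    CurrentMap,
    apply_sloreta,
    compute_inverse_kernel,
    estimate_noise_covariance,
    time_average_map,
)

#: q-threshold ladder walked by :func:`focus_by_threshold`; starts at the
#: 0.05 significance level and is raised (made stricter) step by step.
DEFAULT_LADDER: tuple[float, ...] = (0.05, 0.01, 0.005, 0.001, 5e-4, 1e-4)

BL_WINDOW_S = 0.1  # baseline windows are exactly 100 ms

NONE_REGION = 0  # focus_region sentinel: no significant voxel at alpha = 0.05


class WindowError(ValueError):
    """A window is malformed, out of bounds, or violates the IED guard."""


class ExclusionError(ValueError):
    """Too few IEDs for statistical analysis (fewer than three)."""


@dataclass(frozen=True)
class EventCatalog:
    """IED and baseline window annotations, in seconds.

    Baseline windows must each last exactly 100 ms and keep ``guard_s``
    clear of every IED interval (the 1-s pre/post IED buffer).
    """

    ied_windows: tuple[tuple[float, float], ...]
    bl_windows: tuple[tuple[float, float], ...]
    guard_s: float = 1.0

    def __post_init__(self) -> None:
        ied = tuple((float(a), float(b)) for a, b in self.ied_windows)
        bl = tuple((float(a), float(b)) for a, b in self.bl_windows)
        object.__setattr__(self, "ied_windows", ied)
        object.__setattr__(self, "bl_windows", bl)
        if not ied:
            raise WindowError("catalog must contain at least one IED window")
        for k, (a, b) in enumerate(ied):
            if not a < b:
                raise WindowError(f"IED window {k} has onset >= offset ({a}, {b})")
        for k, (a, b) in enumerate(bl):
            if abs((b - a) - BL_WINDOW_S) > 1e-9:
                raise WindowError(f"BL window {k} is not exactly 100 ms ({a}, {b})")
            for ia, ib in ied:
                if a < ib + self.guard_s and b > ia - self.guard_s:
                    raise WindowError(
                        f"BL window {k} ({a:.3f}-{b:.3f} s) violates the "
                        f"{self.guard_s}-s guard around IED ({ia:.3f}-{ib:.3f} s)"
                    )

    @property
    def n_ied(self) -> int:
        return len(self.ied_windows)


@dataclass(frozen=True)
class CdsConfig:
    """Tunable parameters of the cDS pipeline (defaults follow the method)."""

    low_hz: float = 10.0
    high_hz: float = 50.0
    snr: float = 3.0
    shrinkage: float = 0.1
    n_perm: int = 1000
    ladder: tuple[float, ...] = DEFAULT_LADDER
    seed: int = 0


@dataclass(frozen=True)
class CdsResult:
    p_values: np.ndarray
    q_values: np.ndarray
    threshold_path: tuple[float, ...]
    final_threshold: float
    significant_mask: np.ndarray
    max_voxel: int | None
    focus_region: int            # region label, or NONE_REGION
    mean_ied_map: CurrentMap
    contrast_map: np.ndarray     # mean(IED) - mean(BL) standardized power
    t_map: np.ndarray            # studentized contrast (intensity for focus)


def bandpass(raw: np.ndarray, sr: float, low: float = 10.0, high: float = 50.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    if not (0.0 < low < high < sr / 2.0):
        raise ValueError(f"band ({low}, {high}) Hz invalid for sampling rate {sr} Hz")
    sos = butter(4, [low, high], btype="bandpass", output="sos", fs=sr)
    return sosfiltfilt(sos, np.asarray(raw, dtype=float), axis=-1)


def extract_windows(
    raw: np.ndarray, sr: float, catalog: EventCatalog
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Slice IED and BL windows out of a (n_channels, T) recording.

    Slices are half-open in samples, ``[round(onset*sr), round(offset*sr))``.
    """
    raw = np.asarray(raw)
    n_t = raw.shape[-1]

    def _slice(onset: float, offset: float, name: str) -> np.ndarray:
        i0 = int(round(onset * sr))
        i1 = int(round(offset * sr))
        if i0 < 0 or i1 > n_t:
            raise WindowError(
                f"{name} ({onset:.3f}-{offset:.3f} s) outside recording of {n_t / sr:.3f} s"
            )
        return raw[..., i0:i1]

    ied = [_slice(a, b, f"IED window {k}") for k, (a, b) in enumerate(catalog.ied_windows)]
    bl = [_slice(a, b, f"BL window {k}") for k, (a, b) in enumerate(catalog.bl_windows)]
    return ied, bl


def _as_map_matrix(maps: Sequence[CurrentMap | np.ndarray]) -> np.ndarray:
    rows = [m.values if isinstance(m, CurrentMap) else np.asarray(m, float) for m in maps]
    return np.vstack([r.reshape(1, -1) for r in rows])


def permutation_test(
    ied_maps: Sequence[CurrentMap | np.ndarray],
    bl_maps: Sequence[CurrentMap | np.ndarray],
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Voxelwise two-sided permutation p-values for mean(IED) - mean(BL).

    Labels are permuted jointly across voxels.  With fewer requested
    randomizations than distinct group splits, ``n_perm`` random splits are
    drawn and the p-value uses the add-one convention
    ``(1 + #{|T*| >= |T|}) / (1 + n_perm)``; when ``n_perm`` reaches the
    number of distinct splits the test switches to exhaustive enumeration
    (exact p, identity split included).

    Cases with fewer than three IEDs are excluded from analysis.
    """
    if len(ied_maps) < 3:
        raise ExclusionError(
            f"only {len(ied_maps)} IED map(s); cases with one or two IEDs are excluded"
        )
    if len(bl_maps) < 2:
        raise ValueError("need at least 2 baseline maps")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = _as_map_matrix(ied_maps)
    y = _as_map_matrix(bl_maps)
    n1, n2 = x.shape[0], y.shape[0]
    data = np.vstack([x, y])
    n = n1 + n2
    t_obs = x.mean(axis=0) - y.mean(axis=0)

    # relative tie tolerance: the observed statistic reappears (up to sign)
    # in complementary splits along a different floating-point path
    thresh = np.abs(t_obs) * (1.0 - 1e-9)

    n_splits = math.comb(n, n1)
    if n_perm >= n_splits:
        # exhaustive: every way of relabeling n1 of the n maps as "IED"
        count = np.zeros(data.shape[1], dtype=int)
        total = data.sum(axis=0)
        for idx in combinations(range(n), n1):
            s1 = data[list(idx)].sum(axis=0)
            t_star = s1 / n1 - (total - s1) / n2
            count += np.abs(t_star) >= thresh
        return count / n_splits

    rng = np.random.default_rng(seed)
    sel = np.zeros((n_perm, n), dtype=float)
    for i in range(n_perm):
        sel[i, rng.permutation(n)[:n1]] = 1.0
    s1 = sel @ data
    total = data.sum(axis=0)
    t_star = s1 / n1 - (total[None, :] - s1) / n2
    count = (np.abs(t_star) >= thresh[None, :]).sum(axis=0)
    return (1.0 + count) / (1.0 + n_perm)


def fdr_correct(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def focus_by_threshold(
    q: np.ndarray,
    mean_ied_map: CurrentMap | np.ndarray,
    grid: SourceGrid,
    ladder: Sequence[float] = DEFAULT_LADDER,
) -> tuple[float, np.ndarray, int | None, int]:
    """Raise the q-threshold until the significant voxels span one region.

    Walks ``ladder`` (which must start at 0.05 and strictly decrease);
    stops at the first non-empty mask confined to a single sublobar region,
    or else at the last non-empty mask.  Returns
    ``(final_threshold, significant_mask, max_voxel, focus_region)`` where
    ``max_voxel`` is the argmax of the mean IED map within the mask (ties
    break to the lowest voxel index).  An empty mask already at 0.05 yields
    ``focus_region = NONE_REGION``.
    """
    ladder = tuple(float(t) for t in ladder)
    if not ladder:
        raise ValueError("threshold ladder is empty")
    if abs(ladder[0] - 0.05) > 1e-12:
        raise ValueError("ladder must start at the 0.05 significance level")
    if any(b >= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("ladder must strictly decrease")
    q = np.asarray(q, dtype=float)
    intensity = mean_ied_map.values if isinstance(mean_ied_map, CurrentMap) else np.asarray(mean_ied_map, float)

    chosen_thr = ladder[0]
    chosen_mask = q <= ladder[0]
    if not chosen_mask.any():
        return ladder[0], chosen_mask, None, NONE_REGION
    for thr in ladder:
        mask = q <= thr
        if not mask.any():
            break
        chosen_thr, chosen_mask = thr, mask
        if np.unique(grid.region_labels[mask]).size == 1:
            break
    masked = np.where(chosen_mask, intensity, -np.inf)
    max_voxel = int(np.argmax(masked))  # ties -> lowest index
    return chosen_thr, chosen_mask, max_voxel, int(grid.region_labels[max_voxel])


def run_cds(
    raw: np.ndarray,
    sr: float,
    catalog: EventCatalog,
    leadfield: LeadField,
    grid: SourceGrid,
    config: CdsConfig = CdsConfig(),
) -> CdsResult:
    """Full cDS analysis of one recording; deterministic given the seed."""
    filtered = bandpass(raw, sr, config.low_hz, config.high_hz)
    ied_w, bl_w = extract_windows(filtered, sr, catalog)
    if len(ied_w) < 3:
        raise ExclusionError("cases with one or two IEDs are excluded from cDS analysis")

    noise = estimate_noise_covariance(bl_w, shrinkage=config.shrinkage)
    kernel = compute_inverse_kernel(leadfield, noise, snr=config.snr)

    ied_maps = [
        time_average_map(apply_sloreta(kernel, w, kind="IED", window_id=f"IED{k}"))
        for k, w in enumerate(ied_w)
    ]
    bl_maps = [
        time_average_map(apply_sloreta(kernel, w, kind="BL", window_id=f"BL{k}"))
        for k, w in enumerate(bl_w)
    ]

    p = permutation_test(ied_maps, bl_maps, n_perm=config.n_perm, seed=config.seed)
    q = fdr_correct(p)
    x = _as_map_matrix(ied_maps)
    y = _as_map_matrix(bl_maps)
    mean_ied = CurrentMap(x.mean(axis=0), kind="IED", window_id="mean")
    # intensity = studentized IED-BL contrast: the spike-evoked excess in
    # units of its own sampling noise (the statistic map a reviewer views),
    # rather than raw power, which is dominated by the per-voxel noise floor
    contrast = x.mean(axis=0) - y.mean(axis=0)
    se = np.sqrt(
        x.var(axis=0, ddof=1) / x.shape[0] + y.var(axis=0, ddof=1) / y.shape[0]
    )
    t_map = contrast / np.maximum(se, 1e-30 + se.max() * 1e-12)
    thr, mask, max_voxel, region = focus_by_threshold(q, t_map, grid, config.ladder)
    return CdsResult(
        p_values=p,
        q_values=q,
        threshold_path=tuple(t for t in config.ladder if t >= thr),
        final_threshold=thr,
        significant_mask=mask,
        max_voxel=max_voxel,
        focus_region=region,
        mean_ied_map=mean_ied,
        contrast_map=contrast,
        t_map=t_map,
    )
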