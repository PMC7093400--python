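"""Spherical-conductor forward model for axial-gradiometer MEG.

All geometry lives in a right-handed head coordinate frame, in meters,
with the origin at the center of the (global) head sphere.  Sensors are
axial gradiometers: pairs of coaxial point coils separated by a fixed
baseline along the (radial) coil axis; the channel output is the field
difference between the two coils projected on that axis, in tesla.

The forward model is the closed-form magnetic field of a current dipole
inside a homogeneous conducting sphere (Sarvas).  Two well known
properties of that model are exploited throughout the package:

* a purely radial dipole is magnetically silent outside the sphere, so
  every 3-column lead-field block has rank at most 2;
* field strength decays with source depth, which is the physical reason
  deep epileptic foci are hard to localize.

An "overlapping spheres" variant assigns each channel its own best-fit
sphere center, estimated from scalp points weighted by angular proximity
to that channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

MU0_OVER_4PI = 1e-7  # T·m/A

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class ConfigurationError(ValueError):
    """Non-physical or inconsistent model geometry."""


class DegenerateFitError(ValueError):
    """Sphere fit is underdetermined (e.g. coplanar scalp points)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorArray:
    """Axial-gradiometer array: inner/outer coil positions and coil axes."""

    positions_inner: np.ndarray  # (n, 3) m
    positions_outer: np.ndarray  # (n, 3) m
    axes: np.ndarray             # (n, 3) unit coil normals
    baseline: float              # m

    def __post_init__(self) -> None:
        pi = np.asarray(self.positions_inner, dtype=float)
        po = np.asarray(self.positions_outer, dtype=float)
        ax = np.asarray(self.axes, dtype=float)
        object.__setattr__(self, "positions_inner", pi)
        object.__setattr__(self, "positions_outer", po)
        object.__setattr__(self, "axes", ax)
        if pi.shape != po.shape or pi.shape != ax.shape or pi.ndim != 2 or pi.shape[1] != 3:
            raise ConfigurationError("sensor arrays must share shape (n_channels, 3)")
        norms = np.linalg.norm(ax, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-12):
            raise ConfigurationError("coil axes must be unit vectors")
        if not np.allclose(po, pi + self.baseline * ax, rtol=0.0, atol=1e-12):
            raise ConfigurationError("outer coils must sit at inner + baseline * axis")

    @property
    def n_channels(self) -> int:
        return self.positions_inner.shape[0]


@dataclass(frozen=True)
class SphereModel:
    """Conducting sphere: global center/radius, optional per-channel centers."""

    center: np.ndarray  # (3,) m
    radius: float       # m
    per_channel_centers: np.ndarray | None = None  # (n_channels, 3) m

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        object.__setattr__(self, "center", c)
        if not self.radius > 0:
            raise ConfigurationError("sphere radius must be positive")
        if self.per_channel_centers is not None:
            pcc = np.asarray(self.per_channel_centers, dtype=float)
            if pcc.ndim != 2 or pcc.shape[1] != 3:
                raise ConfigurationError("per_channel_centers must be (n_channels, 3)")
            object.__setattr__(self, "per_channel_centers", pcc)

    def channel_centers(self, n_channels: int) -> np.ndarray:
        """Centers used per channel: overlapping spheres if present, else global."""
        if self.per_channel_centers is not None:
            if self.per_channel_centers.shape[0] != n_channels:
                raise ConfigurationError("per_channel_centers length mismatch")
            return self.per_channel_centers
        return np.broadcast_to(self.center, (n_channels, 3))


@dataclass(frozen=True)
class SourceGrid:
    """Volume source space: dipole locations on a cubic lattice inside the sphere.

    ``region_labels`` partition the grid into 1..K contiguous parcels that
    stand in for an anatomical sublobar atlas (default K = 34).
    """

    voxel_positions: np.ndarray  # (V, 3) m
    spacing: float               # m
    region_labels: np.ndarray    # (V,) int in 1..K
    eccentricities: np.ndarray   # (V,) m, distance from global sphere center

    def __post_init__(self) -> None:
        vp = np.asarray(self.voxel_positions, dtype=float)
        rl = np.asarray(self.region_labels, dtype=int)
        ec = np.asarray(self.eccentricities, dtype=float)
        object.__setattr__(self, "voxel_positions", vp)
        object.__setattr__(self, "region_labels", rl)
        object.__setattr__(self, "eccentricities", ec)
        if not self.spacing > 0:
            raise ConfigurationError("grid spacing must be positive")
        if rl.min(initial=1) < 1:
            raise ConfigurationError("region labels must be >= 1")

    @property
    def n_voxels(self) -> int:
        return self.voxel_positions.shape[0]

    @property
    def n_regions(self) -> int:
        return int(self.region_labels.max())


@dataclass(frozen=True)
class LeadField:
    """Forward operator, n_channels x (3 * n_voxels), tesla per A·m.

    Columns ``3v, 3v+1, 3v+2`` hold the x/y/z unit-moment fields of voxel v.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] % 3 != 0:
            raise ConfigurationError("lead field must be (n_channels, 3*n_voxels)")
        if not np.all(np.isfinite(m)):
            raise ConfigurationError("lead field contains non-finite entries")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1] // 3

    def block(self, voxel: int) -> np.ndarray:
        """(n_channels, 3) gain block of one voxel."""
        return self.matrix[:, 3 * voxel : 3 * voxel + 3]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def build_sensor_array(
    n_channels: int = 160,
    helmet_radius: float = 0.12,
    cap_fraction: float = 0.55,
    baseline: float = 0.05,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> SensorArray:
    """Place axial gradiometers on a spherical-cap helmet.

    Channels are laid out by a deterministic equal-area (golden-angle)
    spiral over the upper cap covering ``cap_fraction`` of the full sphere
    area.  Coil axes point radially outward from the helmet center, and the
    outer coil of each gradiometer sits ``baseline`` meters further out
    along the axis.
    """
    if n_channels < 4:
        raise ConfigurationError("need at least 4 channels")
    if not (0.0 < cap_fraction <= 1.0):
        raise ConfigurationError("cap_fraction must lie in (0, 1]")
    if helmet_radius <= 0 or baseline <= 0:
        raise ConfigurationError("helmet_radius and baseline must be positive")

    center = np.asarray(center, dtype=float).reshape(3)
    z_min = 1.0 - 2.0 * cap_fraction
    i = np.arange(n_channels)
    z = 1.0 - (i + 0.5) / n_channels * (1.0 - z_min)  # equal-area in z
    phi = i * _GOLDEN_ANGLE
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    axes = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    inner = center + helmet_radius * axes
    outer = inner + baseline * axes
    return SensorArray(inner, outer, axes, baseline)


def build_source_grid(
    sphere: SphereModel,
    spacing: float = 0.007,
    n_regions: int = 34,
    margin: float = 0.005,
) -> SourceGrid:
    """Cubic lattice of source voxels clipped strictly inside the sphere.

    The lattice is offset half a spacing from the sphere center so no voxel
    falls exactly at the center (where the spherical forward model is
    singular).  Region labels 1..K are assigned by nearest of K seed voxels
    chosen by deterministic farthest-point sampling on the grid — a
    synthetic stand-in for a sublobar anatomical atlas.
    """
    if spacing <= 0:
        raise ConfigurationError("spacing must be positive")
    if n_regions < 1:
        raise ConfigurationError("n_regions must be >= 1")
    if margin < 0 or margin >= sphere.radius:
        raise ConfigurationError("margin must lie in [0, radius)")

    rmax = sphere.radius - margin
    n_half = int(np.ceil(rmax / spacing)) + 1
    coords = (np.arange(-n_half, n_half) + 0.5) * spacing
    xx, yy, zz = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    ecc = np.linalg.norm(pts, axis=1)
    keep = ecc < rmax
    pts = pts[keep] + sphere.center
    ecc = ecc[keep]
    if pts.shape[0] < n_regions:
        raise ConfigurationError(
            f"only {pts.shape[0]} voxels survive clipping; need >= {n_regions} regions"
        )

    labels = _farthest_point_labels(pts, n_regions)
    return SourceGrid(pts, spacing, labels, ecc)


def _farthest_point_labels(pts: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point seeds, then nearest-seed labels 1..k."""
    n = pts.shape[0]
    seeds = [0]
    mindist = np.linalg.norm(pts - pts[0], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(mindist))  # argmax ties -> lowest index
        seeds.append(nxt)
        mindist = np.minimum(mindist, np.linalg.norm(pts - pts[nxt], axis=1))
    d = cdist(pts, pts[seeds])
    return np.argmin(d, axis=1).astype(int) + 1


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _sarvas_gain(source_pos: np.ndarray, field_pts: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(m, 3, 3) matrices M with B = M @ Q at each field point.

    ``field_pts`` and ``centers`` are (m, 3); each row may use its own
    sphere center (overlapping-spheres variant).
    """
    r = field_pts - centers          # (m, 3)
    rq = source_pos[None, :] - centers  # (m, 3)
    a = r - rq
    an = np.linalg.norm(a, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(an < 1e-12):
        raise ConfigurationError("field point coincides with source")
    adotr = np.einsum("ij,ij->i", a, r)
    rqdotr = np.einsum("ij,ij->i", rq, r)
    f = an * (rn * an + rn**2 - rqdotr)
    if np.any(np.abs(f) < 1e-30):
        raise ConfigurationError("singular Sarvas denominator (source on sensor ray?)")
    gradf = (
        (an**2 / rn + adotr / an + 2.0 * an + 2.0 * rn)[:, None] * r
        - (an + 2.0 * rn + adotr / an)[:, None] * rq
    )
    # B = mu0/4pi/F^2 * (F*A - (A.r) gradF) with A = Q x rq, linear in Q.
    # A = C @ Q where C = -[rq]_x (cross-product matrix).
    m = field_pts.shape[0]
    cmat = np.zeros((m, 3, 3))
    cmat[:, 0, 1] = rq[:, 2]
    cmat[:, 0, 2] = -rq[:, 1]
    cmat[:, 1, 0] = -rq[:, 2]
    cmat[:, 1, 2] = rq[:, 0]
    cmat[:, 2, 0] = rq[:, 1]
    cmat[:, 2, 1] = -rq[:, 0]
    # (F*I - gradF r^T) acting on A
    lin = f[:, None, None] * np.eye(3)[None] - gradf[:, :, None] * r[:, None, :]
    gain = MU0_OVER_4PI / f[:, None, None] ** 2 * np.einsum("mij,mjk->mik", lin, cmat)
    return gain


def _check_source_inside(source_pos: np.ndarray, sphere: SphereModel) -> None:
    ecc = np.linalg.norm(np.asarray(source_pos, float) - sphere.center)
    if ecc >= sphere.radius:
        raise ConfigurationError("source must lie strictly inside the sphere")
    if ecc < 1e-9:
        raise ConfigurationError("source at sphere center is magnetically silent/singular")


def gradiometer_gain(
    source_pos: Sequence[float], sphere: SphereModel, sensors: SensorArray
) -> np.ndarray:
    """(n_channels, 3) gain: channel output per unit moment along x/y/z."""
    source_pos = np.asarray(source_pos, dtype=float).reshape(3)
    _check_source_inside(source_pos, sphere)
    centers = sphere.channel_centers(sensors.n_channels)
    inner_ecc = np.linalg.norm(sensors.positions_inner - centers, axis=1)
    if np.any(inner_ecc <= sphere.radius):
        raise ConfigurationError("sensors must lie strictly outside the sphere")
    g_in = _sarvas_gain(source_pos, sensors.positions_inner, centers)
    g_out = _sarvas_gain(source_pos, sensors.positions_outer, centers)
    # project on coil axis, difference of the two coils
    return np.einsum("mi,mij->mj", sensors.axes, g_in - g_out)


def dipole_field(
    source_pos: Sequence[float],
    moment: Sequence[float],
    sphere: SphereModel,
    sensors: SensorArray,
) -> np.ndarray:
    """Axial-gradiometer signal (tesla) of one current dipole.

    Per channel the output is ``B(inner)·n − B(outer)·n`` with B from the
    spherical-conductor closed form, using the channel's own sphere center
    when the overlapping-spheres variant is active.
    """
    moment = np.asarray(moment, dtype=float).reshape(3)
    return gradiometer_gain(source_pos, sphere, sensors) @ moment


def compute_leadfield(grid: SourceGrid, sensors: SensorArray, sphere: SphereModel) -> LeadField:
    """Assemble the lead field by stacking unit-moment gains voxel by voxel."""
    mat = np.empty((sensors.n_channels, 3 * grid.n_voxels))
    for v in range(grid.n_voxels):
        mat[:, 3 * v : 3 * v + 3] = gradiometer_gain(grid.voxel_positions[v], sphere, sensors)
    return LeadField(mat)


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------


def _fit_sphere_lsq(points: np.ndarray, weights: np.ndarray | None = None) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit. Returns (center, radius, residual)."""
    p = np.asarray(points, dtype=float)
    a = np.column_stack([2.0 * p, np.ones(p.shape[0])])
    b = np.einsum("ij,ij->i", p, p)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        a = a * w[:, None]
        b = b * w
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise DegenerateFitError("scalp points are degenerate (coplanar or too few)")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateFitError("sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))
    resid = float(np.sqrt(np.mean((np.linalg.norm(p - center, axis=1) - radius) ** 2)))
    return center, radius, resid


def fit_overlapping_spheres(
    sensors: SensorArray,
    scalp_points: np.ndarray,
    sigma_deg: float = 30.0,
) -> SphereModel:
    """Global + per-channel sphere fit to digitized scalp points.

    The global sphere is an algebraic least-squares fit to all points.  Each
    channel then refits a sphere with points weighted by
    ``exp(-angular_distance / sigma)``, where the angle is measured from the
    global center between the scalp point and the channel's inner coil.  On
    a perfectly spherical scalp every per-channel center coincides with the
    global one.
    """
    scalp_points = np.asarray(scalp_points, dtype=float)
    if scalp_points.ndim != 2 or scalp_points.shape[1] != 3 or scalp_points.shape[0] < 4:
        raise DegenerateFitError("need >= 4 scalp points of shape (m, 3)")
    center, radius, _ = _fit_sphere_lsq(scalp_points)

    sigma = np.deg2rad(sigma_deg)
    pdir = scalp_points - center
    pdir /= np.linalg.norm(pdir, axis=1, keepdims=True)
    cdir = sensors.positions_inner - center
    cdir /= np.linalg.norm(cdir, axis=1, keepdims=True)
    cosang = np.clip(pdir @ cdir.T, -1.0, 1.0)  # (m_points, n_channels)
    ang = np.arccos(cosang)
    weights = np.exp(-ang / sigma)

    per_centers = np.empty((sensors.n_channels, 3))
    for ch in range(sensors.n_channels):
        c_ch, _, _ = _fit_sphere_lsq(scalp_points, weights[:, ch])
        per_centers[ch] = c_ch
    return SphereModel(center=center, radius=radius, per_channel_centers=per_centers)


def global_fit_residual(scalp_points: np.ndarray) -> float:
    """RMS radial residual of the single global sphere fit."""
    _, _, resid = _fit_sphere_lsq(np.asarray(scalp_points, dtype=float))
    return resid
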