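"""CTD calibration, water-mass classification, stratification, and front geometry.

Conventions used throughout: depth is in metres, positive down, strictly
increasing along a profile; latitudes in degrees north; conservative
temperature Θ in °C; absolute salinity SA in g kg⁻¹; potential density
anomaly σθ in kg m⁻³. Sections are latitude × depth grids with a validity
mask (no extrapolation beyond the profile hull).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0
RHO_0 = 1025.0  # reference density for N², kg m⁻³
GRAVITY = 9.81  # m s⁻²


class WaterMass(enum.Enum):
    """Rule-based water-mass classes in (SA, Θ, σθ) space.

    The classes partition the Arctic shelf-front T/S space: Atlantic-origin
    water (warm, saline), its cooled modification, Polar water (cold, fresh,
    light), warm Polar water, an intermediate mixing class, and cold dense
    bottom water (CBSDW).
    """

    POLAR = "Polar water"
    WARM_POLAR = "Warm Polar water"
    ATLANTIC = "Atlantic water"
    MODIFIED_ATLANTIC = "Modified Atlantic water"
    INTERMEDIATE = "Intermediate water"
    CBSDW = "Cold Barents Sea Dense Water"
    UNCLASSIFIED = "Unclassified"


@dataclass
class CtdProfile:
    """A single CTD cast: depth series of Θ, SA and σθ at one position."""

    station: str
    lat: float
    lon: float
    depth: np.ndarray  # m, positive down, strictly increasing
    theta: np.ndarray  # conservative temperature, °C
    sa: np.ndarray  # absolute salinity, g kg⁻¹
    sigma_theta: np.ndarray  # potential density anomaly, kg m⁻³
    time: str | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.sa = np.asarray(self.sa, dtype=float)
        self.sigma_theta = np.asarray(self.sigma_theta, dtype=float)
        n = self.depth.size
        if not (self.theta.size == self.sa.size == self.sigma_theta.size == n):
            raise ValueError("profile vectors must have equal length")
        if n >= 2 and not np.all(np.diff(self.depth) > 0):
            raise ValueError("depth must be strictly increasing")
        if np.any(self.sa <= 0):
            raise ValueError("absolute salinity must be positive")


@dataclass
class CtdSection:
    """Profiles interpolated onto a latitude × depth grid.

    Fields are (n_lat, n_depth) arrays; ``valid`` is False outside the
    convex hull of the contributing profiles (masked cells carry NaN).
    """

    lat: np.ndarray  # deg N, monotone increasing
    depth: np.ndarray  # m, monotone increasing
    theta: np.ndarray
    sa: np.ndarray
    sigma_theta: np.ndarray
    valid: np.ndarray

    def band_mean_theta(self, zmin: float, zmax: float) -> np.ndarray:
        """Mean Θ over the depth band [zmin, zmax] per latitude (NaN if empty)."""
        sel = (self.depth >= zmin) & (self.depth <= zmax)
        if not sel.any():
            raise ValueError(f"no depth levels inside band [{zmin}, {zmax}] m")
        return self.band_mean("theta", zmin, zmax)

    def band_mean(self, var: str, zmin: float, zmax: float) -> np.ndarray:
        sel = (self.depth >= zmin) & (self.depth <= zmax)
        if not sel.any():
            raise ValueError(f"no depth levels inside band [{zmin}, {zmax}] m")
        ok = self.valid[:, sel]
        vals = np.where(ok, getattr(self, var)[:, sel], 0.0)
        cnt = ok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, vals.sum(axis=1) / np.maximum(cnt, 1),
                            np.nan)


@dataclass
class FrontFix:
    """Daily geometry of the front system: surface/subsurface front and ice edges.

    Any latitude may be None — e.g. the surface thermal front is absent in
    summer when the surface layer is uniformly warm.
    """

    date: str
    surface_front_lat: float | None = None
    subsurface_front_lat: float | None = None
    open_ice_lat: float | None = None
    closed_ice_lat: float | None = None


@dataclass
class StabilityGrid:
    """Latitude × depth grid of Brunt–Väisälä N² (s⁻²) with optional class bins."""

    lat: np.ndarray
    depth_mid: np.ndarray
    n2: np.ndarray
    bins: np.ndarray | None = None  # integer class per cell if thresholds given


# ---------------------------------------------------------------------------
# calibration


def calibrate_offsets(
    reference: CtdProfile,
    target: CtdProfile,
    stable_window: tuple[float, float],
    max_gradient: float = 0.02,
) -> tuple[float, float]:
    """Estimate constant (ΔT, ΔS) offsets of ``target`` against ``reference``.

    Cross-instrument calibration: within a depth window chosen in a stable
    water layer, the offset is the mean difference reference − target of Θ
    and SA. ``max_gradient`` (°C per m) guards against picking a window in a
    stratified layer where sensor depth mismatch would alias into the offset.
    """
    zlo, zhi = stable_window
    if zlo >= zhi:
        raise ValueError("stable window must have zlo < zhi")
    for prof, name in ((reference, "reference"), (target, "target")):
        if prof.depth.min() > zlo or prof.depth.max() < zhi:
            raise ValueError(f"{name} profile does not cover the window")
    sel = (reference.depth >= zlo) & (reference.depth <= zhi)
    if sel.sum() >= 2:
        grad = np.gradient(reference.theta[sel], reference.depth[sel])
        if np.nanmax(np.abs(grad)) > max_gradient:
            raise ValueError(
                "window is not a stable layer: |dΘ/dz| exceeds "
                f"{max_gradient} °C/m"
            )
    t_tgt = np.interp(reference.depth[sel], target.depth, target.theta)
    s_tgt = np.interp(reference.depth[sel], target.depth, target.sa)
    dt = float(np.mean(reference.theta[sel] - t_tgt))
    ds = float(np.mean(reference.sa[sel] - s_tgt))
    return dt, ds


def apply_offsets(profile: CtdProfile, dt: float, ds: float) -> CtdProfile:
    """Return a copy of ``profile`` with the calibration offsets added."""
    return CtdProfile(
        station=profile.station,
        lat=profile.lat,
        lon=profile.lon,
        depth=profile.depth.copy(),
        theta=profile.theta + dt,
        sa=profile.sa + ds,
        sigma_theta=profile.sigma_theta.copy(),
        time=profile.time,
    )


# ---------------------------------------------------------------------------
# water-mass classification

SA_ATLANTIC = 35.06  # g kg⁻¹ salinity limit separating Atlantic-origin water
SIGMA_DENSE = 27.97  # kg m⁻³ density limit separating dense bottom classes
THETA_CBSDW = -1.1  # °C


def classify_water_mass(sa, theta, sigma_theta):
    """Classify (SA, Θ, σθ) into water masses; vectorised, total, deterministic.

    Rules (each sample gets exactly one class):

    * Θ > 2 °C and SA ≥ 35.06       → ATLANTIC
    * 0 < Θ ≤ 2 °C and SA ≥ 35.06   → MODIFIED_ATLANTIC
    * Θ > 0 °C and SA < 35.06       → WARM_POLAR
    * Θ ≤ 0 °C and σθ ≤ 27.97       → POLAR
    * Θ ≤ 0 °C and σθ > 27.97:
        Θ > −1.1 °C → INTERMEDIATE, else CBSDW

    The cold classes overlap in their defining table (Θ ≤ 0 alone satisfies
    several rows); they are made exclusive by splitting on density first and
    then temperature, so the classification is a total function.

    Returns a ``WaterMass`` for scalars, an object array for array input.
    """
    sa = np.asarray(sa, dtype=float)
    theta = np.asarray(theta, dtype=float)
    sigma_theta = np.asarray(sigma_theta, dtype=float)
    if np.any(~np.isfinite(sa)) or np.any(~np.isfinite(theta)) or np.any(
        ~np.isfinite(sigma_theta)
    ):
        raise ValueError("non-finite input to water-mass classification")
    scalar = sa.ndim == 0
    sa, theta, sigma_theta = np.atleast_1d(sa, theta, sigma_theta)

    out = np.full(sa.shape, WaterMass.UNCLASSIFIED, dtype=object)
    warm = theta > 0
    out[warm & (theta > 2) & (sa >= SA_ATLANTIC)] = WaterMass.ATLANTIC
    out[warm & (theta <= 2) & (sa >= SA_ATLANTIC)] = WaterMass.MODIFIED_ATLANTIC
    out[warm & (sa < SA_ATLANTIC)] = WaterMass.WARM_POLAR
    cold = ~warm
    out[cold & (sigma_theta <= SIGMA_DENSE)] = WaterMass.POLAR
    dense = cold & (sigma_theta > SIGMA_DENSE)
    out[dense & (theta > THETA_CBSDW)] = WaterMass.INTERMEDIATE
    out[dense & (theta <= THETA_CBSDW)] = WaterMass.CBSDW
    if scalar:
        return out[()]if out.ndim == 0 else out[0]
    return out


# ---------------------------------------------------------------------------
# stratification


def brunt_vaisala(
    profile: CtdProfile, gravity: float = GRAVITY, rho0: float = RHO_0
) -> tuple[np.ndarray, np.ndarray]:
    """Buoyancy frequency squared N² between adjacent depth levels.

    N²(z_mid) = (g/ρ₀)·Δσθ/Δz with z positive down, so density increasing
    with depth (stable stratification) gives N² > 0. Returns
    (midpoint depths, N² in s⁻²), both length n−1.
    """
    if profile.depth.size < 2:
        raise ValueError("need at least two depth levels")
    dz = np.diff(profile.depth)
    if np.any(dz == 0):
        raise ValueError("duplicate depths")
    n2 = (gravity / rho0) * np.diff(profile.sigma_theta) / dz
    z_mid = 0.5 * (profile.depth[:-1] + profile.depth[1:])
    return z_mid, n2


def stability_section(
    section: CtdSection,
    thresholds: Sequence[float] | None = None,
    gravity: float = GRAVITY,
    rho0: float = RHO_0,
) -> StabilityGrid:
    """N² on a section, between adjacent depth levels per latitude.

    ``thresholds`` optionally bins N² into stability classes (class i when
    thresholds[i-1] <= N² < thresholds[i]); the bin edges are configuration,
    no defaults are claimed.
    """
    dz = np.diff(section.depth)
    n2 = (gravity / rho0) * np.diff(section.sigma_theta, axis=1) / dz
    ok = section.valid[:, :-1] & section.valid[:, 1:]
    n2 = np.where(ok, n2, np.nan)
    z_mid = 0.5 * (section.depth[:-1] + section.depth[1:])
    bins = None
    if thresholds is not None:
        bins = np.digitize(n2, np.asarray(thresholds, dtype=float))
        bins = np.where(ok, bins, -1)
    return StabilityGrid(lat=section.lat, depth_mid=z_mid, n2=n2, bins=bins)


# ---------------------------------------------------------------------------
# sections


def interpolate_section(
    profiles: Sequence[CtdProfile],
    lat_grid: np.ndarray,
    depth_grid: np.ndarray,
) -> CtdSection:
    """Interpolate profiles onto a latitude × depth grid (no extrapolation).

    Each profile is first interpolated onto the common depth grid (valid only
    within its own depth range), then fields are linearly interpolated in
    latitude between adjacent stations. Cells outside the hull — beyond the
    outermost stations, or below the shallower of two bracketing casts — are
    masked.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    lats = np.array([p.lat for p in profiles], dtype=float)
    if np.unique(lats).size < 2:
        raise ValueError("all profiles at a single latitude")
    order = np.argsort(lats)
    profiles = [profiles[i] for i in order]
    lats = lats[order]
    lat_grid = np.asarray(lat_grid, dtype=float)
    depth_grid = np.asarray(depth_grid, dtype=float)

    nz = depth_grid.size
    cols_t = np.full((len(profiles), nz), np.nan)
    cols_s = np.full((len(profiles), nz), np.nan)
    cols_d = np.full((len(profiles), nz), np.nan)
    for i, p in enumerate(profiles):
        inside = (depth_grid >= p.depth.min()) & (depth_grid <= p.depth.max())
        cols_t[i, inside] = np.interp(depth_grid[inside], p.depth, p.theta)
        cols_s[i, inside] = np.interp(depth_grid[inside], p.depth, p.sa)
        cols_d[i, inside] = np.interp(depth_grid[inside], p.depth, p.sigma_theta)

    shape = (lat_grid.size, nz)
    theta = np.full(shape, np.nan)
    sa = np.full(shape, np.nan)
    sig = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    inside_lat = (lat_grid >= lats[0]) & (lat_grid <= lats[-1])
    idx = np.clip(np.searchsorted(lats, lat_grid[inside_lat], side="right") - 1,
                  0, len(profiles) - 2)
    frac = (lat_grid[inside_lat] - lats[idx]) / (lats[idx + 1] - lats[idx])
    frac = frac[:, None]
    both = np.isfinite(cols_t[idx]) & np.isfinite(cols_t[idx + 1])
    theta[inside_lat] = (1 - frac) * cols_t[idx] + frac * cols_t[idx + 1]
    sa[inside_lat] = (1 - frac) * cols_s[idx] + frac * cols_s[idx + 1]
    sig[inside_lat] = (1 - frac) * cols_d[idx] + frac * cols_d[idx + 1]
    valid[inside_lat] = both
    theta[~valid] = np.nan
    sa[~valid] = np.nan
    sig[~valid] = np.nan
    return CtdSection(lat=lat_grid, depth=depth_grid, theta=theta, sa=sa,
                      sigma_theta=sig, valid=valid)


# ---------------------------------------------------------------------------
# front localisation


def _max_gradient_latitude(
    lat: np.ndarray,
    values: np.ndarray,
    resolution: float,
    min_gradient: float,
) -> float | None:
    """Latitude of the strongest change of a latitude series.

    The series is linearly interpolated onto a regular grid at ``resolution``
    degrees; the front is the midpoint of the adjacent-pair interval with the
    largest |Δvalue|, ties broken toward the lowest latitude. Returns None
    when the largest step is below ``min_gradient`` (no discernible front).
    """
    ok = np.isfinite(values)
    lat, values = lat[ok], values[ok]
    if lat.size < 2:
        raise ValueError("need at least two latitudes with data")
    n = int(np.floor((lat[-1] - lat[0]) / resolution)) + 1
    grid = lat[0] + resolution * np.arange(n)
    interp = np.interp(grid, lat, values)
    steps = np.abs(np.diff(interp))
    if steps.size == 0 or steps.max() < min_gradient:
        return None
    i = int(np.argmax(steps))  # argmax takes the first (lowest-latitude) tie
    return float(0.5 * (grid[i] + grid[i + 1]))


def locate_subsurface_front(
    section: CtdSection,
    band: tuple[float, float] = (45.0, 55.0),
    resolution: float = 0.01,
    min_gradient: float = 1e-6,
) -> float | None:
    """Latitude of the subsurface thermal front from a CTD section.

    Θ is averaged over the ``band`` depth window (default 45–55 m, below the
    surface mixed layer), interpolated across latitude at ``resolution``
    (default 0.01°), and the front is placed at the strongest adjacent-point
    temperature change. Returns None if no step exceeds ``min_gradient``.
    """
    means = section.band_mean_theta(*band)
    if not np.isfinite(means).any():
        raise ValueError("depth band entirely masked")
    return _max_gradient_latitude(section.lat, means, resolution, min_gradient)


def locate_surface_front(
    lat: np.ndarray,
    sst: np.ndarray,
    resolution: float = 0.01,
    min_gradient: float = 0.05,
) -> float | None:
    """Latitude of the surface thermal front from an SST(latitude) series.

    Same strongest-gradient rule as the subsurface front. Returns None when
    the largest step is below ``min_gradient`` °C — the summer case where the
    surface layer is uniformly warm and no surface front is discernible.
    """
    lat = np.asarray(lat, dtype=float)
    sst = np.asarray(sst, dtype=float)
    if lat.size < 3:
        raise ValueError("need at least three SST points")
    if np.any(np.diff(lat) <= 0):
        raise ValueError("latitudes must be strictly increasing")
    return _max_gradient_latitude(lat, sst, resolution, min_gradient)


def distance_to_feature(
    lat: float, lon: float, feature_lat: float, signed: bool = True
) -> float:
    """Great-circle distance (km) from a point to a latitude feature.

    Haversine distance (R = 6371 km) between (lat, lon) and
    (feature_lat, lon); positive when the point lies north of the feature
    (set ``signed=False`` for magnitudes). A meridional arc, so this reduces
    to R·|Δlat|, but the haversine form is kept for clarity and symmetry
    with future 2-D features.
    """
    for x in (lat, feature_lat):
        if not np.isfinite(x) or abs(x) > 90:
            raise ValueError("latitude outside [-90, 90]")
    phi1, phi2 = np.radians(lat), np.radians(feature_lat)
    a = np.sin((phi2 - phi1) / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    if signed:
        return float(np.sign(lat - feature_lat) * d)
    return float(d)
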