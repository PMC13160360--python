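"""Synthetic survey scenes with planted ground truth.

Generates the three data streams of a front-crossing survey — a two-water-
mass CTD transect with a logistic thermal front, three-frequency echograms
with TVG-amplified noise floors, impulse pings, frequency-differentiated
fish schools and zooplankton layers over a seabed, and multinomial trawl
communities — so that every downstream stage (front localisation, noise
removal, ΔMVBS classification, NASC integration, community statistics) can
be tested against known truth without any survey data.

All randomness flows from one seed; each simulator draws from its own
derived stream, so adding one simulator call never shifts another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .echogram import EchogramGrid, absorption_coefficient
from .hydrography import CtdSection

# linear equation of state used for the synthetic σθ field; coefficients
# chosen so the scene's end-member waters land in their intended classes
EOS_SIGMA0 = 28.10  # σθ at Θ=0, SA=35 (kg m⁻³)
EOS_BETA = 0.80  # haline contraction, kg m⁻³ per g kg⁻¹
EOS_ALPHA = 0.060  # thermal expansion, kg m⁻³ per °C


def sigma_theta_linear(theta, sa):
    """σθ from the simulator's linear equation of state."""
    return EOS_SIGMA0 + EOS_BETA * (np.asarray(sa) - 35.0) \
        - EOS_ALPHA * np.asarray(theta)


@dataclass
class Target:
    """A painted scatterer patch: a fish school or zooplankton layer.

    ``sv38_db`` is the patch's Sv at 38 kHz; the other frequencies follow
    the configured frequency-response offsets Δ₁₈₋₃₈ and Δ₁₂₀₋₃₈. Fish have
    Δ₁₂₀₋₃₈ ≤ 5 dB, macrozooplankton Δ₁₂₀₋₃₈ > 10 dB.
    """

    kind: str  # "fish" | "zooplankton"
    lat_range: tuple[float, float]
    depth_range: tuple[float, float]  # m
    sv38_db: float
    d18_db: float = 0.0  # Δ18−38
    d120_db: float = 0.0  # Δ120−38


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey scene (defaults = desk-scale survey).

    The default transect is 600 pings at 0.1 nmi spacing crossing a front
    at 77.2° N, 250 m deep with 1 m bins over a 240 m seabed — the survey
    geometry at desk scale. Water-mass end members put Atlantic water south
    of the front and Polar water north of it.
    """

    seed: int = 0
    season: str = "spring"
    # transect
    lat_south: float = 76.7
    lat_north: float = 77.7
    n_pings: int = 600
    ping_spacing_nmi: float = 0.1
    ping_interval_s: float = 1.0
    max_depth_m: float = 250.0
    depth_bin_m: float = 1.0
    lon: float = 30.0
    # front
    front_lat: float = 77.2
    front_width_deg: float = 0.03
    t_south_c: float = 5.0
    t_north_c: float = -1.0
    s_south_gkg: float = 35.2
    s_north_gkg: float = 34.4
    mixed_layer_m: float = 20.0
    cold_surface_arm_deg: float = 0.0  # southward surface overhang of cold water
    ctd_noise_t: float = 0.002  # °C sensor noise sd (SBE-class accuracy)
    ctd_noise_s: float = 0.001  # g kg⁻¹
    n_lat_grid: int = 151
    n_depth_grid: int = 251  # 1 m bins, the standard CTD bin average
    # acoustics
    freqs_khz: tuple[float, ...] = (18.0, 38.0, 120.0)
    noise_floor_db: dict = field(default_factory=lambda: {
        18.0: -132.0, 38.0: -130.0, 120.0: -127.0})
    impulse_fraction: float = 0.02
    impulse_amplitude_db: float = 25.0
    seabed_depth_m: float = 240.0
    seabed_sv_db: float = -15.0
    surface_noise_depth_m: float = 10.0
    surface_noise_db: float = -55.0
    water_temp_c: float = 3.0
    water_sal_psu: float = 35.0
    targets: list = field(default_factory=lambda: [
        Target("fish", (76.75, 77.00), (40.0, 90.0), -57.0,
               d18_db=2.0, d120_db=-2.0),
        Target("fish", (76.90, 77.45), (160.0, 210.0), -62.0,
               d18_db=1.0, d120_db=-3.0),
        Target("zooplankton", (77.25, 77.60), (30.0, 100.0), -72.0,
               d18_db=-8.0, d120_db=13.0),
    ])
    # trawl community
    n_stations: int = 16
    draw_size: int = 300
    mouth_area_m2: float = 80.0
    tow_distance_m: float = 1000.0
    community: dict = field(default_factory=lambda: {
        "atlantic": {"capelin": 0.55, "polar_cod": 0.10, "krill": 0.20,
                     "amphipod": 0.05, "pteropod": 0.10},
        "polar": {"capelin": 0.15, "polar_cod": 0.45, "krill": 0.10,
                  "amphipod": 0.25, "pteropod": 0.05},
    })
    effect_size: float = 1.0  # 0 = identical communities (null)
    taxon_unit_weight_g: dict = field(default_factory=lambda: {
        "capelin": 3.0, "polar_cod": 5.0, "krill": 0.1,
        "amphipod": 0.05, "pteropod": 0.02})

    def validate(self) -> None:
        if self.n_pings < 2:
            raise ValueError("need at least two pings")
        if self.lat_south >= self.lat_north:
            raise ValueError("degenerate transect")
        if not 0.0 <= self.impulse_fraction <= 1.0:
            raise ValueError("impulse fraction outside [0, 1]")
        if self.depth_bin_m <= 0 or self.max_depth_m <= 0:
            raise ValueError("depth bins must be positive and increasing")
        if not self.front_lat <= self.lat_north or not \
                self.front_lat >= self.lat_south:
            raise ValueError("front latitude outside the transect")
        for t in self.targets:
            if t.kind == "fish" and t.d120_db > 5.0:
                raise ValueError(f"fish target with Δ120−38 = {t.d120_db} > 5")
            if t.kind == "zooplankton" and t.d120_db <= 10.0:
                raise ValueError(
                    f"zooplankton target with Δ120−38 = {t.d120_db} <= 10")
            if t.depth_range[1] > self.seabed_depth_m:
                raise ValueError("target extends below the seabed")
        for vec in self.community.values():
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ValueError("community vectors must sum to 1")
        if self.mouth_area_m2 <= 0 or self.tow_distance_m <= 0:
            raise ValueError("negative or zero trawled volume")


@dataclass
class TruthBundle:
    """Planted ground truth aligned with the simulated grids."""

    front_lat: float
    class_mask: np.ndarray | None = None  # (n_pings, n_bins) 0/1/2 codes
    noise_floor_db: dict = field(default_factory=dict)
    impulse_pings: dict = field(default_factory=dict)  # freq -> indices
    community: pd.DataFrame | None = None  # station truth


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


# ---------------------------------------------------------------------------
# CTD transect


def simulate_ctd_transect(config: SimulationConfig
                          ) -> tuple[CtdSection, TruthBundle]:
    """A two-water-mass section with a logistic thermal front.

    Below the mixed layer T(lat, z) = T_south + ΔT·σ((lat − lat_front)/w);
    salinity is analogous. A positive ``cold_surface_arm_deg`` shifts the
    front south within the mixed layer, overhanging cold surface water over
    the warm layer. Small seeded Gaussian sensor noise is added; σθ comes
    from the simulator's linear equation of state.
    """
    config.validate()
    rng = _rng(config, 1)
    lat = np.linspace(config.lat_south, config.lat_north, config.n_lat_grid)
    depth = np.linspace(0.0, config.max_depth_m, config.n_depth_grid)
    w = max(config.front_width_deg, 1e-9)

    front = np.full(depth.size, config.front_lat)
    front[depth < config.mixed_layer_m] -= config.cold_surface_arm_deg
    x = (lat[:, None] - front[None, :]) / w
    sig = _logistic(x)
    theta = config.t_south_c + (config.t_north_c - config.t_south_c) * sig
    sa = config.s_south_gkg + (config.s_north_gkg - config.s_south_gkg) * sig
    theta = theta + rng.normal(0.0, config.ctd_noise_t, theta.shape)
    sa = sa + rng.normal(0.0, config.ctd_noise_s, sa.shape)
    sigma = sigma_theta_linear(theta, sa)
    section = CtdSection(lat=lat, depth=depth, theta=theta, sa=sa,
                         sigma_theta=sigma,
                         valid=np.ones(theta.shape, dtype=bool))
    return section, TruthBundle(front_lat=config.front_lat)


# ---------------------------------------------------------------------------
# echograms


def _target_mask(config: SimulationConfig, target: Target,
                 lat: np.ndarray, depth_centers: np.ndarray) -> np.ndarray:
    in_lat = (lat >= target.lat_range[0]) & (lat <= target.lat_range[1])
    in_z = (depth_centers >= target.depth_range[0]) & \
        (depth_centers < target.depth_range[1])
    return in_lat[:, None] & in_z[None, :]


def simulate_echograms(config: SimulationConfig
                       ) -> tuple[dict[float, EchogramGrid], TruthBundle]:
    """Three-frequency Sv grids: targets + seabed + range-amplified noise.

    Per frequency, Sv = 10·log₁₀(10^(signal/10) + 10^(noise/10)) with
    Sv_noise(r) = N₀ + 20·log₁₀r + 2αr — additive in the power domain, the
    form the background-removal algorithm inverts, so noise-estimate
    recovery is exact. Impulse pings add a constant to whole pings at
    seeded indices; a strong seabed echo sits at the seabed depth and
    elevated contamination fills the top bins. Ping clocks of the 18 and
    120 kHz channels are offset fractions of a second from the 38 kHz
    reference to exercise resampling.
    """
    config.validate()
    rng = _rng(config, 2)
    n = config.n_pings
    lat = np.linspace(config.lat_south, config.lat_north, n)
    dist = config.ping_spacing_nmi * np.arange(n)
    nbins = int(round(config.max_depth_m / config.depth_bin_m))
    edges = config.depth_bin_m * np.arange(nbins + 1)
    zc = 0.5 * (edges[:-1] + edges[1:])

    truth = TruthBundle(front_lat=config.front_lat)
    class_mask = np.zeros((n, nbins), dtype=np.int8)
    for t in config.targets:
        code = 1 if t.kind == "fish" else 2
        class_mask[_target_mask(config, t, lat, zc)] = code
    truth.class_mask = class_mask
    truth.noise_floor_db = dict(config.noise_floor_db)

    clock_offset = {18.0: 0.21, 38.0: 0.0, 120.0: 0.11}
    grids: dict[float, EchogramGrid] = {}
    for f in config.freqs_khz:
        alpha = absorption_coefficient(f, config.water_temp_c,
                                       config.water_sal_psu,
                                       config.max_depth_m / 2.0)
        n0 = config.noise_floor_db[f]
        sv_noise = n0 + 20.0 * np.log10(np.maximum(zc, 1e-6)) + 2 * alpha * zc
        signal_lin = np.zeros((n, nbins))
        for t in config.targets:
            off = t.d18_db if f == 18.0 else (t.d120_db if f == 120.0 else 0.0)
            m = _target_mask(config, t, lat, zc)
            signal_lin[m] += 10.0 ** ((t.sv38_db + off) / 10.0)
        seabed_bins = (zc >= config.seabed_depth_m)
        signal_lin[:, seabed_bins] += 10.0 ** (config.seabed_sv_db / 10.0)
        surf = zc < config.surface_noise_depth_m
        signal_lin[:, surf] += 10.0 ** (config.surface_noise_db / 10.0)

        total = 10.0 * np.log10(signal_lin + 10.0 ** (sv_noise / 10.0)[None, :])

        n_imp = int(round(config.impulse_fraction * n))
        # electrical impulses are single-ping events: keep them >= 3 pings
        # apart so the scene matches the ping-wise removal model
        imp = np.array([], dtype=int)
        if n_imp:
            chosen: list[int] = []
            for cand in rng.permutation(n):
                if all(abs(cand - c) >= 3 for c in chosen):
                    chosen.append(int(cand))
                    if len(chosen) == n_imp:
                        break
            imp = np.sort(np.array(chosen, dtype=int))
        total[imp] += config.impulse_amplitude_db
        truth.impulse_pings[f] = imp

        grids[f] = EchogramGrid(
            freq_khz=f,
            time_s=config.ping_interval_s * np.arange(n) + clock_offset.get(f, 0.0),
            lat=lat.copy(), lon=np.full(n, config.lon),
            distance_nmi=dist.copy(), depth_edges=edges.copy(),
            sv=total, alpha_db_per_m=alpha, sound_speed=1480.0)
    return grids, truth


def truth_on_grid(truth: TruthBundle, dist_edges: np.ndarray,
                  depth_edges: np.ndarray, config: SimulationConfig,
                  pure_frac: float = 0.999) -> np.ndarray:
    """Project the sample-level truth mask onto an integration grid.

    A cell is labelled fish (1) or zooplankton (2) only when at least
    ``pure_frac`` of its samples carry that code — edge cells that straddle
    a target boundary stay 0 so recovery statistics measure classification,
    not rasterisation.
    """
    n, nbins = truth.class_mask.shape
    dist = config.ping_spacing_nmi * np.arange(n)
    zc = config.depth_bin_m * (np.arange(nbins) + 0.5)
    pi = np.clip(np.searchsorted(dist_edges, dist, side="right") - 1,
                 0, dist_edges.size - 2)
    zi = np.clip(np.searchsorted(depth_edges, zc, side="right") - 1,
                 0, depth_edges.size - 2)
    nd, nz = dist_edges.size - 1, depth_edges.size - 1
    out = np.zeros((nd, nz), dtype=np.int8)
    flat = (pi[:, None] * nz + zi[None, :]).ravel()
    total = np.bincount(flat, minlength=nd * nz).astype(float)
    for code in (1, 2):
        hits = np.bincount(flat, weights=(truth.class_mask == code).ravel(),
                           minlength=nd * nz)
        with np.errstate(invalid="ignore"):
            frac = np.where(total > 0, hits / total, 0.0)
        out.ravel()[frac >= pure_frac] = code
    return out


# ---------------------------------------------------------------------------
# trawl communities


def simulate_trawl_catches(config: SimulationConfig
                           ) -> tuple[list, TruthBundle]:
    """Multinomial community samples at stations spanning the transect.

    Stations sit on an even latitude grid; each belongs to the water-mass
    group its side of the true front implies. The effective composition is
    (1 − e)·p̄ + e·p_group with e the configured effect size, so e = 0 makes
    all stations exchangeable (the ANOSIM null) and e = 1 gives the full
    configured contrast. Counts are a single multinomial draw per station;
    dry weights are counts × per-taxon unit weight with lognormal scatter;
    tow distance carries ±10% lognormal variation.
    """
    from .ecostats import TrawlCatch

    config.validate()
    rng = _rng(config, 3)
    taxa = sorted({t for v in config.community.values() for t in v})
    groups = sorted(config.community)
    p = {g: np.array([config.community[g].get(t, 0.0) for t in taxa])
         for g in groups}
    p_mean = np.mean([p[g] for g in groups], axis=0)

    lats = np.linspace(config.lat_south, config.lat_north, config.n_stations)
    catches, rows = [], []
    for i, la in enumerate(lats):
        group = groups[0] if la < config.front_lat else groups[-1]
        pe = (1.0 - config.effect_size) * p_mean + config.effect_size * p[group]
        pe = pe / pe.sum()
        counts = rng.multinomial(config.draw_size, pe)
        tow = config.tow_distance_m * rng.lognormal(0.0, 0.1)
        weights = {t: c * config.taxon_unit_weight_g.get(t, 1.0)
                   * rng.lognormal(0.0, 0.05)
                   for t, c in zip(taxa, counts)}
        catches.append(TrawlCatch(
            station=f"st{i:02d}", season=config.season, water_mass=group,
            mouth_area_m2=config.mouth_area_m2, tow_distance_m=tow,
            counts=dict(zip(taxa, counts.astype(float))),
            dry_weights_g=weights))
        rows.append({"station": f"st{i:02d}", "lat": la, "group": group,
                     **{f"p_{t}": v for t, v in zip(taxa, pe)}})
    truth = TruthBundle(front_lat=config.front_lat,
                        community=pd.DataFrame(rows).set_index("station"))
    return catches, truth
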