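"""End-to-end orchestration: simulate → clean → classify → integrate → stats.

`run_pipeline` ties every stage together on one configuration and writes
the run's outputs (NASC series, front fixes, water-mass section, RGB
composite, statistics tables) plus a machine-readable manifest with SHA-256
hashes, so identical (config, seed) runs are bit-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import composites, ecostats, io
from .classification import (CellClass, Stratum, classify_cells,
                             integrate_nasc, join_covariates)
from .echogram import (apply_sv_threshold, compute_mvbs,
                       detect_and_exclude_bottom, exclude_surface,
                       remove_background_noise, remove_impulse_noise,
                       resample_to_reference, smooth)
from .hydrography import (FrontFix, classify_water_mass,
                          locate_subsurface_front, locate_surface_front)
from .synthetic import (SimulationConfig, simulate_ctd_transect,
                        simulate_echograms, simulate_trawl_catches)


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters, defaulting to the survey's analysis settings."""

    seed: int = 0
    out_dir: str = "frontscan_run"
    # cleaning
    transducer_radius_m: dict = dataclasses.field(default_factory=lambda: {
        18.0: 0.45, 38.0: 0.35, 120.0: 0.16})
    surface_buffer_m: float = 2.0
    bottom_threshold_db: float = -35.0
    bottom_offset_m: float = 1.5
    snr_threshold_db: float = 10.0
    impulse_context_pings: int = 1
    impulse_smooth_samples: int = 5
    impulse_threshold_db: float = 10.0
    smooth_window: tuple[int, int] = (5, 5)  # samples x pings
    sv_threshold_db: float = -80.0
    # gridding: statistics grid 3 m x 0.25 nmi, display grid 1 m x 0.1 nmi
    stats_cell: tuple[float, float] = (3.0, 0.25)
    display_cell: tuple[float, float] = (1.0, 0.1)
    nasc_bin_nmi: float = 0.1
    # classification
    fish_max_delta_db: float = 5.0
    zoop_min_delta_db: float = 10.0
    depth_split_m: float = 150.0
    # fronts
    front_band_m: tuple[float, float] = (45.0, 55.0)
    front_resolution_deg: float = 0.01
    # composites
    gamma: float = 2.0
    brighten: float = 1.0
    simulation: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def clean_echograms(grids: dict, cfg: PipelineConfig) -> dict:
    """Run the full cleaning chain on raw multifrequency grids."""
    aligned = resample_to_reference(list(grids.values()), 38.0)
    out = {}
    for g in aligned:
        g = exclude_surface(g, cfg.transducer_radius_m[g.freq_khz],
                            buffer_m=cfg.surface_buffer_m)
        g, _ = detect_and_exclude_bottom(g, cfg.bottom_threshold_db,
                                         offset_m=cfg.bottom_offset_m)
        g, _ = remove_background_noise(g, snr_threshold_db=cfg.snr_threshold_db)
        g = remove_impulse_noise(g, cfg.impulse_context_pings,
                                 cfg.impulse_smooth_samples,
                                 cfg.impulse_threshold_db)
        g = smooth(g, *cfg.smooth_window)
        g = apply_sv_threshold(g, cfg.sv_threshold_db)
        out[g.freq_khz] = g
    return out


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the whole analysis on a simulated scene; returns the run dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulation
    manifest: dict = {"seed": cfg.seed, "outputs": {}}

    # hydrography
    section, truth_ctd = simulate_ctd_transect(sim)
    sub_front = locate_subsurface_front(section, cfg.front_band_m,
                                        cfg.front_resolution_deg)
    surf_front = locate_surface_front(
        section.lat, section.band_mean_theta(0.0, 2.0),
        cfg.front_resolution_deg)
    fronts = FrontFix(date="day0", surface_front_lat=surf_front,
                      subsurface_front_lat=sub_front)
    io.write_section_csv(section, out / "ctd_section.csv")
    wm = classify_water_mass(section.sa, section.theta, section.sigma_theta)
    pd.DataFrame({
        "lat": np.repeat(section.lat, section.depth.size),
        "depth_m": np.tile(section.depth, section.lat.size),
        "water_mass": [w.name for w in wm.ravel()],
    }).to_csv(out / "water_mass.csv", index=False)
    pd.DataFrame([dataclasses.asdict(fronts)]).to_csv(
        out / "front_fix.csv", index=False)

    # acoustics
    raw, truth_echo = simulate_echograms(sim)
    clean = clean_echograms(raw, cfg)
    mvbs_stats = {f: compute_mvbs(g, *cfg.stats_cell)
                  for f, g in clean.items()}
    mvbs_disp = {f: compute_mvbs(g, *cfg.display_cell)
                 for f, g in clean.items()}
    classified = classify_cells(mvbs_stats[38.0], mvbs_stats[120.0],
                                cfg.fish_max_delta_db, cfg.zoop_min_delta_db,
                                cfg.depth_split_m)
    series = {
        "fish_shallow": integrate_nasc(classified, CellClass.FISH,
                                       Stratum.SHALLOW, cfg.nasc_bin_nmi),
        "fish_deep": integrate_nasc(classified, CellClass.FISH,
                                    Stratum.DEEP, cfg.nasc_bin_nmi),
        "macrozooplankton": integrate_nasc(classified,
                                           CellClass.MACROZOOPLANKTON,
                                           Stratum.SHALLOW, cfg.nasc_bin_nmi),
    }
    frames = []
    for name, s in series.items():
        df = join_covariates(s, fronts, section, lon=sim.lon)
        df.insert(0, "group", name)
        frames.append(df)
    nasc_table = pd.concat(frames, ignore_index=True)
    nasc_table.to_csv(out / "nasc.csv", index=False)

    comp = composites.build_rgb(mvbs_disp[18.0], mvbs_disp[38.0],
                                mvbs_disp[120.0], cfg.gamma, cfg.brighten)
    composites.save_png(comp, out / "composite.png")

    # statistics
    wide = nasc_table.pivot_table(index="distance_nmi", columns="group",
                                  values="nasc_m2nmi2", aggfunc="first")
    cov = nasc_table[nasc_table["group"] == "fish_shallow"].set_index(
        "distance_nmi")
    stats_in = wide.join(cov[[c for c in cov.columns if c.startswith(
        ("lat", "dist_", "temp_", "sal_"))]])
    corr = ecostats.correlation_table(
        stats_in, list(series), ["lat", "dist_subsurface_front_km",
                                 "temp_surface", "temp_middle", "sal_middle"])
    corr.to_csv(out / "correlations.csv", index=False)

    catches, truth_trawl = simulate_trawl_catches(sim)
    io.write_trawl_csv(catches, out / "trawl.csv")
    div = pd.DataFrame([{
        "station": c.station,
        "shannon": ecostats.shannon(c.counts),
        "simpson": ecostats.simpson(c.counts)} for c in catches])
    div.to_csv(out / "diversity.csv", index=False)
    comm = ecostats.community_matrix(catches)
    dist = ecostats.bray_curtis(comm)
    r, p = ecostats.anosim(dist, comm.groups["water_mass"].to_numpy(),
                           seed=cfg.seed)
    pd.DataFrame([{"factor": "water_mass", "R": r, "p": p}]).to_csv(
        out / "anosim.csv", index=False)

    for f in sorted(out.glob("*")):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha(f)
    manifest["fronts"] = {"surface": surf_front, "subsurface": sub_front,
                          "true": truth_ctd.front_lat}
    manifest["anosim"] = {"R": r, "p": p}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return out
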