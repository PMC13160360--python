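"""Round-trippable file formats for grids, sections, catches and series.

Echograms go to NetCDF (ping × depth, with every mask layer persisted by
name) or long-format CSV; CTD, SST/ice, trawl and NASC tables are plain
CSV. Write→read of every format preserves values and masks exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from .echogram import EchogramGrid
from .ecostats import TrawlCatch
from .hydrography import CtdProfile, CtdSection


# ---------------------------------------------------------------------------
# echograms


def echogram_to_dataset(grid: EchogramGrid) -> xr.Dataset:
    ds = xr.Dataset(
        {
            "sv": (("ping", "depth"), grid.sv),
            "latitude": ("ping", grid.lat),
            "longitude": ("ping", grid.lon),
            "time_s": ("ping", grid.time_s),
            "distance_nmi": ("ping", grid.distance_nmi),
            "depth_edges": ("edge", grid.depth_edges),
        },
        coords={"ping": np.arange(grid.n_pings), "depth": grid.depth_centers},
        attrs={
            "freq_khz": grid.freq_khz,
            "alpha_db_per_m": grid.alpha_db_per_m,
            "sound_speed": grid.sound_speed,
            "stages": ",".join(grid.stages),
            "mask_layers": ",".join(grid.masks),
        },
    )
    for name, layer in grid.masks.items():
        ds[f"mask_{name}"] = (("ping", "depth"), layer.astype(np.int8))
    return ds


def write_echogram_netcdf(grid: EchogramGrid, path: str) -> None:
    echogram_to_dataset(grid).to_netcdf(path, engine="scipy")


def read_echogram_netcdf(path: str) -> EchogramGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    masks = {
        name: ds[f"mask_{name}"].values.astype(bool)
        for name in ds.attrs.get("mask_layers", "").split(",")
        if name
    }
    stages = [s for s in ds.attrs.get("stages", "").split(",") if s]
    return EchogramGrid(
        freq_khz=float(ds.attrs["freq_khz"]),
        time_s=ds["time_s"].values,
        lat=ds["latitude"].values,
        lon=ds["longitude"].values,
        distance_nmi=ds["distance_nmi"].values,
        depth_edges=ds["depth_edges"].values,
        sv=ds["sv"].values,
        masks=masks,
        stages=stages,
        alpha_db_per_m=float(ds.attrs["alpha_db_per_m"]),
        sound_speed=float(ds.attrs["sound_speed"]),
    )


def write_echogram_csv(grid: EchogramGrid, path: str) -> None:
    """Long-format CSV: one row per (ping, depth bin) sample."""
    n, nb = grid.sv.shape
    pi, zi = np.meshgrid(np.arange(n), np.arange(nb), indexing="ij")
    df = pd.DataFrame({
        "ping": pi.ravel(),
        "depth_m": grid.depth_centers[zi.ravel()],
        "sv_db": grid.sv.ravel(),
        "excluded": grid.mask.ravel().astype(int),
        "lat": grid.lat[pi.ravel()],
        "lon": grid.lon[pi.ravel()],
        "time_s": grid.time_s[pi.ravel()],
        "distance_nmi": grid.distance_nmi[pi.ravel()],
    })
    df.insert(0, "freq_khz", grid.freq_khz)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CTD


def read_ctd_csv(path: str) -> list[CtdProfile]:
    """CTD CSV: station,lat,lon,time,depth_m,temp_C,sal_gkg[,sigma_theta].

    σθ is computed from the linear equation of state of the synthetic module
    when the column is absent (inputs are assumed pre-converted to
    conservative temperature and absolute salinity).
    """
    from .synthetic import sigma_theta_linear

    df = pd.read_csv(path)
    profiles = []
    for st, g in df.groupby("station", sort=True):
        g = g.sort_values("depth_m")
        sigma = (g["sigma_theta"].to_numpy()
                 if "sigma_theta" in g else
                 sigma_theta_linear(g["temp_C"].to_numpy(),
                                    g["sal_gkg"].to_numpy()))
        profiles.append(CtdProfile(
            station=str(st), lat=float(g["lat"].iloc[0]),
            lon=float(g["lon"].iloc[0]),
            time=str(g["time"].iloc[0]) if "time" in g else None,
            depth=g["depth_m"].to_numpy(), theta=g["temp_C"].to_numpy(),
            sa=g["sal_gkg"].to_numpy(), sigma_theta=np.asarray(sigma)))
    return profiles


def write_section_csv(section: CtdSection, path: str) -> None:
    li, zi = np.meshgrid(np.arange(section.lat.size),
                         np.arange(section.depth.size), indexing="ij")
    pd.DataFrame({
        "lat": section.lat[li.ravel()],
        "depth_m": section.depth[zi.ravel()],
        "temp_C": section.theta.ravel(),
        "sal_gkg": section.sa.ravel(),
        "sigma_theta": section.sigma_theta.ravel(),
        "valid": section.valid.ravel().astype(int),
    }).to_csv(path, index=False)


def read_section_csv(path: str) -> CtdSection:
    df = pd.read_csv(path)
    lat = np.unique(df["lat"].to_numpy())
    depth = np.unique(df["depth_m"].to_numpy())
    shape = (lat.size, depth.size)
    df = df.sort_values(["lat", "depth_m"])
    return CtdSection(
        lat=lat, depth=depth,
        theta=df["temp_C"].to_numpy().reshape(shape),
        sa=df["sal_gkg"].to_numpy().reshape(shape),
        sigma_theta=df["sigma_theta"].to_numpy().reshape(shape),
        valid=df["valid"].to_numpy().reshape(shape).astype(bool))


def read_sst_csv(path: str) -> pd.DataFrame:
    """SST / ice-edge CSV: date,lat,sst_C[,concentration_class]."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# trawl


def write_trawl_csv(catches: list[TrawlCatch], path: str) -> None:
    rows = []
    for c in catches:
        for taxon, count in sorted(c.counts.items()):
            rows.append({
                "station": c.station, "season": c.season,
                "water_mass": c.water_mass,
                "mouth_area_m2": c.mouth_area_m2,
                "tow_distance_m": c.tow_distance_m,
                "taxon": taxon, "count": count,
                "dry_weight_g": c.dry_weights_g.get(taxon, np.nan),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trawl_csv(path: str) -> list[TrawlCatch]:
    df = pd.read_csv(path)
    catches = []
    for st, g in df.groupby("station", sort=True):
        catches.append(TrawlCatch(
            station=str(st), season=str(g["season"].iloc[0]),
            water_mass=str(g["water_mass"].iloc[0]),
            mouth_area_m2=float(g["mouth_area_m2"].iloc[0]),
            tow_distance_m=float(g["tow_distance_m"].iloc[0]),
            counts=dict(zip(g["taxon"], g["count"].astype(float))),
            dry_weights_g={t: float(w) for t, w in
                           zip(g["taxon"], g["dry_weight_g"])
                           if np.isfinite(w)}))
    return catches
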