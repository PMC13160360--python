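"""ΔMVBS frequency-differencing classification and NASC integration.

Fish with gas bladders scatter strongly at low frequency, so their
120 kHz − 38 kHz frequency response (ΔMVBS₁₂₀₋₃₈) is small or negative,
while fluid-like macrozooplankton scatter much more strongly at 120 kHz.
Cells in the upper 150 m are classified by ΔMVBS₁₂₀₋₃₈: ≤ 5 dB is fish,
> 10 dB is macrozooplankton, the band between is left unclassified.
Below 150 m — beyond the usable range of the 120 kHz channel — any defined
38 kHz signal is taken as fish.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .echogram import MvbsGrid, NMI_M
from .hydrography import CtdSection, FrontFix, distance_to_feature


class CellClass(enum.IntEnum):
    EXCLUDED = 0
    FISH = 1
    MACROZOOPLANKTON = 2
    UNCLASSIFIED = 3


class Stratum(enum.IntEnum):
    SHALLOW = 0  # cell top < 150 m
    DEEP = 1  # cell top >= 150 m


DEPTH_SPLIT_M = 150.0  # usable range limit of the 120 kHz channel
FISH_MAX_DELTA_DB = 5.0  # upper limit of fish frequency response
ZOOP_MIN_DELTA_DB = 10.0  # lower (exclusive) limit for macrozooplankton


@dataclass
class ClassifiedGrid:
    """Integration cells labelled fish / macrozooplankton / unclassified.

    Carries the 38 kHz MVBS (used for integration), the frequency response
    Δ = MVBS₁₂₀ − MVBS₃₈ where both are defined, per-cell class and depth
    stratum, and the geometry of the underlying grid.
    """

    dist_edges: np.ndarray
    depth_edges: np.ndarray
    mvbs38: np.ndarray  # (n_dist, n_depth) dB
    delta: np.ndarray  # MVBS120 - MVBS38, NaN where undefined
    cell_class: np.ndarray  # CellClass codes
    stratum: np.ndarray  # Stratum codes, per depth cell broadcast
    lat: np.ndarray  # per distance cell

    @property
    def dist_centers(self) -> np.ndarray:
        return 0.5 * (self.dist_edges[:-1] + self.dist_edges[1:])

    @property
    def thickness_m(self) -> np.ndarray:
        return np.diff(self.depth_edges)


@dataclass
class NascSeries:
    """Along-transect nautical area scattering coefficient per distance bin."""

    dist_centers: np.ndarray  # nmi
    lat: np.ndarray
    nasc: np.ndarray  # m² nmi⁻²
    cell_class: CellClass
    stratum: Stratum | None
    bin_nmi: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "distance_nmi": self.dist_centers,
            "lat": self.lat,
            "nasc_m2nmi2": self.nasc,
            "class": self.cell_class.name,
            "stratum": self.stratum.name if self.stratum is not None else "ALL",
        })


def classify_cells(mvbs38: MvbsGrid, mvbs120: MvbsGrid,
                   fish_max_delta: float = FISH_MAX_DELTA_DB,
                   zoop_min_delta: float = ZOOP_MIN_DELTA_DB,
                   depth_split: float = DEPTH_SPLIT_M) -> ClassifiedGrid:
    """Label each integration cell by its two-frequency response.

    Cells whose top edge is above ``depth_split`` need both frequencies
    defined: Δ ≤ ``fish_max_delta`` → FISH, Δ > ``zoop_min_delta`` →
    MACROZOOPLANKTON, in between → UNCLASSIFIED. Cells with top edge at or
    below the split are FISH wherever the 38 kHz MVBS is defined (the
    120 kHz channel does not reach). Cells with no usable signal are
    EXCLUDED. Cells straddling the split follow their top edge.
    """
    if (mvbs38.mvbs.shape != mvbs120.mvbs.shape
            or not np.allclose(mvbs38.dist_edges, mvbs120.dist_edges)
            or not np.allclose(mvbs38.depth_edges, mvbs120.depth_edges)):
        raise ValueError("38 and 120 kHz grids are not co-registered")
    delta = mvbs120.mvbs - mvbs38.mvbs
    top = mvbs38.depth_edges[:-1]
    shallow = top < depth_split
    cls = np.full(mvbs38.mvbs.shape, CellClass.EXCLUDED, dtype=np.int8)

    both = np.isfinite(delta)
    sh = shallow[None, :] & both
    cls[sh & (delta <= fish_max_delta)] = CellClass.FISH
    cls[sh & (delta > zoop_min_delta)] = CellClass.MACROZOOPLANKTON
    cls[sh & (delta > fish_max_delta) & (delta <= zoop_min_delta)] = \
        CellClass.UNCLASSIFIED
    deep38 = (~shallow)[None, :] & np.isfinite(mvbs38.mvbs)
    cls[deep38] = CellClass.FISH

    stratum = np.where(shallow, Stratum.SHALLOW, Stratum.DEEP).astype(np.int8)
    return ClassifiedGrid(dist_edges=mvbs38.dist_edges.copy(),
                          depth_edges=mvbs38.depth_edges.copy(),
                          mvbs38=mvbs38.mvbs.copy(), delta=delta,
                          cell_class=cls, stratum=stratum,
                          lat=mvbs38.lat.copy())


def integrate_nasc(classified: ClassifiedGrid, cell_class: CellClass,
                   stratum: Stratum | None = None,
                   bin_nmi: float = 0.1) -> NascSeries:
    """Integrate selected cells into along-transect NASC (m² nmi⁻²).

    NASC = 4π·1852² · Σ sv·Δz over the selected cells of each distance bin,
    with sv the linear-domain MVBS and Δz the cell thickness in metres.
    Empty selections integrate to zero — a valid absence, not an error.
    Macrozooplankton is only ever selected in the shallow stratum.
    """
    if bin_nmi <= 0:
        raise ValueError("bin width must be positive")
    sel = classified.cell_class == int(cell_class)
    if stratum is not None:
        sel &= classified.stratum[None, :] == int(stratum)
    sv_lin = np.where(sel & np.isfinite(classified.mvbs38),
                      np.power(10.0, classified.mvbs38 / 10.0), 0.0)
    per_cell = 4.0 * np.pi * NMI_M**2 * sv_lin * classified.thickness_m[None, :]
    per_dist = per_cell.sum(axis=1)

    centers = classified.dist_centers
    d0 = classified.dist_edges[0]
    n_bins = int(np.floor((classified.dist_edges[-1] - d0) / bin_nmi)) + 1
    edges = d0 + bin_nmi * np.arange(n_bins + 1)
    bi = np.clip(np.searchsorted(edges, centers, side="right") - 1, 0, n_bins - 1)
    nasc = np.bincount(bi, weights=per_dist, minlength=n_bins)
    counts = np.bincount(bi, minlength=n_bins).astype(float)
    lat_sum = np.bincount(bi, weights=np.nan_to_num(classified.lat),
                          minlength=n_bins)
    with np.errstate(invalid="ignore"):
        lat = np.where(counts > 0, lat_sum / counts, np.nan)
    keep = counts > 0
    return NascSeries(dist_centers=0.5 * (edges[:-1] + edges[1:])[keep],
                      lat=lat[keep], nasc=nasc[keep], cell_class=cell_class,
                      stratum=stratum, bin_nmi=bin_nmi)


def join_covariates(series: NascSeries, fronts: FrontFix,
                    section: CtdSection,
                    bands: dict[str, tuple[float, float]] | None = None,
                    lon: float = 30.0) -> pd.DataFrame:
    """Join front-geometry and hydrographic covariates onto a NASC series.

    Per distance bin: latitude, signed km to the surface front, subsurface
    front and ice edges (positive north of the feature), and band-mean
    temperature and salinity from the CTD section at the bin's latitude.
    Default bands: surface 0–20 m, middle 45–55 m (the front-defining
    window), bottom 150–250 m. Bins with no latitude are dropped.
    """
    if bands is None:
        bands = {"surface": (0.0, 20.0), "middle": (45.0, 55.0),
                 "bottom": (150.0, 250.0)}
    rows = []
    features = {
        "dist_surface_front_km": fronts.surface_front_lat,
        "dist_subsurface_front_km": fronts.subsurface_front_lat,
        "dist_open_ice_km": fronts.open_ice_lat,
        "dist_closed_ice_km": fronts.closed_ice_lat,
    }
    band_vals = {}
    for name, (zlo, zhi) in bands.items():
        try:
            band_vals[f"temp_{name}"] = section.band_mean("theta", zlo, zhi)
            band_vals[f"sal_{name}"] = section.band_mean("sa", zlo, zhi)
        except ValueError:
            band_vals[f"temp_{name}"] = np.full(section.lat.size, np.nan)
            band_vals[f"sal_{name}"] = np.full(section.lat.size, np.nan)

    for i, lat in enumerate(series.lat):
        if not np.isfinite(lat):
            continue
        row = {"distance_nmi": series.dist_centers[i], "lat": lat,
               "nasc_m2nmi2": series.nasc[i]}
        for col, flat in features.items():
            row[col] = (distance_to_feature(lat, lon, flat)
                        if flat is not None else np.nan)
        for col, vals in band_vals.items():
            row[col] = float(np.interp(lat, section.lat, vals))
        rows.append(row)
    return pd.DataFrame(rows)
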