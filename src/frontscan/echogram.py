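"""Echogram cleaning: from raw Sv grids to thresholded, smoothed, gridded MVBS.

An :class:`EchogramGrid` holds one frequency's volume-backscattering
strength Sv (dB re 1 m⁻¹) over pings × depth bins. Depth bins are half-open
[top, bottom) metre intervals, positive down, 0-based ping indices. Named
boolean exclusion layers (surface, bottom, noise, impulse, below-threshold)
accumulate monotonically — no stage ever unmasks a sample — and masked
samples never enter any mean. All averaging of dB quantities happens in the
linear (power) domain.

The cleaning chain runs in a fixed order:

    recorrect → resample → surface/bottom exclusion → background-noise
    removal → impulse-noise removal → smoothing → Sv threshold → MVBS

and each operation checks that no later stage has already been applied,
raising :class:`PipelineOrderError` on a violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

NMI_M = 1852.0  # metres per nautical mile


class PipelineOrderError(RuntimeError):
    """A cleaning stage was applied out of its mandated order."""


_STAGE_ORDER = [
    "recorrect",
    "resample",
    "exclude_surface",
    "exclude_bottom",
    "remove_background",
    "remove_impulse",
    "smooth",
    "threshold",
]


def _lin(db: np.ndarray) -> np.ndarray:
    return np.power(10.0, np.asarray(db) / 10.0)


def _db(lin: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return 10.0 * np.log10(lin)


@dataclass
class EchogramGrid:
    """One frequency's Sv matrix with ping geometry and exclusion layers."""

    freq_khz: float
    time_s: np.ndarray  # ping times, seconds from transect start
    lat: np.ndarray  # per ping, deg N
    lon: np.ndarray  # per ping, deg E
    distance_nmi: np.ndarray  # along-transect distance per ping
    depth_edges: np.ndarray  # n_bins + 1, strictly increasing, m
    sv: np.ndarray  # (n_pings, n_bins), dB re 1 m⁻¹
    masks: dict = field(default_factory=dict)  # name -> (n_pings, n_bins) bool
    stages: list = field(default_factory=list)
    alpha_db_per_m: float = 0.0  # absorption used for TVG bookkeeping
    sound_speed: float = 1480.0  # m s⁻¹

    def __post_init__(self) -> None:
        self.sv = np.asarray(self.sv, dtype=float)
        self.depth_edges = np.asarray(self.depth_edges, dtype=float)
        if self.sv.shape != (self.time_s.size, self.depth_edges.size - 1):
            raise ValueError("sv shape must be n_pings x n_bins")
        if not np.all(np.diff(self.depth_edges) > 0):
            raise ValueError("depth edges must be strictly increasing")

    # -- geometry -----------------------------------------------------------
    @property
    def n_pings(self) -> int:
        return self.sv.shape[0]

    @property
    def n_bins(self) -> int:
        return self.sv.shape[1]

    @property
    def depth_centers(self) -> np.ndarray:
        return 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])

    @property
    def mask(self) -> np.ndarray:
        """Combined exclusion mask (True = excluded)."""
        out = np.zeros(self.sv.shape, dtype=bool)
        for layer in self.masks.values():
            out |= layer
        return out

    def copy(self) -> "EchogramGrid":
        return EchogramGrid(
            freq_khz=self.freq_khz,
            time_s=self.time_s.copy(),
            lat=self.lat.copy(),
            lon=self.lon.copy(),
            distance_nmi=self.distance_nmi.copy(),
            depth_edges=self.depth_edges.copy(),
            sv=self.sv.copy(),
            masks={k: v.copy() for k, v in self.masks.items()},
            stages=list(self.stages),
            alpha_db_per_m=self.alpha_db_per_m,
            sound_speed=self.sound_speed,
        )

    def _add_mask(self, name: str, layer: np.ndarray) -> None:
        if name in self.masks:
            self.masks[name] = self.masks[name] | layer
        else:
            self.masks[name] = layer.astype(bool)

    def _enter_stage(self, stage: str) -> None:
        rank = _STAGE_ORDER.index(stage)
        for done in self.stages:
            if _STAGE_ORDER.index(done) > rank:
                raise PipelineOrderError(
                    f"stage '{stage}' applied after later stage '{done}'"
                )
        self.stages.append(stage)


@dataclass
class NoiseEstimate:
    """Background-noise estimate: per ping-block receiver noise level (dB)."""

    noise_db: np.ndarray  # one value per ping block
    block_pings: int
    block_samples: int
    snr_threshold_db: float


@dataclass
class MvbsGrid:
    """Echo-integrated mean volume backscattering on a distance × depth grid.

    ``mvbs`` is NaN wherever the unmasked-sample fraction falls below
    ``min_valid_frac``; trailing partial distance cells are kept and flagged.
    """

    freq_khz: float
    dist_edges: np.ndarray  # nmi, half-open cells
    depth_edges: np.ndarray  # m, half-open cells
    mvbs: np.ndarray  # (n_dist, n_depth)
    valid_frac: np.ndarray
    lat: np.ndarray  # mean ping latitude per distance cell
    partial: np.ndarray  # bool per distance cell
    min_valid_frac: float = 0.3

    @property
    def dist_centers(self) -> np.ndarray:
        return 0.5 * (self.dist_edges[:-1] + self.dist_edges[1:])

    @property
    def depth_centers(self) -> np.ndarray:
        return 0.5 * (self.depth_edges[:-1] + self.depth_edges[1:])

    @property
    def thickness_m(self) -> np.ndarray:
        return np.diff(self.depth_edges)


# ---------------------------------------------------------------------------
# physics helpers


def wavelength(c: float, freq_khz: float) -> float:
    """Acoustic wavelength λ = c/f in metres."""
    return c / (freq_khz * 1000.0)


def near_field_depth(radius_m: float, freq_khz: float, c: float = 1480.0,
                     buffer_m: float = 2.0) -> float:
    """Near-field (Fresnel-zone) exclusion depth πa²/λ plus a safety buffer.

    Within the near field the beam is unformed and backscatter is unusable;
    the survey practice of lowering the exclusion line a further 2 m below
    the computed range is the default buffer.
    """
    if radius_m < 0:
        raise ValueError("transducer radius must be non-negative")
    lam = wavelength(c, freq_khz)
    return np.pi * radius_m**2 / lam + buffer_m


def absorption_coefficient(freq_khz: float, temp_c: float, salinity_psu: float,
                           depth_m: float, ph: float = 8.0) -> float:
    """Seawater sound absorption α in dB m⁻¹ (boric acid + MgSO₄ + pure water).

    Standard three-relaxation empirical formulation for 10–500 kHz: a boric
    acid relaxation dominating at low frequency, a magnesium-sulfate
    relaxation dominating in the tens-of-kHz band, and the pure-water
    viscous term growing as f². Inputs: frequency in kHz, temperature in °C,
    salinity in psu, depth in m, pH.
    """
    f = float(freq_khz)
    if not 10.0 <= f <= 500.0:
        raise ValueError("frequency outside the 10-500 kHz validity range")
    T, S, D = float(temp_c), float(salinity_psu), float(depth_m)
    c = 1412.0 + 3.21 * T + 1.19 * S + 0.0167 * D
    theta = T + 273.0

    # boric acid
    a1 = (8.86 / c) * 10.0 ** (0.78 * ph - 5.0)
    f1 = 2.8 * np.sqrt(S / 35.0) * 10.0 ** (4.0 - 1245.0 / theta)
    p1 = 1.0

    # magnesium sulfate
    a2 = 21.44 * (S / c) * (1.0 + 0.025 * T)
    f2 = (8.17 * 10.0 ** (8.0 - 1990.0 / theta)) / (1.0 + 0.0018 * (S - 35.0))
    p2 = 1.0 - 1.37e-4 * D + 6.2e-9 * D**2

    # pure water
    if T <= 20.0:
        a3 = 4.937e-4 - 2.59e-5 * T + 9.11e-7 * T**2 - 1.50e-8 * T**3
    else:
        a3 = 3.964e-4 - 1.146e-5 * T + 1.45e-7 * T**2 - 6.5e-10 * T**3
    p3 = 1.0 - 3.83e-5 * D + 4.9e-10 * D**2

    alpha_db_km = (a1 * p1 * f1 * f**2 / (f1**2 + f**2)
                   + a2 * p2 * f2 * f**2 / (f2**2 + f**2)
                   + a3 * p3 * f**2)
    return alpha_db_km / 1000.0


# ---------------------------------------------------------------------------
# cleaning stages


def recorrect_sv(grid: EchogramGrid, c_old: float, c_new: float,
                 alpha_old: float, alpha_new: float) -> EchogramGrid:
    """Re-correct Sv for in-situ sound speed and absorption.

    Range rescales as r' = r·(c_new/c_old) and the time-varied gain terms
    are swapped: Sv' = Sv + 20·log₁₀(r'/r) + 2(α_new·r' − α_old·r).
    Depth-bin edges are rescaled to the new ranges. Zero-range rows cannot
    be corrected and are masked instead.
    """
    if c_old <= 0 or c_new <= 0:
        raise ValueError("sound speeds must be positive")
    if alpha_old < 0 or alpha_new < 0:
        raise ValueError("absorption coefficients must be non-negative")
    out = grid.copy()
    out._enter_stage("recorrect")
    ratio = c_new / c_old
    r_old = grid.depth_centers
    r_new = r_old * ratio
    corr = np.zeros_like(r_old)
    nz = r_old > 0
    corr[nz] = (20.0 * np.log10(r_new[nz] / r_old[nz])
                + 2.0 * (alpha_new * r_new[nz] - alpha_old * r_old[nz]))
    out.sv = out.sv + corr[None, :]
    if (~nz).any():
        layer = np.zeros(out.sv.shape, dtype=bool)
        layer[:, ~nz] = True
        out._add_mask("zero-range", layer)
    out.depth_edges = grid.depth_edges * ratio
    out.alpha_db_per_m = alpha_new
    out.sound_speed = c_new
    return out


def resample_to_reference(grids: Sequence[EchogramGrid],
                          reference_khz: float = 38.0,
                          tolerance_s: float = 2.0) -> list[EchogramGrid]:
    """Align multifrequency grids onto the reference (38 kHz) ping clock.

    For each reference ping the nearest-in-time ping of every other
    frequency within ``tolerance_s`` is taken (whole column masked where no
    ping is close enough), and depth bins are interpolated onto the
    reference bin grid, linearly in the linear domain.
    """
    ref = next((g for g in grids if g.freq_khz == reference_khz), None)
    if ref is None:
        raise ValueError(f"no {reference_khz} kHz grid supplied")
    out = []
    for g in grids:
        if g is ref:
            r = ref.copy()
            r._enter_stage("resample")
            out.append(r)
            continue
        if g.time_s.max() < ref.time_s.min() or g.time_s.min() > ref.time_s.max():
            raise ValueError("no time overlap with the reference grid")
        idx = np.searchsorted(g.time_s, ref.time_s)
        idx = np.clip(idx, 1, g.time_s.size - 1)
        left = idx - 1
        pick = np.where(
            np.abs(g.time_s[left] - ref.time_s)
            <= np.abs(g.time_s[idx] - ref.time_s),
            left, idx)
        dt = np.abs(g.time_s[pick] - ref.time_s)
        unmatched = dt > tolerance_s

        lin = _lin(g.sv[pick])
        lin[g.mask[pick]] = np.nan
        zc_src = 0.5 * (g.depth_edges[:-1] + g.depth_edges[1:])
        zc_ref = ref.depth_centers
        res = np.empty((ref.n_pings, ref.n_bins))
        for i in range(ref.n_pings):
            col = lin[i]
            ok = np.isfinite(col)
            if ok.sum() < 2:
                res[i] = np.nan
                continue
            res[i] = np.interp(zc_ref, zc_src[ok], col[ok],
                               left=np.nan, right=np.nan)
        aligned = EchogramGrid(
            freq_khz=g.freq_khz,
            time_s=ref.time_s.copy(),
            lat=ref.lat.copy(),
            lon=ref.lon.copy(),
            distance_nmi=ref.distance_nmi.copy(),
            depth_edges=ref.depth_edges.copy(),
            sv=_db(np.where(np.isfinite(res), res, 1e-30)),
            alpha_db_per_m=g.alpha_db_per_m,
            sound_speed=g.sound_speed,
            stages=list(g.stages),
        )
        layer = ~np.isfinite(res)
        layer[unmatched, :] = True
        aligned._add_mask("resample-gap", layer)
        aligned._enter_stage("resample")
        out.append(aligned)
    return out


def exclude_surface(grid: EchogramGrid, transducer_radius_m: float,
                    c: float | None = None, buffer_m: float = 2.0,
                    manual_depth: np.ndarray | None = None) -> EchogramGrid:
    """Mask the transducer near field (plus buffer) at the top of the column.

    The exclusion depth is πa²/λ + buffer. ``manual_depth`` (per ping,
    metres) overrides the computed line where deeper — the path for manual
    adjustment under surface bubble or ice noise.
    """
    if transducer_radius_m <= 0:
        raise ValueError("transducer radius must be positive")
    out = grid.copy()
    out._enter_stage("exclude_surface")
    c = grid.sound_speed if c is None else c
    depth = near_field_depth(transducer_radius_m, grid.freq_khz, c, buffer_m)
    line = np.full(grid.n_pings, depth)
    if manual_depth is not None:
        line = np.maximum(line, np.asarray(manual_depth, dtype=float))
    layer = grid.depth_edges[None, :-1] < line[:, None]
    out._add_mask("surface", layer)
    return out


def detect_and_exclude_bottom(grid: EchogramGrid, threshold_db: float = -35.0,
                              min_depth_m: float = 20.0,
                              offset_m: float = 1.5,
                              manual_bottom: np.ndarray | None = None
                              ) -> tuple[EchogramGrid, np.ndarray]:
    """Detect the seabed echo and mask it together with the dead zone above.

    Per ping the bottom is the top edge of the shallowest bin below
    ``min_depth_m`` whose Sv reaches ``threshold_db``; everything from
    ``offset_m`` above that line down is masked (any bin containing depths
    ≥ bottom − offset). Pings without a detection keep the full column —
    absence of bottom is valid in deep water. ``manual_bottom`` (per ping,
    m; NaN = keep automatic) overrides the detector.

    Returns (masked grid, bottom line per ping; NaN where none).
    """
    out = grid.copy()
    out._enter_stage("exclude_bottom")
    candidates = (grid.sv >= threshold_db) & (
        grid.depth_centers[None, :] >= min_depth_m)
    bottom = np.full(grid.n_pings, np.nan)
    hit_any = candidates.any(axis=1)
    first = np.argmax(candidates, axis=1)
    bottom[hit_any] = grid.depth_edges[first[hit_any]]
    if manual_bottom is not None:
        manual = np.asarray(manual_bottom, dtype=float)
        use = np.isfinite(manual)
        bottom[use] = manual[use]
    layer = np.zeros(grid.sv.shape, dtype=bool)
    has = np.isfinite(bottom)
    # bin is masked iff its half-open interval contains any depth >= bottom-offset
    layer[has] = grid.depth_edges[None, 1:] > (bottom[has, None] - offset_m)
    out._add_mask("bottom", layer)
    return out, bottom


def remove_background_noise(grid: EchogramGrid,
                            block_pings: int = 20,
                            block_samples: int = 5,
                            snr_threshold_db: float = 10.0,
                            max_noise_db: float = -125.0
                            ) -> tuple[EchogramGrid, NoiseEstimate]:
    """Estimate and subtract range-dependent background noise.

    The TVG-removed power P = Sv − 20·log₁₀r − 2αr is averaged in the
    linear domain over cells of ``block_pings`` × ``block_samples``; the
    noise for a ping block is the minimum cell mean over depth (an echo-free
    cell exists somewhere in the column), capped at ``max_noise_db`` — the
    cap bounds the damage a block-wide contaminant (e.g. an impulse ping)
    can do to the estimate. The
    noise echogram Sv_noise(r) = noise + 20·log₁₀r + 2αr is subtracted in
    the linear domain, and samples whose corrected Sv sits less than
    ``snr_threshold_db`` above Sv_noise — or where the subtraction is
    non-positive — are masked as noise.
    """
    if block_pings > grid.n_pings or block_samples > grid.n_bins:
        raise ValueError("noise-estimation cell larger than the grid")
    out = grid.copy()
    out._enter_stage("remove_background")
    r = grid.depth_centers
    tvg = 20.0 * np.log10(np.maximum(r, 1e-12)) + 2.0 * grid.alpha_db_per_m * r
    power_lin = _lin(grid.sv - tvg[None, :])
    power_lin = np.where(grid.mask, np.nan, power_lin)

    n_pblock = int(np.ceil(grid.n_pings / block_pings))
    n_sblock = int(np.ceil(grid.n_bins / block_samples))
    noise = np.full(n_pblock, np.nan)
    for b in range(n_pblock):
        rows = slice(b * block_pings, min((b + 1) * block_pings, grid.n_pings))
        cell_means = []
        for s in range(n_sblock):
            cols = slice(s * block_samples,
                         min((s + 1) * block_samples, grid.n_bins))
            cell = power_lin[rows, cols]
            if np.isfinite(cell).any():
                cell_means.append(np.nanmean(cell))
        if cell_means:
            noise[b] = min(_db(np.array(cell_means)).min(), max_noise_db)

    ping_noise = np.repeat(noise, block_pings)[: grid.n_pings]
    sv_noise = ping_noise[:, None] + tvg[None, :]
    diff = _lin(grid.sv) - _lin(sv_noise)
    with np.errstate(invalid="ignore"):
        sv_corr = _db(np.where(diff > 0, diff, np.nan))
    bad = ~np.isfinite(sv_corr) | ((sv_corr - sv_noise) < snr_threshold_db)
    out.sv = np.where(np.isfinite(sv_corr), sv_corr, grid.sv)
    out._add_mask("noise", bad)
    return out, NoiseEstimate(noise_db=noise, block_pings=block_pings,
                              block_samples=block_samples,
                              snr_threshold_db=snr_threshold_db)


def remove_impulse_noise(grid: EchogramGrid, context_pings: int = 1,
                         smooth_samples: int = 5,
                         threshold_db: float = 10.0) -> EchogramGrid:
    """Remove single-ping impulse (electrical) noise by two-sided comparison.

    After vertical smoothing over ``smooth_samples`` bins (linear domain),
    a sample is an impulse iff it exceeds the sample at the same depth both
    ``context_pings`` before and after by more than ``threshold_db``.
    Flagged samples are replaced by the linear-domain mean of the two
    comparison samples. Edge pings are compared one-sided. Pairs of adjacent
    contaminated pings defeat the two-sided rule at context 1 — a known
    limitation of ping-wise comparison.
    """
    n = int(context_pings)
    if n < 1:
        raise ValueError("context must be at least one ping")
    if n >= grid.n_pings:
        raise ValueError("context exceeds ping count")
    out = grid.copy()
    out._enter_stage("remove_impulse")
    lin = _lin(grid.sv)
    sm = _db(uniform_filter1d(lin, size=max(1, smooth_samples), axis=1,
                              mode="nearest"))
    prev = np.roll(sm, n, axis=0)
    nxt = np.roll(sm, -n, axis=0)
    d_prev = sm - prev
    d_next = sm - nxt
    flag = (d_prev > threshold_db) & (d_next > threshold_db)
    # one-sided at the edges
    flag[:n] = d_next[:n] > threshold_db
    flag[-n:] = d_prev[-n:] > threshold_db

    repl = 0.5 * (np.roll(lin, n, axis=0) + np.roll(lin, -n, axis=0))
    repl[:n] = np.roll(lin, -n, axis=0)[:n]
    repl[-n:] = np.roll(lin, n, axis=0)[-n:]
    out.sv = np.where(flag, _db(repl), grid.sv)
    return out


def smooth(grid: EchogramGrid, window_samples: int = 5,
           window_pings: int = 5) -> EchogramGrid:
    """Moving-mean smoothing in the linear domain over unmasked samples.

    Windows are ``window_pings`` × ``window_samples`` (both odd). Masked
    neighbours are excluded from the mean's denominator; windows with zero
    unmasked samples stay masked.
    """
    if window_samples % 2 == 0 or window_pings % 2 == 0:
        raise ValueError("window dimensions must be odd")
    out = grid.copy()
    out._enter_stage("smooth")
    excl = grid.mask
    lin = np.where(excl, 0.0, _lin(grid.sv))
    w = np.where(excl, 0.0, 1.0)

    def boxsum(a: np.ndarray) -> np.ndarray:
        a = uniform_filter1d(a, size=window_pings, axis=0, mode="constant") \
            * window_pings
        a = uniform_filter1d(a, size=window_samples, axis=1, mode="constant") \
            * window_samples
        return a

    num = boxsum(lin)
    den = boxsum(w)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(den > 0, num / den, np.nan)
    out.sv = np.where(np.isfinite(mean) & ~excl, _db(mean), grid.sv)
    empty = (den == 0) & ~excl
    if empty.any():
        out._add_mask("smooth-empty", empty)
    return out


def apply_sv_threshold(grid: EchogramGrid,
                       threshold_db: float = -80.0) -> EchogramGrid:
    """Mask weak samples with Sv strictly below the minimum-Sv threshold.

    The default −80 dB re 1 m⁻¹ removes signal too weak to originate from
    macrozooplankton or nekton; a sample at exactly the threshold is kept.
    """
    out = grid.copy()
    out._enter_stage("threshold")
    out._add_mask("below-threshold", grid.sv < threshold_db)
    return out


def compute_mvbs(grid: EchogramGrid, cell_depth_m: float = 1.0,
                 cell_dist_nmi: float = 0.1,
                 min_valid_frac: float = 0.3) -> MvbsGrid:
    """Echo-integrate the cleaned grid into distance × depth MVBS cells.

    MVBS = 10·log₁₀(mean of 10^(Sv/10)) over unmasked samples per half-open
    cell. The fraction of unmasked samples is recorded per cell; cells below
    ``min_valid_frac`` are undefined (NaN). A trailing partial distance cell
    is kept and flagged rather than dropped, so NASC additivity over the
    transect holds exactly.
    """
    if cell_depth_m <= 0 or cell_dist_nmi <= 0:
        raise ValueError("cell dimensions must be positive")
    d = grid.distance_nmi
    d0 = d.min()
    n_dist = int(np.floor((d.max() - d0) / cell_dist_nmi)) + 1
    dist_edges = d0 + cell_dist_nmi * np.arange(n_dist + 1)
    z0 = grid.depth_edges[0]
    n_depth = int(np.ceil((grid.depth_edges[-1] - z0) / cell_depth_m))
    depth_edges = z0 + cell_depth_m * np.arange(n_depth + 1)

    pi = np.clip(np.searchsorted(dist_edges, d, side="right") - 1, 0, n_dist - 1)
    zc = grid.depth_centers
    zi = np.clip(np.searchsorted(depth_edges, zc, side="right") - 1,
                 0, n_depth - 1)

    lin = _lin(grid.sv)
    ok = ~grid.mask
    flat_idx = (pi[:, None] * n_depth + zi[None, :]).ravel()
    sums = np.bincount(flat_idx, weights=np.where(ok, lin, 0.0).ravel(),
                       minlength=n_dist * n_depth)
    cnt_ok = np.bincount(flat_idx, weights=ok.ravel().astype(float),
                         minlength=n_dist * n_depth)
    cnt_all = np.bincount(flat_idx, minlength=n_dist * n_depth).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_lin = np.where(cnt_ok > 0, sums / cnt_ok, np.nan)
        frac = np.where(cnt_all > 0, cnt_ok / cnt_all, 0.0)
    mvbs = _db(mean_lin).reshape(n_dist, n_depth)
    frac = frac.reshape(n_dist, n_depth)
    mvbs[frac < min_valid_frac] = np.nan

    lat = np.full(n_dist, np.nan)
    np.add.at(lat, pi, 0.0)  # ensure shape
    counts = np.bincount(pi, minlength=n_dist).astype(float)
    lat_sum = np.bincount(pi, weights=grid.lat, minlength=n_dist)
    with np.errstate(invalid="ignore"):
        lat = np.where(counts > 0, lat_sum / counts, np.nan)
    partial = np.zeros(n_dist, dtype=bool)
    if d.max() < dist_edges[-1]:
        partial[-1] = True
    return MvbsGrid(freq_khz=grid.freq_khz, dist_edges=dist_edges,
                    depth_edges=depth_edges, mvbs=mvbs, valid_frac=frac,
                    lat=lat, partial=partial, min_valid_frac=min_valid_frac)
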