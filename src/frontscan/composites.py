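"""Three-frequency RGB composites of MVBS echograms.

Each frequency channel (red = 18 kHz, green = 38 kHz, blue = 120 kHz) is
linearly rescaled from its transect-wide MVBS range onto the 0–255 colour
scale, gamma-normalised and optionally brightened. Because the minimum
detectable organism size scales with wavelength, colour encodes community:
red/green dominance marks swim-bladdered fish, blue marks
macrozooplankton, and mixed colours mark overlapping assemblages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .echogram import MvbsGrid


@dataclass
class RgbComposite:
    """(n_dist, n_depth, 3) uint8 image; missing data rendered black."""

    rgb: np.ndarray
    channel_khz: tuple[float, float, float]
    gamma: float
    brighten: float


def color_index(mvbs, min_mvbs: float, max_mvbs: float):
    """Linear rescale of MVBS onto the 256-level colour scale.

    255·(MVBS − min)/(max − min), clipped to [0, 255]; min and max are the
    per-frequency extremes over the whole transect. NaN maps to 0.
    """
    if max_mvbs <= min_mvbs:
        raise ValueError("max MVBS must exceed min MVBS")
    x = np.asarray(mvbs, dtype=float)
    out = 255.0 * (x - min_mvbs) / (max_mvbs - min_mvbs)
    out = np.clip(out, 0.0, 255.0)
    return np.where(np.isfinite(x), out, 0.0) if out.ndim else \
        (0.0 if not np.isfinite(x) else float(out))


def gamma_normalize(channel: np.ndarray, gamma: float = 2.0) -> np.ndarray:
    """out = 255·(in/255)^(1/γ); monotone, identity at γ = 1."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return 255.0 * np.power(np.asarray(channel, dtype=float) / 255.0,
                            1.0 / gamma)


def build_rgb(mvbs18: MvbsGrid, mvbs38: MvbsGrid, mvbs120: MvbsGrid,
              gamma: float = 2.0, brighten: float = 1.0,
              exclude_dist_ranges: list[tuple[float, float]] | None = None
              ) -> RgbComposite:
    """Compose the three-frequency RGB image from co-registered MVBS grids.

    Per channel: colour-index rescale over the channel's own transect
    min/max (computed after masking), gamma normalisation, then
    multiplicative brightening clipped at 255. ``exclude_dist_ranges``
    (nmi intervals) blanks ship back-tracking or circling segments.
    """
    grids = (mvbs18, mvbs38, mvbs120)
    shape = mvbs38.mvbs.shape
    for g in grids:
        if g.mvbs.shape != shape:
            raise ValueError("MVBS grids are not co-registered")
    chans = []
    for g in grids:
        vals = g.mvbs[np.isfinite(g.mvbs)]
        if vals.size == 0:
            chans.append(np.zeros(shape))
            continue
        lo, hi = float(vals.min()), float(vals.max())
        if hi <= lo:
            hi = lo + 1e-9
        c = color_index(g.mvbs, lo, hi)
        c = gamma_normalize(c, gamma)
        chans.append(np.clip(c * brighten, 0.0, 255.0))
    rgb = np.stack(chans, axis=-1)
    if exclude_dist_ranges:
        centers = mvbs38.dist_centers
        for lo, hi in exclude_dist_ranges:
            rgb[(centers >= lo) & (centers <= hi)] = 0.0
    return RgbComposite(rgb=np.round(rgb).astype(np.uint8),
                        channel_khz=(mvbs18.freq_khz, mvbs38.freq_khz,
                                     mvbs120.freq_khz),
                        gamma=gamma, brighten=brighten)


def save_png(composite: RgbComposite, path: str) -> None:
    """Write the composite as a PNG, depth down and distance rightward."""
    from PIL import Image

    img = np.transpose(composite.rgb, (1, 0, 2))  # depth rows, distance cols
    Image.fromarray(img, mode="RGB").save(path)
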