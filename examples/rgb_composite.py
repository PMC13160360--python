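"""Render the three-frequency RGB composite of a cleaned scene.

Red = 18 kHz, green = 38 kHz, blue = 120 kHz: red/green dominance marks
swim-bladdered fish, blue marks macrozooplankton, mixed colours mark
overlapping assemblages.
"""

import numpy as np

import frontscan as fs
from frontscan.composites import save_png

cfg = fs.SimulationConfig(seed=42)
grids, _ = fs.simulate_echograms(cfg)
clean = fs.clean_echograms(grids, fs.PipelineConfig(seed=42))

mvbs = {f: fs.compute_mvbs(clean[f], 1.0, 0.1) for f in (18.0, 38.0, 120.0)}
comp = fs.build_rgb(mvbs[18.0], mvbs[38.0], mvbs[120.0], gamma=2.0)

save_png(comp, "composite.png")
blue_dominant = (comp.rgb[..., 2] > comp.rgb[..., 0] + 40) & \
    (comp.rgb[..., 2] > comp.rgb[..., 1] + 40)
print(f"composite shape (distance, depth, rgb): {comp.rgb.shape}")
print(f"blue-dominant pixels (zooplankton signature): "
      f"{blue_dominant.sum()} ({100 * blue_dominant.mean():.1f}%)")
print("wrote composite.png")

# The zooplankton layer north of the front appears blue because its
# backscatter rises ~13 dB from 38 to 120 kHz; fish schools render
# yellow-white (strong red+green).
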