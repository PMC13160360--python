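# frontscan

Acoustic–hydrographic analysis of an Arctic shelf thermal front: a tested
Python pipeline for turning multifrequency echosounder backscatter and CTD
sections into classified fish / macrozooplankton abundance series, front
geometry, water-mass maps, RGB frequency composites, and the ecological
statistics that relate them.

It is written for fisheries acousticians and marine ecologists working on
frontal systems (the motivating case is the Barents Sea Polar Front):
people who have 18/38/120 kHz volume-backscattering grids, CTD casts
across a transect, and trawl catches, and want the standard survey
analysis chain as an importable, reproducible library rather than a GUI
workflow. A synthetic-scene generator with planted ground truth makes
every stage verifiable end to end without any survey data.

## What it computes

**Echogram cleaning.** Volume backscattering strength Sv (dB re 1 m⁻¹)
over pings × depth bins is cleaned in a fixed order: resampling of all
frequencies onto the 38 kHz ping clock; near-field (πa²/λ + 2 m) surface
exclusion and seabed dead-zone exclusion (1.5 m above the detected
bottom); background-noise removal in the linear domain against the
range-amplified noise model Sv_noise(r) = N₀ + 20 log₁₀ r + 2αr, masking
samples with SNR < 10 dB; two-sided impulse-noise removal; 5 × 5
linear-domain smoothing; and a −80 dB minimum-Sv threshold. Absorption α
follows the standard three-relaxation seawater formulation. All dB
averaging happens in the linear domain and exclusion masks only ever grow.

**Classification and abundance.** Cleaned grids are echo-integrated into
MVBS cells (3 m × 0.25 nmi for statistics, 1 m × 0.1 nmi for imagery) and
classified by the two-frequency response ΔMVBS₁₂₀₋₃₈: ≤ 5 dB → fish,
> 10 dB → macrozooplankton, between → unclassified; below 150 m (past the
120 kHz usable range) any 38 kHz signal is fish. Selected cells integrate
to the nautical area scattering coefficient
NASC = 4π·1852²·Σ sv·Δz (m² nmi⁻²) per distance bin, the abundance index.

**Hydrography.** CTD profiles (conservative temperature Θ, absolute
salinity S_A, potential density anomaly σθ) are cross-calibrated by
stable-layer offsets, interpolated into latitude × depth sections,
classified into rule-based water masses (Atlantic, modified Atlantic,
Polar, warm Polar, intermediate, cold dense bottom water), and reduced to
N² = (g/ρ₀)·Δσθ/Δz stratification grids. The subsurface front is the
latitude of the strongest change of the 45–55 m mean temperature on a
0.01° grid; the surface front applies the same rule to an SST series and
is reported absent when no gradient stands out.

**Ecology.** Trawl catches are standardized per m³ filtered; diversity is
Shannon–Wiener H′ = −Σ p ln p and Simpson 1 − Σp²; abundance–environment
relationships use Kendall's τ_b with Benjamini–Hochberg adjustment across
the correlation table; community contrasts use ANOSIM on
square-root-transformed relative-abundance Bray–Curtis distances with
seeded label permutations.

## Worked example

```bash
python examples/clean_and_classify.py
```

simulates the default scene (600 pings × 0.1 nmi crossing a front at
77.2° N, 250 m deep, two fish schools and one zooplankton layer over a
240 m seabed), cleans it and classifies it:

```
planted fish         cells: 3072, recovered as FISH: 100.0%
planted zooplankton  cells: 1932, recovered as MACROZOOPLANKTON: 100.0%
NASC shallow fish    : mean   1096.5 max   4385.9 m^2 nmi^-2 over 240 bins
NASC deep fish       : mean    760.8 max   1387.0 m^2 nmi^-2 over 240 bins
NASC macrozooplankton: mean     67.9 max    195.8 m^2 nmi^-2 over 240 bins
```

Every integration cell inside a planted target recovers its class after
the full cleaning chain, and the NASC lines are the along-transect
abundance series the correlation analysis consumes. The other examples
cover front localisation and water masses (`locate_front.py`, which
recovers the planted front to 0.005°), the RGB composite
(`rgb_composite.py`) and the community statistics
(`community_stats.py`, ANOSIM R = 1.000, p = 0.001 for the fully
contrasted two-water-mass community).

The same chain is available from the shell:

```bash
frontscan simulate --seed 42 --out scene/
frontscan preprocess scene/ --out clean/
frontscan run --seed 42 --out run/
```

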