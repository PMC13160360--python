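# Methods

This note documents the models, conventions and design choices behind
frontscan, the way one would document a survey-analysis configuration: what
each stage assumes, which parameters matter, what the synthetic scenes do
and do not emulate, and where the design was genuinely open.

## Conventions

Depth is metres, positive down; depth bins are half-open `[top, bottom)`
intervals and indices are 0-based. Sv and MVBS are dB re 1 m⁻¹. Every mean
of a dB quantity is taken in the linear (power) domain,
`10·log10(mean(10^(x/10)))`; the test suite includes a check that dB-domain
averaging would give a detectably different (and wrong) answer. Exclusion
masks are named boolean layers (surface, bottom, noise, below-threshold,
…) that accumulate monotonically: no stage ever unmasks a sample, and
masked samples never enter any mean.

## Echogram cleaning chain

The chain runs in a fixed order — resample → surface/bottom exclusion →
background-noise removal → impulse removal → smoothing → Sv threshold →
MVBS gridding — and each operation raises `PipelineOrderError` if applied
after a later stage. The order matters: noise estimation assumes
unsmoothed statistics, and thresholding before noise removal would bias
the noise estimate.

**Resampling.** All frequencies are aligned to the 38 kHz ping clock by
nearest-neighbour matching within a 2 s tolerance (unmatched columns are
masked), and depth bins are interpolated onto the reference bin grid
linearly in the linear domain.

**Surface exclusion.** The near-field range is taken as πa²/λ for
transducer radius a, plus a 2 m buffer. Radii are configuration (the
instrument spec sheet value); the shipped defaults (0.45 / 0.35 / 0.16 m
at 18 / 38 / 120 kHz) put the 38 kHz exclusion near 12 m. A per-ping
manual override deepens the line under bubble or ice noise.

**Bottom exclusion.** A simple detector: per ping, the bottom is the top
edge of the shallowest bin below a minimum depth whose Sv reaches −35 dB;
everything from 1.5 m above that line down is masked (the acoustic dead
zone). Pings without a detection keep the full column — valid in deep
water. The manual per-ping override is first-class, since automated
detection is known to fail on steep or soft bottoms.

**Background noise.** The noise model is additive in the power domain:
`Sv_noise(r) = N₀ + 20·log10(r) + 2αr`, i.e. a constant receiver-noise
level amplified by the time-varied gain. TVG-removed power is averaged in
cells (default 20 pings × 5 samples) and the noise per ping block is the
minimum cell mean over depth, capped at a maximum plausible noise of
−125 dB. The cap is integral to the published algorithm: a block-wide
contaminant (an impulse ping) otherwise inflates the estimate and the
10 dB SNR cut then masks genuine weak scatterers. Noise is subtracted in
the linear domain; non-positive differences and samples within 10 dB of
the noise line are masked.

**Impulse noise.** After vertical smoothing over 5 samples, a sample is an
impulse iff it exceeds the same-depth sample both n pings before and
after by more than 10 dB (n = 1 by default; the threshold is not part of
the published description and is exposed in configuration). Flagged
samples are replaced by the linear mean of the two comparison samples;
edge pings are compared one-sided. Two adjacent contaminated pings defeat
the two-sided rule at n = 1 — a documented limitation of ping-wise
comparison, covered by a test.

**Absorption.** The three-relaxation empirical formulation (boric acid,
magnesium sulfate, pure-water viscosity), valid 10–500 kHz, evaluated at
scene temperature/salinity and mid-column depth. An independently coded
evaluation of the published equations serves as the test oracle.

**Thresholding and gridding.** The −80 dB minimum-Sv threshold is applied
last, with the boundary retained (strict `<` for removal). MVBS cells are
half-open in both distance and depth; each records its unmasked-sample
fraction and is undefined below 30% validity. Trailing partial distance
cells are kept and flagged rather than dropped so that NASC additivity
over the transect holds exactly.

## Classification and NASC

ΔMVBS₁₂₀₋₃₈ thresholds: ≤ 5 dB fish (the published upper limit of fish
frequency response, read as inclusive), > 10 dB macrozooplankton (read as
strict), the 5–10 dB band unclassified. Unclassified cells contribute to
neither NASC series — the conservative choice where the source analysis
is silent. The 150 m split (the 120 kHz usable-range limit) assigns
straddling cells by their top edge, consistent with half-open bins; below
it, any defined 38 kHz cell is fish. NASC = 4π·1852²·Σ sv·Δz over selected
cells, binned at 0.1 nmi by default (0.25 nmi available — the statistics
grid and the reporting resolution differ in the motivating survey, so bin
width is a parameter).

## Hydrography

Water-mass classification is a total function on (S_A, Θ, σθ). The cold
classes overlap in their defining table (Θ ≤ 0 alone satisfies several
rows); they are made exclusive by splitting on density first (σθ ≤ 27.97
→ Polar) and then temperature (Θ > −1.1 → intermediate, else cold dense
bottom water). A dense-grid comparison against an independently coded
rule table is part of acceptance.

Front localisation averages Θ over the 45–55 m band (bin means — whether
the underlying analysis used all samples or bin means is ambiguous, bin
means chosen), interpolates onto a 0.01° latitude grid, and places the
front at the midpoint of the adjacent-pair interval with the largest
|ΔΘ|, ties broken toward the lowest latitude (deterministic; real
sections do not tie). The surface variant applies the same rule to an SST
series and returns "absent" when the largest step is below a minimum
gradient — the summer regime where the surface layer is uniformly warm.
The 0.01° recovery guarantee holds for logistic transition scales up to
about 0.05°; wider transitions have no single well-defined gradient
maximum at that resolution under realistic sensor noise.

Distances to front features are haversine (R = 6371 km) along the
meridian, signed positive north by default; the sign convention is a
flag, because rank correlations need a monotone covariate while plain
"distance from" is unsigned.

N² = (g/ρ₀)·Δσθ/Δz between adjacent levels, g = 9.81 m s⁻², ρ₀ = 1025 kg
m⁻³, both configurable. Stability-class bin edges are configuration with
no claimed defaults (the binning thresholds used by the motivating survey
are not printed in its main text). Section interpolation is bilinear
between adjacent casts with no extrapolation beyond the profile hull.

Cross-instrument calibration estimates constant (ΔT, ΔS) offsets as the
mean reference-minus-target difference over a stable-layer window, guarded
by a |dΘ/dz| ≤ 0.02 °C m⁻¹ check so stratification cannot alias into the
offset.

## Composites

Each channel (red 18, green 38, blue 120 kHz) is rescaled linearly from
its own transect-wide MVBS min/max (computed after masking) onto 0–255,
gamma-normalised with γ = 2, optionally brightened (default 1.0 — the
source analysis does not quantify brightening), with missing data rendered
black. The printed form of the rescaling equation in the motivating
analysis is algebraically garbled; it is implemented as the standard
linear map `255·(x − min)/(max − min)`, the only reading consistent with
"a colour index value on a scale of 256".

## Ecological statistics

Catches standardize by volume filtered (mouth area × tow distance).
Shannon–Wiener uses natural log (consistent with the magnitudes the
motivating survey reports); Simpson is reported as 1 − Σp². A designated
pooled taxon (e.g. a mixed-mesozooplankton fraction enumerated only by
biomass) can be excluded from count-based diversity while its biomass
stays in community outputs. Kendall's τ_b handles ties; its p-value is
exact (enumeration) for small untied samples and asymptotic otherwise,
matching R's `cor.test`. BH adjustment is the step-up rule applied across
the whole correlation table. ANOSIM ranks all pairwise distances (average
ranks for ties), R = (r̄_between − r̄_within)/(M/2), with a seeded
permutation p `(1 + #{R* ≥ R})/(1 + n_perm)`, 999 permutations by
default; a full-enumeration variant exists for validation on tiny
instances. Bray–Curtis distances are computed on square-root-transformed
relative abundance to damp dominance by a few very abundant taxa.

## Synthetic scenes

The generator exists to make every stage falsifiable: each scene carries a
`TruthBundle` (sample-level class mask, true front latitude, noise floors,
impulse-ping indices, station community compositions) aligned with the
grids it annotates. One global seed feeds per-simulator derived streams,
so adding one simulator call never shifts another's draws, and identical
(config, seed) runs are bit-identical.

Defaults define the study conditions at desk scale: a 600-ping × 0.1 nmi
transect crossing a logistic front (scale 0.03°) at 77.2° N; Atlantic
water (5 °C, 35.2 g kg⁻¹) south, Polar water (−1 °C, 34.4 g kg⁻¹) north;
250 m column with 1 m bins over a flat 240 m seabed; noise floors
−132/−130/−127 dB at 18/38/120 kHz; 2% impulse pings at +25 dB; two fish
schools (Δ₁₂₀₋₃₈ of −2 and −3 dB, one above and one below 150 m) and one
zooplankton layer (Δ₁₂₀₋₃₈ = +13 dB) painted as uniform blocks; 16 trawl
stations of 300-individual multinomial draws from two five-taxon
communities whose contrast scales with a 0–1 effect size. CTD sensor
noise is 0.002 °C / 0.001 g kg⁻¹ — the accuracy class of the emulated
instruments — on 1 m bin-averaged profiles. σθ comes from a linear
equation of state (σθ = 28.10 + 0.80·(S_A − 35) − 0.060·Θ), adequate for
rule-based classification over this scene's T–S range; it is not a
TEOS-10 evaluation, and inputs to the hydrography module are assumed
pre-converted to conservative temperature and absolute salinity.

Deliberate simplifications, hence what passing tests do not show: noise is
deterministic at its floor (no Rayleigh fluctuation), so noise-floor
recovery is exact rather than statistical; targets are uniform blocks
with fixed frequency response, not aggregations with target-strength
distributions or beam-pattern effects; impulses hit whole pings, are
isolated (≥ 3 pings apart, the single-ping electrical events the removal
rule addresses), and share no structure with real interference; the
seabed is flat; there is no ship motion, bubble sweep-down or ice
scatter. Recovery rates on these scenes certify the algorithm chain, not
performance on real survey data.

## Problem sizes

Tests and examples run the default 600 × 250 scene (seconds per cleaning
chain); acceptance-style checks use 100 CTD sections for front recovery,
10⁵ points for the water-mass grid, 500 replicates × 199 permutations for
the ANOSIM null calibration, and full enumeration (720 orderings; 120
label permutations) for the small-sample statistics oracles. The whole
suite completes in well under a minute on one core.

## Known limitations

Bottom detection is a threshold detector, not a sounder-grade algorithm —
the manual override is the intended correction path. The background-noise
estimator inherits the published method's sensitivity to block-wide
contamination, bounded but not removed by the maximum-noise cap.
`recorrect_sv` assumes a single sound speed per grid rather than a depth-
dependent profile. NMDS, PERMANOVA, PERMDISP and random-forest covariate
screening are intentionally out of scope; established ecology packages
cover them.
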