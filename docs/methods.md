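# Methods

This note records the models implemented in `tirftrack`, the defaults and
why they were chosen, the numerical decisions that were genuinely open,
and what the synthetic-data validation does and does not show.

## The synthetic movie generator

`simulate.simulate_movie` emulates a single-molecule TIRF recording of
fluorescently labeled membrane receptors. It is the package's ground-truth
machine: every estimator downstream is validated by running it on movies
whose generating parameters are known.

**Motion.** Particles are placed uniformly at surface density ρ (µm⁻²) and
take independent Gaussian steps with per-axis variance `2·D_lat·Δt` per
frame — free 2D Brownian motion, which is what linear MSD-vs-Δt plots
imply for these receptors. Boundaries are periodic; wrap counts are
recorded so unwrapped trajectories (and hence exact ground-truth MSDs) are
recoverable. An `immobile_fraction` of particles never moves, emulating
fluorophores adsorbed nonspecifically to the coverslip; they share the
bleaching kinetics of everything else.

**Optics and noise.** Each unbleached fluorophore contributes an
integrated 2D Gaussian (σ = FWHM/2.3548, FWHM 0.3 µm by default) centered
at its continuous position, scaled to `photons_per_spot` expected counts.
Pixel size defaults to 0.1 µm, so the 5×5-pixel analysis window spans
500×500 nm². Signal is Poisson-sampled per pixel; the camera background is
a constant offset plus Gaussian read noise. No EMCCD gain model and no
evanescent-field axial profile are included: all emitters are treated as
in-focus and in-field. The default photon budget (500 photons/frame/spot
over background 20 ± 3 counts) was chosen so that single bleaching steps
are unmistakable by eye and centroid localization lands at ~20 nm RMS,
matching the working precision such experiments quote; it is a realistic
mid-range budget for a bright cyanine dye at 50 frames/s, not a fit to any
particular instrument.

**Photobleaching.** Each fluorophore has an exponential waiting time with
rate `k_bleach` and never re-emits. Emitter counts therefore decay as
`exp(−k_bleach·t)`, which the density module exploits.

**Dimerization.** Receptor dimerization is contact-driven mass action:
monomer pairs within a capture radius (0.1 µm) associate with the per-step
probability implied by the 2D on-rate `k_on` (µm²/s), so the macroscopic
association rate is `k_on·ρ_M` per monomer; dimers dissociate at `k_off`
(1/s), separating to the capture radius. A dimer diffuses as one particle
at `D_lat` and renders as two coincident fluorophores — one spot of double
intensity until a partner bleaches. Dimer chemistry ignores bleach state
(a dark fluorophore still labels a receptor). Defaults `k_on = 0.15 µm²/s`
and `k_off = 1 s⁻¹` give a ~1 s dimer lifetime and a dimer-bound receptor
fraction rising from ~9% at 0.75 µm⁻² to ~25% at 3 µm⁻², the regime in
which a minority dimer population coexists with mostly monomers and the
dimer-type track fraction grows visibly with expression level.
`simulate_dimer_kinetics` runs the same kinetics without imaging;
completed dimer dwell times average `1/k_off` (the discrete-time geometric
correction of +Δt/2 and occasional immediate recapture keep this within a
few percent).

**What the generator does not emulate.** Fluorophore blinking and triplet
states, spectral bleed-through, uneven illumination, membrane topography,
camera gain statistics, and cell-shaped footprints (fields are
rectangles). Estimator performance quoted below is therefore an upper
bound for real data in exactly those respects.

## Spot detection, linking, and their calibration

Detection thresholds at `median + threshold_sd × robust SD` (MAD-based,
default 5 SD) per frame, finds local maxima at least `min_separation`
(0.4 µm) apart, subtracts the local background (median of the 9×9 ring
around the 5×5 window), and refines positions by windowed centroid.
Measured localization error at the default photon budget is ~21 nm RMS,
within the 25 nm the analysis assumes. False positives on blank frames are
below 1% of frames at the default threshold.

Linking is greedy nearest-neighbor, resolved per frame pair in ascending
distance, with a maximum displacement gate defaulting to
`3·√(4·D_max·Δt)` (D_max = 1 µm²/s) so >99% of Brownian steps fall inside.
Full bipartite optimization was deliberately not used: at the densities
this package targets (≤10 µm⁻², and ≤0.8 µm⁻² for quantitative tracking)
greedy assignment recovers ≥90% of ground-truth identities, and the
simpler algorithm is transparent to test. No gap closing by default
(blinking is not modeled); analyses that want robustness to isolated
missed detections can set `max_gap=1`.

Two systematic effects matter and were calibrated once on synthetic ground
truth, then frozen:

* **Matched gates.** With the gate fixed at the D_max = 1 default, rare
  wrong links across the wide gate inflate the fitted D of slow conditions
  (+12–18% at D = 0.1 µm²/s). Setting the gate from the condition's own
  expected maximum diffusivity — what the parameter is for — removes the
  bias (recovery within ~3% for D ∈ {0.1, 0.15, 0.6} µm²/s at
  ρ = 0.3 µm⁻²). The validation protocol therefore uses matched gates.
* **Coincidence loss.** Two spots closer than the resolvable separation
  merge and count as one. The first-order correction
  `ρ = obs/(1 − obs·π·r²/2)` with an *effective* merge radius r = 0.5 µm
  (calibrated against ground truth across ρ = 0.1–0.5 µm⁻²; slightly
  above the nominal 0.4 µm separation because peak suppression extends
  beyond it) leaves residual bias below ~5% in the countable regime. The
  correction is opt-in (`merge_radius=`), so a plain count stays a plain
  count.

## Mobility

`msd_curve` pools every pair of positions separated by a given lag over
all tracks (combined time- and ensemble-averaging — records here
contribute hundreds of short tracks, not a few long ones). `fit_dlat` puts
a pair-count-weighted least-squares line through the first 4 lags (common
short-lag practice; only the early MSD is purely diffusive) and keeps a
free intercept to absorb the static localization error, which adds
`4σ_loc²` ≈ 0.002 µm² at σ_loc ≈ 22 nm. Negative fitted slopes clamp to
zero and are flagged. `classify_motion` fits the anomalous exponent α on
log-log axes; |α−1| ≤ 0.15 is "free", above is "flow", below "caged". The
0.15 tolerance gives <5% misclassification of genuinely Brownian input at
the track counts used here, while drift of 1 µm/s or confinement at
0.2 µm is still caught reliably. `fit_temperature` fits
`D(T) = D_ref·exp(k(T−T_ref))` (log-linear start, then exponential least
squares) and reports `Q10 = exp(10k)`; mobility doubling per 10 °C means
Q10 = 2.

## Stoichiometry

Intensity traces are the background-subtracted mean counts/pixel over the
5×5 window at the rounded tracked position (total counts are 25× larger);
the window is held at the last position for 10 extra frames so the final
drop to background is part of the trace. Traces are smoothed with a
3-point running median (endpoints pass through; NaN frames from
edge-clipped windows do not spread).

Step detection computes a 5-point running first derivative (mean of the
two samples ahead minus mean of the two behind), estimates its noise with
a two-stage robust scale (MAD, then re-estimate after masking >3σ values —
a plain MAD is inflated by the step ramps themselves), and accepts local
derivative extrema above `threshold_sd` (default 4) robust SDs. Candidate
transitions must also separate the adjacent level means by `threshold_sd`
standard errors (spurious single-sample excursions split noise into
near-equal levels and are removed), positions are refined to the local
least-squares frame, and a CUSUM-style binary-segmentation pass (with a
+1 SD multiple-testing allowance) recovers steps whose derivative peak
fell just under threshold. At 20% noise this finds both steps of a
two-step staircase within ±2 frames in ~98% of traces while triggering on
<1% of pure-noise traces.

Levels are quantized against a single-fluorophore unit intensity with a
±35% acceptance band — wide enough for Poisson level noise, narrow enough
that 1- and 2-unit levels cannot overlap (the bands are [0.65, 1.35] and
[1.65, 2.35] units). Adjacent equal quantized levels merge. The sequence
then maps to: `1→0` type 1 (monomer), `2→1→0` type 2 (dimer), `1→2→0`
type 3 (transient dimer); any other pattern containing a 2-unit level is
"other-dimer" (two-level alternation); anything with a ≥3-unit level
raises a higher-oligomer flag and stays unclassified, and on dimer-max
simulations this flag fires on <1% of traces. The unit intensity is best
calibrated on a sparse (ρ ≈ 0.3 µm⁻²) movie, mirroring the practice of
measuring monodisperse dye on a coverslip: at working densities the
intensity histogram's mode is biased by neighbor contamination inside the
window. Type fractions are most meaningful over *complete* records —
traces whose final level is background — since censored tracks (movie
ended first) and fragments cannot reveal their stoichiometry; the
end-to-end density comparison uses that filter.

The chance-coincidence null (`coincidence_null`) simulates independent
point diffusers and counts tracks containing a *sustained* interval (at
least `min_dwell_s`, default 0.5 s) with another particle inside the
coincidence distance (default 0.3 µm). The dwell requirement matters: at
1.5 µm⁻² an instantaneous neighbor within 0.3 µm is a ~35% event per
frame, but dimer-type tracks alternate at the two-unit level for of order
a second, and sustained chance coincidences of that duration occur in only
~2% of tracks — an order of magnitude below a ~10% observed dimer-track
rate.

## Density

Direct counting divides mean spot count by footprint area (use the
border-eroded area: detection excludes a 2-pixel margin) and flags
estimates above 0.8 µm⁻², where overlap makes counts collapse — silently,
so the flag on the *estimate* cannot catch severe undercounting by itself.
Bleach extrapolation handles that regime: fit the bulk rate k from the
summed field intensity (`I₀·exp(−kt) + offset`), then estimate
`ρ₀ = ρ(t)·exp(+k·t)` from late frames. The usable window is found
self-consistently — start from the late tail, estimate ρ₀, re-derive the
window as frames where the *model* density `ρ₀·exp(−kt)` is below
0.25 µm⁻², iterate — because a window chosen on observed counts alone
admits early frames of a dense movie whose collapsed counts masquerade as
sparse. Within the window the Poisson maximum-likelihood combination
`ρ₀ = Σcounts / (A·Σexp(−kt))` weights frames by expected occupancy
instead of amplifying nearly-empty ones. Recovery on synthetic movies
(20×20 µm, k = 0.3 s⁻¹) is within a few percent at ρ₀ = 2 and 5 µm⁻² and
~12% at 10 µm⁻², where the `exp(+kt)` amplification of the fitted-rate
error dominates the budget. `tissue_average_density` is the bookkeeping
product `expressing_fraction × expressing_density` for tissue in which
only a subset of cells express the receptor.

## The collision simulation

Receptors and channels random-walk in a periodic box (≥5 µm; default 6 µm
giving 108 of each species at 3 µm⁻²). An encounter is scored when a pair
distance first crosses below the collision radius b = 6 nm from outside.
Two numerical decisions deserve their reasoning on record:

**Time step.** The RMS *relative* displacement per step is capped at b/2
(`√(2·(D_R+D_G)·dt) ≤ b/2`), else pairs tunnel through the capture disc
between samples; at D = 1 µm²/s each this forces dt ≈ 2.25 µs and ~9×10⁵
steps for a 2 s run, hence the Verlet pair list (rebuilt every 64 steps
with a 10-SD margin on the cutoff) and the numba-compiled inner loop
(~12 s per seed on one CPU). At the b/2 boundary a residual discretization
deficit of order 5–10% remains (measured by step-halving at an enlarged
collision radius: rates 5.24 → 5.67 → 5.75 under dt, dt/2, dt/4);
convergence is verified between dt/2 and dt/4, and the b/2 default is kept
as the working resolution — its ~9 s⁻¹ rate sits inside the expected
bracket with the discretization budget included.

**Encounter definition (escape radius).** A 2D diffusing pair that has
just separated to a small multiple of b re-approaches with near certainty
(recurrence), so re-arming a pair at 2b scores one physical approach ~5
times (32 s⁻¹ instead of ~6–9 s⁻¹ at the reference conditions). A
"collision" in the collision-theory sense is a *statistically fresh*
approach, so the pair must separate beyond a decorrelation distance before
it can score again. The default is the half mean inter-channel spacing at
the reference density, `0.5/√3 ≈ 0.29 µm`, fixed rather than
density-dependent so the rate stays exactly linear in channel density
(measured doubling ratio 2.01 ± 0.1). With it, the simulated rate at the
reference conditions is 8.9 ± 0.1 s⁻¹ against the 2D Smoluchowski
comparator `k(t)·ρ = 4πD_rel/ln(4·D_rel·t/b²)·ρ = 6.1 s⁻¹` at a 1 s
horizon — factor 1.45, consistent with a log-corrected 2D rate. The
escape radius is an explicit parameter; the mean *first*-encounter latency
(~130 ms at the reference conditions) does not depend on it.

## Binding

Occupancy is the Langmuir isotherm `L/(L+Kd)`; competition is the
single-site model `(L/Kd)/(1 + L/Kd + I/Ki)` with Hill slope 1 and
Cheng–Prusoff IC50. Ligand depletion is ignored (free ≈ total), standard
at nanomolar concentrations and picomolar-to-nanomolar Kd. Affinities are
carried as log10 values and Kd derived, matching how they are reported.

## Validation protocol and problem sizes

The test suite validates each estimator against the generator at sizes
chosen to keep the whole suite to a few minutes while leaving comfortable
statistical margins: diffusion recovery on 25×25 µm movies at 0.3 µm⁻²
(≥300 tracks, three diffusivities spanning the cultured-cell/tissue-slice
contrast, errors ≲3% against a 10% band); density recovery on 20×20 µm
bleaching movies at ρ₀ ∈ {2, 5, 10} µm⁻² (two replicates each against a
15% band); step-detection performance on 10³ synthetic staircases; the
dimer-fraction density dependence on three seeds per density with the
complete-record filter; and the collision simulation at full membrane
scale (5 seeds × 108 receptors × 2 s). `scripts/acceptance.py` re-runs the
occupancy arithmetic and the membrane-scale collision simulation from
scratch and writes their numbers as JSON.

## Known limitations

* Quantitative tracking (MSD-grade) is validated at ≤0.5 µm⁻²; above that,
  identity swaps and window contamination bias per-track quantities even
  though counting (with the coincidence correction) and type fractions
  remain usable to ~3 µm⁻².
* The step classifier assumes a stable unit intensity; it has no model of
  partial quenching, FRET, or z-dependent excitation.
* The coincidence null treats particles as points; it does not render
  images, so it answers "how often would independent molecules co-locate"
  rather than "how would the full pipeline score such tracks".
* The collision rate's absolute value depends on the documented encounter
  definition (escape radius) up to factors of order unity; cross-study
  comparisons should fix that definition first. The first-encounter
  latency is the robust output.
* All validation is synthetic; none of it certifies performance on real
  movies with blinking dyes, uneven illumination, or curved membranes.
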