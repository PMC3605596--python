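# tirftrack

Single-molecule TIRF microscopy simulation and analysis for membrane
receptors: how many are there, how fast do they move, are they monomers or
dimers, and how quickly do they find their signaling partners.

Total internal reflection fluorescence (TIRF) microscopy images only the
~100 nm of sample closest to the coverslip, so a receptor tagged with a
fluorescent antagonist appears as a diffraction-limited spot (~300 nm
FWHM) that can be localized to ~25 nm and tracked as it diffuses in the
plasma membrane. This package implements the full quantitative chain for
that kind of experiment — aimed at G-protein-coupled receptors such as the
M2 muscarinic receptor on cardiomyocytes, but generic in its machinery:

* **`tirftrack.simulate`** — synthetic TIRF movies with per-frame ground
  truth: Brownian diffusers at surface density ρ, integrated-Gaussian
  PSFs, Poisson shot noise, single-step photobleaching, a reversible
  monomer–dimer equilibrium (2D mass-action contact kinetics), and
  immobile nonspecific spots.
* **`tirftrack.tracking`** — spot detection (robust-noise threshold,
  sub-pixel centroid over a 5×5-pixel window), PSF width measurement, and
  greedy nearest-neighbor trajectory linking.
* **`tirftrack.mobility`** — MSD vs Δt curves; the lateral diffusion
  coefficient from `MSD = 4·D_lat·Δt`; motion classification
  (free / flow / caged) from the anomalous exponent; monoexponential
  temperature dependence `D(T) = D_ref·exp(k·(T−T_ref))` with
  `Q10 = exp(10k)`.
* **`tirftrack.stoichiometry`** — per-track intensity traces, 3-point
  median smoothing, photobleaching-step detection (5-point running
  derivative plus a CUSUM recovery pass), trajectory typing
  (type 1 = monomer, type 2 = dimer, type 3 = transient dimer), intensity
  histograms, and a Monte-Carlo chance-coincidence null.
* **`tirftrack.density`** — surface density by direct spot counting
  (reliable below ~0.8 µm⁻²) and by back-extrapolation of late-movie
  counts with the bulk photobleaching rate
  (`ρ₀ = ρ(t)·exp(+k_bleach·t)`), up to ~10 µm⁻².
* **`tirftrack.binding`** — 1:1 ligand occupancy `L/(L+Kd)` and
  single-site competition curves (Cheng–Prusoff IC50).
* **`tirftrack.collision`** — a JIT-compiled 2D Monte-Carlo of
  receptor–channel diffusional encounters: both species random-walk in a
  periodic box, an encounter is a first approach within the 6 nm collision
  radius, and a pair re-arms only after separating beyond a decorrelation
  distance. Compared against the 2D Smoluchowski rate
  `k(t) = 4πD_rel / ln(4·D_rel·t / b²)`.
* **`tirftrack.io` / `tirftrack.cli`** — TIFF + JSON-sidecar movies,
  track CSVs with explicit units, a one-call `pipeline_run`, and a thin
  `tirftrack` command-line wrapper.

## Worked example

Simulate a movie, track it, and recover the diffusion coefficient
(`examples/03_diffusion_from_msd.py`):

```
lag (s)   MSD (um^2)   pairs
  0.02     0.0137     22409
  0.04     0.0259     21698
  0.06     0.0378     20987
  0.08     0.0495     20276
  ...
D_lat = 0.149 +/- 0.001 um^2/s (true 0.150), intercept 1.84 x10^-3 um^2
motion class: free
```

The MSD is linear (free diffusion), its slope/4 recovers the generating
D_lat within 1%, and the intercept of ~0.0018 µm² is the static
localization error (4σ² with σ ≈ 21 nm).

Ask how often a receptor meets a channel
(`examples/06_collision_latency.py`; takes ~2 minutes because the 6 nm
capture radius forces microsecond time steps):

```
encounter rate: 8.90 +/- 0.12 per receptor per second (9614 encounters, 540 receptors)
mean first-encounter latency: 132 +/- 7 ms
2D Smoluchowski comparator (1 s horizon): 6.12 s^-1
```

At 3 receptors and 3 channels per µm², each diffusing at 1 µm²/s, a
receptor encounters a channel 5–10 times per second and waits ~130 ms for
its first encounter — the diffusion-limited share of the delay between
agonist application and potassium-current onset.

The other scripts in `examples/` cover ligand occupancy, tracking,
photobleaching-step classification, and bleach-extrapolated density; each
prints a few numbers and says what they mean.

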