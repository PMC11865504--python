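# Methods

Units throughout: mM for concentrations, µm for lengths, s for times.

## Reaction cycle (`chem_cycle`)

The dilute phase carries four species: precursor peptide `c_P`, activated
(anhydride) peptide `c_A`, aqueous fuel `c_F` and waste `c_W`.

    dc_A/dt =  k_act·c_P·c_F − k_deact·c_A
    dc_P/dt = −k_act·c_P·c_F + k_deact·c_A
    dc_F/dt =  k_exchange·(K_p·c_fuel_oil − c_F) − k_act·c_P·c_F − k_fuel_loss·c_F
    dc_W/dt =  k_act·c_P·c_F + k_fuel_loss·c_F

By default fuel exchange is instantaneous (`k_exchange = ∞`): `c_F` is
clamped to `min(K_p·c_fuel_oil, fuel_solubility)`. Peptide (`c_P + c_A`)
is conserved exactly; waste is monotone. The steady state solves the
fixed point in closed form (instantaneous exchange) or by bracketed root
finding on the fuel balance (finite exchange), and flags whether
`c_A_ss > c_sat` (droplets possible).

### Calibrated default parameters

The experimental system's full rate table is not publicly tabulated
alongside its headline observables, so every default is a placeholder
**calibrated to a reported observable** and exposed in config:

| parameter | default | anchored to |
|---|---|---|
| `K_p` | 0.013 | the 20 mM oil ↔ 0.26 mM aqueous fuel pair |
| `k_deact` | ln2/60 s⁻¹ | activated-peptide half-life of ~1 minute |
| `c_sat` | 0.0375 mM | midpoint of the 0.025–0.05 mM critical range |
| `k_act` | 1.25·10⁻⁴ mM⁻¹s⁻¹ | inside the bracket forced by "no droplets at 0.26 mM fuel, droplets at 0.46 mM" with 10 mM peptide |
| `c_den` | 500 mM | typical complex-coacervate dense-phase concentration |
| `k_up` | 38.5 µm/s | optimal radius R\*(c_sat) = 0.75 µm |
| `fuel_solubility` | 10 mM | upper end of the observed steady-state fuel range |
| `k_fuel_loss` | 10⁻⁴ s⁻¹ | slow direct hydrolysis; secondary to activation |

The bulk reference condition (gel-layer emulsion) uses 14 mM total
peptide and 7 mM aqueous fuel — the middle of the 2.5–10 mM steady-state
fuel range the droplet experiments span. With the calibrated constants
this puts the model's extinction half-life at 2.13 s; the value is always
computed by root finding, never assigned.

## Size control (`size_control`)

Influx through the surface, `4πR²·k_up·c_A`, against efflux from the
volume, `k_deact·c_den·(4/3)πR³`, gives

    dR/dt = k_up·c_A/c_den − (k_deact/3)·R,   R* = 3·k_up·c_A/(k_deact·c_den).

R\* is the unique positive root and is linearly stable. The influx is
driven by `c_A` itself (a supersaturation-driven variant, `c_A − c_sat`,
is a config switch; both are tested). Deactivated material leaves the
droplet instantly as precursor; the dense phase is incompressible at
`c_den`.

**Mean-field emulsion.** All droplets share one dilute pool. Per step the
pool ODE `c_A' = S − (k_deact + β)·c_A` (with `β = Σ4πR²k_up/V` the
uptake conductance) is advanced with its exact exponential solution, and
droplet volume changes are computed from the **time-integrated** pool
concentration, so the peptide inventory closes identically at any step
size — the pool is much stiffer than the radii, and a naive splitting
(chemistry first, uptake second) biases the concentration droplets see by
O(dt·β), which inflates the steady radius. Material bookkeeping is
asserted at 10⁻⁶ relative every output step and holds to rounding.

Nucleation is a Poisson process with rate
`coeff·(c_A − c_sat)·(x)^(p−1)·V` where `x = (c_A − c_sat)/c_sat`;
nuclei enter at `R_nuc = 2·R_min` (0.2 µm) and droplets crossing
`R_min = 0.1 µm` dissolve back into the pool. The mean-field default is
the linear law (`p = 1`) with `coeff = 10⁻²` per mM·µm³·s — fast enough
that the pool tracks its balance point during the transient, which keeps
the steady radius nearly independent of fuel (the observed behavior)
while the droplet number density absorbs the extra material. A
consequence of this strong pinning is that the number density also rises
slightly with peptide concentration, where the source system reports it
stable; the radius trend (slightly increasing) is reproduced.

**Passive mode** switches reactions off and evolves radii by
interface-limited Gibbs–Thomson exchange,
`dR/dt = k_up·(c_pool − c_sat·(1 + ℓ_c/R))/c_den`, reproducing
Ostwald coarsening (mean radius up, count down, distribution widening) —
the control signature opposite to active size control.

**Steady states in simulation.** The emulsion's final pool concentration
(and hence mean radius) depends on how far nucleation overshoots before
the growing droplets absorb the supersaturation; it settles below `c_sat`
and every surviving droplet sits on R\*(pool) to high precision. The
printed-optimum check therefore evaluates the growth-law root at the
coexistence ambient level `c_A = c_sat` (desk calculation), while the
simulated plateau (≈0.39 µm at the reference) is reported as the
emulsion's own steady radius. The experimental plateau values depend on
unpublished fitted constants and are deliberately not targeted.

## Synthetic cell (`cell_sim`)

One sphere of radius `r_cell` (default 25 µm, 10 mM peptide, 250 mM oil
fuel). Dilute species live on `n_layers = 12` horizontal slabs with
conservative explicit vertical diffusion; droplets carry 3-D positions
and exchange material with the layer their center occupies. Motion is
Stokes settling `v = sed_coeff·R²` downward plus isotropic Brownian
displacements with `D = kT_drag/R`; at the wall droplets are projected
inside and roll along the tangential component of gravity, pooling at the
bottom. Contacting droplets coalesce (volume-conserving, ascending-id
tie-break); layers above `c_sat` nucleate with the steepened law `p = 3`
(classical nucleation is sharply supersaturation-dependent) and
`coeff = 10⁻⁴`, which makes nucleation a rare, volume-scaled event — this
is what gives larger cells their shorter lag.

Transport defaults: `D_A = D_P = 50 µm²/s` (small peptide/complex in
buffer), `sed_coeff = 1.0 µm⁻¹s⁻¹` and `kT_drag = 0.02 µm³/s`, chosen
once so that µm-scale droplets cross a 25 µm cell in tens of seconds
while fresh nuclei stay suspended (the Péclet crossover radius
`(kT_drag/sed_coeff)^{1/4} ≈ 0.4 µm` sits between nucleus and optimal
size). None of these transport constants is published for the source
system.

The fixed time step must satisfy
`dt ≤ 0.1·min(Δz²/D, 1/k_deact, 1/(k_act·c_F))` (checked, with a
suggested value on failure) and is snapped to divide the output interval
so recorded series are uniformly sampled. A fixed seed gives bit-identical
trajectories and event logs. Peptide inventory (layers + droplet-bound) is
checked at 10⁻⁶ relative during runs.

With these defaults the reference cell oscillates with a period of 3–7
minutes (seed-dependent), the upper- and lower-half volumes are
anti-correlated, the period shortens with more fuel and with larger
cells, and below ~0.5 mM aqueous fuel the cell holds a single stable
bottom droplet — the threshold behavior expected of a relaxation
oscillator. Gel conditions (`fusion_enabled=False, motion_enabled=False`)
freeze the droplet count after the initial burst with PDI < 0.05.

## Image quantification (`image_quant`)

Per frame: maximum-intensity z-projection → Gaussian blur (σ = 2 px) →
Otsu threshold (256-bin histogram) → 8-connected components →
area ≥ 0.1 µm² and circularity 4πA/P² in [0.8, 1]. Circularity uses the
sub-pixel Crofton perimeter by default (pixel-edge counting deflates the
circularity of small blobs; the raw estimate is available), capped at 1.
Centroids are intensity-weighted, in µm with pixel centers at
half-integers. Radius and volume assume a spherical droplet:
`R = √(A/π)`, `V = (4/3)πR³`.

A known systematic: thresholding after the σ = 2 blur inflates the area
of few-pixel objects (+64 % at R = 3 px, +3 % at 6 px, −5 % at 8 px on
rendered disks). Detection is reliable down to 3 px; area fidelity within
10 % holds from ~6 px (≈0.6 µm, the emulsion's typical droplet scale).

Tracking: per frame, open tracks are matched to detections by the
Hungarian algorithm (scipy's `linear_sum_assignment`) on centroid
distance; links beyond 1 µm are forbidden, unmatched tracks persist at
their last position for up to 3 missing frames (no motion extrapolation),
new detections open tracks. Optimality is cross-checked against
brute-force enumeration of all partial matchings for small frames.

## Wave metrics (`osc_metrics`)

PDI = population σ / mean. Per-half volumes split at the equatorial
plane (ties to the lower half). Period: centered window-3 rolling mean
(shrinking at the ends) → z-normalization (population σ) → real FFT →
dominant non-DC frequency (ties toward lower frequency) → period = 1/f;
a flat series raises a no-oscillation signal. Lag = mean duration of
complete troughs — below-threshold intervals with linearly interpolated
edges — and growth = period − lag. The default trough threshold is the
half depth of the denoised signal (midpoint of its 2nd–98th percentile
range), capped at the mean: half depth marks trough edges at the midpoint
of rise and fall (exact for plateau-burst waveforms even after
smoothing), while the cap keeps rare tall peaks in spiky burst trains
from dragging the threshold above the bulk of the signal. Only complete
troughs are averaged; a truncated final cycle is ignored.

## Synthetic data (`synthetic_data`)

Confocal-like stacks: per z-slice disk cross-sections
(radius √(R² − dz²)), anti-aliased at one-pixel roll-off, Gaussian PSF,
then Poisson shot noise on the photon signal and Gaussian read noise.
Defaults mirror typical confocal settings (103 nm pixels, 0.36 µm
z-step) on a 128×128 px field so suites stay fast; 512×512 px is one
parameter away. Not modelled: photobleaching, drift, spectral crosstalk —
so passing roundtrips demonstrate correctness of the operators, not
robustness to those artefacts.

Oscillation series: plateau bursts separated by flat troughs of duration
`trough_fraction·period`, with raised-cosine ramps one sample wide (the
half-depth threshold then recovers the trough duration exactly); a pure
sine mode is available. The lower series is the upper shifted by
`phase_shift/2π` periods. Perturbed emulsions multiply droplet volumes by
log-normal factors and rescale to conserve the total exactly.

All generators are pure functions of (parameters, seed) and return truth
records sufficient for recovery assertions.

## Orchestration (`config`, `pipeline`, `cli`)

YAML configs mirror the parameter dataclasses section by section; unknown
keys are rejected. One global seed fans out to per-module seeds through
`numpy.random.SeedSequence` (all derived seeds < 2³¹). The four built-in
experiments (perturbation relaxation, parameter sweeps, oscillation,
quantification roundtrip) emit JSON reports embedding the seed and a
config content hash and are byte-identical for identical inputs.

## Problem sizes

Test and reproduction runs use a 25 µm cell for 900 s of simulated time
(≈26 000 steps, seconds of wall time), bulk emulsions of ~10⁵ µm³ for
3000 s, and 128×128 px render fixtures; all are package defaults chosen
to keep the examples interactive, and every size is a plain argument.

## Known limitations

- Mean-field emulsions have no spatial structure; spatial coupling lives
  only in the cell simulator's 1-D layer stack + 3-D droplets.
- No hydrodynamic interactions, droplet deformation during fusion, or
  elasticity of the gel network.
- The steady droplet radius of the simulated emulsion depends on the
  nucleation history (overshoot), not only on the growth law; quantities
  meant to be parameter-independent are computed from the growth law
  directly.
- Whether the dilute phase near droplets is reaction- or
  diffusion-limited is folded into the single uptake coefficient `k_up`.
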