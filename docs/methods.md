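# Methods

## The two-state search picture

A sequence-specific DNA-binding protein in the nucleus alternates between
free 3D diffusion (mean phase duration τ_3D) and nonspecific binding to
chromatin (mean bound duration τ_1D). The long-run mobile time fraction is
f_mobile = τ_3D/(τ_1D + τ_3D); with f_mobile = 0.75 and τ_1D = 2 s this
gives τ_3D = 6 s and a nonspecific-site visit rate of 0.125 s⁻¹. All
downstream quantities — the effective diffusion coefficient
D = D₁·τ_3D/(τ_1D + τ_3D), the facilitated-diffusion association rate, the
single-molecule search time — derive from this partition.

## Synthetic-data generator

`simulate.simulate_trajectory` draws alternating phases: unbound durations
are exponential with mean `mean_unbound_s` (default 6 s); bound durations
come from a pluggable dwell model. While mobile the motion is Brownian in
the imaging plane with a diffusion coefficient drawn **once per phase**
from a finite mixture (default 8 and 1 μm²/s in 33:43 proportion); while
bound it uses `D_bound` (default 0.1 μm²/s, the quasi-immobile population
scale). Positions are sampled exactly at frame times — with piecewise
constant D the displacement over any interval is Gaussian with per-axis
variance 2∫D dt, so no fine time stepping is needed — then localization
noise (default 25 nm per axis) is added and the track truncated at a
geometric per-frame bleach event. Bleaching acts during exposures only:
the per-frame probability is calibrated to the continuous-imaging ensemble
decay (0.34 s⁻¹ at 197 frames/s, i.e. mean 580 frames ≈ 2.9 s) and is the
same for every protocol regardless of dark-gap length, which is precisely
why time-lapse imaging extends the observation window.

Dwell models: `ExponentialDwell(rate)` (random-sequence binding, default
rate 0.5 s⁻¹ for the 2 s mean; 6.36 s⁻¹ when emulating the short
nonspecific events), `TruncatedPowerLawDwell(t_min, t_cut, gamma)` with
SP(t) = (t/t_min)^γ on [t_min, t_cut] and an atom at t_cut,
`EnergyLandscapeDwell(tau0, e0)` (exponentially distributed binding
energies E with mean e0, dwell τ₀e^E, giving the tail exponent −1/e0), and
`MixtureDwell`. The default heterogeneous model
(`heterogeneous_dwell()`) is 95% exponential (rate 6.36 s⁻¹) plus a 5%
power-law tail (γ = −0.7, 0.1–100 s); the 5% weight is the smallest
round fraction that makes the tail dominate the survival beyond ~0.7 s
while keeping the short-time behaviour monoexponential, matching the
qualitative shape of the measured survival curve. Analytic `survival()`
and `mean()` are available for every model, so recovery tests always
compare against a closed form.

What the generator does **not** emulate: confined or subdiffusive motion of
the intermediate population (each phase is pure Brownian), nuclear geometry
(no boundaries or nucleoli), hopping microstructure within bound phases,
and detector effects beyond Gaussian localization error (no motion blur,
no intensity statistics). Passing tests therefore validate the estimators
under the stated statistical structure, not the full complexity of real
movies. One practical consequence: over time-lapse dark gaps of 0.5–1 s a
Brownian "bound" state at 0.1 μm²/s moves farther than the 160-nm pixel
rule allows, whereas real chromatin-bound proteins are confined; time-lapse
validation ensembles therefore use a quasi-static bound state
(`D_bound = 1e-4` μm²/s) to stand in for that confinement.

## Mobility analysis

MSD is time-averaged over overlapping displacement pairs; `fit_dinst` is an
ordinary least-squares line through MSD at lags 2–5 with free intercept
(absorbing the constant 4σ² localization offset), and D_Inst = slope/4
(2D convention MSD = 4Dt). Whole-track D_Inst requires ≥ 9 frames.
Non-positive D_Inst values — possible because the fit is unconstrained —
are excluded from the log₁₀ histogram and reported as a count.

`MobilityModel` fits a k-component Gaussian mixture (scikit-learn, 5
restarts from random data points, tolerance 1e-6) to log₁₀ D_Inst;
components are reported by decreasing mean, fractions are mixture weights,
and D_i = 10^mean_i. On simulated short tracks (0.15 s) at the default
kinetic parameters it recovers fractions within ±5 points and coefficients
within a factor 1.3.

## Binding-event detection and the residence time on random sequences

The running-window D_Inst (80 ms window = 16 frames at 197 fps, step one
frame, same lag-2–5 fit) is intrinsically noisy: its relative standard
deviation is ~70% and ~2% of windows on a D = 8 μm²/s track fall below
0.1 μm²/s. Detection therefore combines three guards beyond the
sub-threshold-run rule (threshold 0.1 μm²/s, ≥ 2 consecutive windows):
gaps of ≤ 2 windows are closed (estimator flicker), event frame-spans are
trimmed at the edges by the one-pixel step rule and must still cover a full
window, and runs whose median frame-to-frame step exceeds one pixel
(160 nm) are rejected — a bound molecule stays put; an estimator fluke does
not. Runs touching either track end are censored: at the end the event was
cut by bleaching, at the start only the residual of an in-progress
(size-biased) event is visible.

The apparent event rate is the left-truncated exponential MLE
(rate = 1/mean(d − t₀); the detector cannot see events shorter than the
window, and the exponential is memoryless), with a histogram decay fit as
an alternative. Dissociation and bleaching compete, so
τ_RS = 1/(k_apparent − k_bleach); with the measured 6.7 s⁻¹ and 0.34 s⁻¹
this gives ~157 ms.

## Survival analysis across imaging protocols

Time-lapse trajectories are segmented by the immobility rule (≤ 1 pixel
displacement over ≥ 2 consecutive frames); an event seen on n frames has
duration (n−1)·interval. `survival_probability` supports three censoring
policies: `drop`, `include`, and `km` (Kaplan–Meier product limit, the
default inside `ResidenceModel`) — bleaching is independent of
dissociation, so the product-limit estimator is the consistent choice and
removes the ~30% downward bias that dropping censored events produces for
heavy-tailed dwells.

`merge_survival_curves` renormalizes each time-lapse SP to the continuous
SP at the 1 s anchor (log-log interpolation between grid points),
concatenates continuous points below the anchor with scaled time-lapse
points above it, and averages coincident times in log SP. Before merging,
`ResidenceModel.fit` (i) optionally multiplies each curve by
exp(rate·t) with the protocol's effective bleach rate, (ii) trims each
time-lapse curve to spans of ≤ 100 frames (beyond that the product-limit
tail rests on a handful of heavily censored events), and (iii) shifts
time-lapse grids by half an interval: an event observed on n frames
reports (n−1) intervals while the dwell covered between (n−1) and (n+1),
so the survival value at the reported duration estimates SP half an
interval later. Without the shift the recovered power-law exponent is
biased shallow by ~0.15.

The exponent γ is a least-squares line through log₁₀ SP vs log₁₀ t; the
fit range defaults to (0.1, 100) s, and the curve is first resampled onto
a log-uniform grid (20 points per decade) so each decade carries equal
weight — empirical grids are linear in duration and would otherwise be
dominated by their long-time points. In the end-to-end validation the
exponent is fit above the anchor (1–100 s) because with the default 95/5
dwell mixture the exponential bulk dominates SP below ~0.7 s.

τ_1D is the trapezoidal integral of SP (SP(0) = 1 prepended; non-monotone
merged curves are first projected onto the decreasing cone, with a
warning). The tail beyond the last point follows the fitted power law out
to `power_law_to:100` (then zero) by default; `truncate` is available for
sensitivity analysis. Because events shorter than the detection floor
(~0.085 s for the continuous running window) are invisible, the pipeline
estimates the mean of the floor-conditioned dwell distribution; the
end-to-end test compares against that analytic conditional mean. The soft
detection threshold near the floor leaves a residual upward bias of
~10–15% on τ_1D, inside the 25% validation band.

## Association kinetics

`fit_monoexponential_rise` fits I(t) = B + A(1 − e^(−kt)) by nonlinear
least squares with a free baseline (flat series return k = 0 with a
warning); a decay variant covers release experiments.
`concentration_from_fcs` is the pure unit conversion c = (1/G₀)/(N_A·V_eff)
with V_eff defaulting to 0.5 fl. `AssociationModel` regresses k_obs on c by
unweighted OLS (statsmodels), ignoring concentration uncertainties — the
simplest reading of the experimental fit — with a WLS option via
`weights`. Slope and intercept come with standard errors; note that OLS
standard errors assume homoskedastic noise, and multiplicative
(concentration-proportional) noise calls for the weighted variant.

`site_scaling_report` compares the k_a ratio between cell lines with the
site-count and insert-count ratios in log space; the measured ratio
(9.2/2.2 ≈ 4.2) is far closer to the insert ratio (200/30 ≈ 6.7) than to
the site ratio (19,200/210 ≈ 91), the signature of 1D sliding merging each
insert into a single target.

## Search-rate models

All closed forms live in `searchmodels`, internally in μm/s units with
molar conversions through N_A (CODATA). The in-locus binding rate κ(λ)
interpolates harmonically between the printed limits 4πDa/v (perfect
association) and λ(4π/3)a³/v (low efficiency); the harmonic form is exact
in both limits with relative error 3D/(λa²) approaching the fast limit.
The locus rate uses the classical uniformly-reactive-sphere solution
4πD·r_t(1 − tanh x/x), x = r_t√(κ/D), with the series x²/3 − 2x⁴/15 below
x = 1e-4 (continuous to < 1e-9 across the switch). The sliding length uses
the 1D span convention ℓ_SL = √(4·D_SL·τ_RS), which reproduces the quoted
lower bound exactly (251 bp at 10⁵ bp²/s) and overshoots the quoted upper
bound by ~6% (795 vs 750 bp) — consistent with rounding in the source
values. `solve_p` inverts the facilitated-diffusion rate for the specific
binding probability and flags out-of-range results instead of failing.
Two figures are reported but never asserted: the absorbing-sphere rate
computed from D = 6 μm²/s and r_t = 350 nm is 1.6 × 10¹⁰ M⁻¹s⁻¹, whereas
the order-of-magnitude figure usually quoted for this regime is ~2 × 10⁹;
both appear in `model_report` inputs/outputs and the discrepancy is left
to the reader (the exact prefactor depends on the locus model).

## Motif scanning

`scan_contiguous_matches` slides the motif over every genomic window on
both strands (vectorized over window offsets), recording the longest run of
consecutive identities and the full-window mismatch count; each window is
reported once, on the strand with the longer run (plus on ties), 0-based
half-open coordinates. Windows containing non-ACGT characters are skipped.
Similarity is operationalized as the longest contiguous identity run —
alignment-tool seeds and E-values are deliberately not reproduced, as they
are tool- and version-dependent. `expected_counts_random` gives the exact
expected number of windows with a run ≥ ℓ in a uniform i.i.d. genome via
the Bernoulli run-probability dynamic programme (exact by linearity even
though windows overlap); the familiar closed form
2G(L−ℓ+1)(3/4)²4^(−ℓ) is kept as `expected_counts_random_approx` and
underestimates by ~30–40% at ℓ ≈ L/2 because edge runs need only one
mismatching flank.

## Problem sizes and numerical choices

Validation ensembles are sized so each recovery band holds with margin
across seeds: 500 tracks × 60 s for the occupancy check; 2,000 short
tracks for population classification; 6,500 tracks × 10 s for the
event-rate recovery (~1,000 events beyond the truncation point); 6,000
continuous plus 1,500/1,000/2,500 time-lapse tracks for the
survival-probability pipeline (the continuous ensemble mainly stabilizes
the handful of events beyond the 1 s anchor). Every stochastic operation
takes an explicit integer seed; ensembles spawn per-track seeds through
`numpy.random.SeedSequence`, so results are bit-reproducible.

## Known limitations

- The intermediate (D₂ ≈ 1 μm²/s) population is modelled as free Brownian
  motion; its empirically subdiffusive/confined character is out of scope,
  and at 5 ms frame intervals its steps are smaller than one pixel, so
  frame-level immobility rules cannot separate it from bound molecules —
  only the window-D_Inst rule with the confinement guards can.
- The running-window detector's floor (~0.085 s) means τ_1D is the mean of
  the observable dwell distribution; recovering the unconditional mean
  would require modelling the detection efficiency near the floor.
- Kaplan–Meier tails under heavy censoring are biased upward at small
  sample sizes; the per-protocol span trimming bounds but does not remove
  this.
- The k_obs regression default ignores per-cell uncertainties in both
  axes.
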