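# Methods

This note documents the models, numerical choices and limitations behind
each stage of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Optical vulnerability curves and P50

**Model.** Cavitation of a leaf vein during bench dehydration appears as an
abrupt, persistent local brightness change between consecutive frames. The
pipeline is deliberately the smallest faithful mechanism:

* consecutive-frame absolute differencing with a single global threshold
  (`diff_threshold`, default 10000 intensity units on 16-bit frames, i.e.
  half the simulated event amplitude). Differences are computed after
  casting to a signed 64-bit domain, so decreasing steps can never wrap
  around in unsigned arithmetic;
* artifact removal by an 8-connected component area filter
  (`min_event_px`, default 4 px) plus an optional binary region (vein)
  mask. Leaf shrinkage produces isolated single-pixel flicker; a
  connected-component filter is the minimal mechanism that separates it
  from vein-scale events, and because the simulator plants such flicker the
  filter is directly testable;
* cumulative retained area expressed as a percentage of the total at the
  final frame. If nothing was retained the curve is marked incomplete and
  P_x extraction refuses to run;
* water potential per frame by linear interpolation of the psychrometer
  trace; frame times outside the trace span are clamped to the nearest
  endpoint with a logged warning;
* P50 read off the empirical curve at the first 50% crossing, linearly
  interpolated in Ψ between the bracketing frames. A logistic-fit readout
  (`extract_px_logistic`) is provided as a sensitivity check but is not the
  default: reading the empirical crossing matches how optical curves are
  normally reduced.

**Parameters that matter.** `diff_threshold` trades sensitivity against
noise: the closed-loop tests show the retained total is
threshold-insensitive over a wide band when events are well separated from
the noise floor (event amplitude ≈ 67 noise SDs in the default simulation).
`min_event_px` must sit above the flicker size (1 px) and below the
smallest real event (6 px by default in the simulator).

**Degenerate inputs.** Single-frame stacks, non-increasing frame times,
positive water potentials and empty traces are rejected at construction.

## The drydown simulator and the image simulator

The image simulator partitions an embolisable pixel pool into connected
patches placed in disjoint blocks; events switch on permanently at the
frame where a logistic cumulative curve
`F(Ψ) = 100 / (1 + exp(s/25 · (Ψ − P50)))` crosses their cumulative pixel
count. The field protocol timing is built in: frames every 3 min,
psychrometer samples every 10 min, Ψ declining linearly in time. The
logistic form is a generator choice (the empirical method fits no curve);
it makes P50 an explicit truth parameter, with the midpoint slope `s` in %
per MPa. Gaussian intensity noise and single-pixel one-frame flicker
emulate sensor noise and leaf shrinkage; camera optics, vein architecture
and registration drift are *not* emulated, so passing recovery tests
demonstrate correctness of the event accounting, not robustness to optical
artifacts beyond those two noise classes.

The mass simulator integrates
`g(t) = g_min(T) + (g₀ − g_min(T))·e^(−t/τ)` (single-exponential stomatal
closure; only the terminal steady state matters downstream) into an exact
closed-form mass curve via
`dm/dt = −g·VPD/P_atm·A·M_w`, then adds Gaussian balance noise.
Defaults emulate the oven protocol: seven temperatures 25–48 °C, RH 40%,
readings every 5 min for 3 h (37 points), τ = 10 min, g₀ = 50 and
g_min = 5 mmol m⁻² s⁻¹ at 25 °C rising 0.5 mmol m⁻² s⁻¹ K⁻¹ above a 36 °C
breakpoint, 0.02 m² double-sided leaf area, 0.1–0.5 mg balance noise.
Water-content exhaustion is not modelled: at the hottest temperatures the
simulated branchlet can lose more water than a real one holds, which is
harmless downstream because only the steady slope is consumed.

## g_min and T_P

`R` is computed as the least-squares slope of mass vs time over the
detected steady window (not first-vs-last differencing) for noise
robustness. The steady window is the longest terminal run of rolling
`window`-point regressions (default 5) whose slope deviates from the final
window's slope by at most `rel_tol` (default 0.15 relative). The run must
contain at least two windows; a purely exponential (never-settling) series
therefore raises a no-steady-state error rather than silently returning
its last window. The default tolerance accepts a small tail of the
stomatal transient (≤1% bias on the default simulation); analyses that
need the 0.1%-level closed loop tighten `rel_tol` to 0.02.

Conversions: slope (g s⁻¹) → mmol s⁻¹ via the molar mass of water
(18.015 g mol⁻¹), per m² of double-sided area from dry mass × SLA × 2.
SLA is conventionally projected area per dry mass, so the ×2 is applied at
area computation (`double_sided=True` default); whether a given study's SLA
was projected or total-surface is a flag, not a guess. Atmospheric pressure
is fixed at the protocol's 101.6 kPa (not 101.325) and is
config-overridable.

T_P is the breakpoint ψ of the continuous two-segment model
`g(T) = b₀ + b₁T + b₂(T − ψ)₊`, fitted by exhaustive 0.1 °C grid search
strictly between the second and penultimate observed temperatures with the
linear coefficients profiled by OLS at each candidate, then refined by
bounded scalar minimisation (xatol 1e-4 °C). SSE flatness is judged
against the total sum of squares of g (tolerance 1e-6), so exactly-linear
inputs raise a breakpoint-not-identifiable error instead of returning an
arbitrary grid point. The fit is applied to the species-mean g(T) curve
across replicates (hence no SE on T_P), matching how mean curves are
reduced in practice; per-replicate fitting is available through the CLI
flag but reported only as the mean-curve value.

## Comparative statistics

**Covariance convention.** `V(λ)` has root-to-tip depths on the diagonal
and λ-scaled root-to-MRCA shared path lengths off it. Trees are
depth-normalised to 1.0 by the simulator; λ is searched on [0, 1]
(bounded Brent, xatol 1e-6), the natural range on ultrametric trees.

**Blomberg's K** uses the phylogenetically corrected mean
`â = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹y` and the expectation term
`(tr V − n/1ᵀV⁻¹1)/(n−1)` at λ = 1, so K ≈ 1 under Brownian motion by
construction. Significance is a tip-shuffling permutation test,
`p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1)`, vectorised over permutations.

**Pagel's λ** maximises the profile likelihood of the single-mean Brownian
model (mean and σ² profiled analytically); the LRT against λ = 0 uses the
χ²₁ reference, which is conservative at the boundary — this is noted
rather than corrected, since the ½(χ²₀+χ²₁) mixture would only make small
p-values smaller. Implementation note: estimates agree with the standard R
implementations (picante's K, phytools' λ) to ≤1e-3, which the test suite
checks by calling Rscript on a shared fixture. Profile-ML λ carries a
known small-sample downward bias for interior truth values (order 0.1 at
n = 64 on unit-depth pure-birth trees); the recovery experiments in the
acceptance suite average over several trees and hundreds of replicates to
measure it stably.

**PGLS** estimates `β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y` with λ fixed or profiled by ML;
standard errors use the unbiased σ̂² = RSS_V/(n−p). R² is GLS-based,
`1 − RSS_V/TSS_V`, with TSS from the intercept-only GLS fit at the same λ
— other R² flavours exist for PGLS, so reported values are comparable only
within this convention. Categorical predictors are dummy-coded against the
alphabetically first level. Interaction terms can be added or dropped;
the default model is main-effects only (trait ~ PC1 + subgenus).

**Cook's distance** is computed on the whitened regression (ỹ = L⁻¹y,
X̃ = L⁻¹X with V = LLᵀ): `D_i = r_i²h_i / (p·s²·(1−h_i)²)` with leverages
from the whitened hat matrix. At λ = 0 on an ultrametric tree this is the
textbook OLS Cook's distance (verified against statsmodels). Leverage 1 is
reported as +inf (infinite influence). Species are flagged when
`D > 4/n` (configurable factor); the refit excluding flagged species is
reported alongside the full fit rather than replacing it.

**Climate PCA** standardises by default (the variables mix °C and mm),
eigendecomposes the correlation matrix and keeps all components, so the
score–loading product reconstructs the standardised matrix exactly and
variance shares sum to 100%. Signs are fixed deterministically
(largest-magnitude loading positive), with PC1 additionally oriented to
have a positive loading on minimum temperature: larger PC1 = warmer/drier.

**Loess** is local linear regression with tricube weights. For span ≤ 1
each fit uses the ⌈span·n⌉ nearest points scaled by the window radius; for
span > 1 (the relevant regime — span 1.5 is used to draw the broad
P50–climate trend) all points are used with distances scaled by
span × max-distance, the conventional oversmoothing extension.

**Bonferroni** is `min(1, p·m)` with `m` allowed to exceed the number of
p-values passed (a pre-declared family); the pipeline's declared family is
the P50 climate slope tested against both PC1 and minimum temperature
(m = 2).

## The simulated study (pipeline fixture)

`hydrophylo run --simulate` generates a 14-species study: a pure-birth
tree (redrawn deterministically until the root split leaves at least
max(3, n/4) species on each side, mirroring the 8 + 6 two-subgenus
design — a 1-vs-13 split would make the subgenus dummy a perfect-leverage
point with undefined Cook's distance); a 5-variable climate table whose
default correlation structure produces a dominant warm-dry/cool-wet axis
(PC1 ≈ 90% of variance); species g_min(25 °C) following
`6.5 − 1.0·PC1 + ε` with phylogenetic residuals (λ = 0.3, σ² = 0.09); one
species — the one nearest the PC1 median, so its climate gives no reason
to stand out — shifted down by 4 mmol m⁻² s⁻¹ as a planted outlier (the
magnitude of the famous low-g_min frost-tolerant eucalypt's deviation);
P50 weakly declining in PC1 with 0.3 MPa scatter; T_P scattered around
36 °C. Image stacks default to 64×64×150 frames and two replicates per
species, drydowns to two replicates per temperature — sizes chosen so a
full simulated study runs in seconds while leaving estimation error well
below the planted effects.

## Reporting and determinism

Every generator and every randomised procedure takes an explicit seed;
the pipeline derives per-stage streams from the config seed via
`numpy.random.SeedSequence`, so reports are bit-identical across runs
(SHA-256 report hash recorded, along with the config hash). All tabular
outputs are CSV with stable column order; all scalars are also emitted in
one JSON report.

## Known limitations

* No image registration: real stacks drift; the differencing stage assumes
  aligned frames.
* Boundary-layer and humidity-sensor errors are not modelled; g_min
  inherits any VPD measurement bias linearly.
* The steady-state criterion is heuristic; drydowns that never settle
  (or oscillate) are rejected rather than salvaged.
* PGLS R² and the χ²₁ LRT conventions differ from some R defaults
  (see above) — compare like with like.
* The synthetic climate is multivariate normal; real climate surfaces have
  spatial structure and bounded supports that the generator does not
  emulate.
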