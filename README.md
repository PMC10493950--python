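# hydrophylo

Leaf hydraulic trait extraction and phylogenetic comparative analysis for
drought-physiology studies of the kind run on the Tasmanian eucalypts: how
do cavitation resistance, cuticular water loss and its thermal breakdown
relate to the climate a species inhabits, once shared ancestry is accounted
for?

The package covers three measurement pipelines and the comparative layer
that joins them:

1. **Optical vulnerability (P50).** A time-lapse image stack of a
   dehydrating leaf is differenced frame-to-frame; thresholded changes are
   cavitation events, small connected components (leaf-shrinkage flicker)
   are filtered out, the retained event area is accumulated and expressed
   as a percentage of the total at complete dehydration, and mapped onto
   the psychrometer water-potential trace. P50 is the water potential at
   the 50% crossing of this vulnerability curve:
   the first Ψ where cumulative embolised area reaches 50%, linearly
   interpolated between frames.

2. **Minimum conductance (g_min) and phase transition temperature (T_P).**
   From a wax-sealed branchlet drying in an oven, the steady post-stomatal
   mass-loss slope gives the transpiration rate `R = Δw/(Δt·A)` over the
   double-sided leaf area `A`; conductance follows from the vapour pressure
   deficit via the Buck formulation,

       SVP = (610.7 · 10^(7.5 T / (237.3 + T))) / 1000        [kPa]
       VPD = (1 − RH/100) · SVP                               [kPa]
       g   = R / VPD · 101.6                                  [mmol m⁻² s⁻¹]

   Fitting a continuous two-segment line to g_min against the seven oven
   temperatures (25–48 °C) gives the breakpoint T_P where the cuticle
   starts leaking rapidly.

3. **Comparative statistics.** Site climate variables are reduced by PCA
   (PC1 = the warm-dry/cool-wet axis, oriented so warm minimum temperatures
   score positive); phylogenetic signal is measured by Blomberg's K (with a
   tip-shuffling permutation test) and Pagel's λ (profile ML with an LRT);
   trait–climate relationships are fitted by phylogenetic generalized least
   squares, `y = Xβ + ε`, `ε ~ N(0, σ²V(λ))`, with Cook's distance on the
   whitened regression used to screen influential species, a Bonferroni
   correction over the declared test family, and a high-span loess smooth
   for visualising curvature.

No raw image stacks or drydown series are publicly deposited for studies of
this kind, so the package ships a **synthetic-data generator** whose outputs
have known ground truth (true P50, g_min(T), T_P, λ, regression
coefficients), making every stage testable by closed-loop parameter
recovery. A species-mean climate/trait table for 14 Tasmanian eucalypt
species is packaged (`hydrophylo.datasets.load_species_table`).

## Worked example

```python
from hydrophylo import simulate, optical, conductance

# a synthetic bench dehydration with known P50 = -5 MPa
stack, trace, truth = simulate.simulate_drydown_images(
    p50=-5.0, noise_sd=300, shrink_events=20, seed=3)
curve = optical.build_curve(stack, trace, diff_threshold=10000, min_event_px=4)
print(optical.extract_px(curve, 50.0))   # -4.997  (true -5.0)

# drydowns at the seven oven temperatures; fit T_P on the g_min(T) curve
series, truth = simulate.simulate_mass_series(seed=0)   # true T_P = 36 C
points = [conductance.gmin_at_temperature(s) for s in series]
print(conductance.fit_breakpoint(points).summary())
```

```
Segmented g_min(T) fit
  T_P (breakpoint)  36.00 deg C
  slope below T_P   -0.0000 mmol m^-2 s^-1 K^-1
  slope above T_P   0.5032 mmol m^-2 s^-1 K^-1
  intercept         5.0398
  SSE               0.000148439
```

The recovered P50 sits within one frame's Ψ step of the generating value,
and the breakpoint lands on the generating 36 °C with a flat segment below
(slope ≈ 0) and the generating 0.5 mmol m⁻² s⁻¹ K⁻¹ rise above.

The full study — simulated stacks and drydowns for every species, trait
table assembly, PCA, signal tests, PGLS with outlier screening — runs from
the shell:

```bash
hydrophylo run --simulate --seed 3 --out out/
```

which writes `report.json`, `species_traits.csv`, `pgls_summary.csv` and a
log; the report records the config hash and is bit-identical across runs
with the same seed.

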