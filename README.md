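# allema

Multi-stage, doubly balanced, unequal-probability sampling designs for
biodiversity monitoring on agricultural land — design construction,
design-based estimation, and design evaluation, in one tested Python
toolkit.

## The problem

National biodiversity monitoring programmes on agricultural land (the
motivating case is the Swiss ALL-EMA survey of habitats, structures and
plant species) must spread a limited field budget over squares, plots and
subsamples so that rare regions, rare habitats and agri-environmental
measures are all represented, while estimation at the national level stays
efficient and the annual field workload is fixed. The design implemented
here selects:

1. **Initial stage** — a systematic grid of 1-km squares with regionally
   varying density: π₀ = 0.9025/48 in dense-grid regions, 0.9025/96
   elsewhere (0.9025 km² = the surveyed 950 m × 950 m part of a square).
2. **First stage** — m = 170 squares from the M = 455-square frame, in
   r = 5 rotation groups (annual panels) of m/r = 34. Within each group the
   conditional probabilities are π₁|S₀ = min(Cₜ·nᵢ·Iᵢ, 1), with nᵢ the
   number of accessible habitat-plot centres and Iᵢ > 0 a **calibrated
   index of interest**: a bounded-logistic calibration solves

       Σ_{i∈U_g} (Aᵢ/A)·Iᵢ = q_g   and   Σ_{i∈V_h} (Aᵢ/A)·Iᵢ = p_h

   for two cross-cutting stratifications (production zones, biogeographic
   regions), with power-allocation targets q_g ∝ A_{U_g}^α (α = 0.5) and
   bounds (0.61, 3). Selection is **stratified, doubly balanced spatial
   sampling**: the local-cube flight phase runs separately in each rotation
   group (balancing vector: π, π×stratum indicators, nᵢ, elevation, 1), the
   unresolved units are pooled and the method reapplied to the rounding
   problem, so every draw realizes exactly 34 squares per group.
3. **Second stage** — a systematic 19 × 19 grid of nested circular plots
   at 50-m spacing in each selected square; every grid point on accessible
   agricultural land is surveyed, so π₂|S₁ = 10·361/950² = 0.004 for the
   10 m² habitat plots (×20 for the 200 m² structure plots).
4. **Third stage** — a vegetation subsample of v₀ = 19 plots per square
   with π₃|S₂ = min(C₃.ᵢ·Jⱼ, 1) guided by a plot-level interest index Jⱼ,
   doubly balanced on terrain covariates (elevation, slope, topographic
   position, orientation). Because squares are drawn proportional to nᵢ·Iᵢ
   and the quota is constant, the first and third stages are (almost)
   **self-weighted**: the total probabilities π_V have small dispersion.

Estimation uses the **Hájek** estimator for plot means and area shares and
a simplified **Hansen–Hurwitz** variance that collapses all stages into a
single between-square sum of squares,

    var̂(Ȳ̂) = (1/N̂²) · 1/(m(m−1)) · Σ_{i∈S₁} (Ŷᵢ/pᵢ − Ŷ)²,  pᵢ = π₁,ᵢ/m,

which is slightly conservative (the with-replacement assumption alone
inflates the variance by (M₀−1)/(M₀−m) ≈ 1.0109 for M₀ ≈ 15 688, m = 170).

The evaluation side provides a double-Poisson habitat population model
(n_{il} = ½·Pois(2)·Pois(p_{lg}·nᵢ), over-dispersed by construction),
Monte Carlo CV comparisons of balanced vs. pure unequal-probability
designs, cost-neutral clustering scenarios, and change-detection power
analysis for permanent plots (m_min = ⌈s²(2−2ρ)(Z₁₋α/₂+Z₁₋β)²/(δȲ)²⌉).

## Worked example

```python
import pandas as pd
from allema.design import DesignConfig, first_stage_sample, third_stage_sample
from allema.simulate import (synthetic_frame, calibrated_index_for_frame,
                             synthetic_plot_frame)

cfg = DesignConfig()                  # m=170, r=5, v0=19, alpha=0.5, bounds=(0.61, 3)
frame = synthetic_frame(455, seed=1)  # synthetic national frame
index = calibrated_index_for_frame(frame, cfg)
print(f"index of interest: min={index.I.min():.3f}, max={index.I.max():.3f}, "
      f"max constraint residual={index.max_residual:.2e}")

draw, probs = first_stage_sample(frame, index, cfg, rng_seed=1)
per_group = pd.Series(draw.indicator).groupby(frame["R"].to_numpy()).sum()
print(f"first stage: {draw.size} squares selected "
      f"({', '.join(f'group {g}: {n}' for g, n in per_group.items())})")

sq = frame.loc[draw.selected[0]]
plots = synthetic_plot_frame(sq, int(sq["n_i"]), cfg, seed=2)
veg, table = third_stage_sample(plots, None, cfg, rng_seed=3)
print(f"square {sq['square_id']}: n_i={int(sq['n_i'])} habitat plots, "
      f"{veg.size} vegetation plots, pi_3|S2 in "
      f"[{table['pi3_given_s2'].min():.3f}, {table['pi3_given_s2'].max():.3f}]")
```

prints

```
index of interest: min=0.894, max=1.190, max constraint residual=9.16e-16
first stage: 170 squares selected (group 1: 34, group 2: 34, group 3: 34, group 4: 34, group 5: 34)
square sq0001: n_i=85 habitat plots, 19 vegetation plots, pi_3|S2 in [0.043, 0.776]
```

— the calibrated index stays inside its bounds and hits the stratum
targets to machine precision; every rotation group realizes exactly its
annual panel of 34 squares; a square with 85 accessible habitat plots
contributes exactly the 19-plot vegetation quota, with plot probabilities
spread by the interest index Jⱼ.

Estimation and power, on the same kind of inputs:

```python
res = estimate_mean(y, plots, squares, "habitat")   # y: 0/1 habitat indicator
# -> area share = 0.2305 +/- 0.0098 (68% CI: 0.2206 to 0.2403), m = 170
s2 = s2_from_design_variance(res.variance, res.m)
minimum_squares(PowerSpec(ybar=res.estimate, s2=s2, rho=0.9, delta=0.2))
```

A command-line interface covers the same stages end to end:

```bash
allema synth --preset allema --seed 1 --out frame_dir
allema design --config design.yaml
allema estimate --plots plots.csv --obs obs.csv --squares squares.csv --out est.csv
allema simulate --config scenario.yaml
allema power --input habitat_specs.csv --out detectability.csv
```

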