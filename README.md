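# mortmix

A parametric mixture model for the age distribution of deaths, built for
demographers and epidemiologists who want to separate **infant/child**,
**accidental + premature**, and **adult** mortality from single-age death
counts — and to decompose life expectancy at birth into those three
components in closed form.

## The model

The density of ages at death is an eight-parameter mixture

```
f(x; θ) = η · f_I(x) + (1 − η) · [ α · f_m(x; θ_m) + (1 − α) · f_M(x; θ_M) ]
```

* `f_I` — a **half normal** with unit scale, `√(2/π)·exp(−x²/2)`, for infant
  and child deaths; its mode is always at age 0 and the weight `η ∈ [0, 1]`
  measures the intensity of infant mortality.
* `f_m` — a **skew normal** `(2/ω)·φ((x−ξ)/ω)·Φ(λ(x−ξ)/ω)` for the middle
  part of the curve: the young-adult accidental hump together with premature
  deaths below the old-age cluster. `α ∈ [0, 1]` is its share of non-infant
  deaths.
* `f_M` — a second skew normal for adult (old-age) mortality, typically
  left-skewed (`λ_M < 0`).

The component areas are `A_I = η`, `A_m = α(1−η)`, `A_M = (1−η)(1−α)`, and
life expectancy at birth decomposes exactly as

```
e0 = e_I + e_m + e_M
   = η·√(2/π) + (1−η)α·E[X_m] + (1−η)(1−α)·E[X_M],
```

where `E[X] = ξ + ω·λ/√(1+λ²)·√(2/π)` is the skew-normal mean. The model
also yields three modal ages: `I = 0`, the young mode `m`, and the adult
modal age at death `M`.

Death counts `D_x` on single-age bins are multinomial with cell
probabilities `p_x(θ) = F(x+1) − F(x)`, so fitting maximizes
`Σ_x D_x log p_x(θ)`. The search runs in **centered coordinates** — mean,
standard deviation and standardized skewness per skew component — where the
likelihood surface is much better behaved: a seeded differential-evolution
global search inside box bounds, followed by a bounded quasi-Newton (L-BFGS-B)
refinement, with automatic restarts at a doubled budget when the diagnostics
look bad. Standard errors come from a multinomial bootstrap; identifiability
is probed by a random-restart recovery study.

## Worked example

```python
import mortmix as mm

theta = mm.reference_theta()   # eta=0.02, alpha=0.08, young (45, 15, 0.10),
                               # adult (80, 10, -0.30) in centered coordinates
data = mm.simulate_death_counts(theta, 1_000_000, seed=42)
res = mm.fit(data, seed=1)

dec = mm.decompose_e0(res.theta_dp)
print(f"e0 = {dec.e0:.2f} = {dec.e_I:.2f} (infant) + {dec.e_m:.2f} (premature) + {dec.e_M:.2f} (adult)")
print(f"adult modal age M = {mm.modes(res.theta_dp)[2]:.1f}")
a = mm.areas(res.theta_dp)
print(f"areas: infant {a.A_I:.3f}, premature {a.A_m:.3f}, adult {a.A_M:.3f}")
print(f"L1 fit error = {res.fit_error:.4f}")
```

prints

```
e0 = 75.71 = 0.02 (infant) + 3.86 (premature) + 71.84 (adult)
adult modal age M = 81.6
areas: infant 0.020, premature 0.083, adult 0.897
L1 fit error = 0.0064
```

One million simulated deaths from the reference truth are refitted from
scratch; the decomposition says people dying in adulthood contribute 71.8 of
the 75.7 years of life expectancy, the premature component carries 8.3% of
deaths, and the fitted distribution is within total variation 0.0064/2 of the
observed one. In a low-mortality population `e0 ≈ e_M`: averting the rare
early deaths would change `e0` only a little.

## Command line

```bash
mortmix simulate --n 100000 --seed 7 --out sim/        # synthetic counts
mortmix fit --input Deaths_1x1.txt --sex m --years 1930-1935 --seed 1 --out fits/
mortmix bootstrap --input sim/counts.csv --B 1000 --seed 1 --out bs/
mortmix recover --n-starts 1000 --seed 1 --out rec/
```

`fit` accepts Human Mortality Database `Deaths_1x1` files (or an
`age,deaths` CSV) and writes one row per year with both parametrizations,
the three modes, areas, the `e0` decomposition and the L1 fit error. Every
command writes a JSON sidecar with the full configuration and seed.

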