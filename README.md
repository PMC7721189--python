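# spatialscaling

Generative modelling of urban scaling laws with explicit spatial
interactions.

## The problem

Urban scaling analyses relate an observable `y` of a city (GDP, deaths,
road miles, patents, ...) to its population `x` through the power law
`y ~ x^β`, with `β > 1` super-linear and `β < 1` sub-linear. The standard
estimate of `β` — ordinary least squares of `log y` on `log x` — treats
cities as independent observations, cannot handle `y = 0`, and ignores
where the cities *are*: a small municipality inside a large metropolitan
belt produces far more than its own population explains.

`spatialscaling` is for quantitative geographers, urban economists and
spatial epidemiologists who want to estimate scaling exponents and spatial
interaction ranges jointly, with honest model comparison, from nothing more
than a table of `(unit, lat, lon, population, count)`.

## The model

`Y = Σ y_i` indivisible tokens are assigned at random to individuals. The
probability that a token lands in unit `i` is

    p_i = x_i A_i^(β−1) / Z(β),      Z(β) = Σ_i x_i A_i^(β−1),

where the *attractiveness* `A_i = Σ_i' x_i' a(d_ii'; α)` counts the
effective interactions available to an individual in unit `i`, weighted by
a distance kernel `a(d; α)` with half-decay scale `α` (km):

| family | kernel `a(d; α)` | parameters |
|--------|------------------|------------|
| P (per-capita) | — (`β = 1`) | none |
| C (city) | `δ(d)` | `β` |
| G (gravitational) | `1 / (1 + (d/α)²)` | `α, β` |
| E (exponential) | `exp(−d ln2 / α)` | `α, β` |

The families nest: `α → 0` reduces G/E to C, `α → ∞` with `β → 1` recovers
P. The observed counts are one multinomial draw `y ~ Multinomial(Y, p)`,
which defines the likelihood; flat priors (`β ∈ [0,2]`,
`α ∈ [0, 6371 km]`, model prior 1/4) give MAP estimates by likelihood
maximisation and rank families by **description length**
`D = −log₂ P(M, D)/8` bytes, computed by adaptive quadrature over the
parameters. Smaller `D` wins; `ΔD` is reported against the per-capita
model. Uncertainty in `β̂` comes from a parametric multinomial bootstrap.

## Worked example

Simulate a 100-unit country with heavy-tailed populations on a ~2000 km
box, draw one million tokens from the gravitational model with
`α = 20 km`, `β = 1.2`, and fit:

```python
import spatialscaling as ss

cfg = ss.GeneratorConfig(n_units=100, total_tokens=10**6, family="G",
                         alpha=20.0, beta=1.2, seed=42)
system, dist = ss.simulate(cfg)

res = ss.ScalingLawModel(system, dist, family="G").fit()
res.bootstrap_sigma_beta(n_boot=100, seed=0)
print(res.summary())
```

```
Token-allocation scaling-law model
==========================================
family:            G
n units:           100
total population:  610936
total tokens Y:    1e+06
alpha (km):        19.1398
beta:              1.2010
sigma_beta (boot): 0.0008
log-likelihood:    -545.2785
```

The fit recovers the generating interaction range (19.1 km vs 20) and
exponent (1.201 vs 1.2, bootstrap σ ≈ 0.001). Comparing all four families:

```python
print(ss.compare_models(system, dist).summary())
```

```
Model comparison (description length in bytes; smaller is better)
        alpha_km  beta_hat     loglik  D_bytes  sigma_beta  quadrature_converged  delta_D_bytes
family
P            NaN         1 -2.509e+04     4524         NaN                  True              0
C            NaN     1.178      -1001    182.1         NaN                  True          -4342
G          19.14     1.201     -545.3    101.3         NaN                  True          -4423
E          20.37      1.19     -604.2      112         NaN                  True          -4412
selected model: G
```

All non-linear families beat per-capita by thousands of bytes; the
generating gravitational family wins, and the conventional log-log OLS
slope on the same data is 1.16 — biased away from the generating 1.2
because it weighs every city equally. The exponential family lands close
to G (ΔD within ~10 bytes), as expected for two kernels with the same
half-decay calibration.

The same workflows are available from the shell:

```bash
spatialscaling simulate --n-units 100 --family G --alpha 20 --beta 1.2 \
    --seed 42 --out units.csv
spatialscaling compare --input units.csv --output-dir results/
```

## Layout

- `city_system` — unit tables, CSV I/O, haversine distance matrices
- `interaction` — kernels and attractiveness
- `likelihood` — allocation probabilities and the multinomial likelihood
- `inference` — MAP fits, α-profiles, bootstrap
- `selection` — priors, evidence quadrature, description lengths
- `baseline` — the conventional log-log OLS fit
- `synthetic` — seeded generator of city systems and token draws
- `model` — `ScalingLawModel` / `ScalingLawResults` front end
- `cli` — `spatialscaling` command (simulate / fit / profile / compare /
  bootstrap)

See `docs/methods.md` for modelling assumptions, numerical choices and
limitations.
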