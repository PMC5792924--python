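# isogloss

Surface-tension dynamics of dialect boundaries: a toolkit for modelling
how the spatial distribution of competing linguistic variants evolves over
a population landscape, why dialect boundaries (isoglosses) straighten,
migrate and stabilize, and when dialects die.

It is aimed at quantitative linguists, cultural-evolution researchers and
statistical physicists of social systems who want a working implementation
of the memory/conformity field model, its analytic interface laws, and the
stochastic and data-analysis machinery around it.

## The model

A binary linguistic variable has variants A and B.  Speakers at **r**
carry a memory m(**r**, t) ∈ [0, 1] of how often they have heard A
(exponential window, timescale τ), and use A with frequency f = p(m),

    p(m) = m^(αβ) / (m^(αβ) + (1 − m^α)^β),

where β ≥ 1 is conformity to the local majority and α an inherent bias
(α = 1: none).  Memory relaxes toward the spatially averaged frequency,

    ∂m/∂t = f̄ − m,   f̄(r) = ∫ ψ(r, r′) f(r′) dr′,

with a two-scale interaction density: a Gaussian kernel (range σ) between
ordinary speakers and a Lorentzian kernel (range γ) between *metropolitan*
speakers, weighted by population ρ and normalized per location.  The
long-range part reproduces the gravity law P₁P₂/r² between city cores and
with it *hierarchical diffusion* — innovations jumping from city to city —
while β > 1 gives the f = 1/2 level set (the isogloss) surface tension, so
boundaries move with normal velocity

    v = −σ²(κ/2 + ∇ρ·ĝ/ρ) − 0.6376·β²σ(α−1)/√(β−1) + …

(curvature shortens them, population gradients repel them from dense
areas, inherent bias pushes one variant back).  The package implements:

* `core` / `operator` — landscapes, city density profiles, the conformity
  map, and the normalized two-kernel interaction operator (FFT fast path +
  dense oracle);
* `dynamics` — nonlocal and local (short-range) time integration, random
  initialization, isogloss extraction (marching squares, curvature,
  normals), front-speed and radius measurement;
* `theory` — closed-form velocity laws, the derived bias constant
  (0.6376), stable-radius prediction, the sector-bound shrinkage test;
* `cities` — the gravity-model ODE reduction for city networks;
* `agents` — the stochastic per-speaker lattice with mixing and
  immigration, and the mean-field extinction threshold ν_c(β);
* `mapping` — the regionalization pipeline: randomized-initial-condition
  ensembles, Ward clustering into dialect areas, overlap scoring with
  optimal label alignment, and the Voronoi null model;
* `fixtures` — seeded synthetic geographies for all standard experiments.

## Worked example: the stable radius of a city dialect

A city with Gaussian population ρ(r) = 2e^(−r²/R²) + 1, R = 30√2, sits in
open country.  Its variant is mildly disfavoured (α = 1.01, β = 1.1,
σ = 5).  How large a region can it hold?

```python
import numpy as np, isogloss as ig

city = ig.CitySpec((0.0, 0.0), omega=2.0, radius=30*np.sqrt(2))
p = ig.ModelParams(sigma=5.0, beta=1.1, alpha=1.01)
res = ig.stable_radius(city, p, background=1.0, route="expansion")
print(res.radius, res.roots)
```

```
63.72994751306571 [(33.62479367619408, False), (63.72994751306571, True)]
```

The velocity balance has an unstable root near 34 (inside it the domain
collapses) and a stable one at 63.7: the bias shrinks the domain until the
outward push of the population gradient balances it.  Without bias
(`alpha=1.0`) the stable radius is 75.19.  A full grid simulation of the
local dynamics (`ig.run_to_equilibrium` on a 300×300-unit landscape, cell
2.5, disc initial condition) equilibrates at a circular isogloss of mean
radius 64.01 — within 0.5% of the analytic prediction.

The same machinery runs from the shell, e.g.

```
isogloss theory stable-radius --alpha 1.01 --route expansion
isogloss fixtures emit --name four_city --out fx/
isogloss simulate-agents --fixture stripe_two_city --experiment ramp --size 200
```

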