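# Methods

## The model

`isogloss` simulates the spatial dynamics of a binary linguistic variable
(variants A and B) over a population landscape.  Each location carries a
*memory* m(**r**, t) ∈ [0, 1] — an exponentially weighted history of how
often variant A has been heard there, with timescale τ (all times are in
units of τ).  Speakers convert memory into use through the conformity map

    p(m) = m^(αβ) / (m^(αβ) + (1 − m^α)^β),        f = p(m),

where β ≥ 1 is conformity (amplification of the local majority; β > 1 is
what gives isoglosses surface tension) and α is inherent bias (α = 1 is
neutral; α > 1 handicaps variant A).  The memory relaxes toward the
spatially averaged frequency a speaker samples,

    ∂m/∂t = f̄ − m,     f̄(r) = ∫ ψ(r, r′) f(r′) dr′,

with interaction density

    ψ(r₁, r₂) ∝ [(1 − M₁M₂)·e^(−d²/2σ²) + M₁M₂/(1 + d²/γ²)]·ρ(r₂),

row-normalized over land.  M(**r**) ∈ [0, 1] is the local fraction of
*metropolitan* speakers, whose mutual interactions follow the long-range
Lorentzian kernel (scale γ); everyone else interacts over the short-range
Gaussian kernel (scale σ).  Integrated between two distant compact
metropolitan cores the Lorentzian reproduces the gravity law P₁P₂/r², which
is what produces hierarchical diffusion — jumps of a variant from city to
city without passing through the countryside in between.

An *isogloss* is the f = 1/2 level set: crossing it changes the locally
dominant variant.

## Numerical scheme

* Fields live on a regular square grid; δA = cell², integrals are masked
  sums.  Default grid spacing ≤ σ/2 (resolves the front, whose width is
  O(σ) — more precisely ≈ σ/(c_f√(β−1)) with c_f = √((4ln2−1)/6), so wide
  fronts at β near 1).
* Forward Euler with dt = 0.1.  For the nonlocal dynamics the update is a
  convex combination of values in [0, 1], hence unconditionally stable and
  bound-preserving for dt ≤ 1.
* The operator is applied by FFT convolution: the kernels are translation
  invariant and the metropolitan weights factorize (M₁·M₂), so
  f̄ = [G∗(ρf) + M·(L−G)∗(Mρf)] / [G∗ρ + M·(L−G)∗(Mρ)].  A dense-matrix
  path over land cells is kept as an independent oracle for small grids
  (agreement ≤ 1e-8 on 24×24 is tested).
* The Gaussian kernel is truncated at 5σ (tail mass < 4e-6); the
  Lorentzian is never truncated (its tail is the point).
* Closed (coastline) boundaries are zero density off-land plus per-row
  renormalization over land; this is what makes stable isoglosses meet
  coasts at right angles.  Periodic boundaries wrap distances.
* The local (short-range) reduction is

      ∂m/∂t = f − m + (σ²/2)·[∇²(ρf) − f∇²ρ]/ρ.

  The −f∇²ρ counterterm comes from expanding the *normalized* average to
  O(σ²).  The reduction is often quoted without it; dropping it destroys
  the uniform fixed points m ≡ const wherever ∇²ρ ≠ 0 and, on the worked
  example below, shifts the equilibrium radius from 64 to ≈ 76.  With the
  counterterm the local and nonlocal equilibria agree to < 1%.  The local
  stepper enforces the FTCS stability bound dt ≤ cell²/(2σ²) and raises
  otherwise.
* Isoglosses are extracted by marching squares with linear interpolation;
  per-vertex curvature uses the Menger (circumcircle) formula, exact for
  circular arcs at any vertex spacing; outward normals follow −∇f.
* Equilibrium means max|ṁ| < 1e-6 for 10 consecutive steps; reaching
  max_time instead is flagged, not raised.  Modal variant of a cell is A
  iff f ≥ 1/2 (ties break toward A).

## Isogloss velocity laws

A front through slowly varying density moves with normal velocity

    v = −σ²·(κ/2 + ∇ρ·ĝ/ρ) − v_bias,

positive v meaning motion along the outward normal ĝ (away from A).
Surface tension shortens loops; population gradients push isoglosses out
of dense areas; inherent bias α > 1 pushes against A.

**No conformity prefactor on the geometric terms.**  The effective
diffusivity of the memory field is (σ²/2)p′(m), but the solvability
average of p′ across the front is (total Δf)/(total Δm) = 1 exactly, for
every β.  A 1/β prefactor is sometimes quoted; it disagrees with the
dynamics by the full factor β.  Measured circle-shrink rates give
d(a²)/dt = −σ² within 0.6–4% for β ∈ {1.1, 1.2, 1.3} at a/σ ∈ {10, 20}
(this package's own property tests re-measure this).  The two forms
coincide as β → 1, which is where the analytic derivation lives.

**Bias speed.**  Three routes of increasing fidelity:

1. `linear` — |v| = 0.6376·β²σ/√(β−1)·(α−1).  The dimensionless constant
   is derived at call time (it equals |∂p/∂α|(1/2)/(β·c_f) = ln2/(2c_f)),
   never hard-coded.
2. `expansion` — the travelling-wave balance evaluated with the exact
   sigmoid at the given α: |v| = |Δp(1/2)|/ϕ′ − (σ²/2)p″(1/2)ϕ′ with
   ϕ′ = |f′|/β and the β→1 front gradient |f′| = c_f√(β−1)/σ.  Keeps an
   O(β−1) curvature term the linear law drops (≈ −9% at β = 1.1).
3. `measured` — same, but |f′| is measured from a relaxed 1-D front at the
   given β (the asymptotic formula is ≈ 2.5% low at β = 1.1).  Runs a short
   simulation (~seconds).

**Worked example.**  For a Gaussian city ρ(r) = ω·e^(−r²/R²) + ρ₀ with
ω = 2, ρ₀ = 1, R = 30√2, σ = 5, β = 1.1 the velocity balance gives a
stable radius of 75.19 without bias; with α = 1.01 the routes give 62.57
(linear), 63.73 (expansion, the default) and 64.05 (measured), against
64.01 from a full grid simulation (cell 2.5, 300×300 units, disc initial
condition, equilibrated to max|ṁ| < 1e-6).  The constant background is
essential: a bare Gaussian has no stable radius at all (curvature and the
unbounded relative density gradient never balance stably), and it is the
flattening of ∇ρ/ρ onto the background that arrests the shrinking domain.
An unstable companion root (~28–35) separates collapse from the stable
basin; `stable_radius` reports all roots with stability flags.

## City-network reduction

With metropolitan cores dominating, per-city memories obey
ṁ_i = Σ_j W_ij p(m_j) − m_i with gravity weights
W_ij ∝ P_j/(1 + r_ij²/γ²) (row-normalized).  Integrated with fixed-step
RK4 at dt = 0.01 (validated against Richardson-extrapolated Euler to
1e-6).  Core populations of Gaussian cities are taken as the integral of
the city profile over the core disc, P = πωR²(1 − e^(−c²)) at core factor
c (the mapping from city shape to P is a modelling choice; this one keeps
the field and ODE models consistent on the fixtures).  The reduction
becomes exact as σ → 0, γ → ∞, which the tests verify as monotone
shrinkage of the field/ODE trajectory discrepancy.

Whether a city can resist a variant held by the rest of the network is a
bistability question: a city with incoming foreign weight w keeps its
variant only if w/(1−w) < ν_c(β) (see below).  At β = 1.1 that threshold
is ≈ 2.7% — hierarchical jumps are easy, and keeping a holdout city
requires genuinely large separations.

### The four-city landscape

The standard hierarchical-diffusion scenario (200×200 units): a large
source city (ω = R = 10) at (32, 32) initially using A, two small
satellites (ω = R = 5) at (62, 47) and (45, 64), and a second large city
at (172, 172); hinterland radii 5R, σ = 2√2, γ = 25, β = 1.1, α = 1; the
initial A region is the source's population bump (disc of radius 28).
City positions are not part of the scenario's published definition; these
were chosen so that the defining event sequence is realized: both
satellites adopt A by long-range jumps (t ≈ 1.3–1.5, the nearer first),
the A wave then spreads by surface tension, stalls against the distant
city's density bump, and the distant city never crosses f = 1/2 (its
foreign weight ≈ 2%, below the bistability threshold; it plateaus near
f ≈ 0.13 in the field model and 0.08 in the ODEs).  At smaller
separations the distant city eventually flips in *both* models — the
holdout regime is genuinely narrow at β = 1.1.

## Stochastic speaker lattice

Sites of a periodic lattice are occupied independently with probability
ρ_xy (the capped two-city profile min{(1−ρ₀)Σe^(−Δ²/R²)+ρ₀, 1}).  Each
occupied pair links with probability e^(−Δ²/2σ²) (pairs beyond 6σ are
skipped, link probability < 2e-8; the stencil is also capped at half the
domain so each unordered pair is drawn once).  Memories relax toward the
neighbour-mean frequency; isolated speakers relax toward their own p(m).
Mixing and immigration are per-step Bernoulli thinnings of Poisson rates
(ϵ·dt, ν·dt at dt = 0.1, O(dt) accurate): a mixing event swaps the
memories of the chosen site and a uniformly chosen occupied partner
(exactly conserving the multiset of memory values); an immigration event
replaces the memory by the incoming value (0 = a pure B speaker).  One
master seed spawns independent substreams for occupancy, network and each
event process.

**Mean-field extinction.**  Averaging the immigration dynamics gives
ṁ = m^β/(m^β + (1−m)^β) − (1+ν)m.  For small ν there is a stable fixed
point m* > 1/2; it disappears by tangency at

    ν_c(β) = max_{m∈(0,1)} [g(m)/m] − 1,

computed by bounded scalar optimization to 1e-6: ν_c(1.5) = 0.1184
(tangency near m ≈ 0.74); ν_c grows with β and → 0 as β → 1⁺.  The
closure replaces ⟨p(m)⟩ by p(⟨m⟩); because immigration maintains a
standing spread of memories, the Jensen gap makes the lattice mean run
systematically ≈ 0.015–0.02 *below* the ODE at (β = 1.5, ν = 0.1) — far
beyond seed-to-seed error (≈ 0.001–0.003 SE with 10 seeds of ~2100
agents).  The ODE is a qualitative guide: its fixed-point structure
(survival below ν_c, extinction above) is confirmed on the lattice, its
trajectory is not statistically exact, and the corresponding
strict-tolerance test in the suite documents this by failing.

**Experiment drivers.**  `run_mixing_ramp` (ϵ(t) = 5×10⁻⁴·t on the
stripe-divided equal-city system; internal destruction: the minority
dissolves from within) and `run_shrink_experiment` (unequal cities R, R/2
at β = 2, constant ϵ = 0.1: the minority domain shrinks coherently to
nothing).  The published versions run on 400×400 lattices; the test suite
runs reduced-size analogues (120–200 per side, radii scaled accordingly),
where destruction happens at lower mixing rates than the full-size
ϵ ≈ 0.10–0.14 window because relative fluctuations are larger; the tests
therefore assert the qualitative outcome (monotone shrinkage to zero;
ramp destruction below ϵ = 0.15), not the full-size window.

**Sector bound.**  When *all* speakers interact long-range, a domain-A
speaker's support can be bounded by circle sectors: A shrinks whenever
θ_A ln(1 + r²/γ²) < θ_B ln(1 + R²/γ²); as γ → ∞ this compares sector
areas — stability becomes a global property of the system.

## Regionalization pipeline

1. `smooth_population`: Gaussian smoothing (s.d. σ_s) that conserves total
   population, re-apportioning any mass that would fall off-land back onto
   land per source cell.  σ_s should be comparable to but smaller than σ.
2. `run_ensemble`: n_runs independent uniform-random initial memory
   fields, each evolved under the local dynamics to t_end; the modal-variant
   map of each run is recorded (non-equilibrated runs are kept and
   flagged).
3. `cluster_dialects`: each scored location (a seeded sample of land
   cells, or all of them) is described by its binary vector of modal
   variants across runs; Ward-linkage agglomerative clustering on
   Euclidean distances, tree cut into n_c areas.  n_c is a user input
   (matched to a reference map's count), never auto-selected.
4. `align_and_overlap`: label-confusion matrix over common cells, optimal
   assignment (Hungarian), OL = matching area fraction, WOL = the
   population-weighted version.
5. `voronoi_null`: nearest-seed partition with seeds uniform on land — the
   geometry-blind baseline.

The pipeline is bit-reproducible from the master seed.  On the two-lobed
test landscape (two 80-unit lobes joined at a waist, one ω = 10, R = 10
city per lobe, σ = 4), about half of the random initial conditions
coarsen to the isogloss pinned at the boundary indentations and the rest
to uniformity, and cutting at n_c = 2 recovers the lobes for ≥ 99% of
scored points.

## What the synthetic landscapes do and do not show

The fixtures emulate the published scenario configurations (city sizes,
scales, rates are the published ones; unpublished geometry such as city
positions is chosen once, as documented above).  They are smooth Gaussian
cities on flat backgrounds with idealized masks: they exercise the
mechanisms (surface tension, gravity jumps, mixing-induced destruction,
boundary pinning) but contain none of the granularity, anisotropy or
correlated history of real census rasters, so passing tests demonstrate
the dynamics and the pipeline, not predictive skill on any real dialect
landscape.  Scoring a real map additionally requires a label raster for
the reference dialect areas; the overlap machinery accepts any such
raster.

## Known limitations

* Travel distance is Euclidean; no barriers or road metrics.
* Explicit fixed-step integration only.
* High conformity on coarse grids pins fronts: at β = 2 with cells of
  σ/3, circular isoglosses with a ≳ 20σ stop moving.  Finer grids (≤ σ/2
  at β ≤ 1.5 in the tests) avoid this.
* The curvature-velocity law is asymptotic in a/(front width); at
  a/σ = 5 it holds within 10% only for thin fronts (β ≥ 2–3), and at
  β = 1.1 the front is ≈ 6σ wide so small-loop speeds exceed it
  substantially.
* Mixing is memory exchange; speakers never relocate, and there is no
  demographic structure beyond the immigration rate.
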