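# Methods

`milestonekit` implements milestoning rate theory — Markovian milestoning
with Voronoi tessellations (MMVT) and conventional (first-hitting)
milestoning — together with the downstream kinetics/thermodynamics
analysis, on toy stochastic-dynamics systems where every quantity has an
analytic or brute-force oracle. This note records the model, the estimator
conventions, the numerical choices, and what the bundled toy systems do and
do not demonstrate.

## The milestoning model

Configuration space is partitioned by an ordered set of interfaces
(*milestones*), each the zero level set of a boundary function that is
negative on the interior side of its cell and positive outside. The regions
between consecutive milestones are Voronoi *cells* (anchors). Two
constructors cover the supported geometries: concentric spherical
milestones on a radial collective variable (CV), and milestones at fixed
positions along a linear CV. Cells are indexed `0..N-1` from innermost
outward and milestone `i` separates cells `i-1` and `i`; `n` milestone
radii therefore produce `n-1` bounded cells. The innermost milestone is the
"bound" milestone; the outermost faces the bulk where the
Brownian-dynamics (BD) stage takes over.

Conventions that the engine and analysis share:

* a CV value exactly on a level set counts as crossed (the engine reflects
  it); `locate_cell` breaks the static tie toward the inner cell;
* units are Å, ps, kcal/mol, amu, K throughout; rates convert to s⁻¹
  (×10¹²) and M⁻¹s⁻¹ (1 Å³/ps = 6.02214076×10⁸ M⁻¹s⁻¹) only at the
  reporting boundary;
* R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and C° = 1 M are fixed constants so
  printed free energies are bit-stable.

## MMVT: confined dynamics and estimators

Within each cell a trajectory is propagated by overdamped Euler–Maruyama
dynamics (`x += (D/kT)F dt + √(2D dt) ξ`) or Langevin BAOAB dynamics.
Crossings are detected by an end-of-step check (every `check_interval`
steps, default every step). On a crossing the collision (milestone id,
simulation clock) is logged, positions are restored to the previous step
and velocities reversed; in overdamped mode there are no velocities and
restoration plus the next step's fresh noise draw is the overdamped analog.
There is no continuous-time root-finding: the crossing rule is part of the
model, and its O(√dt) boundary bias (an effective outward shift of each
interface of roughly 0.58·√(2D dt)) is controlled by choosing timesteps
with √(2D dt) two orders of magnitude below the cell width.

From each cell's collision log we accumulate the total time `T_α`, ordered
cross-milestone transition counts `N_α(i→j)`, same-milestone recollision
counts (tracked, excluded from kernels), per-milestone collision totals,
and incubation times `R_α(i)` — the time between consecutive collisions
attributed to the earlier collision's milestone. The span before a cell's
first collision has no defined prior milestone and is discarded.

Cell weights π solve `π·Q = 0` with `Q_αβ` the per-time collision flux of
cell α against the boundary shared with β (least-squares null space with a
normalization row, dense eigensolver fallback; a disconnected sampled-cell
graph is an error). The milestone-level kernel, lifetimes and stationary
weights are the standard π-weighted combinations

    K_ij = Σ_α π_α N_α(i→j)/T_α  /  Σ_α π_α Σ_{j'≠i} N_α(i→j')/T_α
    t_i  = Σ_α π_α R_α(i)/T_α    /  (same denominator)
    p_i  ∝ Σ_α π_α R_α(i)/T_α .

`p_i` is the stationary probability that the *last milestone touched* is
`i` (an incubation-time weighting); free-energy profiles are
`ΔG_i = −RT ln(p_i/max p)`. The corresponding quadrature oracle for 1-D
reversible diffusion weights the Boltzmann density by the backward
committor, not by the raw boundary density — the test suite carries that
integral explicitly.

A practical note on convergence: boundary-collision counts are heavily
clustered (after each reflection the trajectory sits within one step of the
interface, so collisions arrive in bursts whose length scales like cell
width over step width). The flux estimates behind π therefore converge
with an effective sample size set by the number of *excursions*, not the
raw collision count. The bundled study conditions (4000 ps per cell at
dt = 2×10⁻⁵ ps for the flat-potential oracle) were sized so that this
noise sits at the percent level.

## Conventional (Elber-style) milestoning

First-hitting trajectories are launched on a source milestone — the single
CV point in 1-D, an isotropic shell in 3-D (the cell-confined equilibrium
restricted to the milestone degenerates to these for the toy CVs) — and
run until they first touch an adjacent milestone. The kernel is the count
ratio `K_ij = n(i→j)/n(i→·)` and the lifetime the unconditional mean
hitting time, matching the MFPT solver's contract. Toy chains always
designate explicit reflecting ends (a hard wall at the lowest milestone
where the physics requires one); no half-milestone corrections are applied.

## MFPT, k_off, k_on, ΔG_bind

Mean first passage times solve the absorbing-chain system
`(I − K̃)T = t̃` over non-absorbing milestones; `k_off = 10¹²/MFPT(bound →
bulk)` in s⁻¹. For `k_on`, the diffusion-limited encounter rate with the
b-surface, `k(b) = 4πDb`, is combined with the commitment probability of
the absorbing chain: the outermost milestone's kernel row is replaced by
the BD-stage transition probabilities (inward to the next milestone,
otherwise to an escape state), and `k_on = k(b)·hit_fraction·P(bound
before escape | start at the outermost milestone)`. Standard binding free
energy: `ΔG_bind = RT ln((k_off/k_on)/C°)`. For free diffusion this entire
chain telescopes to `4πD·r_bound`, which is the end-to-end oracle used in
the tests.

## BD stage

Only free (non-interacting) diffusion is simulated: trajectories start
uniformly on a sphere and are propagated by Euler–Maruyama with an adaptive
timestep, `dt = min(dt_max, (0.2·gap)²/2D)` where `gap` is the distance to
the nearest absorbing sphere, and a trajectory within 10⁻³ of the
inter-sphere distance of an absorber is declared absorbed (the adaptive
walk contracts the gap geometrically, so the induced bias is of that same
10⁻³ relative order, well below the binomial errors at the bundled n).
Electrostatics, desolvation forces, hydrodynamic interactions and rigid-body
rotation are out of scope; the analysis accepts an externally supplied
`BDStageResult` JSON so a real BD engine's output can be slotted in. A
finite escape radius `R` is mapped to the infinite-domain hit probability
by `P_∞ = P_R + (1−P_R)·r/R`, which is exact for free diffusion.

## Error margins and convergence

Error margins sample rate matrices from the conjugate posterior of the
observed statistics: for each source milestone the likelihood of the rates
is `∏_j q_ij^{N_ij} e^{−q_ij R_i}`, so `q_ij ~ Gamma(shape=N_ij,
rate=R_i)` is sampled exactly (no MCMC), converted to `(K* = q/Σq,
t* = 1/Σq)` and pushed through the same MFPT/k_on/ΔG pipeline. Counts and
incubation times are pooled over cells at the milestone level before
sampling — exact when all cells run equal simulation time (the bundled
conditions), an approximation otherwise. Transitions never observed are
excluded and their kernel entries fixed at zero with a warning; a
Jeffreys-style option (`shape += 0.5` on observed channels) exists but is
off by default. The k_on margin additionally resamples the BD hit fraction
within its binomial error, independently. Calibration is validated by a
frequency property: on synthetic data with a known generating kernel the
95% central interval covers the true k_off in ≈95% of repetitions.

Convergence is deliberately a separate notion from the posterior spread: a
cumulative-estimate series (the estimator re-run on growing log prefixes)
is declared converged when `max|x − mean|/|mean|` over a trailing window is
at most 10% (window and threshold are parameters), and every sampled
milestone interface should carry at least 100 transitions in each
direction. A tight posterior on a still-drifting series fails convergence;
a converged series with few events fails the transition minimum.

## Synthetic-data generator

`SyntheticSpec`/`generate_synthetic_log` draw collision sequences from the
semi-Markov process of a known row-stochastic kernel and lifetime vector
(exponential dwells by default, fixed dwells for degenerate-case tests),
formatted exactly like engine logs. This is the parameter-recovery oracle
for the estimator chain and the ground truth for the coverage property. It
emulates the milestone-hopping statistics of a confined simulation, not the
underlying dynamics: it cannot expose timestep bias, boundary-detection
effects, or cell-weight estimation (single-cell logs have trivial π), which
is precisely what the engine-based oracles cover instead. Neither layer
says anything about force-field accuracy or sampling of slow orthogonal
degrees of freedom in real molecular systems.

## Other numerical choices

* Overdamped stability: `smd_pull` refuses restraint settings with
  `k·(D/kT)·dt > 1` rather than integrating an unstable Euler step.
* Reproducibility: every user-facing seed is passed through
  `SeedSequence` before reaching the Mersenne-Twister kernels, so
  consecutive small seeds give decorrelated streams; per-cell runs use
  seeds derived from `(master seed, cell id, segment index)` and execute in
  fixed-length segments, making an interrupted-and-resumed run bit-identical
  to an uninterrupted one.
* The MFPT solve raises with condition-number diagnostics on singular
  systems and checks reachability of the absorbing set first.
* `p_i = 0` yields `ΔG_i = +∞` (reported, not raised); zero-probability
  entries in profiles serialize as `null`.

## Study conditions baked into the tests

| quantity | conditions |
| --- | --- |
| flat-potential MFPT oracle | milestones 0–4 Å every 1 Å, D = 1 Å²/ps, dt = 2×10⁻⁵ ps, 4000 ps/cell (≈4×10⁶ collisions) |
| parameter recovery | 5-milestone chain, 10⁵ events |
| BD closed forms | b = 20 Å, reaction 10 Å, escape 40 Å, 10⁴ trajectories |
| posterior coverage | 4-milestone reflecting chain, 3000 events, 400 posterior draws, 200 repetitions |
| cross-method check | same flat landscape, 600 first-hitting trajectories per source |

## Known limitations

* Discrete-time crossing detection biases interface statistics at O(√dt);
  the `check_interval` parameter is exposed so the effect can be studied,
  but no correction is applied.
* Only 1-D chains of milestones (linear or concentric-spherical) are
  automated; general level-set networks would need a different cell/flux
  bookkeeping.
* The Langevin path supports MMVT runs but not the first-hitting (Elber)
  or SMD entry points, which are overdamped-only.
* k_on assembly assumes a radial outer geometry (a b-surface); applying it
  to a linear model is mechanically possible but physically meaningless.
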