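# milestonekit

Milestoning kinetics at desk scale: **Markovian milestoning with Voronoi
tessellations (MMVT)** and **conventional (first-hitting) milestoning** on
toy stochastic-dynamics systems, with the complete downstream analysis —
transition kernels, mean first passage times, k_off, k_on assembled from a
Brownian-dynamics encounter rate, binding free energies, free-energy
profiles, Monte-Carlo error margins and convergence diagnostics.

## Who this is for

Milestoning reconstructs long-time kinetics (ligand residence times,
association/dissociation rate constants) from many short, parallel
simulations confined between interfaces, at a small fraction of the cost of
brute-force trajectories. Production implementations couple the method to
molecular-dynamics and Brownian-dynamics engines, where every estimator is
buried under force fields and hardware concerns. `milestonekit` implements
the *method* — the same statistics, estimators and analysis chain — on toy
systems (point particles on analytic potentials) where every output has an
analytic or brute-force oracle. It is aimed at people studying, teaching,
or validating milestoning estimators, and as a reference implementation of
the analysis layer: the analysis accepts collision statistics and BD-stage
results from any engine that writes the documented formats.

## The model in brief

Space is partitioned by milestones — level sets of a collective variable
(CV), negative inside a cell, positive outside. A confined trajectory in
cell α collides with its boundaries; each collision is logged and the
system is put back (positions restored, velocities reversed). From the logs
one accumulates total time T_α, cross-milestone transition counts N_α(i→j)
and incubation times R_α(i). With cell weights π solving π·Q = 0 for the
boundary-collision flux matrix Q, the milestone kernel and lifetimes are

    K_ij = Σ_α π_α N_α(i→j)/T_α  /  Σ_α π_α Σ_{j'≠i} N_α(i→j')/T_α ,
    t_i  = Σ_α π_α R_α(i)/T_α    /  (same denominator) ,

and the kinetics follow from the absorbing-chain solve (I − K̃)T = t̃:

    k_off = 1 / MFPT(bound → bulk) ,
    k_on  = 4πDb · hit_fraction · P(bound before escape) ,
    ΔG_bind = RT ln((k_off/k_on)/C°) ,   C° = 1 M .

Uncertainties come from exact conjugate sampling of rate matrices
(q_ij ~ Gamma(N_ij, R_i)) propagated through the same pipeline; convergence
is judged separately by a trailing-window fluctuation test (default 10%)
and a minimum-transition count per interface (default 100). See
`docs/methods.md` for conventions, estimator details and limitations.

## Worked example

A ligand-sized particle diffusing freely (D = 1 Å²/ps) among concentric
spherical milestones at 2, 4, 6 and 8 Å. For pure diffusion the association
rate to the innermost milestone has the closed form
4πD·r_bound = 4π·2 Å³/ps = 1.51×10¹⁰ M⁻¹s⁻¹, so the whole pipeline can be
checked end to end:

```python
from milestonekit.project import prepare, run_all, analyze

config = {
    "model": {"kind": "spherical", "radii": [2.0, 4.0, 6.0, 8.0],
              "temperature": 298.15, "ndim": 3},
    "potential": {"kind": "flat"},
    "dynamics": {"timestep_ps": 1e-4, "temperature_K": 298.15,
                 "diffusion_A2_per_ps": 1.0, "seed": 0},
    "run": {"segment_ps": 50.0},
    "bd": {"b_radius": 12.0, "escape_radius": 36.0, "n_trajectories": 20000},
}
layout = prepare(config, "demo_project")
run_all(layout, duration_ps=500.0, seed=42)     # one confined run per cell
results = analyze(layout, seed=1)
print(results["display"])
```

Output from this exact run:

```
{'k_off': '1.058e+11 ± 9.7e+09 s^-1',
 'k_on': '1.712e+10 ± 2.8e+09 M^-1 s^-1',
 'dG': '1.08 kcal/mol'}
```

The computed k_on of 1.7×10¹⁰ M⁻¹s⁻¹ sits 13% above the 1.51×10¹⁰
closed form — consistent with the statistical error of a short 500 ps/cell
run (the acceptance checks below run the equivalent 1-D oracle to well
under 5%). k_off here is the escape rate from the 2 Å milestone to the 8 Å
milestone; with no potential holding the particle, "binding" is purely
entropic and ΔG_bind is correspondingly small and positive.

The same model/fit interface is available directly on in-memory logs:

```python
import milestonekit as mk

model  = mk.build_linear_model([0.0, 1.0, 2.0, 3.0, 4.0])
params = mk.DynamicsParams(timestep_ps=2e-5, temperature_K=298.15,
                           diffusion_A2_per_ps=1.0, seed=0)
logs = [mk.mmvt_run(model, c, mk.FlatPotential(), params, duration_ps=1000.0,
                    seed=c) for c in range(4)]
res = mk.MMVTMilestoningModel(logs, model).fit()
res.mfpt(2, {4})          # ps; closed form (L² - x0²)/2D = 6.0 here
res.conf_int("k_off")     # posterior central interval
print(res.summary())
```

A `click` CLI wraps the workflow: `milestonekit prepare | run | converge |
analyze` (see `--help` on each subcommand). Runs are segmented and
resumable; re-running `analyze` on the same logs is bit-reproducible.

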