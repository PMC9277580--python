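"""Brownian-dynamics stage: b-surface encounter rates and outer transitions.

Desk-scale analog of the BD stages of a milestoning k_on calculation: a
ligand-sized particle diffuses freely (no forces) from a starting sphere
(the "b-surface") until it either reaches an inner "reaction" sphere or an
outer escape sphere.  For free diffusion every quantity has a closed form:

* diffusion-limited encounter rate with an absorbing sphere of radius b:
  ``k(b) = 4π D b`` (converted to M^-1 s^-1);
* probability of reaching radius r before radius R from a start at s
  (r < s < R): ``P = (1/s - 1/R) / (1/r - 1/R)``;
* escape to infinity is recovered from a finite escape radius by
  ``P_∞ = P_R + (1 - P_R) · r/R``.

The analysis layer accepts externally supplied :class:`BDStageResult`
values, so output of a real BD engine (with electrostatics, desolvation,
hydrodynamics) could be slotted in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .units import A3_PER_PS_TO_M_INV_S_INV

__all__ = [
    "BDParams",
    "BDStageResult",
    "analytic_encounter_rate",
    "analytic_hit_probability",
    "simulate_bsurface",
    "bd_milestone_transitions",
]


@dataclass(frozen=True)
class BDParams:
    """Free-diffusion BD stage parameters (Å, ps)."""

    diffusion_A2_per_ps: float
    b_radius: float
    reaction_radius: float
    escape_radius: float
    n_trajectories: int = 10_000
    seed: int = 0
    dt_max_ps: float = 1.0

    def __post_init__(self):
        if self.diffusion_A2_per_ps <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if not (0 < self.reaction_radius <= self.b_radius < self.escape_radius):
            raise ValueError(
                "radii must satisfy 0 < reaction <= b < escape, got "
                f"reaction={self.reaction_radius}, b={self.b_radius}, escape={self.escape_radius}"
            )
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")


@dataclass
class BDStageResult:
    """Encounter rate and hit statistics from a BD stage."""

    encounter_rate_M_s: float
    hit_fraction: float
    hit_fraction_se: float
    n_trajectories: int
    transitions: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.hit_fraction <= 1.0:
            raise ValueError("hit fraction must lie in [0, 1]")
        if self.hit_fraction_se < 0:
            raise ValueError("standard error must be >= 0")

    def to_dict(self) -> dict:
        return {
            "encounter_rate": self.encounter_rate_M_s,
            "hit_fraction": self.hit_fraction,
            "se": self.hit_fraction_se,
            "n_trajectories": self.n_trajectories,
            "transitions": {str(k): v for k, v in self.transitions.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BDStageResult":
        return cls(
            encounter_rate_M_s=float(data["encounter_rate"]),
            hit_fraction=float(data["hit_fraction"]),
            hit_fraction_se=float(data.get("se", 0.0)),
            n_trajectories=int(data.get("n_trajectories", 0)),
            transitions={k: float(v) for k, v in data.get("transitions", {}).items()},
        )


def analytic_encounter_rate(D: float, b: float, per_molar_seconds: bool = False) -> float:
    """Diffusion-limited rate onto an absorbing sphere: 4π D b.

    In internal units the rate is a volume flux in Å^3/ps; with
    ``per_molar_seconds=True`` it is converted to M^-1 s^-1
    (1 Å^3/ps = 6.02214076e8 M^-1 s^-1).
    """
    if D <= 0 or b <= 0:
        raise ValueError("D and b must be positive")
    rate = 4.0 * np.pi * D * b
    if per_molar_seconds:
        rate *= A3_PER_PS_TO_M_INV_S_INV
    return float(rate)


def analytic_hit_probability(start: float, inner: float, escape: float = np.inf) -> float:
    """P(reach ``inner`` before ``escape`` | free diffusion from ``start``).

    The classic radial first-passage result (1/s - 1/R)/(1/r - 1/R); with an
    infinite escape radius it reduces to r/s.
    """
    if not 0 < inner <= start:
        raise ValueError("radii must satisfy 0 < inner <= start")
    if start > escape:
        raise ValueError("start must not exceed the escape radius")
    if np.isinf(escape):
        return inner / start
    return (1.0 / start - 1.0 / escape) / (1.0 / inner - 1.0 / escape)


def _simulate_hit_fraction(
    D: float,
    start: float,
    inner: float,
    escape: float,
    n: int,
    seed: int,
    dt_max: float,
    correct_to_infinity: bool,
) -> tuple[float, float]:
    if start <= inner:
        return 1.0, 0.0
    mixed = int(np.random.SeedSequence(int(seed)).generate_state(1)[0]) & 0x7FFFFFFF
    hits = _kernels.bd_hit_fraction(n, start, inner, escape, D, dt_max, mixed, 10**7)
    frac = hits / n
    se = float(np.sqrt(frac * (1.0 - frac) / n))
    if correct_to_infinity:
        # trajectories that escaped at R would still hit with probability r/R
        corr = inner / escape
        frac = frac + (1.0 - frac) * corr
        se = se * (1.0 - corr)
    return float(frac), se


def simulate_bsurface(params: BDParams, correct_to_infinity: bool = False) -> BDStageResult:
    """Simulate the b-surface stage: fraction reaching the reaction radius.

    Trajectories start uniformly on the b-sphere and run until they reach
    the reaction radius (hit) or the escape radius.  The binomial standard
    error accompanies the estimate; ``correct_to_infinity`` maps the finite
    escape radius to the infinite-domain probability.
    """
    frac, se = _simulate_hit_fraction(
        params.diffusion_A2_per_ps,
        params.b_radius,
        params.reaction_radius,
        params.escape_radius,
        params.n_trajectories,
        params.seed,
        params.dt_max_ps,
        correct_to_infinity,
    )
    rate = analytic_encounter_rate(params.diffusion_A2_per_ps, params.b_radius, per_molar_seconds=True)
    return BDStageResult(
        encounter_rate_M_s=rate,
        hit_fraction=frac,
        hit_fraction_se=se,
        n_trajectories=params.n_trajectories,
    )


def bd_milestone_transitions(
    params: BDParams,
    start_radius: float,
    inner_radius: float,
    escape_radius: Optional[float] = None,
    correct_to_infinity: bool = True,
    seed: Optional[int] = None,
) -> dict:
    """BD milestone stage: P(inner milestone before escape) from a start shell.

    Returns ``{"inward": p, "escape": 1 - p, "se": se}``; the inward
    probability feeds the k_on combination as the outermost row of the
    absorbing milestone chain.
    """
    escape = params.escape_radius if escape_radius is None else escape_radius
    if not inner_radius <= start_radius < escape:
        raise ValueError("radii must satisfy inner <= start < escape")
    frac, se = _simulate_hit_fraction(
        params.diffusion_A2_per_ps,
        start_radius,
        inner_radius,
        escape,
        params.n_trajectories,
        params.seed if seed is None else seed,
        params.dt_max_ps,
        correct_to_infinity,
    )
    return {"inward": frac, "escape": 1.0 - frac, "se": se}
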