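"""Milestone-level kinetics: MFPT solver, rate constants, free energies.

The central object is :class:`MilestoneKinetics`: a transition kernel ``K``
(row-stochastic over milestones) plus the incubation/lifetime vector ``t``
(ps).  Mean first passage times follow from the absorbing-chain linear
solve ``(I - K~) T = t~`` where the tilde drops the absorbing rows/columns;
rate constants and the standard binding free energy are derived from them:

    k_off = 1 / MFPT(bound -> bulk)              [s^-1]
    k_on  = k(b) * P(bound before escape)        [M^-1 s^-1]
    ΔG_bind = RT ln((k_off / k_on) / C°),  C° = 1 M
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .units import (
    GAS_CONSTANT_KCAL,
    PS_INV_TO_S_INV,
    SECONDS_PER_HOUR,
    STANDARD_CONCENTRATION_M,
)

__all__ = [
    "MilestoneKinetics",
    "BindingKinetics",
    "mfpt",
    "k_off",
    "free_energy_profile",
    "combine_kon",
    "delta_g_bind",
    "residence_time",
    "residence_time_hours",
]


class InsufficientSamplingError(RuntimeError):
    """A milestone needed by the analysis has no observed transitions."""


@dataclass
class MilestoneKinetics:
    """Transition kernel, lifetimes and stationary milestone probabilities.

    ``K[i, j]`` is the probability that the next milestone after ``i`` is
    ``j``; rows over non-absorbing milestones sum to one.  ``t_ps[i]`` is
    the mean incubation/lifetime at milestone ``i``.  ``p`` (optional) holds
    stationary milestone probabilities (the basis of free-energy profiles);
    ``n_transitions`` (optional) the observed count matrix behind ``K``.
    """

    K: np.ndarray
    t_ps: np.ndarray
    p: Optional[np.ndarray] = None
    n_transitions: Optional[np.ndarray] = None
    incubation_ps: Optional[np.ndarray] = None
    milestone_cv: Optional[np.ndarray] = None
    absorbing: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        self.t_ps = np.asarray(self.t_ps, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n) or self.t_ps.shape != (n,):
            raise ValueError("inconsistent kernel/lifetime shapes")
        rows = [i for i in range(n) if i not in self.absorbing and self.K[i].sum() > 0]
        sums = self.K[rows].sum(axis=1)
        if rows and not np.allclose(sums, 1.0, atol=1e-10):
            raise ValueError(f"kernel rows must be stochastic, row sums {sums}")

    @property
    def n_milestones(self) -> int:
        return self.K.shape[0]


@dataclass
class BindingKinetics:
    """Assembled binding kinetics and thermodynamics."""

    k_on_M_s: float
    k_off_s: float
    delta_g_kcal: float
    residence_time_s: float
    temperature_K: float
    standard_concentration_M: float = STANDARD_CONCENTRATION_M

    def __post_init__(self):
        implied = delta_g_bind(self.k_on_M_s, self.k_off_s, self.temperature_K)
        if abs(implied - self.delta_g_kcal) > 1e-9:
            raise ValueError(
                f"ΔG {self.delta_g_kcal} inconsistent with rates (implies {implied})"
            )


def _transient_solve(K: np.ndarray, rhs: np.ndarray, transient: list[int]) -> np.ndarray:
    Kt = K[np.ix_(transient, transient)]
    A = np.eye(len(transient)) - Kt
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(A)
        raise np.linalg.LinAlgError(
            f"absorbing-chain system is singular (condition number {cond:.3g})"
        ) from exc
    return sol


def _check_reachable(K: np.ndarray, source: int, absorbing: set[int]) -> None:
    n = K.shape[0]
    seen = {source}
    stack = [source]
    while stack:
        i = stack.pop()
        if i in absorbing:
            return
        for j in range(n):
            if K[i, j] > 0 and j not in seen:
                seen.add(j)
                stack.append(j)
    raise ValueError(f"absorbing set {sorted(absorbing)} unreachable from milestone {source}")


def mfpt(kinetics: MilestoneKinetics, source: int, absorbing: Iterable[int]) -> float:
    """Mean first passage time (ps) from ``source`` to the absorbing set.

    Solves ``(I - K~) T = t~`` over the non-absorbing milestones.
    """
    absorbing = set(int(a) for a in absorbing)
    if not absorbing:
        raise ValueError("absorbing set must be non-empty")
    if source in absorbing:
        return 0.0
    _check_reachable(kinetics.K, source, absorbing)
    n = kinetics.n_milestones
    transient = [i for i in range(n) if i not in absorbing]
    T = _transient_solve(kinetics.K, kinetics.t_ps[transient], transient)
    return float(T[transient.index(source)])


def k_off(kinetics: MilestoneKinetics, bound_milestone: int, bulk_milestone: int) -> float:
    """Dissociation rate constant, s^-1: reciprocal MFPT bound -> bulk."""
    mfpt_ps = mfpt(kinetics, bound_milestone, {bulk_milestone})
    return PS_INV_TO_S_INV / mfpt_ps


def free_energy_profile(p: np.ndarray, temperature_K: float) -> np.ndarray:
    """ΔG_i = -RT ln(p_i / max_j p_j) in kcal/mol; the minimum is zero.

    Milestones with zero probability get +inf (unsampled), not an exception.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    pmax = p.max()
    if pmax <= 0:
        raise ValueError("at least one probability must be positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dg = -GAS_CONSTANT_KCAL * temperature_K * np.log(p / pmax)
    dg[p == 0] = np.inf
    return dg


def combine_kon(
    encounter_rate_M_s: float,
    K: np.ndarray,
    bound: int,
    escaped: int,
    start_distribution: np.ndarray,
) -> float:
    """k_on = k(b) × P(bound before escaped | start distribution).

    ``K`` is a row-stochastic kernel over milestones plus the two absorbing
    states (``bound`` and ``escaped`` are row/column indices into it; their
    rows are ignored).  The commitment probability is computed by the
    absorbing-chain linear solve.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    for name, idx in (("bound", bound), ("escaped", escaped)):
        if not 0 <= idx < n:
            raise ValueError(f"missing absorbing class: {name} index {idx} out of range")
    if bound == escaped:
        raise ValueError("bound and escaped states must be distinct")
    start = np.asarray(start_distribution, dtype=float)
    if start.shape != (n,) or not np.isclose(start.sum(), 1.0):
        raise ValueError("start distribution must be normalized over all states")
    absorbing = {bound, escaped}
    transient = [i for i in range(n) if i not in absorbing]
    if transient:
        rhs = K[transient, bound]
        h = _transient_solve(K, rhs, transient)
        p_bound = start[bound] + float(start[transient] @ h)
    else:
        p_bound = start[bound]
    return float(encounter_rate_M_s * p_bound)


def delta_g_bind(k_on_M_s: float, k_off_s: float, temperature_K: float) -> float:
    """Standard binding free energy ΔG = RT ln((k_off/k_on)/C°), kcal/mol."""
    if k_on_M_s <= 0 or k_off_s <= 0:
        raise ValueError("rate constants must be positive")
    ratio = (k_off_s / k_on_M_s) / STANDARD_CONCENTRATION_M
    return GAS_CONSTANT_KCAL * temperature_K * np.log(ratio)


def residence_time(k_off_s: float) -> float:
    """Residence time 1/k_off in seconds."""
    if k_off_s <= 0:
        raise ValueError("k_off must be positive")
    return 1.0 / k_off_s


def residence_time_hours(k_off_s: float) -> float:
    return residence_time(k_off_s) / SECONDS_PER_HOUR
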