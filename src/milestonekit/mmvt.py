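"""MMVT statistics and estimators.

From each cell's collision log we accumulate

* ``T_α`` — total confined simulation time,
* ``N_α(i→j)`` — ordered transition counts between bounding milestones
  (same-milestone recollisions tracked separately, excluded from kernels),
* ``R_α(i)`` — incubation time attributed to milestone ``i`` (time since the
  last collision, summed while ``i`` was the last milestone touched),
* per-milestone boundary collision totals.

Equilibrium cell weights π solve π·Q = 0 for the cell-to-cell collision
flux matrix ``Q_αβ = (collisions in α against the boundary shared with β)
/ T_α``; milestone-level kernels and lifetimes then combine the per-cell
statistics with π weighting:

    K_ij = Σ_α π_α N_α(i→j)/T_α  /  Σ_α π_α Σ_{j'≠i} N_α(i→j')/T_α
    t_i  = Σ_α π_α R_α(i)/T_α    /  (same denominator)
    p_i  ∝ Σ_α π_α R_α(i)/T_α

The span before a cell's first collision has no defined prior milestone and
is excluded from ``R`` and ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .engine import CollisionLog
from .geometry import MilestoneModel
from .kinetics import InsufficientSamplingError, MilestoneKinetics

__all__ = [
    "CellStatistics",
    "aggregate",
    "cell_flux_matrix",
    "cell_weights",
    "milestone_kernel",
]


@dataclass
class CellStatistics:
    """Per-cell MMVT bookkeeping (times in ps)."""

    cell_id: int
    T_ps: float
    transition_counts: dict = field(default_factory=dict)  # (i, j) i != j -> int
    recollision_counts: dict = field(default_factory=dict)  # i -> int
    incubation_ps: dict = field(default_factory=dict)  # i -> float
    collision_totals: dict = field(default_factory=dict)  # i -> int (all events)

    def validate(self) -> None:
        if any(v < 0 for v in self.transition_counts.values()):
            raise ValueError("negative transition count")
        if sum(self.incubation_ps.values()) > self.T_ps + 1e-9:
            raise ValueError("incubation times exceed total time")
        for (i, _j), n in self.transition_counts.items():
            if n > 0 and self.incubation_ps.get(i, 0.0) <= 0:
                raise ValueError(f"transitions from milestone {i} but no incubation time")

    @property
    def milestones(self) -> set:
        out = set(self.collision_totals)
        for i, j in self.transition_counts:
            out |= {i, j}
        return out


def aggregate(log: CollisionLog) -> CellStatistics:
    """Reduce a collision log to per-cell MMVT statistics.

    For each consecutive collision pair ``(m_i at t_i, m_j at t_j)``:
    ``R(m_i) += t_j - t_i``; ``N(m_i→m_j) += 1`` if the milestones differ,
    otherwise the recollision counter of ``m_i`` is incremented.
    """
    m = np.asarray(log.milestones, dtype=np.int64)
    t = np.asarray(log.times_ps, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("collision times must be non-decreasing")

    stats = CellStatistics(cell_id=log.cell_id, T_ps=float(log.total_time_ps))
    ids, counts = np.unique(m, return_counts=True)
    stats.collision_totals = {int(i): int(c) for i, c in zip(ids, counts)}

    if m.size >= 2:
        src, dst = m[:-1], m[1:]
        dt = np.diff(t)
        # incubation: time to the next collision, attributed to the source
        for i in ids:
            stats.incubation_ps[int(i)] = float(dt[src == i].sum())
        cross = src != dst
        pairs, pair_counts = np.unique(
            np.stack([src[cross], dst[cross]], axis=1), axis=0, return_counts=True
        )
        stats.transition_counts = {
            (int(a), int(b)): int(c) for (a, b), c in zip(pairs, pair_counts)
        }
        same_ids, same_counts = np.unique(src[~cross], return_counts=True)
        stats.recollision_counts = {int(i): int(c) for i, c in zip(same_ids, same_counts)}
    stats.validate()
    return stats


def cell_flux_matrix(stats_list: list[CellStatistics], model: MilestoneModel) -> np.ndarray:
    """Cell-to-cell collision flux matrix Q (ps^-1), rows summing to zero.

    ``Q_αβ`` counts collisions in cell α against the milestone shared with
    the adjacent cell β, per unit simulation time.  The matrix is indexed in
    the order of ``stats_list`` (the sampled cells); collisions against the
    bound/bulk-facing ends have no destination cell and do not enter Q.
    """
    index = {s.cell_id: k for k, s in enumerate(stats_list)}
    n = len(stats_list)
    Q = np.zeros((n, n))
    for a, stats in enumerate(stats_list):
        if stats.T_ps <= 0:
            raise ValueError(f"cell {stats.cell_id} has zero total simulation time")
        cell = model.cells[stats.cell_id]
        for neighbor, shared in (
            (stats.cell_id - 1, cell.lower_milestone),
            (stats.cell_id + 1, cell.upper_milestone),
        ):
            b = index.get(neighbor)
            if b is not None:
                Q[a, b] = stats.collision_totals.get(shared, 0) / stats.T_ps
        Q[a, a] = -Q[a].sum()
    return Q


def cell_weights(stats_list: list[CellStatistics], model: MilestoneModel) -> np.ndarray:
    """Stationary cell probabilities π solving π·Q = 0, Σπ = 1.

    Requires the collision graph over cells to be connected (unique
    stationary distribution); a disconnected graph raises, listing the
    components.
    """
    Q = cell_flux_matrix(stats_list, model)
    n = Q.shape[0]
    if n == 1:
        return np.ones(1)
    adjacency = (Q > 0) | (Q.T > 0)
    n_comp, labels = connected_components(adjacency, directed=False)
    if n_comp > 1:
        comps = [list(np.nonzero(labels == c)[0]) for c in range(n_comp)]
        raise ValueError(f"cell collision graph is disconnected: components {comps}")
    # left null vector of Q: solve Q^T π = 0 with the normalization appended
    A = np.vstack([Q.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.any(pi < -1e-8):
        # fall back to the dense eigensolver
        w, v = np.linalg.eig(Q.T)
        k = int(np.argmin(np.abs(w)))
        pi = np.real(v[:, k])
        pi = pi / pi.sum()
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    residual = float(np.linalg.norm(pi @ Q))
    if residual > 1e-8 * max(1.0, float(np.abs(Q).max())):
        raise RuntimeError(f"stationary solve residual too large: {residual:g}")
    return pi


def milestone_kernel(
    stats_list: list[CellStatistics],
    pi: np.ndarray,
    model: MilestoneModel | None = None,
    n_milestones: int | None = None,
    absorbing: set | frozenset = frozenset(),
) -> MilestoneKinetics:
    """π-weighted milestone transition kernel, lifetimes and probabilities.

    Every milestone with observed incubation time must have at least one
    outgoing cross-milestone transition unless designated absorbing;
    otherwise an :class:`InsufficientSamplingError` names it.
    """
    if n_milestones is None:
        if model is not None:
            n_milestones = model.n_milestones
        else:
            n_milestones = max(max(s.milestones, default=-1) for s in stats_list) + 1
    pi = np.asarray(pi, dtype=float)
    order = {s.cell_id: k for k, s in enumerate(stats_list)}
    if pi.shape[0] != len(stats_list):
        raise ValueError("π must have one weight per cell statistics entry")

    M = n_milestones
    flux = np.zeros((M, M))  # Σ_α π_α N_α(i→j)/T_α
    r_flux = np.zeros(M)  # Σ_α π_α R_α(i)/T_α
    counts = np.zeros((M, M), dtype=np.int64)
    incubation = np.zeros(M)
    for s in stats_list:
        w = pi[order[s.cell_id]]
        if s.T_ps <= 0:
            raise ValueError(f"cell {s.cell_id} has zero total time")
        for (i, j), n in s.transition_counts.items():
            flux[i, j] += w * n / s.T_ps
            counts[i, j] += n
        for i, r in s.incubation_ps.items():
            r_flux[i] += w * r / s.T_ps
            incubation[i] += r

    out_flux = flux.sum(axis=1)
    observed = (r_flux > 0) | (out_flux > 0)
    for i in range(M):
        if observed[i] and out_flux[i] == 0 and i not in absorbing:
            raise InsufficientSamplingError(
                f"milestone {i} has incubation time but no outgoing transitions "
                "(insufficient sampling); rerun or designate it absorbing"
            )

    K = np.zeros((M, M))
    t = np.zeros(M)
    for i in range(M):
        if out_flux[i] > 0 and i not in absorbing:
            K[i] = flux[i] / out_flux[i]
            t[i] = r_flux[i] / out_flux[i]
    p = r_flux / r_flux.sum() if r_flux.sum() > 0 else None
    cv = model.thresholds if model is not None else None
    return MilestoneKinetics(
        K=K,
        t_ps=t,
        p=p,
        n_transitions=counts,
        incubation_ps=incubation,
        milestone_cv=cv,
        absorbing=frozenset(absorbing),
    )
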