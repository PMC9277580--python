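"""Synthetic collision-log generator with known ground truth.

Collision sequences are drawn from the semi-Markov process defined by a
row-stochastic milestone kernel ``K_true`` and lifetime vector ``t_true``
(exponential or fixed dwell times), formatted identically to engine output.
Because the generating kernel is known exactly, these logs are the
parameter-recovery oracle for the whole MMVT estimator chain
(aggregate → cell weights → milestone kernel) and the ground truth for
posterior-coverage checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import CollisionLog

__all__ = ["SyntheticSpec", "generate_synthetic_log", "generate_synthetic_logs"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth for a synthetic collision log.

    ``K_true`` must be row-stochastic on every non-terminal row; ``t_true``
    holds the mean dwell (ps) at each milestone.  ``lifetime`` selects
    exponential (the memoryless semi-Markov case) or fixed dwell times.
    """

    K_true: np.ndarray
    t_true: np.ndarray
    n_events: int
    seed: int = 0
    lifetime: str = "exponential"
    cell_id: int = 0
    start_milestone: Optional[int] = None

    def __post_init__(self):
        K = np.asarray(self.K_true, dtype=float)
        t = np.asarray(self.t_true, dtype=float)
        M = K.shape[0]
        if K.shape != (M, M) or t.shape != (M,):
            raise ValueError("K_true must be square and t_true of matching length")
        row_sums = K.sum(axis=1)
        if np.any(row_sums == 0):
            raise ValueError(
                "absorbing (all-zero) kernel rows are not allowed in a generating "
                f"chain: rows {np.nonzero(row_sums == 0)[0].tolist()}"
            )
        if not np.allclose(row_sums, 1.0, atol=1e-10):
            raise ValueError("K_true rows must sum to 1")
        if np.any(np.diag(K) != 0):
            raise ValueError("K_true must have zero diagonal (milestone-to-different-milestone)")
        if np.any(t <= 0):
            raise ValueError("t_true must be positive")
        if self.n_events < 2:
            raise ValueError("need at least 2 events")
        if self.lifetime not in ("exponential", "fixed"):
            raise ValueError("lifetime must be 'exponential' or 'fixed'")


def generate_synthetic_log(spec: SyntheticSpec) -> CollisionLog:
    """Draw one collision log from the (K_true, t_true) semi-Markov process.

    The first record sits at time 0 on the start milestone (default 0); each
    subsequent record follows after a dwell with mean ``t_true[current]``.
    """
    K = np.asarray(spec.K_true, dtype=float)
    t_mean = np.asarray(spec.t_true, dtype=float)
    M = K.shape[0]
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events

    milestones = np.empty(n, dtype=np.int32)
    times = np.empty(n, dtype=np.float64)
    current = spec.start_milestone if spec.start_milestone is not None else 0
    milestones[0] = current
    times[0] = 0.0

    # pre-draw dwell randomness; destinations need sequential choice
    u_dest = rng.random(n - 1)
    if spec.lifetime == "exponential":
        dwell_u = rng.exponential(1.0, size=n - 1)
    else:
        dwell_u = np.ones(n - 1)
    cum_K = np.cumsum(K, axis=1)

    clock = 0.0
    for k in range(1, n):
        clock += t_mean[current] * dwell_u[k - 1]
        current = int(np.searchsorted(cum_K[current], u_dest[k - 1], side="right"))
        if current >= M:  # guard against cumulative rounding
            current = M - 1
        milestones[k] = current
        times[k] = clock

    return CollisionLog(
        cell_id=spec.cell_id,
        milestones=milestones,
        times_ps=times,
        total_time_ps=float(times[-1]),
        params={"synthetic": True, "seed": spec.seed, "lifetime": spec.lifetime},
    )


def generate_synthetic_logs(spec: SyntheticSpec) -> list[CollisionLog]:
    """Spec-level convenience wrapper returning a list of logs."""
    return [generate_synthetic_log(spec)]
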