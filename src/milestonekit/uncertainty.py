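"""Error margins and convergence diagnostics.

Error margins come from Monte-Carlo sampling of rate matrices consistent
with the observed transition counts and incubation times: for each source
milestone ``i`` the transition rates ``q_ij`` have likelihood
``q^N_ij exp(-q R_i)``, whose conjugate form is sampled exactly as
``q_ij ~ Gamma(shape=N_ij, rate=R_i)``.  Each sample converts to a kernel
``K* = q/Σq`` and lifetime vector ``t* = 1/Σq`` and is propagated through
the same MFPT/k_off/k_on/ΔG pipeline as the point estimate.

Convergence is a separate notion (time-series stability of the cumulative
estimate), reflecting that a posterior can be tight while the simulation is
still drifting: a quantity is declared converged when its fluctuations over
a trailing window stay within a fraction (default 10%) of the window mean,
and every milestone pair should have at least a minimum number of observed
transitions (default 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .kinetics import MilestoneKinetics

__all__ = [
    "MatrixPosteriorSample",
    "ConvergenceReport",
    "milestone_level_counts",
    "sample_rate_matrices",
    "propagate_samples",
    "error_margins",
    "convergence_check",
    "min_transition_check",
]


@dataclass
class MatrixPosteriorSample:
    """One draw of (K*, t*) plus derived quantities filled by the pipeline."""

    K: np.ndarray
    t_ps: np.ndarray
    index: int
    seed: int
    k_off_s: Optional[float] = None
    k_on_M_s: Optional[float] = None
    delta_g_kcal: Optional[float] = None


@dataclass
class ConvergenceReport:
    quantity: str
    times: np.ndarray
    values: np.ndarray
    window: float
    threshold: float
    fluctuation_ratio: float
    passed: bool
    flagged_zero_mean: bool = False
    transition_check: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "quantity": self.quantity,
            "times": np.asarray(self.times, dtype=float).tolist(),
            "values": np.asarray(self.values, dtype=float).tolist(),
            "window": self.window,
            "threshold": self.threshold,
            "fluctuation_ratio": self.fluctuation_ratio,
            "passed": bool(self.passed),
            "flagged_zero_mean": bool(self.flagged_zero_mean),
            "transition_check": {str(k): bool(v) for k, v in self.transition_check.items()},
        }


def milestone_level_counts(stats_list) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-cell statistics into milestone-level (N_ij, R_i).

    Counts and incubation times are summed over cells.  This pooling is the
    exact sufficient statistic when all cells run for equal simulation time
    (the bundled study conditions) and a documented approximation otherwise.
    """
    M = 0
    for s in stats_list:
        if s.milestones:
            M = max(M, max(s.milestones) + 1)
    N = np.zeros((M, M), dtype=np.int64)
    R = np.zeros(M)
    for s in stats_list:
        for (i, j), n in s.transition_counts.items():
            N[i, j] += n
        for i, r in s.incubation_ps.items():
            R[i] += r
    return N, R


def sample_rate_matrices(
    stats,
    n_samples: int,
    seed: int,
    jeffreys: bool = False,
    absorbing: Iterable[int] = (),
) -> list[MatrixPosteriorSample]:
    """Exact conjugate posterior draws of (K*, t*) given counts and times.

    ``stats`` is either a list of per-cell statistics, a
    :class:`~milestonekit.kinetics.MilestoneKinetics` carrying its count
    matrix and incubation times, or a tuple ``(N, R)``.  Transitions never
    observed are excluded from sampling and their kernel entries fixed at 0
    (with a warning when that makes a sampled row empty); ``jeffreys=True``
    adds 0.5 to the shape of every observed transition.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if isinstance(stats, MilestoneKinetics):
        if stats.n_transitions is None or stats.incubation_ps is None:
            raise ValueError("kinetics object lacks count/incubation statistics")
        N, R = np.asarray(stats.n_transitions), np.asarray(stats.incubation_ps)
    elif isinstance(stats, tuple):
        N, R = np.asarray(stats[0]), np.asarray(stats[1])
    else:
        N, R = milestone_level_counts(stats)
    M = N.shape[0]
    absorbing = set(absorbing)
    if np.any((N.sum(axis=1) > 0) & (R <= 0)):
        raise ValueError("positive transition counts require positive incubation times")

    rng = np.random.default_rng(seed)
    shape = N.astype(float)
    if jeffreys:
        shape = shape + 0.5 * (N > 0)
    sources = [i for i in range(M) if i not in absorbing and N[i].sum() > 0]
    for i in range(M):
        if i not in absorbing and i not in sources and N[:, i].sum() > 0 and N[i].sum() == 0:
            warnings.warn(
                f"milestone {i} has no observed outgoing transitions; "
                "its kernel row is fixed at zero in every sample",
                RuntimeWarning,
                stacklevel=2,
            )

    samples: list[MatrixPosteriorSample] = []
    # vectorized: draw all Gamma variates at once, shape (n_samples, M, M)
    q = np.zeros((n_samples, M, M))
    for i in sources:
        for j in range(M):
            if shape[i, j] > 0:
                q[:, i, j] = rng.gamma(shape[i, j], 1.0 / R[i], size=n_samples)
    qsum = q.sum(axis=2)
    for s in range(n_samples):
        K = np.zeros((M, M))
        t = np.zeros(M)
        for i in sources:
            if qsum[s, i] > 0:
                K[i] = q[s, i] / qsum[s, i]
                t[i] = 1.0 / qsum[s, i]
        samples.append(MatrixPosteriorSample(K=K, t_ps=t, index=s, seed=seed))
    return samples


def propagate_samples(
    samples: Sequence[MatrixPosteriorSample],
    fn: Callable[[MatrixPosteriorSample], float],
) -> np.ndarray:
    """Apply a derived-quantity function to every posterior sample."""
    return np.array([fn(s) for s in samples], dtype=float)


def error_margins(values, level: float = 0.95) -> dict:
    """Central interval and ± half-width summary of posterior samples.

    Returns mean, sd, the central ``level`` interval and its half-width —
    the "value ± margin" convention used for reported rate constants.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples for error margins")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 0.5 * (1.0 - level)
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "level": level,
        "lower": float(lo),
        "upper": float(hi),
        "half_width": float(0.5 * (hi - lo)),
    }


def convergence_check(
    times,
    values,
    window: float,
    threshold: float = 0.10,
    quantity: str = "quantity",
) -> ConvergenceReport:
    """Trailing-window fluctuation test for a cumulative-estimate series.

    The series passes when ``max |x - mean| / |mean|`` over the trailing
    ``window`` of simulation time is at most ``threshold`` (default 10%).
    A window mean indistinguishable from zero makes the ratio undefined:
    reported as a flagged failure, not an exception.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.size < 2:
        raise ValueError("times and values must be equal-length series (>= 2 points)")
    if np.any(np.diff(times) <= 0):
        raise ValueError("series times must be strictly increasing")
    span = times[-1] - times[0]
    if window > span:
        raise ValueError(f"window {window} exceeds series span {span}")
    mask = times >= times[-1] - window
    tail = values[mask]
    mean = tail.mean()
    scale = np.max(np.abs(tail))
    if scale == 0 or abs(mean) < 1e-12 * scale:
        return ConvergenceReport(
            quantity, times, values, window, threshold,
            fluctuation_ratio=np.inf, passed=False, flagged_zero_mean=True,
        )
    ratio = float(np.max(np.abs(tail - mean)) / abs(mean))
    return ConvergenceReport(
        quantity, times, values, window, threshold,
        fluctuation_ratio=ratio, passed=bool(ratio <= threshold),
    )


def min_transition_check(stats, minimum: int = 100) -> dict:
    """Flag milestone pairs with fewer than ``minimum`` observed transitions.

    Returns ``{(i, j): passed}`` over the ordered pairs present in the
    statistics (both directions of every sampled interface); an empty
    statistics set yields an empty, all-flagged report via ``{"__any__": False}``.
    """
    if isinstance(stats, np.ndarray) or isinstance(stats, tuple):
        N = np.asarray(stats if isinstance(stats, np.ndarray) else stats[0])
    else:
        N, _ = milestone_level_counts(stats)
    # an interface sampled in either direction is expected in both
    keys: set[tuple[int, int]] = set()
    for i in range(N.shape[0]):
        for j in range(N.shape[1]):
            if N[i, j] > 0:
                keys.add((i, j))
                keys.add((j, i))
    if not keys:
        return {"__any__": False}
    return {(i, j): bool(N[i, j] >= minimum) for (i, j) in sorted(keys)}
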