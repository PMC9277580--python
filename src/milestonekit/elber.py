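"""Conventional (Elber-style) milestoning estimators.

First-hitting records — trajectories launched on a source milestone and run
to the first touch of an adjacent milestone — yield a transition kernel by
count ratios and lifetimes as unconditional mean hitting times.  The same
absorbing-chain MFPT machinery as the MMVT branch consumes the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .engine import FirstHittingRecord
from .kinetics import InsufficientSamplingError, MilestoneKinetics, mfpt

__all__ = ["HittingStatistics", "estimate_kernel", "elber_mfpt"]


@dataclass
class HittingStatistics:
    """Per-source-milestone first-hitting summaries."""

    counts: dict = field(default_factory=dict)  # (source, hit) -> int
    total_time_ps: dict = field(default_factory=dict)  # source -> float
    n_records: dict = field(default_factory=dict)  # source -> int

    @classmethod
    def from_records(cls, records: Iterable[FirstHittingRecord]) -> "HittingStatistics":
        stats = cls()
        for rec in records:
            key = (rec.source, rec.hit)
            stats.counts[key] = stats.counts.get(key, 0) + 1
            stats.total_time_ps[rec.source] = stats.total_time_ps.get(rec.source, 0.0) + rec.time_ps
            stats.n_records[rec.source] = stats.n_records.get(rec.source, 0) + 1
        return stats

    def mean_time_ps(self, source: int) -> float:
        return self.total_time_ps[source] / self.n_records[source]


def estimate_kernel(
    records: Iterable[FirstHittingRecord],
    n_milestones: int | None = None,
    absorbing: set | frozenset = frozenset(),
    require_all: bool = False,
) -> MilestoneKinetics:
    """Kernel K_ij = count(i→j)/count(i→·) and lifetimes t_i = mean hitting time.

    Milestones that appear only as hit targets get an all-zero row (they act
    as terminal states).  With ``require_all=True`` every milestone outside
    ``absorbing`` must have at least one launched record; one without raises,
    naming it.
    """
    records = list(records)
    stats = HittingStatistics.from_records(records)
    seen = set(stats.n_records)
    for _, hit in stats.counts:
        seen.add(hit)
    if n_milestones is None:
        n_milestones = max(seen, default=-1) + 1
    M = n_milestones
    counts = np.zeros((M, M), dtype=np.int64)
    for (i, j), n in stats.counts.items():
        counts[i, j] = n
    K = np.zeros((M, M))
    t = np.zeros(M)
    for i in range(M):
        total = counts[i].sum()
        if total == 0:
            if require_all and i not in absorbing:
                raise InsufficientSamplingError(f"milestone {i} has no first-hitting records")
            continue
        K[i] = counts[i] / total
        t[i] = stats.mean_time_ps(i)
    return MilestoneKinetics(
        K=K, t_ps=t, n_transitions=counts, absorbing=frozenset(absorbing)
    )


def elber_mfpt(kinetics: MilestoneKinetics, source: int, absorbing: Iterable[int]) -> float:
    """MFPT (ps) through the shared absorbing-chain solver."""
    return mfpt(kinetics, source, absorbing)
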