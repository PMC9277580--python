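"""Model/Results interface over the milestoning estimators.

Mirrors the fitting idiom of statistical-modelling packages: a model object
is built from data (collision logs or first-hitting records plus the
milestone geometry), ``fit()`` estimates the transition kernel and
lifetimes, and the returned :class:`MilestoningResults` carries the
estimates, derived kinetic/thermodynamic quantities, posterior-based
uncertainties and a ``summary()`` table.

>>> model = MMVTMilestoningModel(logs, geometry)
>>> res = model.fit()
>>> res.k_off(), res.free_energy_profile()
>>> print(res.summary())
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .elber import estimate_kernel
from .engine import CollisionLog, FirstHittingRecord
from .geometry import MilestoneModel
from .kinetics import (
    MilestoneKinetics,
    free_energy_profile,
    k_off as _k_off,
    mfpt as _mfpt,
)
from .mmvt import aggregate, cell_weights, milestone_kernel
from .uncertainty import error_margins, propagate_samples, sample_rate_matrices

__all__ = ["MMVTMilestoningModel", "ElberMilestoningModel", "MilestoningResults"]


class MilestoningResults:
    """Estimated milestone kernel, lifetimes and derived kinetics.

    Attributes
    ----------
    kinetics : MilestoneKinetics
        Kernel ``K``, lifetimes ``t`` (ps), stationary milestone
        probabilities ``p`` (MMVT only) and observed counts.
    cell_weights : ndarray or None
        Stationary Voronoi-cell probabilities π (MMVT only).
    """

    def __init__(
        self,
        kinetics: MilestoneKinetics,
        geometry: Optional[MilestoneModel] = None,
        cell_stats: Optional[list] = None,
        pi: Optional[np.ndarray] = None,
        method: str = "mmvt",
    ):
        self.kinetics = kinetics
        self.geometry = geometry
        self.cell_stats = cell_stats
        self.cell_weights = pi
        self.method = method

    # -- point estimates -------------------------------------------------
    @property
    def kernel(self) -> np.ndarray:
        return self.kinetics.K

    @property
    def lifetimes_ps(self) -> np.ndarray:
        return self.kinetics.t_ps

    @property
    def milestone_probabilities(self) -> Optional[np.ndarray]:
        return self.kinetics.p

    @property
    def temperature_K(self) -> float:
        if self.geometry is None:
            raise ValueError("no geometry attached; temperature unknown")
        return self.geometry.temperature

    def free_energy_profile(self) -> np.ndarray:
        """Milestone ΔG profile (kcal/mol), minimum at zero."""
        if self.kinetics.p is None:
            raise ValueError(
                "free-energy profiles need stationary milestone probabilities "
                "(available from the MMVT estimator)"
            )
        return free_energy_profile(self.kinetics.p, self.temperature_K)

    def mfpt(self, source: int, absorbing: Iterable[int]) -> float:
        """Mean first passage time (ps), absorbing-chain linear solve."""
        return _mfpt(self.kinetics, source, absorbing)

    def k_off(self, bound: Optional[int] = None, bulk: Optional[int] = None) -> float:
        """Dissociation rate (s^-1) from the bound to the bulk milestone."""
        if bound is None:
            bound = self.geometry.bound_milestone_id if self.geometry else 0
        if bulk is None:
            bulk = (
                self.geometry.bulk_milestone_id
                if self.geometry
                else self.kinetics.n_milestones - 1
            )
        return _k_off(self.kinetics, bound, bulk)

    # -- uncertainty -------------------------------------------------------
    def sample_posterior(self, n_samples: int = 1000, seed: int = 0, jeffreys: bool = False):
        """Draw (K*, t*) samples from the conjugate rate-matrix posterior."""
        stats = self.cell_stats if self.cell_stats is not None else self.kinetics
        return sample_rate_matrices(
            stats, n_samples, seed, jeffreys=jeffreys, absorbing=self.kinetics.absorbing
        )

    def k_off_samples(
        self,
        n_samples: int = 1000,
        seed: int = 0,
        bound: Optional[int] = None,
        bulk: Optional[int] = None,
    ) -> np.ndarray:
        if bound is None:
            bound = self.geometry.bound_milestone_id if self.geometry else 0
        if bulk is None:
            bulk = (
                self.geometry.bulk_milestone_id
                if self.geometry
                else self.kinetics.n_milestones - 1
            )
        samples = self.sample_posterior(n_samples, seed)

        def _koff(s):
            kin = MilestoneKinetics(K=s.K, t_ps=s.t_ps, absorbing=self.kinetics.absorbing)
            value = _k_off(kin, bound, bulk)
            s.k_off_s = value
            return value

        return propagate_samples(samples, _koff)

    def conf_int(
        self, quantity: str = "k_off", level: float = 0.95, n_samples: int = 1000, seed: int = 0
    ) -> dict:
        """Posterior central interval for a derived quantity (value ± margin)."""
        if quantity == "k_off":
            values = self.k_off_samples(n_samples, seed)
        elif quantity == "mfpt":
            bound = self.geometry.bound_milestone_id if self.geometry else 0
            bulk = (
                self.geometry.bulk_milestone_id
                if self.geometry
                else self.kinetics.n_milestones - 1
            )
            samples = self.sample_posterior(n_samples, seed)
            values = propagate_samples(
                samples,
                lambda s: _mfpt(
                    MilestoneKinetics(K=s.K, t_ps=s.t_ps, absorbing=self.kinetics.absorbing),
                    bound,
                    {bulk},
                ),
            )
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
        return error_margins(values, level)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Human-readable estimation summary."""
        kin = self.kinetics
        M = kin.n_milestones
        cv = kin.milestone_cv
        rows = []
        N = kin.n_transitions
        for i in range(M):
            rows.append(
                {
                    "milestone": i,
                    "cv": float(cv[i]) if cv is not None else np.nan,
                    "lifetime_ps": kin.t_ps[i],
                    "p": kin.p[i] if kin.p is not None else np.nan,
                    "n_out": int(N[i].sum()) if N is not None else -1,
                }
            )
        table = pd.DataFrame(rows).to_string(index=False, float_format=lambda v: f"{v:.6g}")
        lines = [
            f"{'MMVT' if self.method == 'mmvt' else 'Elber'} milestoning results",
            "=" * 48,
            f"milestones: {M}",
        ]
        if self.cell_weights is not None:
            lines.append(
                "cell weights π: " + np.array2string(self.cell_weights, precision=4)
            )
        if self.kinetics.p is not None:
            dg = self.free_energy_profile()
            lines.append(
                "ΔG profile (kcal/mol): " + np.array2string(dg, precision=3)
            )
        lines += ["", table]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MilestoningResults method={self.method} "
            f"n_milestones={self.kinetics.n_milestones}>"
        )

    # -- plotting ----------------------------------------------------------
    def plot_free_energy(self, ax=None):
        """Free-energy profile vs milestone CV value (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dg = self.free_energy_profile()
        x = (
            self.kinetics.milestone_cv
            if self.kinetics.milestone_cv is not None
            else np.arange(dg.size)
        )
        ax.plot(x, dg, marker="o")
        ax.set_xlabel("milestone CV (Å)")
        ax.set_ylabel(r"$\Delta G$ (kcal/mol)")
        return ax


class MMVTMilestoningModel:
    """Markovian milestoning with Voronoi tessellations, fitted to collision logs.

    Parameters
    ----------
    logs
        One :class:`~milestonekit.engine.CollisionLog` per simulated cell.
    geometry
        The milestone model the logs were generated under.  Optional for
        single-cell (synthetic) logs.
    absorbing
        Milestones exempt from the outgoing-transition requirement.
    """

    def __init__(
        self,
        logs: Sequence[CollisionLog],
        geometry: Optional[MilestoneModel] = None,
        absorbing: Iterable[int] = (),
    ):
        if not logs:
            raise ValueError("need at least one collision log")
        self.logs = list(logs)
        self.geometry = geometry
        self.absorbing = frozenset(int(a) for a in absorbing)
        if geometry is not None:
            expected = geometry.model_hash()
            for log in self.logs:
                if log.model_hash is not None and log.model_hash != expected:
                    raise ValueError(
                        f"log for cell {log.cell_id} was generated under a different "
                        f"model (hash {log.model_hash} != {expected})"
                    )

    def fit(self) -> MilestoningResults:
        stats = [aggregate(log) for log in self.logs]
        if self.geometry is not None and len(stats) > 1:
            pi = cell_weights(stats, self.geometry)
        else:
            pi = np.ones(len(stats)) / len(stats)
        kinetics = milestone_kernel(
            stats,
            pi,
            model=self.geometry,
            absorbing=self.absorbing,
        )
        return MilestoningResults(
            kinetics, geometry=self.geometry, cell_stats=stats, pi=pi, method="mmvt"
        )


class ElberMilestoningModel:
    """Conventional milestoning fitted to first-hitting records."""

    def __init__(
        self,
        records: Sequence[FirstHittingRecord],
        geometry: Optional[MilestoneModel] = None,
        absorbing: Iterable[int] = (),
    ):
        if not records:
            raise ValueError("need at least one first-hitting record")
        self.records = list(records)
        self.geometry = geometry
        self.absorbing = frozenset(int(a) for a in absorbing)

    def fit(self) -> MilestoningResults:
        n = self.geometry.n_milestones if self.geometry is not None else None
        kinetics = estimate_kernel(self.records, n_milestones=n, absorbing=self.absorbing)
        if self.geometry is not None:
            kinetics.milestone_cv = self.geometry.thresholds
        return MilestoningResults(kinetics, geometry=self.geometry, method="elber")
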