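"""Toy stochastic-dynamics engine with milestoning boundary handling.

This module stands in for a molecular-dynamics engine at desk scale:
point particles on analytic potentials, propagated by overdamped
(Euler–Maruyama) or Langevin (BAOAB) dynamics.  It provides

* :func:`mmvt_run` — cell-confined dynamics: every boundary crossing is
  logged and the system is put back (positions restored, velocities
  reversed), confining the trajectory to its Voronoi cell;
* :func:`elber_run` — conventional-milestoning first-hitting trajectories
  launched on a milestone and stopped at the first touch of a neighbour;
* :func:`smd_pull` — a moving harmonic restraint dragging the CV along a
  linear schedule, harvesting per-cell starting states;
* :func:`hmr_repartition` — hydrogen mass repartitioning bookkeeping.

Crossing detection is an end-of-step check (every ``check_interval`` steps,
default every step); a CV value exactly on a level set counts as crossed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .geometry import MilestoneModel
from .potentials import ToyPotential
from .units import KCAL_PER_MOL_TO_AMU_A2_PS2, kT as thermal_energy

__all__ = [
    "DynamicsParams",
    "State",
    "CollisionRecord",
    "CollisionLog",
    "FirstHittingRecord",
    "SMDResult",
    "mmvt_run",
    "elber_run",
    "smd_pull",
    "reflect_on_crossing",
    "hmr_repartition",
]


@dataclass(frozen=True)
class DynamicsParams:
    """Integrator parameters.

    Exactly one dynamics mode must be specified: Langevin via
    ``friction_per_ps`` + ``mass_amu``, or overdamped via
    ``diffusion_A2_per_ps``.
    """

    timestep_ps: float
    temperature_K: float
    seed: int = 0
    friction_per_ps: Optional[float] = None
    mass_amu: Optional[float] = None
    diffusion_A2_per_ps: Optional[float] = None

    def __post_init__(self):
        if self.timestep_ps <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        langevin = self.friction_per_ps is not None and self.mass_amu is not None
        overdamped = self.diffusion_A2_per_ps is not None
        if langevin == overdamped:
            raise ValueError(
                "specify exactly one mode: (friction_per_ps, mass_amu) or diffusion_A2_per_ps"
            )
        if overdamped and self.diffusion_A2_per_ps <= 0:
            raise ValueError("diffusion coefficient must be positive")

    @property
    def mode(self) -> str:
        return "overdamped" if self.diffusion_A2_per_ps is not None else "langevin"

    @property
    def kT_kcal(self) -> float:
        return thermal_energy(self.temperature_K)

    def to_dict(self) -> dict:
        out = {
            "timestep_ps": self.timestep_ps,
            "temperature_K": self.temperature_K,
            "seed": self.seed,
            "mode": self.mode,
        }
        if self.mode == "overdamped":
            out["diffusion_A2_per_ps"] = self.diffusion_A2_per_ps
        else:
            out["friction_per_ps"] = self.friction_per_ps
            out["mass_amu"] = self.mass_amu
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "DynamicsParams":
        data = dict(data)
        data.pop("mode", None)
        return cls(**data)


@dataclass
class State:
    """Positions (Å) and, for Langevin dynamics, velocities (Å/ps)."""

    positions: np.ndarray
    velocities: Optional[np.ndarray] = None


@dataclass
class CollisionRecord:
    milestone: int
    time_ps: float
    state: Optional[State] = None


@dataclass
class CollisionLog:
    """Time-ordered boundary collisions from one cell's confined run.

    Stored column-wise (``milestones``, ``times_ps``) so multi-million-event
    logs stay cheap; :attr:`records` materialises ``CollisionRecord`` objects
    on demand.
    """

    cell_id: int
    milestones: np.ndarray  # int32, collision milestone ids
    times_ps: np.ndarray  # float64, strictly non-decreasing
    total_time_ps: float
    params: dict = field(default_factory=dict)
    model_hash: Optional[str] = None
    states: list[CollisionRecord] = field(default_factory=list)
    trajectory: Optional[np.ndarray] = None
    final_state: Optional[State] = None

    def __post_init__(self):
        self.milestones = np.asarray(self.milestones, dtype=np.int32)
        self.times_ps = np.asarray(self.times_ps, dtype=np.float64)
        if self.milestones.shape != self.times_ps.shape:
            raise ValueError("milestones and times must have equal length")
        if self.times_ps.size and np.any(np.diff(self.times_ps) < 0):
            raise ValueError("collision times must be non-decreasing")
        if self.times_ps.size and self.total_time_ps < self.times_ps[-1]:
            raise ValueError("total_time_ps must cover the last collision")

    @property
    def n_collisions(self) -> int:
        return int(self.milestones.size)

    @property
    def records(self) -> list[CollisionRecord]:
        return [
            CollisionRecord(int(m), float(t))
            for m, t in zip(self.milestones, self.times_ps)
        ]


@dataclass(frozen=True)
class FirstHittingRecord:
    source: int
    hit: int
    time_ps: float

    def __post_init__(self):
        if self.time_ps <= 0:
            raise ValueError("hitting time must be positive")


@dataclass
class SMDResult:
    times_ps: np.ndarray
    positions: np.ndarray
    cv_values: np.ndarray
    cell_states: dict
    missing_cells: list


def _mix_seed(seed: int) -> int:
    """Decorrelate user seeds (sequential small ints) before the MT RNG."""
    return int(np.random.SeedSequence(int(seed)).generate_state(1)[0]) & 0x7FFFFFFF


def _initial_position(model: MilestoneModel, cv_value: float) -> np.ndarray:
    x = np.zeros(model.ndim)
    x[0] = cv_value
    return x


def _cv_kind(model: MilestoneModel) -> int:
    return 1 if model.geometry == "spherical" else 0


def mmvt_run(
    model: MilestoneModel,
    cell_id: int,
    potential: ToyPotential,
    params: DynamicsParams,
    duration_ps: float,
    x0=None,
    seed: Optional[int] = None,
    save_states: bool = False,
    max_states: int = 1000,
    traj_stride: int = 0,
    check_interval: int = 1,
    time_offset_ps: float = 0.0,
    v0=None,
) -> CollisionLog:
    """Run cell-confined dynamics and log every boundary collision.

    The trajectory starts strictly inside cell ``cell_id`` (default: the
    cell anchor) and is reflected back on every crossing; the identity of
    the crossed milestone and the simulation clock are recorded.
    """
    if duration_ps < 0:
        raise ValueError("duration must be >= 0")
    cell = model.cells[cell_id]
    lo, hi = model.cell_bounds(cell_id)
    if x0 is None:
        x0 = _initial_position(model, cell.anchor_point)
    x0 = np.asarray(x0, dtype=float)
    cv0 = model.cv_value(x0)
    if not (lo < cv0 < hi):
        raise ValueError(
            f"starting point (CV={cv0:g}) is not strictly inside cell {cell_id} ({lo:g}, {hi:g})"
        )
    if not np.isfinite(potential.energy(x0)):
        raise ValueError("non-finite potential energy at the starting point")
    seed = params.seed if seed is None else int(seed)

    n_steps = int(round(duration_ps / params.timestep_ps))
    total_time = n_steps * params.timestep_ps
    pot_params = potential.params_array()
    cv_kind = _cv_kind(model)
    n_keep = max_states if save_states else 0

    kernel_seed = _mix_seed(seed)
    if n_steps == 0:
        side = np.empty(0, np.int8)
        ctimes = np.empty(0)
        x_final = x0.copy()
        traj = None
        st = (np.empty(0, np.int8), np.empty(0), np.empty((0, x0.size)))
        v_final = None
    elif params.mode == "overdamped":
        if x0.size == 1 and cv_kind == 0:
            side, ctimes, x_final, traj_arr, st_side, st_time, st_pos = _kernels.mmvt_overdamped_1d(
                float(x0[0]),
                potential.kind_code,
                pot_params,
                lo,
                hi,
                params.diffusion_A2_per_ps,
                params.kT_kcal,
                params.timestep_ps,
                n_steps,
                kernel_seed,
                check_interval,
                traj_stride,
                n_keep,
            )
        else:
            side, ctimes, x_final, traj_arr, st_side, st_time, st_pos = _kernels.mmvt_overdamped(
                x0,
                potential.kind_code,
                pot_params,
                cv_kind,
                lo,
                hi,
                params.diffusion_A2_per_ps,
                params.kT_kcal,
                params.timestep_ps,
                n_steps,
                kernel_seed,
                check_interval,
                traj_stride,
                n_keep,
            )
        traj = traj_arr if traj_stride > 0 else None
        st = (st_side, st_time, st_pos)
        v_final = None
    else:
        kT_int = params.kT_kcal * KCAL_PER_MOL_TO_AMU_A2_PS2
        if v0 is None:
            rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(1,)))
            v0 = rng.normal(0.0, np.sqrt(kT_int / params.mass_amu), x0.size)
        v0 = np.asarray(v0, dtype=float)
        (
            side,
            ctimes,
            x_final,
            v_final,
            traj_arr,
            st_side,
            st_time,
            st_pos,
            st_vel,
        ) = _kernels.mmvt_langevin(
            x0,
            v0,
            potential.kind_code,
            pot_params,
            cv_kind,
            lo,
            hi,
            params.friction_per_ps,
            params.mass_amu,
            kT_int,
            params.timestep_ps,
            n_steps,
            kernel_seed,
            check_interval,
            traj_stride,
            n_keep,
        )
        traj = traj_arr if traj_stride > 0 else None
        st = (st_side, st_time, st_pos, st_vel)

    side_to_milestone = np.array([cell.lower_milestone, cell.upper_milestone], dtype=np.int32)
    milestone_ids = side_to_milestone[side.astype(np.int64)] if side.size else np.empty(0, np.int32)

    states: list[CollisionRecord] = []
    if save_states and st[0].size:
        st_vel = st[3] if len(st) == 4 else None
        for k in range(st[0].size):
            vel = st_vel[k].copy() if st_vel is not None else None
            states.append(
                CollisionRecord(
                    int(side_to_milestone[st[0][k]]),
                    float(st[1][k]) + time_offset_ps,
                    State(st[2][k].copy(), vel),
                )
            )

    log = CollisionLog(
        cell_id=cell_id,
        milestones=milestone_ids,
        times_ps=ctimes + time_offset_ps,
        total_time_ps=total_time + time_offset_ps,
        params={**params.to_dict(), "seed": seed, "duration_ps": duration_ps},
        model_hash=model.model_hash(),
        states=states,
        trajectory=traj,
    )
    log.final_state = State(
        np.asarray(x_final, dtype=float), None if v_final is None else np.asarray(v_final, dtype=float)
    )
    return log


def reflect_on_crossing(previous: State, crossed: State) -> State:
    """MMVT collision handling: restore previous positions, reverse velocities.

    Overdamped states carry no velocities; restoration plus the fresh noise
    draw of the next step is the overdamped analog of velocity reversal.
    """
    velocities = None if previous.velocities is None else -np.asarray(previous.velocities, dtype=float)
    return State(np.asarray(previous.positions, dtype=float).copy(), velocities)


def elber_run(
    model: MilestoneModel,
    source_milestone: int,
    potential: ToyPotential,
    params: DynamicsParams,
    n_trajectories: int,
    seed: Optional[int] = None,
    max_steps: int = 10**8,
    reflecting_wall: Optional[float] = None,
) -> list[FirstHittingRecord]:
    """First-hitting trajectories for conventional (Elber) milestoning.

    Each trajectory is launched on the source milestone (for these toy
    models: the point/isotropic shell at the milestone's CV value) and run
    until it first touches an adjacent milestone.  ``reflecting_wall``
    optionally places a hard reflecting end of the domain (linear models
    only), used when the lowest milestone is an explicit reflecting end.
    """
    if params.mode != "overdamped":
        raise NotImplementedError("elber_run currently supports overdamped dynamics")
    if n_trajectories < 1:
        raise ValueError("n_trajectories must be >= 1")
    thr = model.thresholds
    n = thr.size
    if not 0 <= source_milestone < n:
        raise ValueError(f"unknown milestone {source_milestone}")
    neighbors = [m for m in (source_milestone - 1, source_milestone + 1) if 0 <= m < n]
    if not neighbors:
        raise ValueError("source milestone has no adjacent milestones")

    has_lo = source_milestone - 1 >= 0
    has_hi = source_milestone + 1 < n
    lo = thr[source_milestone - 1] if has_lo else 0.0
    hi = thr[source_milestone + 1] if has_hi else 0.0
    cv_kind = _cv_kind(model)
    seed = params.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    records: list[FirstHittingRecord] = []
    for k in range(n_trajectories):
        if model.geometry == "spherical":
            direction = rng.normal(size=model.ndim)
            direction /= np.linalg.norm(direction)
            x0 = thr[source_milestone] * direction
        else:
            x0 = _initial_position(model, thr[source_milestone])
        traj_seed = int(rng.integers(0, 2**31 - 1))
        hit_side, steps = _kernels.first_hitting_overdamped(
            x0,
            potential.kind_code,
            potential.params_array(),
            cv_kind,
            lo,
            hi,
            has_lo,
            has_hi,
            params.diffusion_A2_per_ps,
            params.kT_kcal,
            params.timestep_ps,
            max_steps,
            traj_seed,
            reflecting_wall if reflecting_wall is not None else 0.0,
            reflecting_wall is not None,
        )
        if hit_side < 0:
            raise RuntimeError(
                f"trajectory {k} from milestone {source_milestone} did not hit within {max_steps} steps"
            )
        hit = source_milestone + 1 if hit_side == 1 else source_milestone - 1
        records.append(FirstHittingRecord(source_milestone, hit, steps * params.timestep_ps))
    return records


def smd_pull(
    potential: ToyPotential,
    params: DynamicsParams,
    k_spring: float,
    schedule: tuple[float, float, float],
    model: Optional[MilestoneModel] = None,
    x0=None,
    seed: Optional[int] = None,
    record_stride: int = 10,
    geometry: str = "linear",
    ndim: Optional[int] = None,
) -> SMDResult:
    """Drag the CV with a moving harmonic restraint (steered dynamics).

    ``schedule`` is ``(cv_start, cv_end, duration_ps)``; the restraint
    centre moves linearly in time.  If a milestoning ``model`` is given, the
    result collects, for each cell the schedule traverses, a saved state
    whose CV is strictly interior to that cell; cells never visited are
    reported in ``missing_cells`` rather than silently skipped.
    """
    cv_start, cv_end, duration_ps = schedule
    if duration_ps <= 0:
        raise ValueError("schedule duration must be positive")
    if k_spring <= 0:
        raise ValueError("spring constant must be positive")
    if params.mode != "overdamped":
        raise NotImplementedError("smd_pull currently supports overdamped dynamics")
    # overdamped Euler stability for the restraint: k * (D/kT) * dt must stay
    # well below 2; refuse clearly unstable settings instead of overflowing
    stiffness = k_spring * params.diffusion_A2_per_ps / params.kT_kcal * params.timestep_ps
    if stiffness > 1.0:
        raise ValueError(
            f"k_spring * mobility * dt = {stiffness:.3g} makes the Euler step unstable; "
            "reduce the timestep or the spring constant"
        )
    if model is not None:
        geometry = model.geometry
        ndim = model.ndim
    ndim = ndim or (3 if geometry == "spherical" else 1)
    if x0 is None:
        x0 = np.zeros(ndim)
        x0[0] = cv_start
    x0 = np.asarray(x0, dtype=float)
    seed = params.seed if seed is None else int(seed)
    n_steps = int(round(duration_ps / params.timestep_ps))
    cv_kind = 1 if geometry == "spherical" else 0
    pos, cvs, _x_final = _kernels.smd_overdamped(
        x0,
        potential.kind_code,
        potential.params_array(),
        cv_kind,
        k_spring,
        cv_start,
        cv_end,
        params.diffusion_A2_per_ps,
        params.kT_kcal,
        params.timestep_ps,
        n_steps,
        _mix_seed(seed),
        record_stride,
    )
    times = params.timestep_ps * record_stride * np.arange(1, pos.shape[0] + 1)

    cell_states: dict[int, State] = {}
    missing: list[int] = []
    if model is not None:
        for cell in model.cells:
            lo, hi = model.cell_bounds(cell.id)
            inside = np.nonzero((cvs > lo) & (cvs < hi))[0]
            if inside.size:
                cell_states[cell.id] = State(pos[inside[0]].copy())
            else:
                missing.append(cell.id)
    return SMDResult(times, pos, cvs, cell_states, missing)


def hmr_repartition(
    masses: Sequence[float],
    hydrogen_flags: Sequence[bool],
    bonds: Sequence[tuple[int, int]],
    target_hydrogen_mass: float,
) -> np.ndarray:
    """Hydrogen mass repartitioning: shift heavy-atom mass onto bonded hydrogens.

    Each hydrogen's mass is set to ``target_hydrogen_mass`` and the bonded
    heavy atom loses the difference, conserving total mass exactly.  Every
    hydrogen must be bonded to exactly one heavy atom; a repartition that
    would drive a heavy atom's mass to zero or below raises, naming the atom.
    """
    masses = np.asarray(masses, dtype=float).copy()
    flags = np.asarray(hydrogen_flags, dtype=bool)
    if masses.shape != flags.shape:
        raise ValueError("masses and hydrogen_flags must have equal length")
    partners: dict[int, list[int]] = {i: [] for i in range(masses.size) if flags[i]}
    for a, b in bonds:
        if flags[a] and not flags[b]:
            partners[a].append(b)
        elif flags[b] and not flags[a]:
            partners[b].append(a)
    for h, heavies in partners.items():
        if len(heavies) != 1:
            raise ValueError(
                f"hydrogen {h} must be bonded to exactly one heavy atom, found {len(heavies)}"
            )
    new = masses.copy()
    for h, (heavy,) in partners.items():
        delta = target_hydrogen_mass - masses[h]
        new[h] = target_hydrogen_mass
        new[heavy] -= delta
    heavy_idx = np.nonzero(~flags)[0]
    bad = heavy_idx[new[heavy_idx] <= 0]
    if bad.size:
        raise ValueError(f"repartitioning drives heavy atom {int(bad[0])} to mass {new[bad[0]]:g} amu")
    return new
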