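"""Project layout, file formats, and the prepare → run → analyze workflow.

A project directory holds everything one milestoning calculation needs:

.. code-block:: text

    root/
      config.yaml          # validated copy of the user configuration
      model.yaml           # the milestone geometry (content-hashed)
      cells/cell_0000/
        mmvt.jsonl         # collision log (JSON lines, header first)
        run_state.json     # resume bookkeeping (segments done, final state)
      results/results.json

Collision logs are JSON-lines: a header object with the run parameters and
the model hash, then one ``{"milestone": i, "time_ps": t}`` object per
collision.  ``analyze`` refuses logs whose recorded model hash does not
match the project's model.  Runs are split into fixed-length segments with
per-segment seeds derived from ``(master seed, cell id, segment index)``, so
a run resumed after an interruption reproduces the single uninterrupted run
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .bd import BDParams, BDStageResult, bd_milestone_transitions, simulate_bsurface
from .engine import CollisionLog, DynamicsParams, mmvt_run
from .geometry import MilestoneModel, ModelValidationError
from .kinetics import combine_kon, delta_g_bind, residence_time
from .models import MMVTMilestoningModel
from .potentials import potential_from_config
from .uncertainty import (
    convergence_check,
    error_margins,
    min_transition_check,
    milestone_level_counts,
)

__all__ = [
    "ProjectLayout",
    "prepare",
    "run_all",
    "analyze",
    "convergence_series",
    "write_collision_log",
    "read_collision_log",
    "write_statistics",
    "read_statistics",
]


@dataclass
class ProjectLayout:
    """Paths of one milestoning project."""

    root: Path
    config: dict

    @property
    def model_path(self) -> Path:
        return self.root / "model.yaml"

    @property
    def config_path(self) -> Path:
        return self.root / "config.yaml"

    @property
    def results_path(self) -> Path:
        return self.root / "results" / "results.json"

    def cell_dir(self, cell_id: int) -> Path:
        return self.root / "cells" / f"cell_{cell_id:04d}"

    def log_path(self, cell_id: int) -> Path:
        return self.cell_dir(cell_id) / "mmvt.jsonl"

    def state_path(self, cell_id: int) -> Path:
        return self.cell_dir(cell_id) / "run_state.json"

    def load_model(self) -> MilestoneModel:
        return MilestoneModel.load(self.model_path)

    @classmethod
    def open(cls, root) -> "ProjectLayout":
        root = Path(root)
        config_path = root / "config.yaml"
        if not config_path.exists():
            raise FileNotFoundError(f"no prepared project at {root} (missing config.yaml)")
        with open(config_path) as fh:
            config = yaml.safe_load(fh)
        return cls(root=root, config=config)


# ---------------------------------------------------------------------------
# collision-log and statistics files
# ---------------------------------------------------------------------------

def write_collision_log(log: CollisionLog, path) -> None:
    """JSON-lines collision log: header line, then one record per collision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "cell": log.cell_id,
        "total_time_ps": log.total_time_ps,
        "model_hash": log.model_hash,
        "params": log.params,
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for m, t in zip(log.milestones, log.times_ps):
            fh.write(f'{{"milestone": {int(m)}, "time_ps": {float(t):.17g}}}\n')


def read_collision_log(path) -> CollisionLog:
    with open(path) as fh:
        header = json.loads(fh.readline())
        milestones, times = [], []
        for line in fh:
            rec = json.loads(line)
            milestones.append(rec["milestone"])
            times.append(rec["time_ps"])
    return CollisionLog(
        cell_id=int(header["cell"]),
        milestones=np.array(milestones, dtype=np.int32),
        times_ps=np.array(times, dtype=np.float64),
        total_time_ps=float(header["total_time_ps"]),
        params=header.get("params") or {},
        model_hash=header.get("model_hash"),
    )


def write_statistics(stats_list, path, fmt: str = "json") -> None:
    """Per-cell statistics table (JSON, or TSV with one row per entry)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = [
            {
                "cell": s.cell_id,
                "T_ps": s.T_ps,
                "N": {f"{i}->{j}": n for (i, j), n in sorted(s.transition_counts.items())},
                "N_self": {str(i): n for i, n in sorted(s.recollision_counts.items())},
                "R_ps": {str(i): r for i, r in sorted(s.incubation_ps.items())},
                "collisions": {str(i): n for i, n in sorted(s.collision_totals.items())},
            }
            for s in stats_list
        ]
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    elif fmt == "tsv":
        lines = ["cell\tkind\ti\tj\tvalue"]
        for s in stats_list:
            lines.append(f"{s.cell_id}\tT\t-\t-\t{s.T_ps:.17g}")
            for (i, j), n in sorted(s.transition_counts.items()):
                lines.append(f"{s.cell_id}\tN\t{i}\t{j}\t{n}")
            for i, n in sorted(s.recollision_counts.items()):
                lines.append(f"{s.cell_id}\tN\t{i}\t{i}\t{n}")
            for i, r in sorted(s.incubation_ps.items()):
                lines.append(f"{s.cell_id}\tR\t{i}\t-\t{r:.17g}")
            for i, n in sorted(s.collision_totals.items()):
                lines.append(f"{s.cell_id}\tC\t{i}\t-\t{n}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown statistics format {fmt!r}")


def read_statistics(path):
    """Read the JSON statistics format back into CellStatistics objects."""
    from .mmvt import CellStatistics

    with open(path) as fh:
        payload = json.load(fh)
    out = []
    for entry in payload:
        s = CellStatistics(cell_id=int(entry["cell"]), T_ps=float(entry["T_ps"]))
        for key, n in entry.get("N", {}).items():
            i, j = key.split("->")
            s.transition_counts[(int(i), int(j))] = int(n)
        s.recollision_counts = {int(i): int(n) for i, n in entry.get("N_self", {}).items()}
        s.incubation_ps = {int(i): float(r) for i, r in entry.get("R_ps", {}).items()}
        s.collision_totals = {int(i): int(n) for i, n in entry.get("collisions", {}).items()}
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# prepare / run / analyze
# ---------------------------------------------------------------------------

_REQUIRED_SECTIONS = ("model", "potential", "dynamics")


def _validate_config(config: dict) -> dict:
    for section in _REQUIRED_SECTIONS:
        if section not in config:
            raise ModelValidationError(f"config missing required section '{section}'")
    # constructing the objects validates each section in depth
    MilestoneModel.from_dict(config["model"])
    potential_from_config(config["potential"])
    DynamicsParams.from_dict(config["dynamics"])
    return config


def prepare(config, root) -> ProjectLayout:
    """Create (idempotently) the project tree for a configuration.

    One subdirectory per Voronoi cell, a validated model file and a copy of
    the configuration.  Re-running on an existing tree never deletes data.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = _validate_config(config)
    model = MilestoneModel.from_dict(config["model"])
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    (root / "results").mkdir(exist_ok=True)
    for cell in model.cells:
        (root / "cells" / f"cell_{cell.id:04d}").mkdir(parents=True, exist_ok=True)
    layout = ProjectLayout(root=root, config=config)
    model.save(layout.model_path)
    with open(layout.config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return layout


def _segment_seed(master_seed: int, cell_id: int, segment: int) -> int:
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(cell_id, segment))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def _merge_segments(cell_id: int, segments: list[CollisionLog], model_hash: str, params: dict) -> CollisionLog:
    milestones = np.concatenate([s.milestones for s in segments]) if segments else np.empty(0, np.int32)
    times = np.concatenate([s.times_ps for s in segments]) if segments else np.empty(0)
    total = segments[-1].total_time_ps if segments else 0.0
    return CollisionLog(
        cell_id=cell_id,
        milestones=milestones,
        times_ps=times,
        total_time_ps=total,
        params=params,
        model_hash=model_hash,
    )


def run_all(
    layout: ProjectLayout,
    duration_ps: float,
    seed: int = 0,
    cells: Optional[Sequence[int]] = None,
    segment_ps: Optional[float] = None,
) -> dict[int, CollisionLog]:
    """Run MMVT in every (or a subset of) cell(s), writing logs to disk.

    The requested duration is rounded up to whole segments
    (``run.segment_ps`` in the config, default 100 ps).  Already-completed
    segments found on disk are reused, making interrupted runs resumable and
    a split run identical to a single one.
    """
    model = layout.load_model()
    potential = potential_from_config(layout.config["potential"])
    params = DynamicsParams.from_dict(layout.config["dynamics"])
    if segment_ps is None:
        segment_ps = float(layout.config.get("run", {}).get("segment_ps", 100.0))
    if segment_ps <= 0:
        raise ValueError("segment_ps must be positive")
    cell_ids = list(cells) if cells is not None else [c.id for c in model.cells]
    n_segments = max(1, int(np.ceil(duration_ps / segment_ps - 1e-9)))

    logs: dict[int, CollisionLog] = {}
    for cell_id in cell_ids:
        state_path = layout.state_path(cell_id)
        done = 0
        x0 = None
        v0 = None
        segments: list[CollisionLog] = []
        if state_path.exists():
            with open(state_path) as fh:
                run_state = json.load(fh)
            if run_state.get("seed") == seed and run_state.get("segment_ps") == segment_ps:
                done = int(run_state["segments_done"])
                x0 = np.array(run_state["final_position"], dtype=float)
                if run_state.get("final_velocity") is not None:
                    v0 = np.array(run_state["final_velocity"], dtype=float)
                existing = read_collision_log(layout.log_path(cell_id))
                segments.append(existing)
        for k in range(done, n_segments):
            log = mmvt_run(
                model,
                cell_id,
                potential,
                params,
                duration_ps=segment_ps,
                x0=x0,
                v0=v0,
                seed=_segment_seed(seed, cell_id, k),
                time_offset_ps=k * segment_ps,
            )
            segments.append(log)
            x0 = log.final_state.positions
            v0 = log.final_state.velocities
        merged = _merge_segments(
            cell_id,
            segments,
            model.model_hash(),
            {**params.to_dict(), "seed": seed, "segment_ps": segment_ps,
             "duration_ps": n_segments * segment_ps},
        )
        write_collision_log(merged, layout.log_path(cell_id))
        with open(state_path, "w") as fh:
            json.dump(
                {
                    "seed": seed,
                    "segment_ps": segment_ps,
                    "segments_done": n_segments,
                    "final_position": np.asarray(x0, dtype=float).tolist(),
                    "final_velocity": None if v0 is None else np.asarray(v0, dtype=float).tolist(),
                },
                fh,
            )
        logs[cell_id] = merged
    return logs


def _load_logs(layout: ProjectLayout, model: MilestoneModel) -> list[CollisionLog]:
    logs = []
    expected = model.model_hash()
    missing = []
    for cell in model.cells:
        path = layout.log_path(cell.id)
        if not path.exists():
            missing.append(cell.id)
            continue
        log = read_collision_log(path)
        if log.model_hash != expected:
            raise ValueError(
                f"collision log for cell {cell.id} carries model hash {log.model_hash}, "
                f"project model is {expected}; refusing to mix models"
            )
        logs.append(log)
    if missing:
        raise FileNotFoundError(
            f"missing collision logs for cells {missing}; run `milestonekit run` "
            "(or seed starting states with smd_pull) first"
        )
    return logs


def _bd_result_for(layout: ProjectLayout, model: MilestoneModel, seed: int) -> BDStageResult:
    bd_cfg = dict(layout.config.get("bd", {}))
    dynamics = layout.config["dynamics"]
    D = bd_cfg.pop("diffusion_A2_per_ps", dynamics.get("diffusion_A2_per_ps"))
    if D is None:
        raise ValueError("BD stage needs a diffusion coefficient (bd.diffusion_A2_per_ps)")
    radii = model.thresholds
    b_radius = float(bd_cfg.pop("b_radius", 1.5 * radii[-1]))
    escape = float(bd_cfg.pop("escape_radius", 3.0 * radii[-1]))
    n_traj = int(bd_cfg.pop("n_trajectories", 10_000))
    params = BDParams(
        diffusion_A2_per_ps=float(D),
        b_radius=b_radius,
        reaction_radius=float(radii[-1]),
        escape_radius=escape,
        n_trajectories=n_traj,
        seed=seed,
    )
    result = simulate_bsurface(params, correct_to_infinity=True)
    result.transitions = bd_milestone_transitions(
        params,
        start_radius=float(radii[-1]),
        inner_radius=float(radii[-2]),
        escape_radius=escape,
        correct_to_infinity=True,
        seed=seed + 1,
    )
    return result


def analyze(
    layout: ProjectLayout,
    bd_result: Optional[BDStageResult] = None,
    seed: int = 0,
    n_error_samples: int = 500,
    min_transitions: int = 100,
    strict: bool = True,
    convergence_points: int = 10,
    convergence_window_fraction: float = 0.5,
) -> dict:
    """End-to-end analysis: k_off, k_on, ΔG_bind, profile, errors, convergence.

    Re-running on the same logs reproduces the results bit-exactly (the only
    randomness is the seeded posterior/BD sampling).  ``strict`` turns
    milestone pairs below the minimum transition count into an error listing
    them, as a guard against under-sampled projects.
    """
    model = layout.load_model()
    logs = _load_logs(layout, model)
    fitted = MMVTMilestoningModel(logs, model).fit()

    N, _ = milestone_level_counts(fitted.cell_stats)
    transition_report = min_transition_check(N, minimum=min_transitions)
    failing = [k for k, ok in transition_report.items() if not ok]
    if strict and failing:
        raise RuntimeError(
            f"under-sampled milestone pairs (fewer than {min_transitions} transitions): {failing}"
        )

    bound = model.bound_milestone_id
    bulk = model.bulk_milestone_id
    mfpt_ps = fitted.mfpt(bound, {bulk})
    koff = fitted.k_off()
    koff_samples = fitted.k_off_samples(n_error_samples, seed)
    koff_margin = error_margins(koff_samples)

    # k_on: BD encounter rate × commitment probability from the bulk milestone
    if bd_result is None:
        bd_result = _bd_result_for(layout, model, seed)
    kernel_kon = _kon_kernel(fitted, bd_result)
    n_states = kernel_kon.shape[0]
    start = np.zeros(n_states)
    start[bulk] = 1.0
    k_on = combine_kon(
        bd_result.encounter_rate_M_s * bd_result.hit_fraction,
        kernel_kon,
        bound=bound,
        escaped=n_states - 1,
        start_distribution=start,
    )
    kon_samples = _kon_posterior(fitted, bd_result, n_error_samples, seed + 17, bound, bulk)
    kon_margin = error_margins(kon_samples)

    temperature = model.temperature
    dg = delta_g_bind(k_on, koff, temperature)
    dg_samples = [
        delta_g_bind(kon_s, koff_s, temperature)
        for kon_s, koff_s in zip(kon_samples, koff_samples)
        if kon_s > 0 and koff_s > 0
    ]
    dg_margin = error_margins(dg_samples) if len(dg_samples) >= 2 else None

    times, series = convergence_series(logs, model, n_points=convergence_points)
    window = convergence_window_fraction * (times[-1] - times[0])
    conv = convergence_check(times, series, window=window, quantity="k_off")
    conv.transition_check = transition_report

    profile = fitted.free_energy_profile()
    results = {
        "temperature_K": temperature,
        "mfpt_ps": mfpt_ps,
        "k_off": koff,
        "k_off_se": koff_margin["sd"],
        "k_off_interval": [koff_margin["lower"], koff_margin["upper"]],
        "k_on": k_on,
        "k_on_se": kon_margin["sd"],
        "k_on_interval": [kon_margin["lower"], kon_margin["upper"]],
        "dG": dg,
        "dG_se": dg_margin["sd"] if dg_margin else None,
        "residence_time_s": residence_time(koff),
        "profile": [None if not np.isfinite(v) else float(v) for v in profile],
        "milestone_cv": model.thresholds.tolist(),
        "bd": bd_result.to_dict(),
        "convergence": conv.to_dict(),
        "display": {
            "k_off": f"{koff:.4g} ± {koff_margin['half_width']:.2g} s^-1",
            "k_on": f"{k_on:.4g} ± {kon_margin['half_width']:.2g} M^-1 s^-1",
            "dG": f"{dg:.2f} kcal/mol",
        },
    }
    layout.results_path.parent.mkdir(parents=True, exist_ok=True)
    with open(layout.results_path, "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    return results


def _kon_kernel(fitted, bd_result: BDStageResult) -> np.ndarray:
    """Milestone kernel extended with an escape state and the BD outer row."""
    K = fitted.kernel
    M = K.shape[0]
    out = np.zeros((M + 1, M + 1))
    out[:M, :M] = K
    bulk = M - 1
    inward = bd_result.transitions.get("inward")
    if inward is None:
        raise ValueError("BD result lacks the outer-milestone transition probabilities")
    out[bulk, :] = 0.0
    out[bulk, bulk - 1] = inward
    out[bulk, M] = 1.0 - inward  # escape state
    return out


def _kon_posterior(fitted, bd_result, n_samples, seed, bound, bulk) -> np.ndarray:
    """k_on posterior: milestoning posterior × binomial BD resampling."""
    rng = np.random.default_rng(seed)
    samples = fitted.sample_posterior(n_samples, seed)
    inward = bd_result.transitions["inward"]
    inward_se = bd_result.transitions.get("se", 0.0)
    hit = bd_result.hit_fraction
    hit_se = bd_result.hit_fraction_se
    values = np.empty(len(samples))
    for idx, s in enumerate(samples):
        M = s.K.shape[0]
        kk = np.zeros((M + 1, M + 1))
        kk[:M, :M] = s.K
        inw = np.clip(rng.normal(inward, inward_se) if inward_se > 0 else inward, 0.0, 1.0)
        kk[bulk, :] = 0.0
        kk[bulk, bulk - 1] = inw
        kk[bulk, M] = 1.0 - inw
        hit_s = np.clip(rng.normal(hit, hit_se) if hit_se > 0 else hit, 0.0, 1.0)
        start = np.zeros(M + 1)
        start[bulk] = 1.0
        values[idx] = combine_kon(
            bd_result.encounter_rate_M_s * hit_s, kk, bound=bound, escaped=M, start_distribution=start
        )
    return values


def convergence_series(
    logs: list[CollisionLog],
    model: MilestoneModel,
    n_points: int = 10,
    quantity: str = "k_off",
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative-data estimates of k_off vs simulation time per cell.

    The logs are truncated to increasing fractions of their duration and the
    full estimator re-run on each prefix; undefined prefixes (not yet enough
    transitions) are skipped.
    """
    fractions = np.linspace(1.0 / n_points, 1.0, n_points)
    times, values = [], []
    for frac in fractions:
        trimmed = []
        for log in logs:
            cutoff = frac * log.total_time_ps
            mask = log.times_ps <= cutoff
            trimmed.append(
                CollisionLog(
                    cell_id=log.cell_id,
                    milestones=log.milestones[mask],
                    times_ps=log.times_ps[mask],
                    total_time_ps=cutoff,
                    params=log.params,
                    model_hash=log.model_hash,
                )
            )
        try:
            res = MMVTMilestoningModel(trimmed, model).fit()
            value = res.k_off() if quantity == "k_off" else res.mfpt(
                model.bound_milestone_id, {model.bulk_milestone_id}
            )
        except Exception:
            continue
        times.append(frac * max(log.total_time_ps for log in logs))
        values.append(value)
    if len(times) < 2:
        raise RuntimeError("not enough analyzable prefixes for a convergence series")
    return np.array(times), np.array(values)
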