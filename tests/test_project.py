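import json

import numpy as np
import pytest

import milestonekit as mk
from milestonekit.geometry import ModelValidationError
from milestonekit.project import (
    ProjectLayout,
    analyze,
    prepare,
    read_collision_log,
    read_statistics,
    run_all,
    write_collision_log,
    write_statistics,
)


def _config(radii=(1.0, 2.0, 3.0, 4.0), kind="spherical", segment_ps=10.0):
    key = "radii" if kind == "spherical" else "positions"
    return {
        "model": {"kind": kind, key: list(radii), "temperature": 298.15,
                  "ndim": 3 if kind == "spherical" else 1},
        "potential": {"kind": "flat"},
        "dynamics": {"timestep_ps": 1e-4, "temperature_K": 298.15,
                     "diffusion_A2_per_ps": 1.0, "seed": 0},
        "run": {"segment_ps": segment_ps},
        "bd": {"b_radius": 6.0, "escape_radius": 18.0, "n_trajectories": 4000},
    }


class TestPrepare:
    def test_twelve_cell_layout(self, tmp_path):
        layout = prepare(_config(radii=list(range(1, 14))), tmp_path / "p")
        dirs = sorted((tmp_path / "p" / "cells").iterdir())
        assert len(dirs) == 12
        assert layout.load_model().n_cells == 12

    def test_idempotent_rerun_preserves_data(self, tmp_path):
        config = _config()
        layout = prepare(config, tmp_path / "p")
        marker = layout.cell_dir(0) / "mmvt.jsonl"
        marker.write_text("precious data\n")
        prepare(config, tmp_path / "p")
        assert marker.read_text() == "precious data\n"

    def test_malformed_radii_named_error(self, tmp_path):
        config = _config(radii=[3.0, 2.0, 1.0])
        with pytest.raises(ModelValidationError, match="increasing"):
            prepare(config, tmp_path / "p")

    def test_missing_section_named(self, tmp_path):
        config = _config()
        del config["dynamics"]
        with pytest.raises(ModelValidationError, match="dynamics"):
            prepare(config, tmp_path / "p")


class TestRunAll:
    def test_subset_selection(self, tmp_path):
        layout = prepare(_config(), tmp_path / "p")
        logs = run_all(layout, duration_ps=10.0, seed=1, cells=[0])
        assert set(logs) == {0}
        assert layout.log_path(0).exists()
        assert not layout.log_path(1).exists()

    def test_same_seed_identical_logs(self, tmp_path):
        a = prepare(_config(), tmp_path / "a")
        b = prepare(_config(), tmp_path / "b")
        run_all(a, duration_ps=10.0, seed=5, cells=[1])
        run_all(b, duration_ps=10.0, seed=5, cells=[1])
        assert a.log_path(1).read_bytes() == b.log_path(1).read_bytes()

    def test_resumed_run_equals_single_run(self, tmp_path):
        """Two 10 ps continuations reproduce one 20 ps run bit-for-bit."""
        split = prepare(_config(segment_ps=5.0), tmp_path / "split")
        run_all(split, duration_ps=10.0, seed=3, cells=[0])
        run_all(split, duration_ps=20.0, seed=3, cells=[0])
        single = prepare(_config(segment_ps=5.0), tmp_path / "single")
        run_all(single, duration_ps=20.0, seed=3, cells=[0])
        assert split.log_path(0).read_bytes() == single.log_path(0).read_bytes()


class TestFileFormats:
    def test_collision_log_round_trip_byte_identical(self, tmp_path, linear_chain,
                                                     flat_potential, overdamped_params):
        log = mk.mmvt_run(linear_chain, 0, flat_potential, overdamped_params, 5.0, seed=2)
        log.model_hash = linear_chain.model_hash()
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_collision_log(log, p1)
        clone = read_collision_log(p1)
        write_collision_log(clone, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert np.array_equal(clone.milestones, log.milestones)
        assert np.array_equal(clone.times_ps, log.times_ps)

    def test_statistics_round_trip(self, tmp_path, hand_trace_log):
        stats = [mk.aggregate(hand_trace_log)]
        path = tmp_path / "stats.json"
        write_statistics(stats, path)
        clone = read_statistics(path)[0]
        assert clone.transition_counts == stats[0].transition_counts
        assert clone.incubation_ps == stats[0].incubation_ps
        assert clone.T_ps == stats[0].T_ps

    def test_statistics_tsv_format(self, tmp_path, hand_trace_log):
        stats = [mk.aggregate(hand_trace_log)]
        path = tmp_path / "stats.tsv"
        write_statistics(stats, path, fmt="tsv")
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "cell\tkind\ti\tj\tvalue"
        assert any("\tN\t1\t2\t1" in line for line in lines)


@pytest.fixture(scope="module")
def project(tmp_path_factory):
    root = tmp_path_factory.mktemp("proj")
    layout = prepare(_config(segment_ps=50.0), root / "p")
    run_all(layout, duration_ps=200.0, seed=11)
    return layout


class TestAnalyze:
    def test_end_to_end_results(self, project):
        results = analyze(project, seed=1, strict=False)
        assert results["k_off"] > 0
        assert results["k_on"] > 0
        assert results["mfpt_ps"] > 0
        assert len(results["profile"]) == 4
        assert project.results_path.exists()

    def test_rerun_is_bit_exact(self, project):
        a = analyze(project, seed=1, strict=False)
        blob_a = project.results_path.read_bytes()
        b = analyze(project, seed=1, strict=False)
        assert a["k_off"] == b["k_off"] and a["k_on"] == b["k_on"]
        assert project.results_path.read_bytes() == blob_a

    def test_missing_cell_log_named(self, tmp_path):
        layout = prepare(_config(), tmp_path / "p")
        run_all(layout, duration_ps=10.0, seed=1, cells=[0, 1])
        with pytest.raises(FileNotFoundError, match=r"\[2\]"):
            analyze(layout, seed=0, strict=False)

    def test_model_hash_mismatch_refused(self, tmp_path):
        layout = prepare(_config(), tmp_path / "p")
        run_all(layout, duration_ps=10.0, seed=1)
        # swap the project's model for a different one after the fact
        mk.build_spherical_model([1.0, 2.0, 3.0, 4.5]).save(layout.model_path)
        with pytest.raises(ValueError, match="hash"):
            analyze(layout, seed=0, strict=False)

    def test_undersampled_project_rejected_when_strict(self, tmp_path):
        layout = prepare(_config(segment_ps=1.0), tmp_path / "p")
        run_all(layout, duration_ps=1.0, seed=1)
        with pytest.raises(RuntimeError, match="under-sampled"):
            analyze(layout, seed=0, strict=True)

    def test_external_bd_result_used(self, project):
        bd = mk.BDStageResult(
            encounter_rate_M_s=1e10, hit_fraction=1.0, hit_fraction_se=0.0,
            n_trajectories=0, transitions={"inward": 1.0, "escape": 0.0, "se": 0.0},
        )
        results = analyze(project, bd_result=bd, seed=1, strict=False)
        # all flux committed inward: k_on = k(b) x P(bound | outermost)
        assert 0 < results["k_on"] <= 1e10
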