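import os
import signal
import subprocess
import sys
import time

import pytest
import yaml

from conftest import edit_config, normalize_annotation, reload_graph, tree_snapshot
from provflow import (
    execute_run,
    execute_workflow,
    output_dir,
    run_pipeline,
    template_workflow,
)
from provflow.config import ToolSpec
from provflow.errors import ToolMissingError
from provflow.executor import MISSING_OUTPUT, PROCESS_FAILURE, SUCCESS
from provflow.provenance import FAILED_SENTINEL, staging_dir
from provflow.steps_library import CommandGroup

NATIVE = {"native": ToolSpec(name="native", path="native")}
PY = {"py": ToolSpec(name="py", path=sys.executable)}


def test_successful_run_promotes_atomically_and_clears_temp(workspace):
    _cfg, g = workspace("chain")
    run = g.runs[("raw", "s1")]
    rec = execute_run(run, g, g.destination)
    assert rec.outcome == SUCCESS
    assert os.path.isdir(rec.final_dir)
    assert not os.path.isdir(rec.staging_dir)


def test_nonzero_exit_keeps_staging_with_sentinel_and_stderr(workspace):
    cfg, g = workspace("chain")
    edit_config(cfg, lambda d: d["steps"]["trim"].__setitem__("_fail_mode", "exit"))
    g = reload_graph(cfg)
    execute_workflow(g, g.destination)
    run = g.runs[("trim", "s1")]
    assert not os.path.isdir(output_dir(run, run.fingerprint, g.destination))
    stage = staging_dir(run, g.destination)
    assert os.path.isfile(os.path.join(stage, FAILED_SENTINEL))
    with open(os.path.join(stage, ".annotation.yaml")) as fh:
        ann = yaml.safe_load(fh)
    assert ann["outcome"] == PROCESS_FAILURE
    assert "injected failure" in ann["processes"][0]["stderr_tail"]


def test_missing_planned_output_fails_the_run(workspace):
    cfg, g = workspace("chain")
    edit_config(cfg, lambda d: d["steps"]["trim"].__setitem__(
        "_fail_mode", "missing_output"))
    g = reload_graph(cfg)
    summary = execute_workflow(g, g.destination)
    assert summary.failed == 2
    for run in (g.runs[("trim", "s1")], g.runs[("trim", "s2")]):
        assert not os.path.isdir(output_dir(run, run.fingerprint, g.destination))


def test_pipe_connects_stdout_to_stdin_in_order(tmp_path):
    group = CommandGroup(argvs=(
        ("native", "emit-lines", "--n", "10"),
        ("native", "count-lines"),
    ))
    records, _ = run_pipeline(group, str(tmp_path), dict(os.environ), NATIVE, None)
    assert [r.exit_code for r in records] == [0, 0]
    assert records[-1].stdout_tail.strip() == "10"


def test_failure_of_first_pipe_stage_is_not_masked(tmp_path):
    group = CommandGroup(argvs=(
        ("py", "-c", "import sys; sys.exit(7)"),
        ("py", "-c", "import sys; sys.stdin.read()"),
    ))
    records, _ = run_pipeline(group, str(tmp_path), dict(os.environ), PY, None)
    assert records[0].exit_code == 7
    assert records[1].exit_code == 0  # every status checked individually


def test_stderr_tail_is_exactly_the_last_kilobyte(tmp_path):
    group = CommandGroup(argvs=(
        ("py", "-c",
         "import sys; sys.stderr.write('x'*(1<<20) + 'END')"),
    ))
    records, _ = run_pipeline(group, str(tmp_path), dict(os.environ), PY, None)
    tail = records[0].stderr_tail
    assert len(tail.encode()) == 1024
    assert tail.endswith("END")


def test_missing_executable_raises_tool_missing(tmp_path):
    tools = {"gone": ToolSpec(name="gone", path="/no/such/exe")}
    group = CommandGroup(argvs=(("gone", "arg"),))
    with pytest.raises(ToolMissingError):
        run_pipeline(group, str(tmp_path), dict(os.environ), tools, None)


def test_monitoring_reports_positive_cpu_and_rss(completed_chain):
    _cfg, g = completed_chain
    for run in g.runs_in_order():
        if run.is_source:
            continue
        d = output_dir(run, run.fingerprint, g.destination)
        with open(os.path.join(d, ".annotation.yaml")) as fh:
            ann = yaml.safe_load(fh)
        for proc in ann["processes"]:
            assert proc["cpu_seconds"] >= 0
            assert proc["peak_rss_bytes"] > 0
            assert len(proc["stdout_tail"].encode()) <= 1024
            assert len(proc["stderr_tail"].encode()) <= 1024


def test_step_environment_variables_reach_only_that_step(tmp_path):
    cfg = template_workflow("chain", str(tmp_path))
    edit_config(cfg, lambda d: d["steps"]["trim"].__setitem__(
        "_environment", {"PROVFLOW_PROBE": "42"}))
    g = reload_graph(cfg)
    run = g.runs[("trim", "s1")]
    assert run.environment == {"PROVFLOW_PROBE": "42"}
    assert g.runs[("counts", "s1")].environment == {}


def test_workflow_idempotence_and_failure_skips_descendants(workspace):
    cfg, g = workspace("chipseq_toy")
    s1 = execute_workflow(g, g.destination)
    assert (s1.executed, s1.failed) == (9, 0)
    s2 = execute_workflow(g, g.destination)
    assert s2.executed == 0

    edit_config(cfg, lambda d: d["steps"]["trim"].__setitem__("_fail_mode", "exit"))
    g = reload_graph(cfg)
    s3 = execute_workflow(g, g.destination)
    assert s3.failed == 3 and s3.skipped == 3  # counts runs never started


def test_parallel_and_serial_execution_produce_identical_trees(tmp_path):
    roots = []
    snaps = []
    for i, par in enumerate((1, 4)):
        d = str(tmp_path / f"w{i}")
        cfg = template_workflow("diamond", d, seed=11)
        g = reload_graph(cfg)
        summary = execute_workflow(g, g.destination, max_parallel=par)
        assert summary.ok
        roots.append(d)
        snaps.append(g.destination)
    t1 = tree_snapshot(snaps[0], roots=[roots[0]])
    t2 = tree_snapshot(snaps[1], roots=[roots[1]])
    assert t1 == t2


def _interrupted_then_resumed(workdir, kill_after):
    """Run a slow chain in a subprocess, SIGKILL it, resume in-process.
    Returns (graph, killed_midway)."""
    cfg = template_workflow("chain", workdir, seed=5)
    edit_config(cfg, lambda d: (
        d["steps"]["trim"].__setitem__("_delay", 0.4),
        d["steps"]["counts"].__setitem__("_delay", 0.4),
    ))
    code = (
        "import sys; from provflow import parse_config_file, build_graph, "
        "execute_workflow; g = build_graph(parse_config_file(sys.argv[1])); "
        "execute_workflow(g, g.destination)"
    )
    proc = subprocess.Popen([sys.executable, "-c", code, cfg])
    time.sleep(kill_after)
    killed = proc.poll() is None
    if killed:
        proc.send_signal(signal.SIGKILL)
    proc.wait()
    g = reload_graph(cfg)
    # no partial results: every final run directory carries its annotation
    for step in ("raw", "trim", "counts"):
        step_dir = os.path.join(g.destination, step)
        if not os.path.isdir(step_dir):
            continue
        for run_dir in os.listdir(step_dir):
            assert os.path.isfile(
                os.path.join(step_dir, run_dir, ".annotation.yaml"))
    summary = execute_workflow(g, g.destination)
    assert summary.failed == 0
    return cfg, g, killed


def test_crash_atomicity_and_resume_matches_uninterrupted_run(tmp_path):
    cfg, g, killed = _interrupted_then_resumed(str(tmp_path / "killed"), 1.2)
    assert killed, "expected to interrupt the executor mid-run"

    ref_dir = str(tmp_path / "ref")
    ref_cfg = template_workflow("chain", ref_dir, seed=5)
    edit_config(ref_cfg, lambda d: (
        d["steps"]["trim"].__setitem__("_delay", 0.4),
        d["steps"]["counts"].__setitem__("_delay", 0.4),
    ))
    gr = reload_graph(ref_cfg)
    assert execute_workflow(gr, gr.destination).ok
    resumed = tree_snapshot(g.destination, roots=[str(tmp_path / "killed")])
    reference = tree_snapshot(gr.destination, roots=[ref_dir])
    assert resumed == reference
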