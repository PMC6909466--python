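"""Local run execution: staging, per-process monitoring, atomic promotion.

Partial processing of large files by prematurely killed tools is the
classic silent corruption mode of multi-step analyses.  The executor closes
it off structurally: every run executes inside a staging directory under
``<destination>/temp/``; its result files reach the final content-addressed
directory only through a single atomic rename, performed after *every*
process of the run exited with its expected code and *every* planned output
exists.  A failed run keeps its staging directory (with logs, a failure
sentinel and an annotation) for inspection, and the final location stays
absent, so downstream steps cannot consume half-written data.

Monitoring is sampled from ``/proc`` every 0.5 s while processes run, and
finalized from the kernel's per-child rusage (``os.wait4``): cumulative CPU
seconds and peak resident set size per process, plus the last kilobyte of
each stream.
"""

from __future__ import annotations

import datetime
import os
import shutil
import subprocess
import sys
import threading
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

from .config import engine_version_string
from .errors import (
    FileMissingError,
    StagingError,
    ToolMissingError,
    UnknownToolError,
    VolatilizedInputError,
)
from .provenance import (
    ANNOTATION_FILENAME,
    FAILED_SENTINEL,
    VOLATILE_SUFFIX,
    AnnotationRecord,
    file_checksum,
    output_dir,
    staging_dir,
    write_annotation,
)
from .state import READY, CHANGED, FAILED, all_states, _SATISFIED

TAIL_BYTES = 1024
MONITOR_INTERVAL = 0.5

SUCCESS = "success"
PROCESS_FAILURE = "process_failure"
MISSING_OUTPUT = "missing_output"


@dataclass
class ProcessRecord:
    argv: list
    exit_code: int
    cpu_seconds: float
    peak_rss_bytes: int
    stdout_tail: str
    stderr_tail: str

    def to_dict(self):
        return {
            "argv": list(self.argv),
            "exit_code": self.exit_code,
            "cpu_seconds": self.cpu_seconds,
            "peak_rss_bytes": self.peak_rss_bytes,
            "stdout_tail": self.stdout_tail,
            "stderr_tail": self.stderr_tail,
        }


@dataclass
class ExecutionRecord:
    run: object
    staging_dir: str
    started: str
    ended: str = ""
    processes: list = field(default_factory=list)
    outcome: str = SUCCESS
    final_dir: Optional[str] = None


@dataclass
class WorkflowSummary:
    executed: int = 0
    succeeded: int = 0
    failed: int = 0
    skipped: int = 0
    records: list = field(default_factory=list)

    @property
    def ok(self):
        return self.failed == 0


class ExecutionBackend:
    """Contract for run-execution backends.

    ``submit(run, graph, env)`` hands a schedulable run to the backend and
    returns an opaque handle; ``poll(handle)`` returns None while the run is
    in flight and its :class:`ExecutionRecord` once complete; ``collect()``
    blocks until at least one in-flight run completes and returns its
    record.  The shipped :class:`LocalBackend` executes synchronously in
    ``submit``; a batch-system backend would enqueue and poll.
    """

    def submit(self, run, graph, env):
        raise NotImplementedError

    def poll(self, handle):
        raise NotImplementedError

    def collect(self):
        raise NotImplementedError


class LocalBackend(ExecutionBackend):
    def submit(self, run, graph, env):
        return execute_run(run, graph, graph.destination, environment=env)

    def poll(self, handle):
        return handle

    def collect(self):
        raise RuntimeError("LocalBackend completes runs synchronously")


def _now():
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def _resolve_tool(name, tools):
    try:
        spec = tools[name]
    except KeyError:
        raise UnknownToolError(f"command references undeclared tool {name!r}") from None
    if spec.path == "native":
        return [sys.executable, "-m", "provflow.native"], spec
    return [spec.path], spec


def _resolve_argv(argv, tools, graph):
    head, spec = _resolve_tool(argv[0], tools)
    resolve = graph.resolve_path if graph is not None else (lambda a: a)
    rest = [resolve(a) for a in argv[1:]]
    return head + rest, spec


class _TailReader(threading.Thread):
    """Drains a pipe, retaining only the final TAIL_BYTES bytes."""

    def __init__(self, stream):
        super().__init__(daemon=True)
        self.stream = stream
        self.buf = deque()
        self.size = 0

    def run(self):
        while True:
            chunk = self.stream.read(65536)
            if not chunk:
                break
            self.buf.append(chunk)
            self.size += len(chunk)
            while self.size - len(self.buf[0]) >= TAIL_BYTES:
                self.size -= len(self.buf.popleft())
        self.stream.close()

    def tail(self) -> str:
        data = b"".join(self.buf)[-TAIL_BYTES:]
        return data.decode("utf-8", "replace")


def _proc_peak_rss(pid) -> int:
    try:
        with open(f"/proc/{pid}/status", "rt") as fh:
            for line in fh:
                if line.startswith("VmHWM:"):
                    return int(line.split()[1]) * 1024
    except OSError:
        pass
    return 0


def run_pipeline(command_group, staging, environment, tools, graph,
                 monitor_interval=MONITOR_INTERVAL):
    """Execute one command group (a pipe of argv lists) inside *staging*.

    Processes are connected stdin -> stdout in order.  Every process's exit
    status is checked individually by the caller — a failing first stage of
    a pipe is never masked by a succeeding last stage.  stdout of the final
    process goes to ``command_group.stdout_to`` (a staging-relative file) if
    set, otherwise it is captured; stderr is captured per process.  Captured
    streams are truncated to their final 1024 bytes.
    """
    procs = []
    stderr_readers = []
    stdout_reader = None
    out_fh = None
    resolved_argvs = []
    specs = []
    try:
        n = len(command_group.argvs)
        prev_stdout = subprocess.DEVNULL
        for i, argv in enumerate(command_group.argvs):
            resolved, spec = _resolve_argv(list(argv), tools, graph)
            resolved_argvs.append(resolved)
            specs.append(spec)
            last = i == n - 1
            if last and command_group.stdout_to:
                out_fh = open(os.path.join(staging, command_group.stdout_to), "wb")
                stdout = out_fh
            else:
                stdout = subprocess.PIPE
            try:
                p = subprocess.Popen(
                    resolved,
                    stdin=prev_stdout,
                    stdout=stdout,
                    stderr=subprocess.PIPE,
                    cwd=staging,
                    env=environment,
                )
            except FileNotFoundError as e:
                raise ToolMissingError(f"cannot execute {resolved[0]!r}") from e
            if prev_stdout not in (subprocess.DEVNULL,):
                prev_stdout.close()  # parent's copy of the inherited pipe end
            procs.append(p)
            r = _TailReader(p.stderr)
            r.start()
            stderr_readers.append(r)
            if last:
                if command_group.stdout_to:
                    prev_stdout = subprocess.DEVNULL
                else:
                    stdout_reader = _TailReader(p.stdout)
                    stdout_reader.start()
            else:
                prev_stdout = p.stdout

        # live peak-RSS sampling at monitor_interval while processes run
        peaks = [0] * len(procs)
        stop = threading.Event()

        def _sample():
            while not stop.wait(monitor_interval):
                for i, p in enumerate(procs):
                    if p.returncode is None:
                        peaks[i] = max(peaks[i], _proc_peak_rss(p.pid))

        sampler = threading.Thread(target=_sample, daemon=True)
        sampler.start()
        rusages = [None] * len(procs)
        for i, p in enumerate(procs):
            pid, status, ru = os.wait4(p.pid, 0)
            p.returncode = os.waitstatus_to_exitcode(status)
            rusages[i] = ru
        stop.set()
        sampler.join()

        for r in stderr_readers:
            r.join()
        if stdout_reader:
            stdout_reader.join()

        records = []
        for i, p in enumerate(procs):
            ru = rusages[i]
            cpu = (ru.ru_utime + ru.ru_stime) if ru else 0.0
            peak = max(peaks[i], (ru.ru_maxrss * 1024) if ru else 0)
            records.append(ProcessRecord(
                argv=resolved_argvs[i],
                exit_code=p.returncode,
                cpu_seconds=cpu,
                peak_rss_bytes=peak,
                stdout_tail=stdout_reader.tail() if (stdout_reader and i == n - 1) else "",
                stderr_tail=stderr_readers[i].tail(),
            ))
        return records, specs
    finally:
        if out_fh:
            out_fh.close()
        for p in procs:
            if p.returncode is None:
                p.kill()
                try:
                    os.waitpid(p.pid, 0)
                    p.returncode = -9
                except ChildProcessError:
                    p.returncode = -9


def _check_inputs(run, graph):
    for conn, entries in run.inputs.items():
        for up_hash, path in entries:
            resolved = graph.resolve_path(path)
            if os.path.isfile(resolved):
                continue
            if os.path.isfile(resolved + VOLATILE_SUFFIX):
                up = graph.run_by_hash(up_hash)
                raise VolatilizedInputError(
                    up.step_id if up else "?", up.run_id if up else "?", path
                )
            raise FileMissingError(
                f"run {run.step_id}/{run.run_id}: input {path} is missing"
            )
    if run.is_source:
        for p in run.source_files:
            resolved = graph.config.resolve_source_path(p)
            if not os.path.isfile(resolved):
                raise FileMissingError(
                    f"source run {run.step_id}/{run.run_id}: no such file {p}"
                )


def _tool_versions(run, graph):
    from .config import _probe_tool

    versions = {}
    for tool in graph.steps[run.step_id].tools:
        spec = graph.config.tools.get(tool)
        if spec is None:
            continue
        if spec.path == "native":
            versions[tool] = engine_version_string()
        else:
            probed = _probe_tool(spec)
            versions[tool] = probed.version_string or spec.path
    return versions


def execute_run(run, graph, destination_path, environment=None) -> ExecutionRecord:
    """Execute one run: stage, monitor, and atomically finalize.

    On success the staging directory (results plus annotation) is renamed in
    one operation to the content-addressed final directory; on any failure
    the final directory stays absent and staging is retained with a FAILED
    sentinel and an annotation.  Partial files never appear at the final
    location.
    """
    _check_inputs(run, graph)

    stage = staging_dir(run, destination_path)
    final = output_dir(run, run.fingerprint, destination_path)
    try:
        if os.path.isdir(stage):
            shutil.rmtree(stage)
        os.makedirs(stage)
    except OSError as e:
        raise StagingError(f"cannot create staging directory {stage}: {e}") from e

    env = dict(os.environ)
    env.update({k: str(v) for k, v in run.environment.items()})
    if environment:
        env.update(environment)

    record = ExecutionRecord(run=run, staging_dir=stage, started=_now())
    tools = graph.config.tools
    try:
        for group in run.commands:
            procs, specs = run_pipeline(group, stage, env, tools, graph)
            record.processes.extend(procs)
            bad = any(
                p.exit_code != s.expected_exit_code for p, s in zip(procs, specs)
            )
            if bad:
                record.outcome = PROCESS_FAILURE
                break
        if record.outcome == SUCCESS and not run.is_source:
            for name in run.output_names():
                if not os.path.isfile(os.path.join(stage, name)):
                    record.outcome = MISSING_OUTPUT
                    break
    except (ToolMissingError, UnknownToolError):
        record.ended = _now()
        _finalize_failure(record, run, graph, reason="tool missing")
        raise
    record.ended = _now()

    if record.outcome != SUCCESS:
        _finalize_failure(record, run, graph, reason=record.outcome)
        return record

    output_files = {}
    if run.is_source:
        for p in run.source_files:
            resolved = graph.config.resolve_source_path(p)
            output_files[p] = {
                "sha256": file_checksum(resolved),
                "size_bytes": os.path.getsize(resolved),
            }
    else:
        for name in run.output_names():
            path = os.path.join(stage, name)
            output_files[name] = {
                "sha256": file_checksum(path),
                "size_bytes": os.path.getsize(path),
            }

    ann = AnnotationRecord(
        engine_version=engine_version_string(),
        step_id=run.step_id,
        run_id=run.run_id,
        fingerprint=run.hash_full,
        config_snapshot=graph.config.to_dict(),
        tool_versions=_tool_versions(run, graph),
        commands=[p.argv for p in record.processes],
        started=record.started,
        ended=record.ended,
        processes=[p.to_dict() for p in record.processes],
        output_files=output_files,
        outcome=SUCCESS,
    )
    write_annotation(ann, stage)

    os.makedirs(os.path.dirname(final), exist_ok=True)
    if os.path.isdir(final):
        # stale same-fingerprint directory (e.g. an output was deleted and
        # the run re-executed): discard it before promoting the fresh one
        shutil.rmtree(final)
    os.rename(stage, final)  # the atomic promotion
    record.final_dir = final
    return record


def _finalize_failure(record, run, graph, reason):
    stage = record.staging_dir
    try:
        with open(os.path.join(stage, FAILED_SENTINEL), "wt") as fh:
            fh.write(reason + "\n")
        ann = AnnotationRecord(
            engine_version=engine_version_string(),
            step_id=run.step_id,
            run_id=run.run_id,
            fingerprint=run.hash_full,
            config_snapshot=graph.config.to_dict(),
            tool_versions=_tool_versions(run, graph),
            commands=[p.argv for p in record.processes],
            started=record.started,
            ended=record.ended or _now(),
            processes=[p.to_dict() for p in record.processes],
            output_files={},
            outcome=record.outcome if record.outcome != SUCCESS else "crash",
        )
        write_annotation(ann, stage)
    except OSError:
        pass


def execute_workflow(graph, destination_path, max_parallel=1,
                     environment=None) -> WorkflowSummary:
    """Execute every schedulable run, respecting dependencies.

    Launch order is deterministic (topological, then lexicographic) and, at
    ``max_parallel=1``, strictly serial.  With parallelism, at most
    *max_parallel* runs are in flight and only over whole runs.  After a run
    fails, its descendants are skipped for this invocation; independent
    branches continue.  A volatilized input aborts the invocation with
    :class:`VolatilizedInputError` (the operator must re-execute the
    producer first).
    """
    from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait

    summary = WorkflowSummary()
    attempted = set()
    failed_hashes = set()

    def descends_from_failure(run, states):
        for dep in graph.dependency_runs(run):
            if dep.hash_full in failed_hashes:
                return True
            if states[dep.key] not in _SATISFIED and descends_from_failure(dep, states):
                return True
        return False

    def next_candidates():
        states = all_states(graph, destination_path)
        out = []
        for run in graph.runs_in_order():
            if run.key in attempted or states[run.key] not in (READY, CHANGED, FAILED):
                continue
            if any(states[d.key] not in _SATISFIED for d in graph.dependency_runs(run)):
                continue
            if any(d.hash_full in failed_hashes for d in graph.dependency_runs(run)):
                continue
            out.append(run)
        return out

    with ThreadPoolExecutor(max_workers=max(1, max_parallel)) as pool:
        in_flight = {}
        while True:
            for run in next_candidates():
                if len(in_flight) >= max_parallel:
                    break
                attempted.add(run.key)
                fut = pool.submit(execute_run, run, graph, destination_path,
                                  environment)
                in_flight[fut] = run
                if max_parallel == 1:
                    break  # serial: complete before considering the next
            if not in_flight:
                break
            done, _pending = wait(list(in_flight), return_when=FIRST_COMPLETED)
            for fut in done:
                run = in_flight.pop(fut)
                record = fut.result()  # propagates VolatilizedInputError etc.
                summary.records.append(record)
                summary.executed += 1
                if record.outcome == SUCCESS:
                    summary.succeeded += 1
                else:
                    summary.failed += 1
                    failed_hashes.add(run.hash_full)

    # count runs left unexecuted downstream of this invocation's failures
    if failed_hashes:
        states = all_states(graph, destination_path)
        for run in graph.runs_in_order():
            if run.key in attempted or states[run.key] in _SATISFIED:
                continue
            if descends_from_failure(run, states):
                summary.skipped += 1
    return summary
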