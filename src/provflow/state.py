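"""Run lifecycle states, derived from the filesystem and the DAG.

A run's state is never stored; it is recomputed from what exists on disk
relative to the run's *current* fingerprint:

``finished``
    the content-addressed directory exists, its annotation parses with the
    matching fingerprint, and every planned output (or its volatilization
    placeholder) is present;
``volatilized``
    finished, but at least one output was replaced by a placeholder;
``failed``
    a staging directory for this fingerprint exists carrying the failure
    sentinel (intermediate results and logs are kept on failure);
``waiting``
    some dependency run is not finished/volatilized;
``changed``
    no directory matches the current fingerprint, but an orphaned directory
    exists for the same (step, run) — the configuration was edited after
    results were produced;
``ready``
    dependencies satisfied, own outputs absent.

Re-scheduling follows from the states alone: exactly the ready, changed and
failed runs whose dependencies are all satisfied are schedulable, so failed
or changed runs halt their descendants until re-executed.
"""

from __future__ import annotations

import datetime
import os
from collections import Counter

from .errors import VolatilizeRefusedError
from .provenance import (
    FAILED_SENTINEL,
    VOLATILE_SUFFIX,
    file_checksum,
    output_dir,
    read_annotation,
    staging_dir,
)

FINISHED = "finished"
READY = "ready"
WAITING = "waiting"
FAILED = "failed"
CHANGED = "changed"
VOLATILIZED = "volatilized"

_SATISFIED = (FINISHED, VOLATILIZED)


def _own_completion(run, destination_path):
    """finished | volatilized | None, looking only at the run's own directory."""
    directory = output_dir(run, run.fingerprint, destination_path)
    if not os.path.isdir(directory):
        return None
    ann = read_annotation(directory)
    if ann is None or ann.fingerprint != run.hash_full:
        return None
    volatile = False
    if run.is_source:
        # outputs are external files emitted by reference; existence is
        # checked at graph build, so the annotation alone marks completion
        return FINISHED
    for name in run.output_names():
        if os.path.isfile(os.path.join(directory, name)):
            continue
        if os.path.isfile(os.path.join(directory, name + VOLATILE_SUFFIX)):
            volatile = True
            continue
        return None  # a planned output vanished: not finished any more
    return VOLATILIZED if volatile else FINISHED


def _has_orphan_sibling(run, destination_path):
    step_dir = os.path.join(destination_path, run.step_id)
    if not os.path.isdir(step_dir):
        return False
    prefix = f"{run.run_id}-"
    for name in os.listdir(step_dir):
        if name.startswith(prefix) and name != f"{run.run_id}-{run.hash_short}":
            if os.path.isdir(os.path.join(step_dir, name)):
                return True
    return False


def run_state(run, graph, destination_path) -> str:
    own = _own_completion(run, destination_path)
    if own is not None:
        return own
    stage = staging_dir(run, destination_path)
    if os.path.isdir(stage) and os.path.isfile(os.path.join(stage, FAILED_SENTINEL)):
        return FAILED
    for dep in graph.dependency_runs(run):
        if run_state(dep, graph, destination_path) not in _SATISFIED:
            return WAITING
    if _has_orphan_sibling(run, destination_path):
        return CHANGED
    return READY


def all_states(graph, destination_path) -> dict:
    """(step_id, run_id) -> state for every run, computed bottom-up."""
    states = {}
    for run in graph.runs_in_order():  # topological: deps precede consumers
        own = _own_completion(run, destination_path)
        if own is not None:
            states[run.key] = own
            continue
        stage = staging_dir(run, destination_path)
        if os.path.isdir(stage) and os.path.isfile(os.path.join(stage, FAILED_SENTINEL)):
            states[run.key] = FAILED
            continue
        if any(states[d.key] not in _SATISFIED for d in graph.dependency_runs(run)):
            states[run.key] = WAITING
        elif _has_orphan_sibling(run, destination_path):
            states[run.key] = CHANGED
        else:
            states[run.key] = READY
    return states


def status_summary(graph, destination_path):
    """(Counter state -> count, table rows).  Rows are ordered topologically
    by step, then lexicographically by run id, so output is bit-stable."""
    states = all_states(graph, destination_path)
    rows = [
        (run.step_id, run.run_id, states[run.key], run.hash_short)
        for run in graph.runs_in_order()
    ]
    return Counter(states.values()), rows


def schedulable_runs(graph, destination_path):
    """Runs that an execution pass would start now, in deterministic
    topological order: exactly those ready, changed, or failed (retry) whose
    dependencies are all finished or volatilized.  Descendants of failed or
    changed runs are excluded — downstream work halts until the problem run
    is re-executed successfully."""
    states = all_states(graph, destination_path)
    out = []
    for run in graph.runs_in_order():
        if states[run.key] not in (READY, CHANGED, FAILED):
            continue
        if all(states[d.key] in _SATISFIED for d in graph.dependency_runs(run)):
            out.append(run)
    return out


def volatilize(run, graph, destination_path) -> int:
    """Replace the finished run's output files by checksum placeholders.

    Frees disk space without breaking the DAG: downstream finished runs stay
    finished, and the run itself reports state ``volatilized``.  Refused
    unless the run is finished and every consumer of its outputs is finished
    (or itself volatilized); source runs are refused because their files are
    the workflow's primary inputs.  Returns the number of files replaced.
    """
    if run.is_source:
        raise VolatilizeRefusedError(
            f"{run.step_id}/{run.run_id}: source runs emit primary inputs and "
            f"cannot be volatilized"
        )
    state = run_state(run, graph, destination_path)
    if state == VOLATILIZED:
        return 0
    if state != FINISHED:
        raise VolatilizeRefusedError(
            f"{run.step_id}/{run.run_id} is {state}, not finished"
        )
    for consumer in graph.consumers_of(run):
        cstate = run_state(consumer, graph, destination_path)
        if cstate not in _SATISFIED:
            raise VolatilizeRefusedError(
                f"consumer {consumer.step_id}/{consumer.run_id} is {cstate}; "
                f"volatilization would strand it"
            )

    import yaml

    directory = output_dir(run, run.fingerprint, destination_path)
    ann = read_annotation(directory)
    replaced = 0
    stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
    for name in run.output_names():
        path = os.path.join(directory, name)
        if not os.path.isfile(path):
            continue
        recorded = (ann.output_files.get(name) if ann else None) or {}
        placeholder = {
            "original_filename": name,
            "sha256": recorded.get("sha256") or file_checksum(path),
            "size_bytes": recorded.get("size_bytes", os.path.getsize(path)),
            "volatilized_at": stamp,
        }
        with open(path + VOLATILE_SUFFIX, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(placeholder, fh, sort_keys=True)
        os.remove(path)
        replaced += 1
    return replaced
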