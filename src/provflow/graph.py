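"""Workflow DAG: steps, connections, runs, deterministic traversal.

The DAG has *steps* as nodes and *connections* as edges.  A step is a
blueprint; a *run* is its atomic executable instance for one set of inputs
(typically one sample).  Runs are declared in topological order so that each
run can embed the fingerprints of its upstream runs — this is what chains
hashes through the graph and makes any upstream change propagate into every
downstream output path.

Path tokens.  Run inputs and command arguments never contain absolute
paths.  A path is one of:

* ``dest://<step>/<run>-<hash16>/<file>`` — relative to the results tree;
* ``src://<relpath>`` — relative to the configuration file's directory;
* an absolute path (only when the user configured one).

Fingerprints therefore survive relocation of the results tree unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .config import WorkflowConfig
from .errors import (
    ConnectionMismatchError,
    CycleError,
    MergeMismatchError,
)
from .steps_library import REGISTRY, SOURCE, StepDefinition, StepRegistry

DEST_TOKEN = "dest://"
SRC_TOKEN = "src://"

#: run identifier of a collect-mode run (it aggregates all upstream runs)
COLLECT_RUN_ID = "all"


@dataclass(frozen=True)
class Step:
    step_id: str
    kind: str
    in_connections: tuple
    out_connections: tuple
    tools: tuple
    depends: tuple
    params: dict
    environment: dict
    definition: StepDefinition


@dataclass(frozen=True)
class Connection:
    producer: tuple  # (step_id, out_connection)
    consumer: tuple  # (step_id, in_connection)


@dataclass
class Run:
    """Atomic unit of the analysis: one step instance with fixed inputs,
    commands and planned outputs.  ``fingerprint`` is attached immediately
    after declaration (see :mod:`provflow.provenance`)."""

    step_id: str
    run_id: str
    kind: str
    inputs: dict = field(default_factory=dict)   # in_conn -> [(up_hash, path)]
    source_files: tuple = ()                     # source runs: config-literal paths
    commands: tuple = ()                         # ordered CommandGroups
    planned_outputs: dict = field(default_factory=dict)  # out_conn -> [names]
    params: dict = field(default_factory=dict)
    environment: dict = field(default_factory=dict)
    step_version: int = 1
    fingerprint: Optional[object] = None         # RunFingerprint

    @property
    def key(self):
        return (self.step_id, self.run_id)

    @property
    def hash_full(self):
        return self.fingerprint.hash_full

    @property
    def hash_short(self):
        return self.fingerprint.hash_short

    @property
    def is_source(self):
        return self.kind == SOURCE

    def output_names(self):
        """Staging-relative planned output filenames (processing runs only)."""
        names = []
        for conn in sorted(self.planned_outputs):
            names.extend(self.planned_outputs[conn])
        return names

    def dep_hashes(self):
        return sorted({h for entries in self.inputs.values() for h, _ in entries})


@dataclass
class WorkflowGraph:
    config: WorkflowConfig
    steps: dict                      # step_id -> Step
    connections: list                # [Connection]
    runs: dict = field(default_factory=dict)   # (step_id, run_id) -> Run
    _order: tuple = ()

    @property
    def destination(self) -> str:
        return self.config.resolved_destination()

    def step_order(self):
        return list(self._order)

    def runs_in_order(self):
        """All runs, topological by step then lexicographic by run_id."""
        out = []
        for sid in self._order:
            for rid in sorted(r for s, r in self.runs if s == sid):
                out.append(self.runs[(sid, rid)])
        return out

    def run_by_hash(self, hash_full):
        for run in self.runs.values():
            if run.hash_full == hash_full:
                return run
        return None

    def dependency_runs(self, run: Run):
        by_hash = {r.hash_full: r for r in self.runs.values()}
        return [by_hash[h] for h in run.dep_hashes()]

    def consumers_of(self, run: Run):
        return [
            r for r in self.runs.values()
            if run.hash_full in {h for es in r.inputs.values() for h, _ in es}
        ]

    def resolve_path(self, path: str) -> str:
        """Token path -> absolute filesystem path."""
        import os
        if path.startswith(DEST_TOKEN):
            return os.path.join(self.destination, path[len(DEST_TOKEN):])
        if path.startswith(SRC_TOKEN):
            return os.path.join(self.config.config_dir, path[len(SRC_TOKEN):])
        return path


def _wire_connections(config: WorkflowConfig, steps: dict) -> list:
    """Resolve every in-connection of every processing step to its producers.

    Explicit ``_connect`` entries win; otherwise producers are auto-matched
    among dependencies by the trailing connection name ("in/reads" matches a
    dependency's "out/reads").  Strict (per-sample) steps require exactly one
    producer per in-connection; collect-mode steps may aggregate several.
    """
    connections = []
    for sid, step in steps.items():
        if step.kind == SOURCE:
            continue
        sc = config.steps[sid]
        for in_conn in step.in_connections:
            if in_conn in sc.connect:
                targets = []
                for tgt in sc.connect[in_conn]:
                    dep, _, out_conn = tgt.partition("/")
                    targets.append((dep, out_conn))
            else:
                tail = in_conn.split("/", 1)[-1]
                targets = [
                    (dep, f"out/{tail}")
                    for dep in step.depends
                    if f"out/{tail}" in steps[dep].out_connections
                ]
            if not targets:
                raise ConnectionMismatchError(
                    f"step {sid!r}: no producer found for {in_conn!r}"
                )
            if len(targets) > 1 and not step.definition.collect:
                raise ConnectionMismatchError(
                    f"step {sid!r}: {in_conn!r} is fed by multiple producers "
                    f"{sorted(t[0] for t in targets)}; only collect-mode steps "
                    f"accept more than one"
                )
            for dep, out_conn in targets:
                connections.append(
                    Connection(producer=(dep, out_conn), consumer=(sid, in_conn))
                )
    return connections


def topological_order(graph: WorkflowGraph):
    """Step ids, every step after all its dependencies; ties broken
    lexicographically so the order is bit-stable."""
    return list(graph._order)


def _compute_order(steps: dict) -> tuple:
    g = nx.DiGraph()
    g.add_nodes_from(steps)
    for sid, step in steps.items():
        for dep in step.depends:
            g.add_edge(dep, sid)
    if not nx.is_directed_acyclic_graph(g):
        cycle_edges = nx.find_cycle(g)
        raise CycleError([u for u, _v in cycle_edges])
    return tuple(nx.lexicographical_topological_sort(g))


def _connection_outputs(run: Run, out_conn: str):
    """(hash, token path) pairs a downstream run receives from *run*."""
    if run.is_source:
        paths = run.planned_outputs.get(out_conn, [])
        out = []
        import os
        for p in paths:
            out.append((run.hash_full, p if os.path.isabs(p) else SRC_TOKEN + p))
        return out
    base = f"{run.step_id}/{run.run_id}-{run.hash_short}"
    return [
        (run.hash_full, f"{DEST_TOKEN}{base}/{name}")
        for name in run.planned_outputs.get(out_conn, [])
    ]


def declare_runs(step: Step, producers: dict, graph: WorkflowGraph):
    """Declare the runs of *step* given its producers' already-declared runs.

    *producers* maps in_connection -> list of producing (step_id,
    out_connection) pairs.  Source steps yield one run per sample group.
    Strict processing steps yield one run per upstream run_id, matching
    run_ids across all in-connections (merge semantics); a run_id present on
    one side but absent on another raises :class:`MergeMismatchError`.
    Collect-mode steps yield a single run aggregating every upstream run,
    inputs ordered by (run_id, path).
    """
    defn = step.definition
    runs = []
    if step.kind == SOURCE:
        groups = defn.enumerate_source_runs(step.params, graph.config.config_dir)
        for run_id in sorted(groups):
            runs.append(Run(
                step_id=step.step_id, run_id=run_id, kind=SOURCE,
                source_files=tuple(groups[run_id]),
                planned_outputs={defn.out_connections[0]: list(groups[run_id])},
                params=dict(step.params), environment=dict(step.environment),
                step_version=defn.version,
            ))
        return runs

    upstream = {}  # in_conn -> {run_id: [(hash, path)]} or collect list
    for in_conn, prods in producers.items():
        per_id = {}
        for (dep, out_conn) in prods:
            for (sid, rid), up_run in graph.runs.items():
                if sid != dep:
                    continue
                per_id.setdefault(rid, []).extend(_connection_outputs(up_run, out_conn))
        upstream[in_conn] = per_id

    if defn.collect:
        inputs = {}
        for in_conn, per_id in upstream.items():
            flat = []
            for rid in sorted(per_id):
                flat.extend(sorted(per_id[rid], key=lambda e: e[1]))
            inputs[in_conn] = flat
        groups, planned = defn.build_commands(COLLECT_RUN_ID, inputs, step.params)
        runs.append(Run(
            step_id=step.step_id, run_id=COLLECT_RUN_ID, kind=step.kind,
            inputs=inputs, commands=tuple(groups), planned_outputs=planned,
            params=dict(step.params), environment=dict(step.environment),
            step_version=defn.version,
        ))
        return runs

    id_sets = {in_conn: set(per_id) for in_conn, per_id in upstream.items()}
    union = set().union(*id_sets.values()) if id_sets else set()
    for in_conn, ids in id_sets.items():
        missing = union - ids
        if missing:
            raise MergeMismatchError(
                f"step {step.step_id!r}: run ids {sorted(missing)} missing on "
                f"connection {in_conn!r}"
            )
    for run_id in sorted(union):
        inputs = {ic: sorted(upstream[ic][run_id], key=lambda e: e[1])
                  for ic in upstream}
        groups, planned = defn.build_commands(run_id, inputs, step.params)
        runs.append(Run(
            step_id=step.step_id, run_id=run_id, kind=step.kind,
            inputs=inputs, commands=tuple(groups), planned_outputs=planned,
            params=dict(step.params), environment=dict(step.environment),
            step_version=defn.version,
        ))
    return runs


def build_graph(config: WorkflowConfig, registry: StepRegistry = REGISTRY) -> WorkflowGraph:
    """Construct the workflow DAG and declare (and fingerprint) every run.

    Order of checks is part of the failing-fast contract: connection wiring
    and the acyclicity test run before any run is declared, so a cyclic or
    mis-wired configuration aborts before source files are even probed.
    """
    from .provenance import fingerprint_run

    steps = {}
    for sid, sc in config.steps.items():
        defn = registry.lookup(sc.step_type)
        steps[sid] = Step(
            step_id=sid, kind=defn.kind,
            in_connections=defn.in_connections,
            out_connections=defn.out_connections,
            tools=defn.tools, depends=sc.depends,
            params=dict(sc.params), environment=dict(sc.environment),
            definition=defn,
        )

    connections = _wire_connections(config, steps)
    order = _compute_order(steps)
    graph = WorkflowGraph(config=config, steps=steps, connections=connections,
                          _order=order)

    producers_by_step = {}
    for conn in connections:
        sid, in_conn = conn.consumer
        producers_by_step.setdefault(sid, {}).setdefault(in_conn, []).append(conn.producer)

    for sid in order:
        for run in declare_runs(steps[sid], producers_by_step.get(sid, {}), graph):
            run.fingerprint = fingerprint_run(run)
            graph.runs[run.key] = run
    return graph


def render_dot(graph: WorkflowGraph, states: Optional[dict] = None) -> str:
    """Graphviz DOT text for the step DAG; byte-stable for a fixed graph.

    *states*, when given, maps (step_id, run_id) -> state name; each step
    node is then annotated with its per-state run counts.
    """
    lines = ["digraph workflow {", "  rankdir=TB;", '  node [shape=box, fontname="Helvetica"];']
    for sid in sorted(graph.steps):
        step = graph.steps[sid]
        label = f"{sid}\\n({step.definition.type_name})"
        attrs = ""
        if states is not None:
            counts = {}
            for (s, _r), st in states.items():
                if s == sid:
                    counts[st] = counts.get(st, 0) + 1
            summary = " ".join(f"{k}:{v}" for k, v in sorted(counts.items()))
            label += f"\\n[{summary}]"
            if counts and set(counts) == {"finished"}:
                attrs = ', style=filled, fillcolor="palegreen"'
            elif "failed" in counts:
                attrs = ', style=filled, fillcolor="lightcoral"'
        lines.append(f'  "{sid}" [label="{label}"{attrs}];')
    seen = set()
    for conn in graph.connections:
        (prod, out_conn), (cons, in_conn) = conn.producer, conn.consumer
        edge = (prod, cons, out_conn, in_conn)
        if edge in seen:
            continue
        seen.add(edge)
    for prod, cons, out_conn, in_conn in sorted(seen):
        lines.append(f'  "{prod}" -> "{cons}" [label="{out_conn} > {in_conn}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
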