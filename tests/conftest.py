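import os

import pytest
import yaml

from provflow import build_graph, execute_workflow, parse_config_file, template_workflow
from provflow.steps_library import (
    PROCESSING,
    SOURCE,
    CommandGroup,
    NATIVE_TOOL,
    StepDefinition,
    default_registry,
)


@pytest.fixture
def workspace(tmp_path):
    """Factory: materialize a template workflow, return (config_path, graph)."""

    def make(name="chain", seed=42, subdir=None):
        d = tmp_path / (subdir or name)
        cfg = template_workflow(name, str(d), seed=seed)
        return cfg, build_graph(parse_config_file(cfg))

    return make


@pytest.fixture
def completed_chain(workspace):
    cfg, graph = workspace("chain")
    summary = execute_workflow(graph, graph.destination)
    assert summary.failed == 0
    return cfg, graph


def edit_config(config_path, mutate):
    """Load, mutate in place, and rewrite a workflow config file."""
    with open(config_path) as fh:
        doc = yaml.safe_load(fh)
    mutate(doc)
    with open(config_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return config_path


def reload_graph(config_path):
    return build_graph(parse_config_file(config_path))


# ---------------------------------------------------------------------------
# Minimal step types for graph-shape tests (no files, no commands needed)
# ---------------------------------------------------------------------------

def _null_source_runs(params, config_dir):
    return {rid: [] for rid in (params.get("run_ids") or ["s1"])}


def _gather_commands(run_id, inputs, params):
    out = f"{run_id}.dat"
    argv = [NATIVE_TOOL, "concat", "--out", out]
    argv += [p for _h, p in inputs["in/data"]]
    return [CommandGroup(argvs=(tuple(argv),))], {"out/data": [out]}


def _pair_commands(run_id, inputs, params):
    out = f"{run_id}.dat"
    paths = [p for _h, p in inputs["in/a"]] + [p for _h, p in inputs["in/b"]]
    argv = [NATIVE_TOOL, "concat", "--out", out] + paths
    return [CommandGroup(argvs=(tuple(argv),))], {"out/data": [out]}


def make_test_registry():
    """Built-ins plus shape-testing steps:

    * ``null_source``: source emitting configurable run ids with no files;
    * ``gather``: collect-mode relay, accepts any number of producers;
    * ``pair``: strict two-input step (exercises merge-by-run_id semantics).
    """
    reg = default_registry()
    reg.register(StepDefinition(
        type_name="null_source", kind=SOURCE, out_connections=("out/data",),
        param_defaults={"run_ids": ["s1"]},
        enumerate_source_runs=_null_source_runs,
    ))
    reg.register(StepDefinition(
        type_name="gather", kind=PROCESSING, in_connections=("in/data",),
        out_connections=("out/data",), tools=(NATIVE_TOOL,), collect=True,
        param_defaults={"_fail_mode": "none", "_delay": 0},
        build_commands=_gather_commands,
    ))
    reg.register(StepDefinition(
        type_name="pair", kind=PROCESSING, in_connections=("in/a", "in/b"),
        out_connections=("out/data",), tools=(NATIVE_TOOL,),
        param_defaults={"_fail_mode": "none", "_delay": 0},
        build_commands=_pair_commands,
    ))
    return reg


def digraph_config(edges, n_nodes):
    """Workflow config text realizing an arbitrary digraph on n nodes.

    Nodes without in-edges become ``null_source`` steps; the rest become
    collect-mode ``gather`` steps depending on their in-neighbours.
    """
    names = [f"n{i}" for i in range(n_nodes)]
    steps = {}
    for i, name in enumerate(names):
        deps = sorted({names[a] for (a, b) in edges if b == i})
        if deps:
            steps[name] = {"_type": "gather", "_depends": deps}
        else:
            steps[name] = {"_type": "null_source"}
    return yaml.safe_dump(
        {"destination_path": "results", "steps": steps}, sort_keys=False
    )


def normalize_annotation(doc, roots=()):
    """Strip run-to-run-varying fields (timestamps, resource readings) and
    replace workspace roots, so provenance records from equivalent
    executions compare equal."""
    def scrub(v):
        if isinstance(v, str):
            for root in roots:
                v = v.replace(root, "<ROOT>")
            return v
        if isinstance(v, list):
            return [scrub(x) for x in v]
        if isinstance(v, dict):
            return {k: scrub(x) for k, x in v.items()}
        return v

    doc = scrub(dict(doc))
    doc.pop("started", None)
    doc.pop("ended", None)
    for proc in doc.get("processes", []):
        proc.pop("cpu_seconds", None)
        proc.pop("peak_rss_bytes", None)
    return doc


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def tree_snapshot(dest, roots=()):
    """Map of every file under *dest* (excluding temp/) to comparable
    content: normalized YAML for annotations/placeholders, raw bytes
    otherwise."""
    snap = {}
    for base, dirs, files in os.walk(dest):
        dirs[:] = [d for d in dirs if not (base == dest and d == "temp")]
        for f in sorted(files):
            full = os.path.join(base, f)
            rel = os.path.relpath(full, dest)
            if f.endswith(".yaml"):
                snap[rel] = normalize_annotation(read_yaml(full), roots=roots)
                snap[rel].pop("volatilized_at", None)
            else:
                with open(full, "rb") as fh:
                    snap[rel] = fh.read()
    return snap
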