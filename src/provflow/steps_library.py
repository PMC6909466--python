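"""Step plug-in architecture and the built-in desk-scale steps.

A *step definition* is the blueprint for one analysis stage: it declares the
step kind (source or processing), its named in/out connections, the tools it
needs, a fully-defaulted parameter schema, and the procedure that turns
concrete inputs into executable commands and planned output files.  The
engine never knows what a step computes; it only schedules, hashes and
monitors what the definition declares.

The built-in steps are self-contained (they run through the engine's own
``native`` tool, i.e. a python subprocess), so whole workflows execute with
no external binaries:

``fastq_source``
    emits existing FASTQ files into the workflow, grouped into samples.
``count_reads``
    counts FASTQ records across the input files of a run.
``trim_adapter``
    clips 3' adapter read-through by exact suffix-prefix overlap.
``merge_files``
    concatenates all upstream files of a connection (collect mode).

Processing steps additionally accept two test-support parameters,
``_fail_mode`` ("none" | "exit" | "missing_output") and ``_delay`` (seconds),
which let failure-injection and interruption scenarios run through the
ordinary configuration path; both participate in the run fingerprint like
any other parameter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

from .errors import (
    ConfigError,
    DuplicateStepError,
    FileMissingError,
    MalformedFastqError,
    UnknownStepError,
)

SOURCE = "source"
PROCESSING = "processing"

#: tool name every built-in step uses; resolves to ``python -m provflow.native``
NATIVE_TOOL = "native"

_COMMON_PROCESSING_PARAMS = {"_fail_mode": "none", "_delay": 0}


@dataclass(frozen=True)
class CommandGroup:
    """An ordered pipe of argv lists: stdout of each feeds stdin of the next.

    ``argvs[i][0]`` is always a *tool name*, resolved to an executable by the
    executor.  ``stdout_to``, when set, redirects the final process's stdout
    into that staging-relative file.
    """

    argvs: tuple
    stdout_to: Optional[str] = None

    def to_payload(self):
        return {
            "argvs": [list(a) for a in self.argvs],
            "stdout_to": self.stdout_to,
        }


@dataclass(frozen=True)
class StepDefinition:
    """Declares one step type: connections, tools, params, run construction."""

    type_name: str
    kind: str
    in_connections: tuple = ()
    out_connections: tuple = ()
    tools: tuple = ()
    param_defaults: Mapping[str, object] = field(default_factory=dict)
    required_params: tuple = ()
    #: collect-mode processing steps receive ALL upstream runs as one run
    collect: bool = False
    #: version tag of the definition; part of the run fingerprint
    version: int = 1
    #: source steps: params, config_dir -> ordered {run_id: [file paths]}
    enumerate_source_runs: Optional[Callable] = None
    #: processing steps: (run_id, inputs, params) ->
    #:   (command_groups, {out_connection: [staging-relative names]})
    build_commands: Optional[Callable] = None
    #: optional params validator, called at parse time (failing fast)
    validate_params: Optional[Callable] = None

    def __post_init__(self):
        if self.kind not in (SOURCE, PROCESSING):
            raise ConfigError(f"step kind must be source|processing, got {self.kind!r}")
        if self.kind == SOURCE and self.in_connections:
            raise ConfigError("source steps declare no in-connections")
        if self.kind == PROCESSING and not self.in_connections:
            raise ConfigError("processing steps declare at least one in-connection")


class StepRegistry:
    """Name -> StepDefinition lookup; registration is append-only."""

    def __init__(self):
        self._defs: dict[str, StepDefinition] = {}

    def register(self, definition: StepDefinition) -> StepDefinition:
        if definition.type_name in self._defs:
            raise DuplicateStepError(
                f"step type {definition.type_name!r} already registered"
            )
        self._defs[definition.type_name] = definition
        return definition

    def lookup(self, type_name: str) -> StepDefinition:
        try:
            return self._defs[type_name]
        except KeyError:
            raise UnknownStepError(f"unknown step type {type_name!r}") from None

    def __contains__(self, type_name):
        return type_name in self._defs

    def type_names(self):
        return sorted(self._defs)

    def copy(self) -> "StepRegistry":
        clone = StepRegistry()
        clone._defs = dict(self._defs)
        return clone


# ---------------------------------------------------------------------------
# FASTQ primitives (used in-process and by the native subprocess runner)
# ---------------------------------------------------------------------------

def iter_fastq_records(path):
    """Yield (title, sequence, quality) from a 4-line-record FASTQ file.

    Raises :class:`MalformedFastqError` on a line count not divisible by 4,
    a record not starting with '@' / '+', or quality length differing from
    sequence length.  Quality strings are treated as opaque bytes of checked
    length; no encoding is interpreted.
    """
    with open(path, "rt", encoding="ascii") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise MalformedFastqError(
            f"{path}: {len(lines)} lines is not a multiple of 4"
        )
    for i in range(0, len(lines), 4):
        title, seq, plus, qual = lines[i : i + 4]
        if not title.startswith("@"):
            raise MalformedFastqError(f"{path}: record {i // 4} title lacks '@'")
        if not plus.startswith("+"):
            raise MalformedFastqError(f"{path}: record {i // 4} separator lacks '+'")
        if len(qual) != len(seq):
            raise MalformedFastqError(
                f"{path}: record {i // 4} quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        yield title, seq, qual


def count_fastq_records(paths: Sequence[str]) -> int:
    """Total number of FASTQ records across *paths* (validating each file)."""
    return sum(sum(1 for _ in iter_fastq_records(p)) for p in paths)


def find_clip_position(seq: str, adapter: str, min_overlap: int) -> Optional[int]:
    """3' adapter clip position for *seq*, or None if no match.

    Rule: if the full adapter occurs as a substring, clip at its leftmost
    occurrence; otherwise clip at the smallest position p (i.e. the longest
    read suffix) such that ``seq[p:]`` equals a prefix of the adapter of
    length >= *min_overlap*.  Exact matching only — no mismatches allowed.
    """
    full = seq.find(adapter)
    if full != -1:
        return full
    for p in range(max(0, len(seq) - len(adapter) + 1), len(seq)):
        k = len(seq) - p
        if k < min_overlap:
            break
        if seq[p:] == adapter[:k]:
            return p
    return None


def trim_fastq(in_paths, out_path, adapter, min_overlap=3, min_length=1):
    """Clip adapter read-through from every read; drop reads shorter than
    *min_length* after clipping.  Returns the number of dropped reads.

    Input order is preserved; qualities are clipped in step with sequences.
    """
    dropped = 0
    with open(out_path, "wt", encoding="ascii") as out:
        for path in in_paths:
            for title, seq, qual in iter_fastq_records(path):
                p = find_clip_position(seq, adapter, min_overlap)
                if p is not None:
                    seq, qual = seq[:p], qual[:p]
                if len(seq) < min_length:
                    dropped += 1
                    continue
                out.write(f"{title}\n{seq}\n+\n{qual}\n")
    return dropped


# ---------------------------------------------------------------------------
# Built-in step definitions
# ---------------------------------------------------------------------------

def _common_flags(params):
    flags = []
    if params.get("_delay", 0):
        flags += ["--delay", str(params["_delay"])]
    if params.get("_fail_mode", "none") == "exit":
        flags += ["--fail-exit", "1"]
    elif params.get("_fail_mode") == "missing_output":
        flags += ["--skip-output"]
    return flags


def _fastq_source_runs(params, config_dir):
    samples = params.get("samples") or {}
    if not isinstance(samples, dict) or not samples:
        raise ConfigError("fastq_source requires a non-empty 'samples' map")
    runs = {}
    for sample in sorted(samples):
        files = samples[sample]
        if not isinstance(files, list) or not files:
            raise ConfigError(f"sample {sample!r}: file list must be non-empty")
        for f in files:
            resolved = f if os.path.isabs(f) else os.path.join(config_dir, f)
            if not os.path.isfile(resolved):
                raise FileMissingError(f"sample {sample!r}: no such file: {f}")
        runs[sample] = list(files)
    return runs


def _count_reads_commands(run_id, inputs, params):
    out = f"{run_id}.count.txt"
    argv = [NATIVE_TOOL, "count-reads", "--out", out]
    argv += _common_flags(params)
    argv += [path for _hash, path in inputs["in/reads"]]
    return [CommandGroup(argvs=(tuple(argv),))], {"out/counts": [out]}


def _validate_adapter(params):
    adapter = params.get("adapter")
    if not adapter or not isinstance(adapter, str):
        raise ConfigError("trim_adapter: 'adapter' must be a non-empty sequence")
    bad = set(adapter) - set("ACGT")
    if bad:
        raise ConfigError(
            f"trim_adapter: adapter contains invalid characters {sorted(bad)!r}"
        )
    if int(params.get("min_overlap", 3)) < 1 or int(params.get("min_length", 1)) < 0:
        raise ConfigError("trim_adapter: min_overlap >= 1 and min_length >= 0 required")


def _trim_adapter_commands(run_id, inputs, params):
    trimmed = f"{run_id}.trimmed.fastq"
    disc = f"{run_id}.discarded.txt"
    argv = [
        NATIVE_TOOL, "trim-adapter",
        "--adapter", params["adapter"],
        "--min-overlap", str(params["min_overlap"]),
        "--min-length", str(params["min_length"]),
        "--out-trimmed", trimmed,
        "--out-count", disc,
    ]
    argv += _common_flags(params)
    argv += [path for _hash, path in inputs["in/reads"]]
    return (
        [CommandGroup(argvs=(tuple(argv),))],
        {"out/trimmed": [trimmed], "out/discarded_count": [disc]},
    )


def _merge_files_commands(run_id, inputs, params):
    out = f"{run_id}.merged.dat"
    argv = [NATIVE_TOOL, "concat", "--out", out]
    argv += _common_flags(params)
    argv += [path for _hash, path in inputs["in/files"]]
    return [CommandGroup(argvs=(tuple(argv),))], {"out/merged": [out]}


def _builtin_definitions():
    yield StepDefinition(
        type_name="fastq_source",
        kind=SOURCE,
        out_connections=("out/reads",),
        param_defaults={"samples": {}},
        required_params=("samples",),
        enumerate_source_runs=_fastq_source_runs,
    )
    yield StepDefinition(
        type_name="count_reads",
        kind=PROCESSING,
        in_connections=("in/reads",),
        out_connections=("out/counts",),
        tools=(NATIVE_TOOL,),
        param_defaults=dict(_COMMON_PROCESSING_PARAMS),
        build_commands=_count_reads_commands,
    )
    yield StepDefinition(
        type_name="trim_adapter",
        kind=PROCESSING,
        in_connections=("in/reads",),
        out_connections=("out/trimmed", "out/discarded_count"),
        tools=(NATIVE_TOOL,),
        param_defaults={
            "adapter": None,
            "min_overlap": 3,
            "min_length": 1,
            **_COMMON_PROCESSING_PARAMS,
        },
        required_params=("adapter",),
        build_commands=_trim_adapter_commands,
        validate_params=_validate_adapter,
    )
    yield StepDefinition(
        type_name="merge_files",
        kind=PROCESSING,
        in_connections=("in/files",),
        out_connections=("out/merged",),
        tools=(NATIVE_TOOL,),
        collect=True,
        param_defaults=dict(_COMMON_PROCESSING_PARAMS),
        build_commands=_merge_files_commands,
    )


def default_registry() -> StepRegistry:
    """A fresh registry holding the built-in step definitions."""
    reg = StepRegistry()
    for d in _builtin_definitions():
        reg.register(d)
    return reg


# module-level registry used when callers pass none of their own
REGISTRY = default_registry()


def register_step(definition: StepDefinition, registry: StepRegistry = REGISTRY):
    return registry.register(definition)


def lookup_step(type_name: str, registry: StepRegistry = REGISTRY) -> StepDefinition:
    return registry.lookup(type_name)
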