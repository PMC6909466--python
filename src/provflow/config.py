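"""Workflow configuration: parsing, normalization, tool validation.

A workflow is completely described by one YAML document.  The schema is
frozen and small:

.. code-block:: yaml

    destination_path: results          # results tree root
    constants:                         # optional ${name} substitutions
      adapter: ACGTACGT
    tools:                             # optional; "native" is implicit
      wc:
        path: /usr/bin/wc
        version_command: [wc, --version]
        version_regex: '([0-9.]+)'
        expected_exit_code: 0
    steps:                             # ordered map step_id -> step block
      raw:
        _type: fastq_source
        samples: {s1: [data/s1.fastq]}
      trim:
        _type: trim_adapter
        _depends: [raw]
        _connect: {in/reads: raw/out/reads}
        adapter: ${adapter}

Per-step keys starting with ``_`` are structural (``_type``, ``_depends``,
``_connect``, ``_environment``); everything else is a parameter of the step
type.  Parsing merges each step's parameters over the registered defaults,
so the normalized configuration — and therefore every run fingerprint —
always carries the full effective parameter set, including defaults the user
never wrote down.
"""

from __future__ import annotations

import os
import re
import shutil
import subprocess
import sys
from dataclasses import dataclass, field
from typing import Optional

import yaml

from . import __version__
from .errors import (
    ConfigError,
    ParseError,
    UnknownDependencyError,
    UnknownToolError,
)
from .steps_library import REGISTRY, SOURCE, StepRegistry

_STRUCTURAL_KEYS = {"_type", "_depends", "_connect", "_environment"}
_CONST_RE = re.compile(r"\$\{([A-Za-z_][A-Za-z0-9_]*)\}")

#: implicit tool backing the built-in steps: the engine's own subprocess runner
NATIVE_TOOL_NAME = "native"


def engine_version_string() -> str:
    return f"provflow {__version__}"


@dataclass(frozen=True)
class ToolSpec:
    name: str
    path: str
    version_command: Optional[tuple] = None
    version_regex: Optional[str] = None
    expected_exit_code: int = 0

    def __post_init__(self):
        if not self.path:
            raise ConfigError(f"tool {self.name!r}: path must be non-empty")
        if self.path == "native" and self.version_command:
            raise ConfigError(f"tool {self.name!r}: native tools have no version_command")

    def to_dict(self):
        return {
            "path": self.path,
            "version_command": list(self.version_command) if self.version_command else None,
            "version_regex": self.version_regex,
            "expected_exit_code": self.expected_exit_code,
        }


@dataclass(frozen=True)
class StepConfig:
    step_id: str
    step_type: str
    depends: tuple = ()
    connect: dict = field(default_factory=dict)
    environment: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_dict(self):
        d = {"_type": self.step_type}
        if self.depends:
            d["_depends"] = list(self.depends)
        if self.connect:
            d["_connect"] = dict(self.connect)
        if self.environment:
            d["_environment"] = dict(self.environment)
        d.update(self.params)
        return d


@dataclass(frozen=True)
class WorkflowConfig:
    destination_path: str
    constants: dict
    tools: dict            # name -> ToolSpec
    steps: dict            # ordered step_id -> StepConfig
    config_dir: str = "."

    def resolved_destination(self) -> str:
        p = self.destination_path
        return p if os.path.isabs(p) else os.path.abspath(os.path.join(self.config_dir, p))

    def resolve_source_path(self, p: str) -> str:
        return p if os.path.isabs(p) else os.path.abspath(os.path.join(self.config_dir, p))

    def to_dict(self):
        d = {"destination_path": self.destination_path}
        if self.constants:
            d["constants"] = dict(self.constants)
        d["tools"] = {n: t.to_dict() for n, t in sorted(self.tools.items())}
        d["steps"] = {sid: sc.to_dict() for sid, sc in self.steps.items()}
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _interpolate(value, constants):
    if isinstance(value, str):
        def sub(m):
            name = m.group(1)
            if name not in constants:
                raise ConfigError(f"unknown constant ${{{name}}}")
            return str(constants[name])
        return _CONST_RE.sub(sub, value)
    if isinstance(value, list):
        return [_interpolate(v, constants) for v in value]
    if isinstance(value, dict):
        return {k: _interpolate(v, constants) for k, v in value.items()}
    return value


def _parse_tool(name, block):
    if not isinstance(block, dict):
        raise ParseError(f"tool {name!r}: expected a mapping")
    unknown = set(block) - {"path", "version_command", "version_regex", "expected_exit_code"}
    if unknown:
        raise ParseError(f"tool {name!r}: unknown keys {sorted(unknown)}")
    vc = block.get("version_command")
    return ToolSpec(
        name=name,
        path=str(block.get("path", "")),
        version_command=tuple(str(a) for a in vc) if vc else None,
        version_regex=block.get("version_regex"),
        expected_exit_code=int(block.get("expected_exit_code", 0)),
    )


def parse_config(
    yaml_text: str,
    registry: StepRegistry = REGISTRY,
    config_dir: str = ".",
) -> WorkflowConfig:
    """Parse YAML text into a normalized :class:`WorkflowConfig`.

    Normalization performed here, before anything is hashed:

    * every step's params are merged over the step type's declared defaults
      (so defaults are explicit in the normalized config);
    * ``${name}`` constants are substituted into parameter values;
    * structural references (step types, dependencies, connections, tools)
      are resolved and validated — failing fast, before any graph is built.
    """
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as e:
        raise ParseError(f"malformed YAML: {e}") from e
    if not isinstance(doc, dict):
        raise ParseError("top level of the configuration must be a mapping")
    unknown = set(doc) - {"destination_path", "constants", "tools", "steps"}
    if unknown:
        raise ParseError(f"unknown top-level keys {sorted(unknown)}")

    dest = doc.get("destination_path")
    if not dest or not isinstance(dest, str):
        raise ParseError("destination_path must be a non-empty string")
    constants = doc.get("constants") or {}
    if not isinstance(constants, dict):
        raise ParseError("constants must be a mapping")

    tools = {}
    for name, block in (doc.get("tools") or {}).items():
        tools[name] = _parse_tool(name, block)
    # the engine's own runner is always available
    tools.setdefault(NATIVE_TOOL_NAME, ToolSpec(name=NATIVE_TOOL_NAME, path="native"))

    steps_doc = doc.get("steps")
    if not isinstance(steps_doc, dict) or not steps_doc:
        raise ParseError("steps must be a non-empty mapping")

    steps: dict[str, StepConfig] = {}
    for step_id, block in steps_doc.items():
        if not isinstance(block, dict):
            raise ParseError(f"step {step_id!r}: expected a mapping")
        if "_type" not in block:
            raise ParseError(f"step {step_id!r}: missing _type")
        defn = registry.lookup(str(block["_type"]))

        depends = tuple(block.get("_depends") or ())
        for dep in depends:
            if dep not in steps_doc:
                raise UnknownDependencyError(
                    f"step {step_id!r} depends on unknown step {dep!r}"
                )
            if dep == step_id:
                raise UnknownDependencyError(f"step {step_id!r} depends on itself")
        if defn.kind == SOURCE and depends:
            raise ConfigError(f"source step {step_id!r} must not declare _depends")

        connect = {}
        for in_conn, targets in (block.get("_connect") or {}).items():
            if in_conn not in defn.in_connections:
                raise ConfigError(
                    f"step {step_id!r}: unknown in-connection {in_conn!r}"
                )
            targets = targets if isinstance(targets, list) else [targets]
            parsed = []
            for tgt in targets:
                dep, _, out_conn = str(tgt).partition("/")
                if dep not in depends:
                    raise UnknownDependencyError(
                        f"step {step_id!r}: connection target {tgt!r} names a "
                        f"step outside _depends"
                    )
                dep_defn = registry.lookup(str(steps_doc[dep]["_type"]))
                if out_conn not in dep_defn.out_connections:
                    raise ConfigError(
                        f"step {step_id!r}: {tgt!r} is not a declared "
                        f"out-connection of {dep!r}"
                    )
                parsed.append(tgt)
            connect[in_conn] = parsed

        for tool in defn.tools:
            if tool not in tools:
                raise UnknownToolError(
                    f"step {step_id!r} requires undeclared tool {tool!r}"
                )

        user_params = {k: v for k, v in block.items() if k not in _STRUCTURAL_KEYS}
        unknown_params = set(user_params) - set(defn.param_defaults)
        if unknown_params:
            raise ConfigError(
                f"step {step_id!r}: unknown parameters {sorted(unknown_params)}"
            )
        params = {**defn.param_defaults, **user_params}
        params = _interpolate(params, constants)
        for req in defn.required_params:
            if params.get(req) in (None, {}):
                raise ConfigError(f"step {step_id!r}: parameter {req!r} is required")
        if defn.validate_params is not None:
            defn.validate_params(params)

        environment = dict(block.get("_environment") or {})
        steps[step_id] = StepConfig(
            step_id=step_id,
            step_type=defn.type_name,
            depends=depends,
            connect=connect,
            environment=environment,
            params=params,
        )

    return WorkflowConfig(
        destination_path=dest,
        constants=dict(constants),
        tools=tools,
        steps=steps,
        config_dir=os.path.abspath(config_dir),
    )


def parse_config_file(path: str, registry: StepRegistry = REGISTRY) -> WorkflowConfig:
    with open(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    return parse_config(text, registry=registry, config_dir=os.path.dirname(os.path.abspath(path)))


# ---------------------------------------------------------------------------
# Tool validation (failing fast)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToolReportEntry:
    available: bool
    version_string: Optional[str] = None
    probe_exit: Optional[int] = None


def _probe_tool(spec: ToolSpec) -> ToolReportEntry:
    if spec.path == "native":
        return ToolReportEntry(available=True, version_string=engine_version_string())
    resolved = spec.path if os.path.sep in spec.path else shutil.which(spec.path)
    if not resolved or not (os.path.isfile(resolved) and os.access(resolved, os.X_OK)):
        return ToolReportEntry(available=False)
    if spec.version_command is None:
        return ToolReportEntry(available=True)
    try:
        proc = subprocess.run(
            list(spec.version_command),
            stdout=subprocess.PIPE,
            stderr=subprocess.STDOUT,
            timeout=30,
        )
    except (OSError, subprocess.TimeoutExpired):
        return ToolReportEntry(available=False)
    out = proc.stdout.decode("utf-8", "replace")
    version = None
    if spec.version_regex:
        m = re.search(spec.version_regex, out)
        if m:
            version = m.group(1) if m.groups() else m.group(0)
    if version is None:
        version = out.strip().splitlines()[0] if out.strip() else None
    if proc.returncode != spec.expected_exit_code:
        return ToolReportEntry(
            available=False, version_string=version, probe_exit=proc.returncode
        )
    return ToolReportEntry(
        available=True, version_string=version, probe_exit=proc.returncode
    )


def validate_tools(config: WorkflowConfig, registry: StepRegistry = REGISTRY) -> dict:
    """Probe every tool any configured step references (plus explicit extras).

    Probing runs version commands only — never an analysis command.
    Unavailability is reported, not raised; the caller decides to abort.
    """
    referenced = set()
    for sc in config.steps.values():
        referenced.update(registry.lookup(sc.step_type).tools)
    names = sorted(referenced | set(config.tools))
    report = {}
    for name in names:
        spec = config.tools.get(name)
        if spec is None:
            report[name] = ToolReportEntry(available=False)
        else:
            report[name] = _probe_tool(spec)
    return report
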