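"""Content-addressed provenance: run fingerprints, annotations, verification.

The engine links analysis code and results by hashing each run's complete
command-and-parameter specification and appending the digest to the run's
output path.  Any edit to a step's commands or parameters — or to anything
upstream, because upstream fingerprints are part of a run's inputs — moves
the expected output location, so stale results are immediately detectable
as *orphaned* directories.

Canonical serialization (format version ``pfv1``)
-------------------------------------------------
``canonical_bytes`` is the UTF-8 encoding of the line ``pfv1`` followed by
the compact, key-sorted JSON of this payload::

    {
      "step_id":       str,
      "run_id":        str,
      "step_version":  int,
      "params":        {name: scalar | list | map},   # effective, defaulted
      "commands":      [[{"argvs": [[str]], "stdout_to": str|null}]],
      "inputs":        [[upstream_hash, in_connection, path], ...]  # sorted
      "source_files":  [str],                          # config-literal paths
      "planned_outputs": {out_connection: [str]},
    }

``hash_full`` is the SHA-256 hex digest of ``canonical_bytes``;
``hash_short`` is its first 16 characters and appears in output paths.
The version tag is itself hashed, so a future format revision can never
silently alias an old digest.  Tool *versions* are recorded in annotations
but deliberately excluded from the fingerprint: re-probing an environment
must not invalidate results; version drift is surfaced by verification
instead.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import FileMissingError, SerializationError

SERIALIZATION_VERSION = "pfv1"
ANNOTATION_FILENAME = ".annotation.yaml"
VOLATILE_SUFFIX = ".volatile.yaml"
FAILED_SENTINEL = "FAILED"
HASH_SHORT_LEN = 16


@dataclass(frozen=True)
class RunFingerprint:
    canonical_bytes: bytes
    hash_full: str
    hash_short: str


def _check_jsonable(value, where):
    if value is None or isinstance(value, (str, int, float, bool)):
        return
    if isinstance(value, (list, tuple)):
        for v in value:
            _check_jsonable(v, where)
        return
    if isinstance(value, dict):
        for k, v in value.items():
            if not isinstance(k, str):
                raise SerializationError(f"{where}: non-string key {k!r}")
            _check_jsonable(v, where)
        return
    raise SerializationError(f"{where}: value {value!r} is not serializable")


def canonical_bytes_for(run) -> bytes:
    _check_jsonable(run.params, f"run {run.step_id}/{run.run_id} params")
    payload = {
        "step_id": run.step_id,
        "run_id": run.run_id,
        "step_version": run.step_version,
        "params": run.params,
        "commands": [g.to_payload() for g in run.commands],
        "inputs": sorted(
            [h, conn, path]
            for conn, entries in run.inputs.items()
            for h, path in entries
        ),
        "source_files": sorted(run.source_files),
        "planned_outputs": {c: list(ns) for c, ns in sorted(run.planned_outputs.items())},
    }
    body = json.dumps(payload, sort_keys=True, separators=(",", ":"), ensure_ascii=True)
    return (SERIALIZATION_VERSION + "\n" + body).encode("utf-8")


def fingerprint_run(run) -> RunFingerprint:
    """Fingerprint of a fully declared run.

    Deterministic; depends on upstream content only through upstream run
    hashes (change propagation is transitive and O(1) per run); independent
    of absolute filesystem locations and wall-clock time.
    """
    cb = canonical_bytes_for(run)
    full = hashlib.sha256(cb).hexdigest()
    return RunFingerprint(canonical_bytes=cb, hash_full=full,
                          hash_short=full[:HASH_SHORT_LEN])


def output_dir(run, fingerprint: RunFingerprint, destination_path: str) -> str:
    """Final content-addressed directory: <dest>/<step>/<run_id>-<hash16>."""
    return os.path.join(destination_path, run.step_id,
                        f"{run.run_id}-{fingerprint.hash_short}")


def staging_dir(run, destination_path: str) -> str:
    """Temp working directory; same filesystem as the final location so the
    promoting rename is atomic."""
    return os.path.join(destination_path, "temp",
                        f"{run.step_id}-{run.run_id}-{run.hash_short}")


def file_checksum(path: str) -> str:
    """Lower-case hex SHA-256 of the file's bytes."""
    if not os.path.isfile(path):
        raise FileMissingError(f"no such file: {path}")
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationRecord:
    """Per-run provenance document, stored next to the run's result files."""

    engine_version: str
    step_id: str
    run_id: str
    fingerprint: str
    config_snapshot: dict
    tool_versions: dict
    commands: list                      # argv-exact, as executed
    started: str
    ended: str
    processes: list = field(default_factory=list)
    output_files: dict = field(default_factory=dict)  # path -> {sha256, size_bytes}
    outcome: str = "success"

    def to_dict(self):
        return {
            "engine_version": self.engine_version,
            "step_id": self.step_id,
            "run_id": self.run_id,
            "fingerprint": self.fingerprint,
            "config": self.config_snapshot,
            "tool_versions": dict(sorted(self.tool_versions.items())),
            "commands": self.commands,
            "started": self.started,
            "ended": self.ended,
            "processes": self.processes,
            "output_files": {p: dict(v) for p, v in sorted(self.output_files.items())},
            "outcome": self.outcome,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            engine_version=d["engine_version"], step_id=d["step_id"],
            run_id=d["run_id"], fingerprint=d["fingerprint"],
            config_snapshot=d["config"], tool_versions=d["tool_versions"],
            commands=d["commands"], started=d["started"], ended=d["ended"],
            processes=d.get("processes", []),
            output_files=d.get("output_files", {}),
            outcome=d.get("outcome", "success"),
        )


def write_annotation(record: AnnotationRecord, directory: str) -> str:
    path = os.path.join(directory, ANNOTATION_FILENAME)
    with open(path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(record.to_dict(), fh, sort_keys=True)
    return path


def read_annotation(directory: str) -> Optional[AnnotationRecord]:
    path = os.path.join(directory, ANNOTATION_FILENAME)
    if not os.path.isfile(path):
        return None
    try:
        with open(path, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return AnnotationRecord.from_dict(doc)
    except (yaml.YAMLError, KeyError, TypeError):
        return None


def read_placeholder(path: str) -> Optional[dict]:
    """Parse a volatilization placeholder file, or None if it is not one."""
    if not path.endswith(VOLATILE_SUFFIX) or not os.path.isfile(path):
        return None
    try:
        with open(path, "rt", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError:
        return None
    if isinstance(doc, dict) and {"original_filename", "sha256", "size_bytes"} <= set(doc):
        return doc
    return None


# ---------------------------------------------------------------------------
# Tree verification
# ---------------------------------------------------------------------------

CONSISTENT = "consistent"
CHECKSUM_MISMATCH = "checksum_mismatch"
MISSING_FILE = "missing_file"
ORPHANED = "orphaned"
ABSENT = "absent"


@dataclass
class VerificationReport:
    #: (step_id, run_id) -> consistent | checksum_mismatch | missing_file | absent
    entries: dict = field(default_factory=dict)
    #: destination-relative directories matching no current fingerprint
    orphaned: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        bad = {CHECKSUM_MISMATCH, MISSING_FILE}
        return not self.orphaned and not bad & set(self.entries.values())


def _verify_run_dir(run, directory) -> str:
    ann = read_annotation(directory)
    if ann is None or ann.fingerprint != run.hash_full:
        return CHECKSUM_MISMATCH
    listed = set(ann.output_files)
    for name in sorted(os.listdir(directory)):
        if name == ANNOTATION_FILENAME:
            continue
        if name.endswith(VOLATILE_SUFFIX):
            ph = read_placeholder(os.path.join(directory, name))
            orig = name[: -len(VOLATILE_SUFFIX)]
            if ph is None or orig not in listed:
                return CHECKSUM_MISMATCH
            if ph["sha256"] != ann.output_files[orig]["sha256"]:
                return CHECKSUM_MISMATCH
            listed.discard(orig)
            continue
        if name not in listed:
            return CHECKSUM_MISMATCH  # unexpected unlisted file
        if file_checksum(os.path.join(directory, name)) != ann.output_files[name]["sha256"]:
            return CHECKSUM_MISMATCH
        listed.discard(name)
    # entries still listed were never seen in the directory
    missing = [
        n for n in listed
        if not os.path.isabs(n) and not os.path.exists(os.path.join(directory, n))
    ]
    if missing:
        return MISSING_FILE
    return CONSISTENT


def verify_tree(destination_path: str, graph) -> VerificationReport:
    """Check consistency between the current workflow and the results tree.

    A result directory whose hash suffix matches no current run fingerprint
    is *orphaned* (the analysis changed after it was produced).  A matching
    directory whose files disagree with its annotation's checksums is a
    *checksum_mismatch*; a planned output with neither file nor placeholder
    is *missing_file*.  Findings are reported, never auto-deleted.
    """
    report = VerificationReport()
    current = {}
    for run in graph.runs_in_order():
        current[(run.step_id, f"{run.run_id}-{run.hash_short}")] = run

    known_steps = set(graph.steps)
    if os.path.isdir(destination_path):
        for step_dir in sorted(os.listdir(destination_path)):
            if step_dir == "temp" or not os.path.isdir(os.path.join(destination_path, step_dir)):
                continue
            for run_dir in sorted(os.listdir(os.path.join(destination_path, step_dir))):
                full = os.path.join(destination_path, step_dir, run_dir)
                if not os.path.isdir(full):
                    continue
                if step_dir not in known_steps or (step_dir, run_dir) not in current:
                    report.orphaned.append(f"{step_dir}/{run_dir}")

    for run in graph.runs_in_order():
        directory = output_dir(run, run.fingerprint, destination_path)
        if not os.path.isdir(directory):
            report.entries[run.key] = ABSENT
            continue
        if run.is_source:
            ann = read_annotation(directory)
            ok = ann is not None and ann.fingerprint == run.hash_full
            report.entries[run.key] = CONSISTENT if ok else CHECKSUM_MISMATCH
            continue
        report.entries[run.key] = _verify_run_dir(run, directory)
    return report
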