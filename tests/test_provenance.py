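import hashlib
import json
import os
import shutil

import pytest
import yaml

from conftest import edit_config, reload_graph
from provflow import (
    build_graph,
    execute_workflow,
    file_checksum,
    fingerprint_run,
    output_dir,
    parse_config,
    parse_config_file,
    verify_tree,
)
from provflow.errors import FileMissingError, SerializationError
from provflow.fixtures import Lcg
from provflow.graph import Run
from provflow.provenance import (
    ABSENT,
    CHECKSUM_MISMATCH,
    CONSISTENT,
    read_annotation,
)
from provflow.steps_library import PROCESSING, CommandGroup


def toy_run(**overrides):
    kwargs = dict(
        step_id="trim",
        run_id="s1",
        kind=PROCESSING,
        inputs={"in/reads": [("ab" * 32, "src://data/s1.fastq")]},
        commands=(CommandGroup(argvs=(("native", "count-reads", "--out", "s1.txt"),)),),
        planned_outputs={"out/counts": ["s1.txt"]},
        params={"min_overlap": 3, "adapter": "ACGT"},
        step_version=1,
    )
    kwargs.update(overrides)
    return Run(**kwargs)


def test_identical_runs_hash_identically():
    assert fingerprint_run(toy_run()).hash_full == fingerprint_run(toy_run()).hash_full


def test_any_single_field_change_changes_the_hash():
    base = fingerprint_run(toy_run()).hash_full
    variants = [
        toy_run(params={"min_overlap": 4, "adapter": "ACGT"}),
        toy_run(run_id="s2"),
        toy_run(inputs={"in/reads": [("cd" * 32, "src://data/s1.fastq")]}),
        toy_run(planned_outputs={"out/counts": ["other.txt"]}),
        toy_run(step_version=2),
    ]
    hashes = {base} | {fingerprint_run(v).hash_full for v in variants}
    assert len(hashes) == 6  # all pairwise distinct


def test_toy_run_hash_matches_independent_sha256_of_frozen_serialization():
    """Oracle: reconstruct the documented pfv1 canonical form with json +
    hashlib only, without touching the engine's serializer."""
    run = toy_run()
    payload = {
        "step_id": "trim",
        "run_id": "s1",
        "step_version": 1,
        "params": {"min_overlap": 3, "adapter": "ACGT"},
        "commands": [{"argvs": [["native", "count-reads", "--out", "s1.txt"]],
                      "stdout_to": None}],
        "inputs": [["ab" * 32, "in/reads", "src://data/s1.fastq"]],
        "source_files": [],
        "planned_outputs": {"out/counts": ["s1.txt"]},
    }
    body = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    expected = hashlib.sha256(("pfv1\n" + body).encode()).hexdigest()
    fp = fingerprint_run(run)
    assert fp.hash_full == expected
    assert fp.hash_short == expected[:16]
    assert fp.canonical_bytes.startswith(b"pfv1\n")


def test_unserializable_param_raises():
    with pytest.raises(SerializationError):
        fingerprint_run(toy_run(params={"bad": object()}))


def test_output_dir_rule():
    run = toy_run()
    fp = fingerprint_run(run)
    assert output_dir(run, fp, "/dest") == f"/dest/trim/s1-{fp.hash_short}"


@pytest.mark.parametrize(
    "content, digest",
    [
        (b"", "e3b0c44298fc1c149afbf4c8996fb92427ae41e4649b934ca495991b7852b855"),
        (b"abc", "ba7816bf8f01cfea414140de5dae2223b00361a396177a9cb410ff61f20015ad"),
    ],
)
def test_file_checksum_known_vectors(tmp_path, content, digest):
    p = tmp_path / "f"
    p.write_bytes(content)
    assert file_checksum(str(p)) == digest


def test_file_checksum_missing_file(tmp_path):
    with pytest.raises(FileMissingError):
        file_checksum(str(tmp_path / "nope"))


def _chain_config_text(k):
    steps = {"n0": {"_type": "null_source"}}
    for i in range(1, k):
        steps[f"n{i}"] = {"_type": "gather", "_depends": [f"n{i-1}"]}
    return yaml.safe_dump({"destination_path": "results", "steps": steps})


def test_hash_chain_propagation_over_random_chains():
    """Editing step j of a k-step chain changes the fingerprints of exactly
    steps j..k (checked for random j over several chain lengths)."""
    from conftest import make_test_registry
    rng = Lcg(7)
    reg = make_test_registry()
    for trial in range(6):
        k = 3 + rng.randint(4)  # 3..6 steps
        j = 1 + rng.randint(k - 1)  # edit step j in 1..k-1 (0 is the source)
        text = _chain_config_text(k)
        g1 = build_graph(parse_config(text, registry=reg), registry=reg)
        doc = yaml.safe_load(text)
        doc["steps"][f"n{j}"]["_delay"] = 1  # any effective-param edit
        g2 = build_graph(parse_config(yaml.safe_dump(doc), registry=reg), registry=reg)
        changed = {s for (s, r) in g1.runs
                   if g1.runs[(s, r)].hash_full != g2.runs[(s, r)].hash_full}
        assert changed == {f"n{i}" for i in range(j, k)}


def test_fingerprints_invariant_under_results_relocation(completed_chain, tmp_path):
    cfg, graph = completed_chain
    before = {k: r.hash_full for k, r in graph.runs.items()}
    # move the whole results tree and point the config at the new location
    new_dest = tmp_path / "moved_results"
    shutil.move(graph.destination, str(new_dest))
    edit_config(cfg, lambda d: d.__setitem__("destination_path", str(new_dest)))
    g2 = reload_graph(cfg)
    assert {k: r.hash_full for k, r in g2.runs.items()} == before
    # and the relocated tree still verifies clean
    assert verify_tree(g2.destination, g2).ok


def test_annotation_roundtrip_and_completeness(completed_chain):
    _cfg, graph = completed_chain
    for run in graph.runs_in_order():
        d = output_dir(run, run.fingerprint, graph.destination)
        ann = read_annotation(d)
        assert ann is not None and ann.fingerprint == run.hash_full
        # round-trip: re-serialize and re-parse to an equal document
        text = yaml.safe_dump(ann.to_dict(), sort_keys=True)
        assert yaml.safe_load(text) == ann.to_dict()
        if run.is_source:
            continue
        # every file except the annotation is listed, with verifying checksums
        files = {f for f in os.listdir(d) if f != ".annotation.yaml"}
        assert files == set(ann.output_files)
        for name in files:
            assert file_checksum(os.path.join(d, name)) == \
                   ann.output_files[name]["sha256"]


def test_verify_tree_flags_tampering_and_orphans(completed_chain):
    cfg, graph = completed_chain
    report = verify_tree(graph.destination, graph)
    assert report.ok
    assert set(report.entries.values()) == {CONSISTENT}

    # flip a byte in one finished output file
    run = graph.runs[("counts", "s1")]
    d = output_dir(run, run.fingerprint, graph.destination)
    target = os.path.join(d, run.output_names()[0])
    data = bytearray(open(target, "rb").read())
    data[0] ^= 0xFF
    open(target, "wb").write(bytes(data))
    report = verify_tree(graph.destination, graph)
    assert report.entries[("counts", "s1")] == CHECKSUM_MISMATCH
    assert not report.ok

    # edit a parameter: old directories orphan, new fingerprints absent
    edit_config(cfg, lambda doc: doc["steps"]["trim"].__setitem__("min_length", 7))
    g2 = reload_graph(cfg)
    report = verify_tree(g2.destination, g2)
    assert len(report.orphaned) == 4  # trim + counts, two samples each
    assert report.entries[("trim", "s1")] == ABSENT
    assert report.entries[("raw", "s1")] == CONSISTENT
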