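import os

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from provflow import build_graph, execute_workflow, output_dir, parse_config
from provflow.errors import (
    ConfigError,
    DuplicateStepError,
    FileMissingError,
    MalformedFastqError,
    UnknownStepError,
)
from provflow.fixtures import FastqSpec, generate_fastq
from provflow.steps_library import (
    PROCESSING,
    StepDefinition,
    StepRegistry,
    count_fastq_records,
    default_registry,
    find_clip_position,
    trim_fastq,
)


class TestRegistry:
    def test_register_then_lookup_returns_same_definition(self):
        reg = StepRegistry()
        d = StepDefinition(type_name="x", kind=PROCESSING,
                           in_connections=("in/a",))
        assert reg.register(d) is d
        assert reg.lookup("x") is d

    def test_duplicate_registration_rejected(self):
        reg = default_registry()
        with pytest.raises(DuplicateStepError):
            reg.register(StepDefinition(type_name="count_reads",
                                        kind=PROCESSING,
                                        in_connections=("in/a",)))

    def test_unknown_lookup_rejected(self):
        with pytest.raises(UnknownStepError):
            default_registry().lookup("no_such_step")


class TestFastqSource:
    def _config(self, samples, tmp_path):
        import yaml
        return parse_config(yaml.safe_dump({
            "destination_path": "results",
            "steps": {"raw": {"_type": "fastq_source", "samples": samples}},
        }), config_dir=str(tmp_path))

    def test_one_run_per_sample(self, tmp_path):
        for n in ("a", "b"):
            generate_fastq(FastqSpec(2, 10, seed=1), str(tmp_path / f"{n}.fastq"))
        g = build_graph(self._config({"s1": ["a.fastq"], "s2": ["b.fastq"]}, tmp_path))
        assert sorted(r for _s, r in g.runs) == ["s1", "s2"]

    def test_paired_files_stay_in_one_run(self, tmp_path):
        for n in ("r1", "r2"):
            generate_fastq(FastqSpec(2, 10, seed=1), str(tmp_path / f"{n}.fastq"))
        g = build_graph(self._config({"s1": ["r1.fastq", "r2.fastq"]}, tmp_path))
        run = g.runs[("raw", "s1")]
        assert len(run.planned_outputs["out/reads"]) == 2

    def test_missing_file_fails_before_any_execution(self, tmp_path):
        with pytest.raises(FileMissingError):
            build_graph(self._config({"s1": ["ghost.fastq"]}, tmp_path))


class TestCountReads:
    def test_counts_fixture_reads_exactly(self, tmp_path):
        p = str(tmp_path / "r.fastq")
        generate_fastq(FastqSpec(100, 30, seed=9), p)
        assert count_fastq_records([p]) == 100

    def test_empty_fastq_counts_zero(self, tmp_path):
        p = tmp_path / "e.fastq"
        p.write_text("")
        assert count_fastq_records([str(p)]) == 0

    def test_seven_line_file_is_malformed(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r\nACGT\n+\nIIII\n@q\nACGT\n+\n")  # 7 lines
        with pytest.raises(MalformedFastqError):
            count_fastq_records([str(p)])

    def test_quality_length_mismatch_is_malformed(self, tmp_path):
        p = tmp_path / "bad.fastq"
        p.write_text("@r\nACGT\n+\nIII\n")
        with pytest.raises(MalformedFastqError):
            count_fastq_records([str(p)])


def brute_force_clip(seq, adapter, min_overlap):
    """Independent oracle: exhaustive scan of every position."""
    full = [p for p in range(len(seq) - len(adapter) + 1)
            if seq[p:p + len(adapter)] == adapter]
    if full:
        return full[0]
    candidates = [
        p for p in range(len(seq))
        if len(seq) - p >= min_overlap and seq[p:] == adapter[: len(seq) - p]
    ]
    return min(candidates) if candidates else None


class TestTrimAdapter:
    def test_exact_internal_match_clips_there(self):
        assert find_clip_position("ACGTTTAGACGCGCG", "ACGCGCG", 3) == 8

    def test_no_overlap_leaves_read_unchanged(self):
        assert find_clip_position("AAAAAAAAAA", "CGCGCG", 3) is None

    def test_suffix_shorter_than_min_overlap_ignored(self):
        # only 2 bases of adapter at the 3' end, min_overlap 3
        assert find_clip_position("TTTTTTTTAC", "ACGCGCG", 3) is None
        assert find_clip_position("TTTTTTTTAC", "ACGCGCG", 2) == 8

    @settings(max_examples=300, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=1, max_size=40),
        adapter=st.text(alphabet="ACGT", min_size=1, max_size=12),
        min_overlap=st.integers(min_value=1, max_value=6),
    )
    def test_matches_bruteforce_scan(self, seq, adapter, min_overlap):
        assert find_clip_position(seq, adapter, min_overlap) == \
               brute_force_clip(seq, adapter, min_overlap)

    def test_trim_clips_quality_in_step_and_counts_drops(self, tmp_path):
        src = tmp_path / "in.fastq"
        src.write_text(
            "@keep\nACGTTTAGACGCGCG\n+\nABCDEFGHIJKLMNO\n"
            "@drop\nACGCGCGTTTTTTTT\n+\nABCDEFGHIJKLMNO\n"
        )
        out = tmp_path / "out.fastq"
        dropped = trim_fastq([str(src)], str(out), "ACGCGCG",
                             min_overlap=3, min_length=1)
        assert dropped == 1  # @drop clips at position 0 -> empty read
        assert out.read_text() == "@keep\nACGTTTAG\n+\nABCDEFGH\n"

    def test_invalid_adapter_rejected_at_parse_time(self, tmp_path):
        import yaml
        generate_fastq(FastqSpec(1, 10, seed=1), str(tmp_path / "a.fastq"))
        doc = {
            "destination_path": "results",
            "steps": {
                "raw": {"_type": "fastq_source", "samples": {"s1": ["a.fastq"]}},
                "trim": {"_type": "trim_adapter", "_depends": ["raw"],
                         "_connect": {"in/reads": "raw/out/reads"},
                         "adapter": "ACGTX"},
            },
        }
        with pytest.raises(ConfigError):
            parse_config(yaml.safe_dump(doc), config_dir=str(tmp_path))


class TestMergeFiles:
    def test_concatenation_is_ordered_and_deterministic(self, workspace):
        _cfg, g = workspace("diamond")
        assert execute_workflow(g, g.destination).ok
        run = g.runs[("merged", "all")]
        d = output_dir(run, run.fingerprint, g.destination)
        merged = open(os.path.join(d, "all.merged.dat"), "rb").read()
        pieces = b""
        for _h, path in run.inputs["in/files"]:
            pieces += open(g.resolve_path(path), "rb").read()
        assert merged == pieces
        # inputs are sorted by (run_id, path): stable regardless of timing
        paths = [p for _h, p in run.inputs["in/files"]]
        keyed = [(os.path.basename(p), p) for p in paths]  # basename carries run_id
        assert keyed == sorted(keyed)


def test_planned_outputs_exactly_match_produced_files(workspace):
    _cfg, g = workspace("rnaseq_toy")
    assert execute_workflow(g, g.destination).ok
    for run in g.runs_in_order():
        if run.is_source:
            continue
        d = output_dir(run, run.fingerprint, g.destination)
        produced = {f for f in os.listdir(d) if f != ".annotation.yaml"}
        assert produced == set(run.output_names())


def test_trimming_never_increases_read_count_or_length(workspace):
    _cfg, g = workspace("chain")
    assert execute_workflow(g, g.destination).ok
    for sample in ("s1", "s2"):
        raw = g.config.resolve_source_path(f"data/{sample}.fastq")
        trim_run = g.runs[("trim", sample)]
        d = output_dir(trim_run, trim_run.fingerprint, g.destination)
        trimmed = os.path.join(d, f"{sample}.trimmed.fastq")
        assert count_fastq_records([trimmed]) <= count_fastq_records([raw])
        from provflow.steps_library import iter_fastq_records
        raw_lens = {t: len(s) for t, s, _q in iter_fastq_records(raw)}
        for title, seq, _q in iter_fastq_records(trimmed):
            assert len(seq) <= raw_lens[title]
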