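# Methods

## The problem and the model

Multi-step sequence-analysis pipelines are directed acyclic graphs: each
node (*step*) is a blueprint for one analysis stage, each edge
(*connection*) a named channel along which files flow.  A step is
instantiated per sample into *runs* — the atomic, independently schedulable
and independently failing units of the analysis.  provflow enforces four
reproducibility properties mechanically rather than by convention:

1. **Dependency maintenance** — runs execute only after all the runs they
   consume; upstream edits invalidate exactly their downstream closure.
2. **Completion before successors** — a run's results become visible only
   if every one of its processes exited as expected *and* every planned
   output exists; descendants of a failed run never start.
3. **Complete logging** — every run leaves an annotation carrying the full
   normalized configuration (defaults included), the argv-exact commands,
   tool versions, per-process exit codes, cumulative CPU seconds, peak RSS,
   the last kilobyte of stdout/stderr, and SHA-256 checksums of outputs.
4. **Code–result linkage** — each run's output directory name embeds a
   digest of its complete specification, so results and the code that
   produced them cannot silently drift apart.

## Content addressing

A run's *fingerprint* is the SHA-256 of a frozen canonical serialization
(format tag `pfv1`, itself hashed): the version-tagged JSON of step id, run
id, step-definition version, effective parameters (defaults merged and
constants interpolated at parse time, so unset defaults are covered),
ordered command groups, sorted inputs as (upstream-hash, connection, path)
triples, source file paths as written in the configuration, and sorted
planned output names.  The first 16 hex characters form the directory
suffix `<dest>/<step>/<run_id>-<hash16>`.

Inputs enter the fingerprint by upstream *run hash*, never by file content:
linking is O(1) per run and transitive, so a parameter edit at depth *j* of
a chain re-addresses exactly steps *j..k*.  Three deliberate choices:

* **Tool versions are logged but not hashed.**  Hashing them would force
  re-execution after benign environment probes; drift is surfaced by
  verification instead.
* **Planned output filenames are hashed.**  Renaming an output is a change
  to the run's observable contract.
* **Paths are symbolic.**  Command arguments and input references use
  `dest://` (results-tree-relative) and `src://` (config-dir-relative)
  tokens resolved only at execution, so fingerprints are invariant under
  relocation of the results tree.  Source-file paths are hashed as written
  in the config: moving the input data is a real change to the declared
  analysis.

## Execution and atomicity

Runs execute in `<dest>/temp/<step>-<run>-<hash16>/` on the same
filesystem as their final location; promotion is a single `rename`, done
after per-process exit-code checks (against each tool's expected code —
pipe failures are never masked by the last stage) and planned-output
existence checks, with the annotation already inside the staged directory.
A killed executor therefore leaves either nothing or a complete result;
failures retain staging with a `FAILED` sentinel plus annotation for
inspection.  Monitoring samples `/proc/<pid>/status` every 0.5 s while
processes run and takes the authoritative per-child reading from
`os.wait4` rusage; CPU is recorded as cumulative user+system seconds
(instantaneous load is not meaningful for short-lived desk-scale
processes).

Parallel execution (`max_parallel`) is over whole runs only; because every
run writes only inside its own staging directory and promotion is atomic,
results are byte-identical to a serial run (annotations differ only in
timestamps and resource readings).  At `max_parallel=1` launch order is
strictly topological with lexicographic tie-breaks, as are all orderings
in the system (status tables, DOT output, input lists) — bit-stable output
is treated as a correctness property, not cosmetics.

## States, re-scheduling, volatilization

States are recomputed from the filesystem on every invocation, never
stored: `finished` / `volatilized` from the run's own content-addressed
directory, `failed` from a sentinel-bearing staging directory, `waiting`
from unsatisfied dependencies, `changed` when only an orphaned sibling
directory (same step and run id, different hash) exists, else `ready`.
Schedulable = {ready, changed, failed (retry)} with all dependencies
satisfied; descendants of failed or changed runs halt.  Orphaned
directories are reported by verification and never auto-deleted.

Volatilization replaces a finished interior run's output files with YAML
placeholders (`<name>.volatile.yaml`: original name, SHA-256, size,
timestamp).  It is refused unless every consumer is finished, keeps
downstream states intact, and makes any *new* consumer fail with an error
naming the run to re-execute.  Source runs are never volatilized (their
files are the primary inputs, not reclaimable intermediates).

## Configuration and plug-ins

One YAML file fully describes an analysis (schema in `provflow.config`).
Steps are plug-ins: a `StepDefinition` declares kind, connections, tools,
a fully defaulted parameter schema and a run-construction procedure.
Multi-input steps match upstream runs by identical run id (strict merge;
asymmetric id sets are an error), except *collect*-mode steps, which
aggregate all upstream runs — from several producers if wired so — into
one run with inputs ordered by (run id, path).  Strict steps accept
exactly one producer per in-connection.  Per-step environment variables
replace environment-module loading and apply only to that step's
processes.

## Built-in steps and their simplifications

The shipped steps (`fastq_source`, `count_reads`, `trim_adapter`,
`merge_files`) run through the engine's own `python -m provflow.native`
subprocess so complete workflows execute hermetically.  `trim_adapter`
clips 3' adapter read-through by *exact* matching: leftmost full-adapter
occurrence, else the longest read suffix equal to an adapter prefix of at
least `min_overlap` (default 3) bases; reads shorter than `min_length`
(default 1) after clipping are dropped and counted.  Real trimmers
tolerate mismatches and model quality; exact matching was chosen because
it admits an exhaustive brute-force oracle and keeps results bit-stable.
FASTQ qualities are validated for length but treated as opaque bytes.
Processing steps carry `_fail_mode` and `_delay` parameters so failure and
interruption scenarios are driven through the ordinary configuration/hash
path; they default to inert values and hash like any parameter.

## Synthetic data

`provflow.fixtures` generates FASTQ (default templates: 50 reads × 40 bp
per sample, adapter-contamination rates 0.4–0.6 with the TruSeq universal
adapter prefix `AGATCGGAAGAGC`) from a specified 64-bit LCG (MMIX
multiplier, top-31-bit outputs), so fixture bytes are identical across
platforms.  Adapter insertion positions are drawn uniformly; the truth
sidecar records, per read, the insertion position and the expected clip
position computed by exhaustive scan (valid even when a chance upstream
match shifts the clip).  The generator emulates the *shape* of HTS data
only — no sequencing-error profiles, quality distributions, duplicates, or
genomic structure — so passing tests certify engine behaviour, not
biological fidelity of any analysis.  Template workflows (`chain`,
`diamond`, `rnaseq_toy`, `chipseq_toy`) are toy analogues of per-sample,
branch-merge, and pooled pipeline shapes; problem sizes (2–3 samples,
≤1000 reads, 6–10 runs) were chosen as the smallest that exercise every
code path including merging and pooling.

## Numerical and degenerate-input choices

SHA-256 with a 16-hex-character path prefix (collision probability
negligible at desk scale; the full digest is kept in annotations).
Canonical JSON uses sorted keys, compact separators and ASCII escaping;
only scalars, lists and string-keyed maps are serializable — anything else
is a hard error.  Empty FASTQ files count zero reads; a line count not
divisible by 4 or a quality/sequence length mismatch fails the run.
Stream tails are byte-truncated (the final 1024 bytes), which may split a
multi-byte character; decoding uses replacement characters.  Re-executing
a run whose same-fingerprint directory already exists (an output was
deleted) replaces that directory on promotion.

## Known limitations

Single-machine execution only; the `ExecutionBackend` interface documents
the submit/poll/collect contract for batch-system backends but only the
local backend ships.  Monitoring relies on `/proc` and `os.wait4`
(Linux/Unix).  State derivation walks the results tree per invocation —
appropriate at desk scale, not for millions of runs.  Orphan detection is
name-based (same step directory); results produced under a renamed step id
appear as orphans of an unknown step.
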