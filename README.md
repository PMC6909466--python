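# provflow

A desk-scale workflow engine that makes multi-step sequence analyses
reproducible by construction.  A single YAML file declares the analysis as
a DAG of steps; the engine expands steps into per-sample *runs*, hashes
each run's complete command-and-parameter specification into its output
path, executes runs atomically in monitored staging directories, and
writes a full provenance annotation next to every result.

It is written for bioinformaticians who run multi-step pipelines (trim →
map → count → …) on a workstation and need four guarantees that ad-hoc
scripting does not give:

1. dependencies between steps and intermediate results are always
   maintained;
2. a step's results become visible only after *every* process exited as
   expected and *every* declared output exists — downstream steps never
   consume partial files;
3. tools, versions and the **full** parameter set (including defaults the
   user never typed) are logged per run, with checksums and resource usage;
4. the code defining the analysis and the results on disk are verifiably
   consistent: any edit re-addresses the affected outputs, so stale results
   are detected as *orphaned* directories instead of being silently reused.

## The core mechanism

For a run r with effective parameters θ, command groups C, and inputs
drawn from upstream runs u₁…uₘ, the engine computes

    h(r) = SHA-256( pfv1 ‖ canonical(step, run_id, θ, C,
                    {(h(uᵢ), connection, path)}, planned_outputs) )

and writes the run's results to `<dest>/<step>/<run_id>-h₁₆(r)/`, where
h₁₆ is the first 16 hex digits.  Because h(r) depends on upstream runs
only through *their* hashes, invalidation propagates transitively: editing
step j of a k-step chain changes exactly the addresses of steps j..k.
Execution happens in `<dest>/temp/…` and reaches the final address through
a single atomic rename.  Run states (`ready`, `waiting`, `finished`,
`failed`, `changed`, `volatilized`) are derived from the filesystem on
every invocation — there is no state database to corrupt.

Bulky intermediates of a finished step can be *volatilized* — replaced by
checksum-bearing placeholders — without breaking the DAG: downstream runs
stay `finished`, and only a newly attached consumer forces re-execution.

## Worked example

Materialize a toy two-sample workflow (source → adapter-trim → read-count)
with deterministic synthetic FASTQ data:

```pycon
>>> from provflow import template_workflow
>>> template_workflow("chain", "demo", seed=42)
'demo/chain.yaml'
```

```console
$ provflow status demo/chain.yaml
raw/s1     ready        20f8a0f50c157e2f
raw/s2     ready        bf7f31a5ee0ef76e
trim/s1    waiting      35c617c9430dec72
trim/s2    waiting      aba523eba56cc7af
counts/s1  waiting      7f2e6a1765384c5a
counts/s2  waiting      2ea07b4def47f4b1
total: 6  ready: 2  waiting: 4

$ provflow run demo/chain.yaml
executed: 6  succeeded: 6  failed: 0  skipped: 0

$ provflow run demo/chain.yaml        # nothing left to do: idempotent
executed: 0  succeeded: 0  failed: 0  skipped: 0
```

The third column is each run's 16-hex-digit fingerprint prefix — the same
string that names its output directory, e.g.
`demo/results/counts/s1-7f2e6a1765384c5a/s1.count.txt`, which contains
`50`: all 50 generated reads of sample s1 survived trimming.  Next to it,
`.annotation.yaml` records the full configuration, the exact argv of every
process, exit codes, CPU seconds, peak RSS, output tails, and SHA-256
checksums.

Reclaim space held by the trimmed FASTQ intermediates, then audit the
tree:

```console
$ provflow volatilize demo/chain.yaml trim
volatilized 4 file(s) of step trim
$ provflow verify demo/chain.yaml
counts/s1: consistent
counts/s2: consistent
raw/s1: consistent
raw/s2: consistent
trim/s1: consistent
trim/s2: consistent
```

Editing any parameter in `chain.yaml` flips the affected runs to
`changed`/`waiting` in `status`, and `run` re-executes exactly those.
Other subcommands: `render` (Graphviz DOT of the DAG), `steps` (registered
step types), `run --dry-run` (print commands without executing).  New step
types are plug-ins: a `StepDefinition` declaring connections, tools, a
defaulted parameter schema, and a run-construction procedure — see
`provflow.steps_library`.

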