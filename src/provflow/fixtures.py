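"""Deterministic toy data and template workflows for hermetic testing.

Real sequencing data and the external aligners/peak-callers of production
pipelines are deliberately absent here: the engine, not the tools, is what
these fixtures exercise.  The generator emulates the *shape* of small HTS
inputs — 4-line FASTQ records over {A,C,G,T} with optional 3' adapter
read-through at known positions — and records ground truth (the expected
clip position per read) in a YAML sidecar, so adapter-trimming output can
be checked exactly.  It does not emulate sequencing error profiles, quality
score distributions, or genomic structure.

Determinism is bit-exact across platforms: all randomness comes from an
explicitly specified 64-bit linear congruential generator (the classic
MMIX multiplier), never from a platform RNG or float arithmetic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import yaml

from .errors import ConfigError
from .steps_library import find_clip_position

_LCG_A = 6364136223846793005
_LCG_C = 1442695040888963407
_MASK64 = (1 << 64) - 1


class Lcg:
    """64-bit LCG; outputs are the top 31 bits of the state."""

    def __init__(self, seed: int):
        self.state = (seed ^ 0x9E3779B97F4A7C15) & _MASK64
        self._next()  # discard the correlated first value

    def _next(self) -> int:
        self.state = (_LCG_A * self.state + _LCG_C) & _MASK64
        return self.state >> 33

    def randint(self, n: int) -> int:
        """Uniform-ish integer in [0, n); modulo bias is irrelevant here."""
        return self._next() % n

    def fraction(self) -> float:
        return self._next() / float(1 << 31)


@dataclass(frozen=True)
class FastqSpec:
    n_reads: int
    read_length: int
    seed: int
    adapter: Optional[str] = None
    adapter_rate: float = 0.0
    min_overlap: int = 3

    def __post_init__(self):
        if self.n_reads < 0 or self.read_length < 1:
            raise ConfigError("n_reads >= 0 and read_length >= 1 required")
        if not 0.0 <= self.adapter_rate <= 1.0:
            raise ConfigError("adapter_rate must lie in [0, 1]")
        if self.adapter_rate > 0 and not self.adapter:
            raise ConfigError("adapter_rate > 0 requires an adapter")


_BASES = "ACGT"


def generate_fastq(spec: FastqSpec, path: str) -> str:
    """Write a deterministic FASTQ file plus a ``<path>.truth.yaml`` sidecar.

    For a fraction ``adapter_rate`` of reads, the read's 3' end is
    overwritten from a random position with the adapter sequence (truncated
    at the read boundary), emulating adapter read-through.  The sidecar
    records, per read, the insertion position (or null) and the expected
    clip position — computed by an exhaustive suffix-prefix scan, so it is
    valid ground truth even when a chance upstream match shifts the clip.
    Returns the sidecar path.
    """
    rng = Lcg(spec.seed)
    truth = []
    with open(path, "wt", encoding="ascii") as fh:
        for i in range(spec.n_reads):
            seq = [_BASES[rng.randint(4)] for _ in range(spec.read_length)]
            inserted = None
            if spec.adapter and rng.fraction() < spec.adapter_rate:
                lo = 1
                hi = max(lo, spec.read_length - spec.min_overlap)
                inserted = lo + rng.randint(hi - lo + 1)
                for j, base in enumerate(spec.adapter):
                    if inserted + j >= spec.read_length:
                        break
                    seq[inserted + j] = base
            sequence = "".join(seq)
            qual = "".join(chr(33 + rng.randint(40)) for _ in range(spec.read_length))
            fh.write(f"@r{i:06d}\n{sequence}\n+\n{qual}\n")
            clip = None
            if spec.adapter:
                clip = find_clip_position(sequence, spec.adapter, spec.min_overlap)
            truth.append({"index": i, "inserted": inserted, "clip": clip})

    sidecar = path + ".truth.yaml"
    with open(sidecar, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "adapter": spec.adapter,
                "min_overlap": spec.min_overlap,
                "n_reads": spec.n_reads,
                "read_length": spec.read_length,
                "seed": spec.seed,
                "reads": truth,
            },
            fh, sort_keys=True,
        )
    return sidecar


def read_truth(sidecar_path: str) -> dict:
    with open(sidecar_path, "rt", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Template workflows
# ---------------------------------------------------------------------------

TEMPLATES = ("chain", "diamond", "rnaseq_toy", "chipseq_toy")

_ADAPTER = "AGATCGGAAGAGC"  # Illumina TruSeq universal adapter prefix


def _write_samples(workdir, samples, seed, adapter=None, adapter_rate=0.0,
                   n_reads=50, read_length=40):
    datadir = os.path.join(workdir, "data")
    os.makedirs(datadir, exist_ok=True)
    sample_map = {}
    for k, name in enumerate(samples):
        rel = f"data/{name}.fastq"
        spec = FastqSpec(
            n_reads=n_reads, read_length=read_length, seed=seed + 1000 * (k + 1),
            adapter=adapter, adapter_rate=adapter_rate,
        )
        generate_fastq(spec, os.path.join(workdir, rel))
        sample_map[name] = [rel]
    return sample_map


def template_workflow(name: str, workdir: str, seed: int = 42) -> str:
    """Materialize a toy template: input FASTQ files plus a workflow config.

    * ``chain``: per-sample 3-step chain (source -> trim -> count), 2
      samples, 6 runs;
    * ``diamond``: source branches into two differently parameterized trim
      steps whose outputs are merged (branch-and-merge shape), 7 runs;
    * ``rnaseq_toy``: per-sample trim and count plus a pooled branch that
      merges all trimmed samples and counts the pool, 8 runs;
    * ``chipseq_toy``: linear trim -> count over 3 samples, 9 runs.

    Returns the path of the written configuration file.  All paths inside
    the config are relative, so the whole directory is relocatable.
    """
    if name not in TEMPLATES:
        raise ConfigError(f"unknown template {name!r}; choose from {TEMPLATES}")
    os.makedirs(workdir, exist_ok=True)

    def step(type_, depends=None, connect=None, **params):
        d = {"_type": type_}
        if depends:
            d["_depends"] = depends
        if connect:
            d["_connect"] = connect
        d.update(params)
        return d

    if name == "chain":
        samples = _write_samples(workdir, ["s1", "s2"], seed,
                                 adapter=_ADAPTER, adapter_rate=0.5)
        steps = {
            "raw": step("fastq_source", samples=samples),
            "trim": step("trim_adapter", depends=["raw"],
                         connect={"in/reads": "raw/out/reads"},
                         adapter="${adapter}"),
            "counts": step("count_reads", depends=["trim"],
                           connect={"in/reads": "trim/out/trimmed"}),
        }
    elif name == "diamond":
        samples = _write_samples(workdir, ["s1", "s2"], seed,
                                 adapter=_ADAPTER, adapter_rate=0.5)
        steps = {
            "raw": step("fastq_source", samples=samples),
            "trim_loose": step("trim_adapter", depends=["raw"],
                               connect={"in/reads": "raw/out/reads"},
                               adapter="${adapter}", min_overlap=5),
            "trim_strict": step("trim_adapter", depends=["raw"],
                                connect={"in/reads": "raw/out/reads"},
                                adapter="${adapter}", min_overlap=3,
                                min_length=10),
            "merged": step("merge_files",
                           depends=["trim_loose", "trim_strict"],
                           connect={"in/files": ["trim_loose/out/trimmed",
                                                 "trim_strict/out/trimmed"]}),
        }
    elif name == "rnaseq_toy":
        samples = _write_samples(workdir, ["s1", "s2"], seed,
                                 adapter=_ADAPTER, adapter_rate=0.6)
        steps = {
            "raw": step("fastq_source", samples=samples),
            "trim": step("trim_adapter", depends=["raw"],
                         connect={"in/reads": "raw/out/reads"},
                         adapter="${adapter}"),
            "counts": step("count_reads", depends=["trim"],
                           connect={"in/reads": "trim/out/trimmed"}),
            "pool": step("merge_files", depends=["trim"],
                         connect={"in/files": "trim/out/trimmed"}),
            "pool_counts": step("count_reads", depends=["pool"],
                                connect={"in/reads": "pool/out/merged"}),
        }
    else:  # chipseq_toy
        samples = _write_samples(workdir, ["input", "ip_rep1", "ip_rep2"],
                                 seed, adapter=_ADAPTER, adapter_rate=0.4)
        steps = {
            "raw": step("fastq_source", samples=samples),
            "trim": step("trim_adapter", depends=["raw"],
                         connect={"in/reads": "raw/out/reads"},
                         adapter="${adapter}", min_length=15),
            "counts": step("count_reads", depends=["trim"],
                           connect={"in/reads": "trim/out/trimmed"}),
        }

    doc = {
        "destination_path": "results",
        "constants": {"adapter": _ADAPTER},
        "steps": steps,
    }
    config_path = os.path.join(workdir, f"{name}.yaml")
    with open(config_path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return config_path
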