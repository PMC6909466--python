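"""Subprocess entry point backing the built-in steps.

Invoked by the executor as ``python -m provflow.native <op> ...`` so that
built-in analysis stages run as ordinary monitored child processes, exactly
like external tools would.  Kept import-light: heavy imports happen inside
``main`` to minimize per-run startup cost.

Common flags (test support, driven by step params):

``--delay SECONDS``   sleep before doing any work;
``--fail-exit CODE``  exit with CODE before doing any work;
``--skip-output``     do the work but remove the primary output afterwards.
"""

from __future__ import annotations

import argparse
import sys


def _add_common(parser):
    parser.add_argument("--delay", type=float, default=0.0)
    parser.add_argument("--fail-exit", type=int, default=None)
    parser.add_argument("--skip-output", action="store_true")


def _common_preamble(args):
    if args.delay:
        import time
        time.sleep(args.delay)
    if args.fail_exit is not None:
        print("injected failure", file=sys.stderr)
        sys.exit(args.fail_exit)


def main(argv=None):
    parser = argparse.ArgumentParser(prog="provflow-native")
    sub = parser.add_subparsers(dest="op", required=True)

    p = sub.add_parser("count-reads")
    p.add_argument("--out", required=True)
    _add_common(p)
    p.add_argument("inputs", nargs="*")

    p = sub.add_parser("trim-adapter")
    p.add_argument("--adapter", required=True)
    p.add_argument("--min-overlap", type=int, default=3)
    p.add_argument("--min-length", type=int, default=1)
    p.add_argument("--out-trimmed", required=True)
    p.add_argument("--out-count", required=True)
    _add_common(p)
    p.add_argument("inputs", nargs="*")

    p = sub.add_parser("concat")
    p.add_argument("--out", required=True)
    _add_common(p)
    p.add_argument("inputs", nargs="*")

    p = sub.add_parser("emit-lines")
    p.add_argument("--n", type=int, required=True)
    _add_common(p)

    p = sub.add_parser("count-lines")
    _add_common(p)

    args = parser.parse_args(argv)
    _common_preamble(args)

    import os

    from .errors import MalformedFastqError
    from .steps_library import count_fastq_records, trim_fastq

    try:
        if args.op == "count-reads":
            n = count_fastq_records(args.inputs)
            with open(args.out, "wt") as fh:
                fh.write(f"{n}\n")
            if args.skip_output:
                os.remove(args.out)
        elif args.op == "trim-adapter":
            dropped = trim_fastq(
                args.inputs, args.out_trimmed, args.adapter,
                min_overlap=args.min_overlap, min_length=args.min_length,
            )
            with open(args.out_count, "wt") as fh:
                fh.write(f"{dropped}\n")
            if args.skip_output:
                os.remove(args.out_trimmed)
        elif args.op == "concat":
            with open(args.out, "wb") as out:
                for path in args.inputs:
                    with open(path, "rb") as fh:
                        while True:
                            chunk = fh.read(1 << 20)
                            if not chunk:
                                break
                            out.write(chunk)
            if args.skip_output:
                os.remove(args.out)
        elif args.op == "emit-lines":
            for i in range(args.n):
                sys.stdout.write(f"line {i}\n")
        elif args.op == "count-lines":
            n = sum(1 for _ in sys.stdin)
            sys.stdout.write(f"{n}\n")
    except MalformedFastqError as e:
        print(f"error: {e}", file=sys.stderr)
        sys.exit(1)
    except OSError as e:
        print(f"error: {e}", file=sys.stderr)
        sys.exit(1)
    return 0


if __name__ == "__main__":
    sys.exit(main())
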