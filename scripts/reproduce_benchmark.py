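#!/usr/bin/env python
"""Rerun the full selection protocol on a user-supplied two-class benchmark.

This is an optional reproduction entry point for users who have a real
labelled dataset (for example the publicly hosted 122-enzyme
acidic/alkaline benchmark: 54 acidic + 68 alkaline sequences,
redundancy-reduced to < 25% pairwise identity).  It is not used by the
test suite and performs no downloads.

With the default full grid (21 x 11 hyperparameter points, re-searched per
gap) and the complete gap 0-10 x t 1-400 IFS scan this takes hours on one
CPU; the --c-exp-step/--gamma-exp-step and --gap-max flags trade
completeness for time.

Usage:
    python scripts/reproduce_benchmark.py --acidic acidic.fasta \
        --alkaline alkaline.fasta --out benchmark_run
"""

from __future__ import annotations

import argparse
from pathlib import Path

from ggapsvm.pipeline import RunConfig, run_full_selection
from ggapsvm.svm_engine import SVMGridSpec


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--acidic", type=Path, required=True, help="FASTA of acidic-class sequences")
    parser.add_argument("--alkaline", type=Path, required=True, help="FASTA of alkaline-class sequences")
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--gap-max", type=int, default=10)
    parser.add_argument("--min-length", type=int, default=100)
    parser.add_argument("--c-exp-step", type=int, default=1)
    parser.add_argument("--gamma-exp-step", type=int, default=1)
    parser.add_argument("--ifs-mode", choices=["fast", "regrid"], default="fast")
    args = parser.parse_args()

    config = RunConfig(
        gap_min=0,
        gap_max=args.gap_max,
        min_length=args.min_length,
        grid=SVMGridSpec(c_exp_step=args.c_exp_step, gamma_exp_step=args.gamma_exp_step),
        ifs_mode=args.ifs_mode,
        out_dir=args.out,
    )
    _, summary = run_full_selection(args.acidic, args.alkaline, config)
    print(
        f"selected g0={summary['g0']}, t0={summary['t0']}; "
        f"jackknife Ac={summary['jackknife']['ac_percent']}%, "
        f"Sn={summary['jackknife']['sn_percent']}%, "
        f"Sp={summary['jackknife']['sp_percent']}%, "
        f"CC={summary['jackknife']['cc']:.4f}, "
        f"AUC={summary['jackknife']['auc']:.3f}"
    )
    print(f"report bundle written to {args.out}")


if __name__ == "__main__":
    main()
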