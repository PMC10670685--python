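"""Shared argument handling for the numbered analysis drivers."""

import argparse
import logging
from pathlib import Path

import vncstudy as v


def study_args(description: str):
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=11,
                        help="master seed for every stochastic stage")
    parser.add_argument("--n-patients", type=int, default=20)
    parser.add_argument("--out", type=Path, default=Path("results"),
                        help="directory for output tables")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    return args


def default_config(args) -> "v.RunConfig":
    return v.RunConfig(n_patients=args.n_patients, seed=args.seed)
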