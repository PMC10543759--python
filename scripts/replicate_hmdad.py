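#!/usr/bin/env python
"""Pair-scheme cross-validation on a real HMDAD snapshot (manual run).

This script is NOT part of the test suite: it needs a locally downloaded
copy of the HMDAD microbe-disease association list (http://www.cuilab.cn/hmdad),
saved as a two-column edge list (disease, microbe; TSV or CSV). Expected
scale: 450 associations between 39 diseases and 292 microbes.

    python scripts/replicate_hmdad.py --edges hmdad_edges.tsv \
        [--repeats 5] [--seed 1] [--out cv_hmdad.tsv]

With full per-fold retraining this takes a while (minutes per repeat on one
CPU); reported mean AUC is expected in the neighbourhood of the mid-0.9s
for the pair scheme, with run-to-run spread from the stochastic training.
"""

from __future__ import annotations

import argparse
import logging

from mdalink import CVConfig, GateConfig, load_associations, run_cv
from mdalink.data_io import write_matrix
from mdalink.dnn import DnnConfig
from mdalink.pipeline import PipelineConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--edges", required=True,
                        help="downloaded HMDAD edge list (disease, microbe)")
    parser.add_argument("--repeats", type=int, default=5)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--gate-epochs", type=int, default=200)
    parser.add_argument("--dnn-epochs", type=int, default=300)
    parser.add_argument("--out", default=None,
                        help="optional TSV of fold-level metrics")
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO)

    assoc = load_associations(args.edges)
    print(f"loaded {assoc.n_associations} associations, "
          f"{assoc.n_diseases} diseases x {assoc.n_microbes} microbes")

    config = PipelineConfig(gate=GateConfig(epochs=args.gate_epochs),
                            dnn=DnnConfig(epochs=args.dnn_epochs),
                            seed=args.seed)
    result = run_cv(assoc, config,
                    CVConfig(scheme="pair", n_folds=5,
                             repeats=args.repeats, seed=args.seed))
    print(f"pair CV: AUC {result.mean_auc:.4f} +/- {result.std_auc:.4f}, "
          f"AUPR {result.mean_aupr:.4f} +/- {result.std_aupr:.4f}")
    if args.out:
        write_matrix(result.summary().set_index("repeat"), args.out)


if __name__ == "__main__":
    main()
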