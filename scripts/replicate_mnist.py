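#!/usr/bin/env python
"""Full-scale MNIST replication protocols (optional; hours of runtime).

Requires the uncompressed MNIST IDX files
(train-images-idx3-ubyte, train-labels-idx1-ubyte, t10k-images-idx3-ubyte,
t10k-labels-idx1-ubyte) in --data-dir.

Protocols:
  5-class:  digits 0-4, groups of 20 excitatory neurons, 15,000 training
            patterns over 2 epochs, 5,000 + 5,000 evaluation patterns.
  10-class: all digits, groups of 10, 15,000 training patterns over
            4 epochs, 10,000 + 10,000 evaluation patterns.

Usage:
    python scripts/replicate_mnist.py --data-dir mnist/ --protocol 10class \
        --seed 0 --out results/mnist_10class
"""

from __future__ import annotations

import argparse
import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from spikefix.config import RunConfig  # noqa: E402
from spikefix.engine import SimConfig  # noqa: E402
from spikefix.experiments import run_experiment  # noqa: E402

PROTOCOLS = {
    "5class": dict(n_classes=5, group_size=20, n_train=15_000, epochs=2,
                   n_eval_train=5_000, n_eval_test=5_000),
    "10class": dict(n_classes=10, group_size=10, n_train=15_000, epochs=4,
                    n_eval_train=10_000, n_eval_test=10_000),
}


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", required=True)
    ap.add_argument("--protocol", choices=PROTOCOLS, default="10class")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--precision", default="fixed16")
    ap.add_argument("--out", required=True, help="output directory")
    args = ap.parse_args(argv)

    run = RunConfig.from_dict({"precision": args.precision})
    cfg = SimConfig(run=run, mode="train", seed=args.seed)
    proto = PROTOCOLS[args.protocol]
    tr, te = run_experiment("mnist", cfg=cfg, data_dir=args.data_dir,
                            **proto)
    os.makedirs(args.out, exist_ok=True)
    tr.save(os.path.join(args.out, "train_subset_result.json"))
    te.save(os.path.join(args.out, "test_subset_result.json"))
    summary = {"protocol": args.protocol, "seed": args.seed,
               "precision": args.precision,
               "train_subset_accuracy": tr.accuracy,
               "test_subset_accuracy": te.accuracy}
    with open(os.path.join(args.out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
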