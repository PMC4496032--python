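#!/usr/bin/env python
"""Train one GA-BP-ANN hybrid model per cultivar.

Reconstructs the 108 replicate-level pairs, draws the 90/18 split, runs
the hybrid optimizer at the default configuration, reports training and
held-out RMSE, and serializes the best network of each run under
results/models/ for the mapping step.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

from thermogerm import evaluation as ev
from thermogerm import germination_data as gd
from thermogerm.ga_optimizer import GAConfig, evolve
from thermogerm.response_models import save_model

OUT = pathlib.Path("results")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    (OUT / "models").mkdir(parents=True, exist_ok=True)
    rows = []
    for cultivar in gd.CULTIVARS:
        rep = np.asarray(gd.to_pairs(gd.builtin_table(cultivar), "replicate"))
        split = ev.split_train_test(rep, seed=args.seed)
        run = evolve(
            rep[list(split.train_idx)],
            rep[list(split.test_idx)],
            config=GAConfig(seed=args.seed),
        )
        net = run.best_genome.to_network()
        slug = cultivar.lower().replace(" ", "_")
        save_model(
            net, OUT / "models" / f"{slug}_ga_bp_ann.txt",
            metadata={"cultivar": cultivar, "seed": args.seed,
                      "train_rmse": f"{run.best_fitness:.4f}",
                      "test_rmse": f"{run.test_rmse:.4f}"},
        )
        rows.append({
            "cultivar": cultivar,
            "n_hidden": net.n_hidden,
            "rmse_train": round(run.best_fitness, 4),
            "rmse_test": round(run.test_rmse, 4),
            "generations": len(run.history_best),
            "seed": args.seed,
        })
        print(f"{cultivar}: H={net.n_hidden}, train RMSE "
              f"{run.best_fitness:.4f}, held-out RMSE {run.test_rmse:.4f}")
    pd.DataFrame(rows).to_csv(OUT / "ga_training.csv", index=False)
    print(f"\nwrote {OUT / 'ga_training.csv'} and results/models/*_ga_bp_ann.txt")


if __name__ == "__main__":
    main()
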