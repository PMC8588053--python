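#!/usr/bin/env python
"""Bootstrap hold-out classification for all six membrane-pair/mode combinations.

For each pair the larger-MWCO membrane is the positive class; ten
Monte-Carlo datasets are drawn from the fixture Gammas, each split 80%
evaluation : 20% training, and AUC / accuracy / Youden aggregated over
replicates.  A single raw draw per pair provides the raw-vs-bootstrap
agreement check.  Writes replicate_auc.csv.
"""

import argparse
import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from afmpore import (
    MODE_DESIGN,
    PairConfig,
    ReportBundle,
    agreement_check,
    fixture_gamma_params,
    roc_curve,
    run_pair_classification,
    run_report,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-datasets", type=int, default=10)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    rows = []
    for mode in ("tapping", "fluid"):
        n, _ = MODE_DESIGN[mode]
        for small, large in itertools.combinations((50, 100, 1000), 2):
            ga, gb = fixture_gamma_params(mode, small), fixture_gamma_params(mode, large)
            cfg = PairConfig(
                gamma_a=ga, gamma_b=gb, n_a=n, n_b=n,
                n_datasets=args.n_datasets, eval_fraction=0.8, seed=args.seed,
            )
            summary = run_pair_classification(cfg)
            # raw-data analogue: one direct draw at the experimental design,
            # scored on the pore radius itself
            rng = np.random.default_rng([args.seed, 777])
            xa = rng.gamma(ga.shape_a, ga.scale_b, n)
            xb = rng.gamma(gb.shape_a, gb.scale_b, n)
            raw = roc_curve(
                np.concatenate([xa, xb]), np.concatenate([np.zeros(n), np.ones(n)])
            )
            rows.append(
                dict(
                    mode=mode, comparison=f"{small} vs {large} kDa",
                    auc_mean=round(summary.auc_mean, 4), auc_sd=round(summary.auc_sd, 4),
                    acc_mean=round(summary.acc_mean, 4), acc_sd=round(summary.acc_sd, 4),
                    youden_mean=round(summary.youden_mean, 4),
                    raw_auc=round(raw.auc, 4),
                    agreement=agreement_check(raw.auc, summary.auc_mean, summary.auc_sd),
                )
            )
    table = pd.DataFrame(rows)
    run_report(ReportBundle(replicate_auc_table=table), args.outdir)
    print(table.to_string(index=False))
    print(
        "\nAUC categories per the discrimination scale are in the written "
        "table. The generating Gammas are recovered from published mean/"
        "skewness pairs only; they overlap far more than the raw laboratory "
        "data (and the extreme fluid 1000 kDa skewness even reverses the "
        "median ordering), so absolute AUCs here are not comparable to the "
        "laboratory values — see the methods note."
    )


if __name__ == "__main__":
    main()
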