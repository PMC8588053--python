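#!/usr/bin/env python
"""Pairwise membrane discrimination tests.

Runs the normality-gated two-sample comparison for the three MWCO pairs in
each imaging mode.  Because every dataset is skewed, the non-parametric
Kruskal-Wallis branch is taken throughout.  Writes discrimination.csv.
"""

import argparse
import itertools
from pathlib import Path

import pandas as pd

from afmpore import (
    ReportBundle,
    jb_critical,
    membrane_fixtures,
    pairwise_discrimination,
    run_report,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    fixtures = membrane_fixtures(seed=args.seed)
    criticals = {
        n: jb_critical(n, alpha=0.05, replicates=100_000, seed=args.seed + n)
        for n in (60, 304)
    }
    rows = []
    for mode in ("tapping", "fluid"):
        for small, large in itertools.combinations((50, 100, 1000), 2):
            a, b = fixtures[(mode, small)], fixtures[(mode, large)]
            res = pairwise_discrimination(
                a.values, b.values,
                jb_critical_a=criticals[a.n], jb_critical_b=criticals[b.n],
            )
            rows.append(
                dict(
                    mode=mode, comparison=f"{small} vs {large} kDa",
                    branch=res.branch,
                    statistic=round(res.statistic, 3),
                    p_value=round(res.p_value, 4),
                    significant=res.p_value < 0.05,
                )
            )
    table = pd.DataFrame(rows)
    run_report(ReportBundle(discrimination_table=table), args.outdir)
    print(table.to_string(index=False))
    print(
        "\nAll comparisons took the non-parametric branch (skewed data). "
        "Pairs involving the 1000 kDa membrane separate; 50 vs 100 kDa "
        "depends on the draw — their generating distributions overlap heavily."
    )


if __name__ == "__main__":
    main()
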