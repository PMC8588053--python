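#!/usr/bin/env python
"""Theoretical Stokes radii, measurement accuracy errors and the swelling scan.

Computes the sphere-model pore radius for each membrane cutoff, compares the
published mean measured radii against it (relative and absolute accuracy
error per mode), and scans the hypothetical hydrogel swelling ratio 50-200%
to ask whether a common swollen state could explain the departures.

Writes reference_errors.csv and swelling_scan.csv to --outdir.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from afmpore import FIXTURE_MOMENTS, accuracy_errors, stokes_radius_kda, swelling_error_scan


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for mode in ("tapping", "fluid"):
        for mwco in (1000, 100, 50):
            # errors are quoted against the tabulated 1-dp radius
            rp = round(stokes_radius_kda(mwco), 1)
            measured = FIXTURE_MOMENTS[(mode, mwco)][0]
            err = accuracy_errors(measured, rp)
            rows.append(
                dict(
                    mode=mode, mwco_kda=mwco,
                    stokes_radius_nm=rp,
                    measured_mean_nm=measured,
                    relative_error_pct=err.relative_percent_display,
                    absolute_error_nm=err.absolute_nm_display,
                )
            )
    ref = pd.DataFrame(rows)
    ref.to_csv(args.outdir / "reference_errors.csv", index=False)

    sr_grid = np.round(np.arange(0.5, 2.01, 0.25), 10)
    scan_rows = []
    for mwco in (1000, 100, 50):
        rp = round(stokes_radius_kda(mwco), 1)
        measured = FIXTURE_MOMENTS[("fluid", mwco)][0]
        scan = swelling_error_scan(measured, rp, sr_grid)
        for sr, err in zip(scan.sr_grid, scan.abs_error):
            scan_rows.append(
                dict(mwco_kda=mwco, swelling_ratio=sr, abs_error_nm=round(float(err), 3))
            )
    pd.DataFrame(scan_rows).to_csv(args.outdir / "swelling_scan.csv", index=False)

    print(ref.to_string(index=False))
    print(
        "\nRelative accuracy error grows as the pore shrinks "
        "(lowest for 1000 kDa in each mode), consistent with a resolution "
        "floor near 5 nm."
    )
    scan50 = [r for r in scan_rows if r["mwco_kda"] == 50]
    best = min(scan50, key=lambda r: r["abs_error_nm"])
    print(
        f"50 kDa fluid swelling scan: minimum |error| {best['abs_error_nm']:.1f} nm "
        f"at SR = {best['swelling_ratio']:.0%} — swelling alone cannot reconcile "
        "all three membranes at a common ratio."
    )


if __name__ == "__main__":
    main()
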