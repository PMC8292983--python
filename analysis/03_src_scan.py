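#!/usr/bin/env python
"""Scan the cellular Src concentration with and without feedback coupling.

Sweeps total Src over four orders of magnitude for wild-type Src and for
the SH2/SH3-deleted variant (which cannot bind phospho-LAT), measuring the
lit/dark pLAT contrast at steady state.  Reports the contiguous range of
Src concentrations over which the circuit still discriminates clustered
from unclustered LAT by at least 10-fold.
"""

import argparse
from pathlib import Path

import numpy as np

from clusterfb import ModelParameters, scan, src_contrast_range


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--n-grid", type=int, default=33)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    params = ModelParameters()
    values = np.logspace(-3, 1, args.n_grid)

    wt = scan("src_cyt", values, params)
    wt.to_frame().to_csv(args.out_dir / "src_scan_wt.csv", index=False)
    lo, hi, decades = src_contrast_range(wt, 10.0)

    dsh2 = scan("src_cyt", values, params, scenario="src_dsh2dsh3")
    dsh2.to_frame().to_csv(args.out_dir / "src_scan_dsh2dsh3.csv", index=False)
    _, _, dec2 = src_contrast_range(dsh2, 10.0)

    print(
        f"Wild-type Src maintains >=10x lit/dark pLAT contrast over "
        f"[{lo:.3g}, {hi:.3g}] uM Src = {decades:.2f} orders of magnitude."
    )
    print(
        f"The feedback-disconnected variant achieves 10x contrast over "
        f"{dec2:.2f} orders of magnitude (max contrast "
        f"{np.max(dsh2.lit_plat_frac / dsh2.dark_plat_frac):.2f}x): without "
        f"SH2-mediated recruitment the circuit cannot sense clustering."
    )


if __name__ == "__main__":
    main()
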