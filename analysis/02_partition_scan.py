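#!/usr/bin/env python
"""Scan the degree of light-induced clustering (partition coefficient K).

Sweeps K over a log grid from 1 to 100 in the clustering construct,
computing dark and lit steady-state phospho-fractions, and reports the K at
which the lit response first reaches 90% of its large-K plateau.
"""

import argparse
from pathlib import Path

import numpy as np

from clusterfb import ModelParameters, k_at_fraction_of_plateau, scan


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--n-grid", type=int, default=241)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    params = ModelParameters()
    kvals = np.logspace(0, 2, args.n_grid)
    res = scan("partition_k_light", kvals, params)
    res.to_frame().to_csv(args.out_dir / "partition_scan.csv", index=False)

    k90 = k_at_fraction_of_plateau(res, 0.9)
    print(
        f"Lit pLAT fraction rises monotonically with K from "
        f"{res.lit_plat_frac[0]:.3f} (K=1) to {res.lit_plat_frac[-1]:.3f} "
        f"(K=100), reaching 90% of the plateau at K = {k90:.2f} "
        f"(~10-fold LAT concentration)."
    )


if __name__ == "__main__":
    main()
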