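#!/usr/bin/env python
"""Titrate the Src inhibitor PP2 and demonstrate inhibition-constant fitting.

Computes the steady lit pLAT dose-response for wild-type and
feedback-disconnected Src, then generates noisy synthetic observations from
the wild-type curve and fits (K_I, amplitude) back by least squares,
reporting the recovered inhibition constant.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from clusterfb import (
    DoseResponse,
    ModelParameters,
    effective_dose_range,
    fit_dose_response,
    gen_noisy_readouts,
    pp2_titration,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--noise-sd", type=float, default=0.05)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    params = ModelParameters()
    doses = np.concatenate(([0.0], np.logspace(-2, 2, 33)))

    wt = pp2_titration(doses, params)
    wt.to_frame().to_csv(args.out_dir / "pp2_titration_wt.csv", index=False)
    dsh2 = pp2_titration(doses, params, scenario="src_dsh2dsh3")
    dsh2.to_frame().to_csv(
        args.out_dir / "pp2_titration_dsh2dsh3.csv", index=False
    )

    r_wt = effective_dose_range(wt)
    r_ds = effective_dose_range(dsh2)
    print(
        f"pLAT stays above half its drug-free value up to {r_wt:.2f} uM PP2 "
        f"for wild-type Src vs {r_ds:.2f} uM for the feedback-disconnected "
        f"variant ({r_wt / r_ds:.1f}x wider effective range with feedback)."
    )

    fit_doses = np.logspace(-1.5, 1.5, 8)
    df = gen_noisy_readouts(
        params, "ilid_drop", fit_doses, noise_sd=args.noise_sd, seed=args.seed
    )
    df.to_csv(args.out_dir / "pp2_noisy_observations.csv", index=False)
    obs = DoseResponse(
        pp2_concs=df["pp2_um"].to_numpy(), plat_frac=df["observed"].to_numpy()
    )
    fit = fit_dose_response(obs, params, exact_polish=True)
    out = {
        "true_ki_pp2_um": params.ki_pp2,
        "fitted_ki_pp2_um": fit.ki_pp2,
        "fitted_amplitude": fit.amplitude,
        "residual_ss": fit.residual,
        "at_bound": fit.at_bound,
        "noise_sd": args.noise_sd,
        "seed": args.seed,
    }
    (args.out_dir / "pp2_fit.json").write_text(json.dumps(out, indent=2) + "\n")
    print(
        f"Recovered K_I = {fit.ki_pp2:.3f} uM from {args.noise_sd:.0%}-noise "
        f"observations (truth {params.ki_pp2:.3f} uM, "
        f"error {abs(fit.ki_pp2 - params.ki_pp2) / params.ki_pp2:.1%})."
    )


if __name__ == "__main__":
    main()
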