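#!/usr/bin/env python
"""Simulate the six experimental regimes through the dark-to-light protocol.

For each regime (clustering construct, dimer-only control, constitutive
kinase, kinase-dead, non-phosphorylatable LAT, feedback-disconnected Src)
the model is equilibrated in the dark and illuminated for 20 min.  Writes
tidy per-scenario timecourses and an endpoint summary, and prints the
qualitative findings: strong induction requires clustering, an active
kinase, a phosphorylatable substrate, and an SFK that can engage the
feedback loop.
"""

import argparse
from pathlib import Path

import pandas as pd

from clusterfb import (
    LightProtocol,
    ModelParameters,
    run_six_scenarios,
    six_scenario_summary,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    params = ModelParameters()
    protocol = LightProtocol()
    results = run_six_scenarios(params, protocol)

    frames = [tc.to_frame(scenario=name) for name, (_, tc) in results.items()]
    tidy = pd.concat(frames, ignore_index=True)
    tidy.to_csv(args.out_dir / "six_scenarios_timecourses.csv", index=False)

    summary = six_scenario_summary(results, params)
    summary.to_csv(args.out_dir / "six_scenarios_summary.csv", index=False)
    params.to_json(args.out_dir / "six_scenarios_params.json")

    print("Endpoint phospho-fractions after 20 min of light vs dark:\n")
    print(summary.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    s = summary.set_index("scenario")
    print(
        f"\nOnly the clustering construct ignites the feedback loop "
        f"(lit/dark pLAT {s.loc['ilid_drop', 'lit_dark_plat_ratio']:.0f}x); "
        f"the one-to-one dimer stays near zero "
        f"({s.loc['ilid_only', 'lit_plat_frac']:.3f}), the constitutive "
        f"kinase signals without clustering "
        f"({s.loc['zap70_k362e', 'lit_plat_frac']:.3f}), and the "
        f"feedback-disconnected SFK is light-insensitive "
        f"(ratio {s.loc['src_dsh2dsh3', 'lit_dark_plat_ratio']:.2f})."
    )


if __name__ == "__main__":
    main()
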