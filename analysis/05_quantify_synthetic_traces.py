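#!/usr/bin/env python
"""Generate synthetic biosensor data and run the quantification pipeline.

Builds a labeled calcium-trace corpus (sustained responders, transient
blinkers, non-responders), KTR cytoplasm/nucleus pairs, and membrane images
with and without clusters; then runs the sustained-response classifier, the
AUC statistics, and the membrane-CV clustering metric against their ground
truth.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from clusterfb import (
    MaskedStack,
    SynthSpec,
    auc,
    cn_ratio,
    gen_cluster_images,
    gen_gcamp_traces,
    gen_ktr_traces,
    membrane_cv_timeseries,
    quantify_traces,
    traces_to_frame,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-cells", type=int, default=1000)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    # --- calcium corpus and classifier -------------------------------
    spec = SynthSpec(
        seed=args.seed, n_cells=args.n_cells, responder_fraction=0.3,
        blinker_fraction=0.3, noise_sd=0.05,
    )
    traces, labels = gen_gcamp_traces(spec)
    table = traces_to_frame(traces, field_id="synthetic")
    per_cell, per_field = quantify_traces(table, protocol="jurkat")
    per_cell = per_cell.merge(
        pd.DataFrame({"cell_id": [t.cell_id for t in traces], "label": labels}),
        on="cell_id",
    )
    per_cell.to_csv(args.out_dir / "gcamp_per_cell.csv", index=False)
    per_field.to_csv(args.out_dir / "gcamp_per_field.csv", index=False)

    truth = per_cell["label"] == "responder"
    calls = per_cell["sustained"].astype(bool)
    sens = (calls & truth).sum() / truth.sum()
    spec_ = (~calls & ~truth).sum() / (~truth).sum()
    print(
        f"Sustained-response classifier on {args.n_cells} labeled traces: "
        f"sensitivity {sens:.3f}, specificity {spec_:.3f}; "
        f"fraction responding {per_field['fraction_responding'].iloc[0]:.3f} "
        f"(true responder fraction 0.30)."
    )

    # --- KTR AUC accuracy ---------------------------------------------
    kspec = SynthSpec(seed=args.seed + 1, n_cells=200, responder_fraction=0.5,
                      blinker_fraction=0.0, noise_sd=0.05, dt=15.0,
                      duration=900.0)
    pairs, klabels, true_aucs = gen_ktr_traces(kspec)
    measured = np.array([auc(cn_ratio(c, n)) for c, n in pairs])
    ktr = pd.DataFrame(
        {"cell_id": [c.cell_id for c, _ in pairs], "label": klabels,
         "true_auc": true_aucs, "measured_auc": measured}
    )
    ktr.to_csv(args.out_dir / "ktr_aucs.csv", index=False)
    err = np.abs(measured - true_aucs)
    print(
        f"KTR C/N AUC on the 61-point grid: mean |error| {err.mean():.2f} "
        f"(responder true AUC {true_aucs.max():.1f})."
    )

    # --- membrane clustering metric -----------------------------------
    ispec = SynthSpec(seed=args.seed + 2)
    pre, post = gen_cluster_images(ispec)
    stack = MaskedStack(
        np.concatenate([pre.frames, post.frames]), pre.membrane_mask
    )
    dcv = membrane_cv_timeseries(stack)
    pd.DataFrame({"frame": range(len(dcv)), "delta_cv": dcv}).to_csv(
        args.out_dir / "membrane_delta_cv.csv", index=False
    )
    print(
        f"Membrane CV metric: dCV = {dcv[1]:.3f} after cluster formation "
        f"(total masked intensity conserved), 0 by construction before."
    )


if __name__ == "__main__":
    main()
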