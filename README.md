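# clusterfb

**Clustering-gated positive feedback in a minimal Zap70 / LAT / Src kinase
circuit.**

Protein clustering is everywhere in cell signaling, but it is hard to say
whether clusters *cause* signaling or merely accompany it.  A clean way to
ask the question is a synthetic circuit in which the kinase Zap70 and its
scaffold substrate LAT can be switched, by light, between one-to-one
heterodimers and higher-order membrane clusters.  Experimentally, clusters
ignite downstream signaling and dimers do not; the mechanism is a
three-component positive feedback loop in which phosphorylated LAT recruits
an Src-family kinase through its SH2 domain, the recruited (and thereby
activated) Src phosphorylates more Zap70, and active Zap70 phosphorylates
more LAT.

This package is for modelers and quantitative biologists who want to
simulate, perturb, and fit that circuit, and to run the matching single-cell
quantification statistics.  It provides:

* `clusterfb.model` / `clusterfb.dynamics` — the two-compartment kinetic
  model: clustering as a `K`-fold shrinkage of the membrane compartment
  (`[LAT] = K·[LAT]0`), equilibrium tethering
  (`[Zap70] = [LAT]·f + [Zap70]0`, `f = [Zap70]0·KA/(1+[Zap70]0·KA)`),
  equilibrium Src activation by pLAT
  (`[Src]a = [pLAT]·[Src]0·KA/(1+[Src]0·KA)`), Michaelis–Menten
  phosphorylation with first-order dephosphorylation, non-competitive PP2
  inhibition (`kcat·K_I/(K_I+[PP2])`), stiff-capable integration, steady
  states, and the dark→light stimulation protocol.
* `clusterfb.scenarios` — the seven experimental regimes (clustering
  construct, dimer-only, constitutive Zap70-K362E, kinase-dead,
  non-phosphorylatable LAT, SH2/SH3-deleted Src, and LAT clustering without
  Zap70 recruitment), parameter scans over the partition coefficient and the
  Src concentration, PP2 titrations, and least-squares dose-response
  fitting.
* `clusterfb.quantify` — biosensor trace statistics: KTR cytoplasm/nucleus
  ratio, baselined-sum AUC, GCaMP min-normalization, the ≥30 s
  sustained-response classifier, per-field responder fractions, and the
  membrane coefficient-of-variation clustering metric.
* `clusterfb.synthetic` — seeded generators for labeled calcium traces,
  KTR pairs with analytic AUCs, membrane images with conserved-intensity
  cluster formation, and noisy model readouts for parameter recovery.

The analysis drivers under `analysis/` reproduce the figure-level results
in order and write their tables to `results/`.

## Worked example

Simulate the six regimes through dark equilibration and 20 min of light:

```bash
python analysis/01_simulate_scenarios.py
```

```
Endpoint phospho-fractions after 20 min of light vs dark:

    scenario  dark_plat_frac  lit_plat_frac  dark_pzap_frac  lit_pzap_frac  lit_dark_plat_ratio
   ilid_drop          0.0018         0.8925          0.0033         0.6320             492.4528
   ilid_only          0.0018         0.0049          0.0033         0.0020               2.6899
 zap70_k362e          0.0079         0.0826          0.0047         0.0191              10.5107
    zap70_kd          0.0000         0.0000          0.0029         0.0001                  NaN
     lat_fff          0.0000         0.0000          0.0029         0.0001                  NaN
src_dsh2dsh3          0.0016         0.0016          0.0029         0.0001               1.0136
```

Reading the table: `lit_plat_frac` is the steady phosphorylated fraction of
the LAT pool under illumination.  Only the clustering construct
(`ilid_drop`) ignites the feedback loop — 89% of LAT phosphorylated, ~500×
its dark level.  The same tethering without clustering (`ilid_only`) stays
below 1%; a weakly constitutively active kinase (`zap70_k362e`) bypasses the
clustering requirement; killing the kinase (`zap70_kd`) or the substrate
(`lat_fff`) abolishes the response entirely; and an Src that cannot bind
pLAT (`src_dsh2dsh3`) is blind to light.

The same circuit from the library:

```python
import numpy as np
from clusterfb import ModelParameters, scan, k_at_fraction_of_plateau

params = ModelParameters()                      # calibrated defaults
res = scan("partition_k_light", np.logspace(0, 2, 49), params)
print(k_at_fraction_of_plateau(res, 0.9))       # -> 10.0
```

i.e. the lit pLAT fraction rises monotonically with the degree of
clustering and plateaus once LAT is concentrated about ten-fold — the
model's quantitative statement of *how much* clustering the switch needs.
The other drivers report that wild-type Src holds a ≥10× lit/dark contrast
across 2.25 orders of magnitude of Src concentration (robustness), that
the feedback-competent circuit tolerates ~8× more of the Src inhibitor PP2
before losing half its response, and that the inhibition constant is
recovered from 5%-noise synthetic dose-response data to within a few
percent.

## Layout

```
src/clusterfb/     model_core, dynamics, scenarios, quantify, synthetic, I/O
analysis/          numbered drivers reproducing the figure-level analyses
tests/             pytest suite (unit, property, and acceptance tests)
scripts/           acceptance.py
docs/methods.md    model assumptions, calibration, numerics, limitations
```
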