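# Methods

## The model

`clusterfb` implements a deterministic two-compartment kinetic model of a
three-protein signaling circuit: the transmembrane scaffold LAT, its kinase
Zap70, and an Src-family kinase (SFK, "Src" below).  The membrane/cluster
compartment holds LAT and everything bound to it; the cytosol holds free
Zap70 and Src at fixed concentrations (the cell is an infinite reservoir for
both).  Two optogenetic perturbations enter the model:

* **Tethering.**  Blue light tightens the iLID/SspB heterodimerization that
  links Zap70 to LAT.  Binding is fast relative to phosphorylation and is
  treated as an equilibrium: a fraction
  `f = [Zap70]0·KA / (1 + [Zap70]0·KA)` of LAT molecules carry a tethered
  Zap70, and free Zap70 additionally diffuses into the compartment at its
  cytosolic concentration, so the membrane Zap70 pool is
  `[Zap70] = [LAT]·f + [Zap70]0`.
* **Clustering.**  Cluster formation is modeled as the membrane compartment
  volume shrinking by a partition coefficient `K >= 1`, which concentrates
  LAT and all LAT-bound species: `[LAT] = K·[LAT]0`.

Four phospho-pools are integrated in time: membrane pZap70, cytosolic
pZap70, and pLAT split into a Zap70-bound and a free pool.  The reactions:

* Zap70 is phosphorylated by **active Src** (Michaelis–Menten, fast) and by
  **autoinhibited free Src** (Michaelis–Menten, slow — the "leaky" basal
  activity present in the dark).  Active Src is the equilibrium pool bound
  to phospho-LAT via its SH2 domain,
  `[Src]a = [pLAT]·[Src]0·KA_SH2 / (1 + [Src]0·KA_SH2)`; binding releases
  autoinhibition.  The substrate of this equilibrium is the *total*
  phosphorylated LAT (bound + free pools): the mechanism is SH2
  engagement of phosphotyrosine, which does not depend on whether the LAT
  molecule also carries a tethered Zap70.
* LAT is phosphorylated by membrane pZap70 (Michaelis–Menten) and, for the
  Zap70-bound pool only, by its own tethered pZap70 at first order
  (`k_tethered` times the pool of bound complexes whose Zap70 is
  phosphorylated, taken as the bound unphosphorylated LAT times the
  membrane phospho-fraction `pZap70/[Zap70]`).
* Both species dephosphorylate constitutively at first order.
* The inhibitor PP2 is non-competitive: both Src catalytic constants are
  scaled by `K_I / (K_I + [PP2])`.

This wiring contains a positive feedback loop — pLAT recruits and activates
Src, active Src makes more pZap70, pZap70 makes more pLAT — whose loop gain
scales with the product of the membrane Zap70 and LAT concentrations and
therefore roughly with `K²` under clustering.  That super-linear dependence
is what makes the circuit a clustering detector: at the calibrated operating
point the loop gain crosses 1 between the unclustered (`K = 1`) and
clustered (`K = 10`) configurations.

### Scenarios

Seven experimental regimes are encoded as deterministic equation
modifications (`apply_scenario`); the base parameters are never mutated —
transforms are applied at evaluation time (`effective_parameters`), which
makes scenario construction idempotent.

| scenario | modification |
|---|---|
| `ilid_drop` | base clustering construct (identity) |
| `ilid_only` | light-insensitive clustering domain: `K = 1` in both light states |
| `zap70_k362e` | weak constitutive kinase in the non-clustering configuration: both Zap70 phospho-forms phosphorylate LAT, kcat ×0.1, KM ×10 |
| `zap70_kd` | kinase-dead: LAT phosphorylation rate constants set to 0 |
| `lat_fff` | non-phosphorylatable LAT: no Src binding to pLAT and no LAT phosphorylation |
| `src_dsh2dsh3` | feedback-disconnected SFK: no SH2 binding to pLAT, free-Src kcat ×10, total Src ×0.1 |
| `jurkat_no_recruitment` | clustering without a Zap70 tether (`KA_iLID = 0`); pZap70 pools seeded at `basal_pzap70_frac` of their totals |

The K362E factors (0.1×, 10×) and the SH2/SH3-deletion factors (10×, 0.1×)
are free modeling choices, configurable per run; `k_tethered` is scaled by
the same 0.1× factor as the K362E kcat so the mutant kinase is uniformly
weaker in both phosphorylation mechanisms.

### Parameters, units, defaults

Concentrations are µM, time is seconds, association constants 1/µM; volumes
never appear explicitly (only `K`).  The default set is a calibration, not a
measurement.  Anchored values: lit iLID-SspB K_D = 0.1 µM with a 100-fold
looser dark state (the measured photo-switching of that pair), SH2–pY
K_D = 1 µM (typical of that interaction class), `K = 10` in the lit
clustered state (protein condensates concentrate their clients roughly
ten-fold).  The remaining rate constants were calibrated jointly so that the
default model reproduces the figure-level behaviors: strong light induction
only for the clustering construct; near-zero induction for the dimer-only,
kinase-dead, and non-phosphorylatable variants; signaling plateau at
~10-fold LAT concentration; a ≥2-decade Src-concentration range of ≥10×
lit/dark contrast; and a small but nonzero dark pZap70 pool (leaky SFK
activity).  The calibrated values (see `ModelParameters`):

```
lat_total=1.0  zap70_cyt=0.3  src_cyt=0.05          (µM)
ka_ilid_dark=0.1  ka_ilid_light=10  ka_sh2=1        (1/µM)
kcat_src_active=5.2  km_src_active=10               (1/s, µM)
kcat_src_inactive=0.002  km_src_inactive=0.02       (1/s, µM)
kcat_pzap70=8.0  km_pzap70=100  k_tethered=0.05     (1/s, µM, 1/s)
kdeph_zap70=0.1  kdeph_lat=0.05                     (1/s)
ki_pp2=1.0                                          (µM)
partition_k_light=10
```

Three calibration trade-offs are worth recording.  (i) The dark membrane
Zap70 pool (`zap70_cyt` plus the weakly bound fraction) caps how much LAT a
fully ignited *dark* state can phosphorylate; keeping that capacity about
ten-fold below the lit response is what buys the two-decade Src robustness
window.  (ii) A large `km_pzap70` keeps LAT phosphorylation near-linear in
substrate so the loop gain scales almost as `K²`, maximizing the clustered /
unclustered separation.  (iii) The feedback-disconnected Src variant
consequently sits at its basal (dark) level under both illumination states
rather than at a mid-range plateau; this matches the corresponding
experiment (similar phosphorylation in dark and light, never reaching the
lit wild-type level), and a literal mid-range level would be incompatible
with (i), because the same leaky activity that would raise it also raises
the wild-type dark state at high Src.

### Numerics

* Integrator: LSODA (stiff-capable, adaptive) at `rtol=1e-8`, `atol=1e-10`.
  The feedback makes the system stiff near the ignition threshold.
  Tolerances are recorded in every timecourse's metadata sidecar.
* Steady state: long integration (at least 10× the slowest
  dephosphorylation timescale, doubling on failure) followed by Newton
  polishing, accepted when `max|d/dt| < 1e-9 µM/s`.  Which basin is reached
  depends on the initial state; `hysteresis_probe` reports the steady states
  from both an all-zero and a fully phosphorylated start and flags any
  disagreement instead of averaging.  Scans always approach the lit state
  from the dark steady state through the light switch, i.e. along the
  physically accessible branch.
* Light switch: the dark steady state (from all-zero phospho, except the
  no-recruitment scenario's basal seed) is remapped at the switch.
  Compartment shrinkage concentrates every LAT species `K`-fold, so total
  pLAT is multiplied by `K_new/K_old` (the phospho-*fraction* of LAT is
  continuous) and redistributed between bound and free pools by the new
  equilibrium bound fraction; membrane pZap70 keeps its concentration, with
  newly recruited Zap70 arriving at the cytosolic phospho-fraction, clipped
  to the new pool bounds.
* Dose-response fitting: PP2 enters the model only through the single scale
  factor `s = K_I/(K_I+[PP2])` applied to both Src kcats, so the whole
  (K_I, dose) family of model curves collapses onto one function of `s`.
  `fit_dose_response` precomputes that function on a dense log grid
  (160 steady-state solves), interpolates it monotonically (PCHIP), and runs
  a deterministic multi-start least-squares over the dose grid; an optional
  exact-polish step re-optimizes the best start against direct model solves,
  recovering noiseless data to solver precision.

### Open structural points, implemented literally

The membrane and cytosolic pZap70 pools do not exchange mass even though
Zap70 binding is at equilibrium; whether dissociating phospho-Zap70 carries
its phospho-state back to the cytosol is left unmodeled, and the single
membrane phospho-variable covers both tethered and free-diffusing Zap70 in
the compartment.  Spatial cluster nucleation, droplet coarsening, multi-site
LAT phosphorylation, explicit phosphatases, and the receptor-level module
upstream of LAT are out of scope.

## Quantification statistics

* **KTR C/N ratio**: per-timepoint `(cyto − bg)/(nuc − bg)`; a
  non-positive denominator flags the point as missing (NaN), never clipped.
* **AUC**: the baselined plain sum `Σ_t (value_t − value_0)` over the
  sampling grid — deliberately *not* a trapezoidal integral.  The default
  fibroblast protocol is 61 points at 15 s; a unit step after t=0 gives
  exactly 60.
* **GCaMP normalization**: background-subtracted trace divided by its own
  minimum, so the trace minimum maps to exactly 1 and the statistic is
  invariant to multiplicative intensity scaling.
* **Sustained-response classifier** (T-cell protocol, 5 s sampling over
  3 min): a trace is a sustained responder iff its maximum exceeds a noise
  threshold AND some *consecutive* run of samples at or above half the
  trace maximum spans ≥ 30 s.  A run of n samples spans (n−1)·dt, so 7
  samples are needed at 5 s; cumulative non-consecutive time is not
  counted, which is what separates responses from single-frame "blinking".
  The default noise threshold is `1 + 8·σ̂`, where `σ̂` is a robust
  per-sample noise SD estimated from the median absolute successive
  difference of the normalized trace.  Successive differences are blind to
  the slow signal component, so the estimate is valid on responders too;
  the 8σ margin accounts for the extreme-value inflation of a
  min-normalized maximum (for pure noise, max/min of ~37 samples sits ~4 SD
  above 1 with a heavy tail — a short pre-stimulus window with a 3σ margin
  misclassifies about half of all flat traces).  An absolute threshold can
  be supplied instead.
* **Fraction responding** is computed per field of view; fields, not cells,
  are the unit of replication.
* **Membrane clustering metric**: per-frame coefficient of variation
  (std/mean) of pixel intensities inside a fixed membrane mask, reported as
  `CV_t − CV_0`.  CV is dimensionless and scale-invariant (robust to the
  two-fold brightening of the red tag under blue light); plain variance is
  available as an option.

## Synthetic data

The generators are pure functions of their spec (mandatory integer seed;
fixed seed ⇒ byte-identical output) and emulate the *statistical structure*
the analysis assumes, not microscopy physics:

* **Calcium traces** (5 s × 3 min, 37 points): responders rise sigmoidally
  (onset 20–60 s, ~15 s rise — maximal within 2–3 min) to a plateau held to
  the end of the recording; blinkers carry 1–2 isolated single-sample
  spikes; non-responders stay at baseline.  Noise is multiplicative
  log-normal (unit mean), default SD 5%.
* **KTR pairs** (15 s × 15 min, 61 points): the C/N ratio rises
  exponentially from 1 toward 3 with a 150 s timescale (maximal within
  ~10 min); the analytic baselined-sum AUC of the noiseless ratio is stored
  as the ground-truth label.
* **Membrane images**: a uniform disk-masked membrane plane; cluster
  formation redistributes the same total masked intensity into Gaussian
  puncta (sum conserved to machine precision), so the CV change isolates
  spatial reorganization from brightness changes.
* **Noisy model readouts**: steady-state dose-response outputs with
  multiplicative Gaussian noise truncated to [0, 1], with ground-truth
  parameters recorded.

What passing tests on these fixtures do and do not show: they validate the
statistics' conventions, determinism, error paths, and detection properties
under the stated noise model; they do not validate segmentation, tracking,
photobleaching, movement artifacts, or any feature of real microscopy noise
(which is neither log-normal nor stationary).

## Problem sizes used by the shipped analyses

Partition-coefficient scan: 241 log-spaced K values in [1, 100] (the
90%-of-plateau point is read off this grid, resolution ~1.9%).  Src scan:
33 log-spaced values in [1e-3, 10] µM for both Src variants.  PP2
titration: 33 log-spaced doses in [1e-2, 1e2] µM plus zero.  Parameter
recovery: 8 log-spaced doses spanning ±1.5 decades around K_I, 5%
multiplicative noise, 200 seeded replicates.  Classifier validation: 1000
labeled traces at 5% noise.  Oracle checks: 100 random parameter/state
draws for the right-hand side (1e-12 relative) and 20 draws against a
fixed-step RK4 reference at dt = 1e-3 s (1e-6 relative); box invariance is
spot-checked on 60 random draws per scenario batch.

## Known limitations

The parameter set is a calibration against qualitative figure-level
behaviors, not a fit to quantitative data; absolute fractions (e.g. the
0.89 lit pLAT fraction) should be read as model units.  The equilibrium
treatment of binding is invalid on timescales comparable to binding
kinetics (seconds), so the first moments after the light switch are
idealized.  Bistability means scan curves depend on the approach branch;
all shipped scans use the dark-to-light branch, and the hysteresis probe is
the tool for mapping the other one.
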