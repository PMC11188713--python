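# striatnet

Simulation and parameter inference for the striatal medium-spiny-neuron
(MSN) network.

MSNs, the GABAergic projection neurons that make up over 90% of the
striatum, inhibit each other through axon collaterals and, under tonic
excitation, organize into *cell assemblies* — groups of co-active cells
that switch dominance on timescales of minutes.  This patterning is
disrupted in Parkinsonian and dyskinetic tissue.  `striatnet` packages the
three pieces needed to study this quantitatively from calcium-imaging-like
data:

1. **A biophysical network model.**  Single-compartment MSN cells carrying
   the classic current complement (I_Na, I_K, I_Kir, I_Af, I_As, I_Krp,
   I_NaP, I_NaS; delayed first spiking, ~10 Hz ceiling), coupled at random
   (p = 0.4) by GABA synapses with deterministic Tsodyks–Markram
   short-term plasticity (U = 0.41, D = 222 ms, F = 1859 ms, 20 ms decay,
   −85 mV reversal, 1–3 ms delays).  Two scalars set the operating point:
   the lateral inhibition scale `G_I ∈ [0.002, 0.02]` (per-edge weights
   uniform in [0.3125 G_I, 0.9375 G_I]) and the excitatory drive scale
   `G_E ∈ [0, 2·10⁻⁵]` (per-cell constant drives uniform in
   [0.001305, 0.001305 + G_E]).
2. **Calcium-raster features.**  Spikes are binarized into 250 ms bins;
   each raster is summarized by three cell-averaged statistics — mean
   activity, mean activation interval, and interval CV — plus a
   quality-control statistic (CV of the population-mean activity) that
   flags networks frozen into winners-take-all (WTA) fixed points
   (removed below 0.09 before training).
3. **Simulation-based inference.**  A conditional Gaussian-mixture density
   network q(G_I, G_E | features) trained by negative log-likelihood on
   (parameter, feature) pairs, with 30 random-holdout restarts scored by
   the weighted error (G_I* − G_I)² + 900² (G_E* − G_E)², grid-based MAP
   extraction, and best-fit simulation lookup.

A descriptive assembly-analysis module (UMAP 3D embedding, density
clustering, dominant-cluster transition graphs) and a synthetic-data
module (Markov rasters with closed-form statistics, and a fast analytic
surrogate of the feature landscape) round out the pipeline.

## Worked example

```python
from striatnet import (CellParams, DriveSpec, simulate_cell, ipsp_peak,
                       NetworkParams, build_network, run_network,
                       binarize, feature_vector)

trace = simulate_cell(CellParams(), DriveSpec(increment=2e-5, duration_s=10.0))
print(f"isolated MSN at max drive: {trace.rate_hz:.1f} Hz, "
      f"first spike after {trace.first_spike_latency_ms:.0f} ms")
for gi in (0.002, 0.008, 0.02):
    print(f"single-spike IPSP at G_I={gi}: {ipsp_peak(gi):.3f} mV")

params = NetworkParams(n_cells=100, g_i=0.008, g_e=1.8e-5,
                       duration_s=120.0, seed=1)
raster = run_network(build_network(params))
fv = feature_vector(binarize(raster))
print(f"network: {raster.n_spikes} spikes; activity={fv.activity:.3f}, "
      f"mean interval={fv.interval:.4f} bins, interval CV={fv.interval_cv:.2f}")
```

prints

```
isolated MSN at max drive: 10.0 Hz, first spike after 702 ms
single-spike IPSP at G_I=0.002: 0.100 mV
single-spike IPSP at G_I=0.008: 0.469 mV
single-spike IPSP at G_I=0.02: 1.500 mV
network: 68599 spikes; activity=0.990, mean interval=0.0051 bins, interval CV=4.13
```

The isolated cell shows the MSN signature — a ~700 ms ramp to the first
spike and ~10 Hz tonic firing at the top of the drive range.  Single-spike
IPSPs (cell held at −80 mV, chloride reversal −40 mV) grow from 0.1 mV at
the weakest inhibition to 1.5 mV at the strongest; the physiological
mid-range value near G_I = 0.008 is ~0.45 mV.  The 100-cell network at
high drive sits just above the WTA transition: almost every cell is active
in most bins, but the gaps between activations are strongly irregular
(interval CV ≈ 4), the signature of fluctuating assembly dynamics.  Below
G_I ≈ 0.006 the interval CV collapses toward zero as the network freezes
into tonic winners-take-all firing.

A command-line interface mirrors the library
(`striatnet simulate|sweep|features|train|infer|bestfit|synth|assembly|pipeline`);
`striatnet pipeline --profile desk --outdir runs/demo` executes the whole
sweep → filter → train → infer → best-fit chain with a manifest for exact
reproduction.

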