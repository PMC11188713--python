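# Methods

## Cell model

Each MSN is a single isopotential compartment (C = 1 µF/cm²) with leak and
eight voltage-gated currents: fast sodium I_Na (instantaneous cubed
activation, inactivating), delayed-rectifier I_K (squared activation),
inward rectifier I_Kir (instantaneous), fast and slow A-type potassium
I_Af and I_As, persistent potassium I_Krp, and persistent plus slow sodium
I_NaP and I_NaS.  Gating steady states are Boltzmann functions of voltage;
the six non-instantaneous gates relax first-order with fixed time
constants (h_Na 1.2 ms, n_K 2.5 ms, a_Af 1 ms, h_Af 25 ms, h_As 400 ms,
m_NaS 150 ms).  The slow inactivation of I_As together with the slow
activation of I_NaS produces the MSN signature: a hyperpolarized rest
(≈ −84 mV, maintained by I_Kir), a ramp of hundreds of milliseconds to the
first spike, and low tonic rates.

The exact kinetics of the cited eight-channel MSN formulations are not
pinned by the study conditions, which instead pin *behavior*; the gating
parameters here are therefore our own and the model is calibrated to three
behavioral anchors:

1. the rheobase in abstract drive units lies below the shared network base
   drive 0.001305 (calibrated rheobase ≈ 0.00086);
2. an isolated cell at the top of the drive range (0.001305 + 2·10⁻⁵)
   fires at 10 Hz over a 10 s protocol;
3. the first-spike latency is pronounced (≈ 0.7 s at network drives) and
   decreases monotonically with drive.

Calibration fixes one constant: the drive-to-current scale
κ = 942.7382 (µA/cm² per drive unit), found by bisecting the injected
current for which the 10 s spike count is exactly 100 and dividing by the
maximum drive.  Every simulation starts from the state reached after 2 s
of drive-free settling.

One consequence of the narrow drive interval (a 1.5% span in current) is
that isolated-cell rates across a network vary only between ≈ 9.3 and
10 Hz; heterogeneity in the network dynamics is generated almost entirely
by the random connectivity, weights and synaptic depression rather than by
the drive spread.

## Synapse model

MSN-MSN synapses follow the deterministic Tsodyks–Markram scheme with the
striatal collateral constants U = 0.41, D = 222 ms, F = 1859 ms.  State is
advanced lazily at presynaptic spike times by the closed-form relaxation
(R → 1 with constant D, S → 0 with constant F), then the event update:
S⁺ = S + U(1 − S), conductance transient ∝ R⁻ S⁺, R⁺ = R⁻(1 − S⁺)
(facilitation before depletion; the transient uses the pre-spike R).
Because R and S depend only on the presynaptic train, one (R, S) pair per
presynaptic cell serves all its efferent synapses exactly.  Conductances
decay exponentially with τ = 20 ms, reverse at −85 mV in the network, and
transients sum without saturation.  Delays (uniform 1–3 ms per edge) are
rounded to the integration grid.

The map from an abstract synaptic weight w (drawn uniformly in
[0.3125 G_I, 0.9375 G_I]) to a conductance density is the calibrated
monotone quadratic φ(w) = a w + b w² with a = 0.5615, b = 29.007.  Both
coefficients are fixed by the two endpoint anchors of the single-spike
IPSP characterization (0.1 mV at G_I = 0.002 and 1.5 mV at G_I = 0.02,
measured at the characterization weight 0.625 G_I, i.e. the mean weight
fraction).  A single linear scale cannot satisfy both anchors — their
amplitude ratio is 15 for a weight ratio of 10, while a point-conductance
synapse on a near-linear membrane responds proportionally or slightly
sublinearly — so the quadratic term absorbs the supralinearity (receptor-
and morphology-level effects a point synapse does not represent).  With
only the two endpoints calibrated, the protocol *predicts* 0.469 mV at
G_I = 0.008 and 0.692 mV at G_I = 0.011, matching the physiological
mid-range values (~0.45 and ~0.7 mV) it was not fitted to.

The characterization protocol holds the postsynaptic cell at −80 mV by a
somatic current computed in closed form from the channel steady states
(no clamping dynamics), sets the chloride reversal to −40 mV so the IPSP
is depolarizing, delivers one transient of size φ(0.625 G_I)·U, and
reports the peak depolarization.

## Network integration

The integrator is a single numba kernel shared by the isolated-cell and
network paths.  Voltage uses the conductance-form exponential update
V ← V∞ + (V − V∞)·exp(−g_tot Δt / C) (unconditionally stable); gates use
exponential Euler with precomputed decay factors; Boltzmann curves are
linearly interpolated from tables on a 0.05 mV grid.  Default Δt is
0.025 ms; halving it changes a 10 s spike count at maximum drive by at
most one spike.  Spikes are upward crossings of 0 mV with a 2 ms
detection lockout.  Delayed transients queue in a ring buffer.  There is
no extrinsic noise: given a built network the dynamics are bit-for-bit
reproducible, and all randomness in construction flows from a master seed
through four independent streams (topology, weights, delays, drives), so
any one draw class can be held fixed.

## Raster features

Spike trains are binned into non-overlapping 250 ms windows, half-open on
the right (a spike at exactly the recording end joins the last bin), and
binarized; silent cells are dropped but their indices recorded.  Per-cell
statistics: mean activity (fraction of active bins); activation intervals
as the linear-scan gaps between consecutive active bins (adjacent active
bins count as a zero interval; the stretch before the first activation is
*not* an interval, so onset latency does not contaminate the statistics);
mean interval and interval CV (population SD over mean).  Cells with
fewer than two active bins contribute 0 to the interval and CV averages.
Intervals are reported in bins (× 250 ms for time units).  The three
features are exactly invariant to independent temporal translations of
individual cells' rows, which is why single-cell statistics can reveal
population assembly structure without any cross-correlation feature.

The WTA quality-control statistic is the CV of the population-mean
activity series after dropping a 120-bin (30 s) transient; it is zero for
a network frozen into a fixed point.  Records below 0.09 are removed
before training (the boundary value itself is kept).  Unlike the three
features this statistic depends strongly on how many cells are recorded:
in 100-cell desk-scale runs its dynamic range tops out near 0.05, so the
pipeline's desk profile uses a profile-scaled cutoff (0.02) with the same
role, while the full-scale profile keeps 0.09.

## Winners-take-all transition

At high drive (G_E = 1.8·10⁻⁵) the network crosses a sharp transition as
inhibition falls: above it, depression-driven assembly switching gives
high interval CV (≈ 4–7); below it, a set of cells fires tonically in
every bin and the CV collapses to ≈ 0.  The scaled-down sweep (100 cells,
120 s, two seeds, G_I ∈ {0.003 … 0.012}) locates the collapse — the
largest G_I whose seed-averaged CV is below half the sweep maximum — at
G_I = 0.006.  Desk scale preserves this transition and the qualitative
feature trends (activity decreasing and interval increasing with G_I) but
not the absolute feature values of full-scale networks: with in-degree
≈ 40 instead of ≈ 160 and near-homogeneous drives, desk-scale rasters are
much denser (activity ≈ 0.8–1.0) than 400-cell, 10-minute runs.

## Surrogate feature map

For inference-recovery studies a fast analytic stand-in replaces the
simulator: activity is a logistic falling in G_I and rising in G_E;
interval is saturating-increasing in G_I with a weaker G_E modulation;
interval CV is a bump that peaks just above a collapse boundary (at
G_I = 0.006 for maximal drive, falling to 0.004 at zero drive) and is
gated to near zero below it.  Gaussian observation noise has SD equal to
5% of each feature's range.  The map honors the directions and the
transition geometry of the simulated landscape — including a G_E
dependence of activity strong enough that excitation is identifiable from
features, as it must be for posterior recovery — but its absolute values
are arbitrary; it is a test double, not a fit to simulation output.

## Posterior estimation

The density estimator is a mixture density network: a tanh MLP (two
hidden layers of 64) emitting logits, means and per-dimension log-SDs of
an 8-component diagonal Gaussian mixture over min-max-scaled parameters;
features are z-scored with training-set moments and both transforms are
stored with the estimator.  Training minimizes the exact negative
log-likelihood by full-batch Adam (lr 5·10⁻³, up to 500 epochs, early
stopping on a 10% validation split with patience 50); gradients are
analytic (responsibility-weighted) and verified against finite
differences in the test suite.  Architecture and optimizer settings are
our own choices, sized to train in seconds on ~150 records.

Thirty restarts each hold out 20 random records; a restart is scored by
the mean weighted error (G_I* − G_I)² + 900²(G_E* − G_E)² of its MAP
estimates on its own holdout, and the minimum wins (ties break by restart
index).  Posterior summaries evaluate the conditional mixture on a
200 × 200 cell-centered grid over the prior box, normalize there, and
report the joint argmax as the MAP along with marginal peaks; the MAP is
thus quantized at 1/200 of each prior width.  Samples are drawn from the
mixture with rejection outside the box.  A feature vector more than 3
training-SDs from the training mean sets an out-of-support flag.

On surrogate data (train 150, test 20) the median absolute MAP error is
≈ 2% of the prior width in G_I and ≈ 8% in G_E.  Excitation is
intrinsically the harder axis: it moves the features less than inhibition
does, which is also why its error term carries the 900² compensation.

## Assembly analysis

Cell activity vectors are embedded in 3D by UMAP (15 neighbors, min_dist
0.1, fixed seed, deterministic) and clustered by HDBSCAN (minimum cluster
size 5); density-noise points are attached to the nearest labeled
cluster so every active cell is labeled, and labels are contiguous from
0.  Identical rows short-circuit to a single cluster.  Per bin, the
cluster with the largest fraction of its cells active is dominant if that
fraction reaches 0.5 (ties → none); transitions between successive
distinct dominant clusters (skipping none-gaps, ignoring self-repeats)
accumulate into a directed weighted graph.  These parameters are pinned
reproductions of a published visualization protocol whose exact settings
live in external code; the module is descriptive and feeds nothing into
inference.

## Problem sizes and limitations

The default test and acceptance configurations are desk-scale by design:
100-cell, 120 s networks (in-degree ≈ 40), 150-record surrogate training
sets, and a seconds-scale `tiny` pipeline profile for smoke tests; the
`paper` profile (400 cells, 600 s, 200 simulations) reproduces the full
study conditions when compute allows.  Known limitations: D1/D2 cell
types and dopamine-receptor mechanics are not modeled; excitation is a
constant somatic drive (no spiking afferents or feedforward
interneurons); the drive interval compresses isolated-cell rate
heterogeneity (see above); connection probability is fixed at 0.4; the
fluorescence forward model of calcium imaging is out of scope — rasters
are compared at the binarized 250 ms level only.
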