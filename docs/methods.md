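# Methods

## Scientific question

A statistically significant activity event — a group of neurons raising
their firing rates in a correlated manner — need not have any impact on the
network it is embedded in. Whether it does depends on *where* the active
neurons sit in the connectivity graph: their structural embeddedness. This
package quantifies that dependence in three complementary ways:

1. a **thought experiment** on a modular network in which a small
   subnetwork produces highly significant correlated events that are, by
   construction, dynamically irrelevant to the rest of the network;
2. a **stimulation-grid study** correlating per-subpopulation embeddedness
   (out-degree, k-shell-out index) with the evoked population response in
   leaky integrate-and-fire (LIF) networks spanning a range of topologies;
3. a **deterministic cascade model** showing that which embeddedness metric
   ranks influence correctly depends on single-neuron firing properties
   (regular vs bursting).

## Network generation

**Multifractal generator.** A k x k symmetric link-probability matrix P and
interval lengths l (summing to 1) are iterated m times: the unit interval
refines into k^m cells with lengths given by m-fold products of l and link
probabilities by m-fold products of P entries. Each node draws a uniform
coordinate; the probability of an edge between two nodes is the iterated
measure value at their coordinates, rescaled globally so the expected edge
count is n x (target mean degree), clipped to [0,1] (an error is raised if
more than 1% of pairs clip — the measure is then too concentrated for the
requested density). Directions are sampled independently per ordered pair,
the simplest directed extension of the (undirected) generator. Two facts
worth knowing:

- With equal interval lengths and a symmetric diagonal measure every
  category has the same expected out-degree (all row sums equal), so the
  degree distribution collapses to the Erdős–Rényi (ER) one. Out-degree
  heterogeneity requires unequal lengths and/or unequal diagonal entries.
- A diagonal-dominant measure over unequal intervals yields a dense
  assortative core over a sparse periphery — high clustering, short paths,
  strongly heterogeneous out-degree: small-world indices well above 1.

**Ensembles.** The default topology-spectrum ensemble
(`netgen.default_ensemble_spec`) draws 100 two-category measures with
m in {2,3}, diagonal entries in [0.3, 0.95], off-diagonal in [0.02, 0.4],
first interval length in [0.2, 0.8]; realized SWI spans sub- and
super-unity values. The stimulation study's scaled ensemble
(`replication.draw_heterogeneous_measure`) narrows the draws to diagonal
0.65–0.95, off-diagonal 0.03–0.15, first length 0.2–0.45 and keeps only
draws whose realized out-degree variance is at least 3x the matched-ER
value — the study stratifies by out-degree, which requires genuinely
heterogeneous degrees. Five ER controls are matched in node and edge
counts.

**Modular-hub fixture.** 900 neurons (700 excitatory, ids 1–700 in display
numbering; 200 inhibitory, 701–900). A large subnetwork (750) and a small
one (150) are each internally random (p = 0.1); 30 excitatory hub neurons
of the large subnetwork each project onto 100 random small-subnetwork
neurons. Not a single edge leads from the small subnetwork back out — the
small subnetwork is a pure listener.

**Toy network.** 14 nodes. Printed constraints: node 1 projects to
{2,3,4,6}; node 5 to {7..14}; nodes 7–14 are sinks. The completion used
here adds the core cycle edges 2→{3,4}, 3→{4,6}, 4→{6,1}, 6→{1,2} and the
bridge 6→5 — the sparsest structure satisfying all printed cascade
behaviours while ranking node 1 (shell index 2) above node 5 (shell
index 0) in the k-shell-out decomposition.

## Embeddedness metrics

- **Out-degree**: distinct outgoing edges per node.
- **k-shell-out index**: for k = 1, 2, ... iteratively delete nodes whose
  out-degree *within the surviving subgraph* is below k; a node removed
  during sweep k gets index k−1 (sinks get 0), i.e. the largest k for
  which the node belongs to the out-degree k-core. Implemented with an
  in-neighbour queue (near-linear in edges); an independent brute-force
  pruning oracle backs it in the tests.
- **Betweenness**: standard unnormalized shortest-path betweenness on the
  directed graph.
- **Small-world index**: SWI = (C/C_r)/(L/L_r), where C is the average
  local clustering coefficient and L the mean shortest-path length over
  reachable pairs of the giant component, both on the *undirected
  projection* (the convention of the small-world literature; the
  embeddedness metrics stay directed), and C_r, L_r are means over ER
  references with identical node and directed-edge counts (default 10
  references). Unreachable pairs are excluded and counted rather than
  imputed, which keeps L finite on fragmented graphs.

## LIF network model

Current-based delta synapses with homogeneous weights: an excitatory spike
deposits j_exc on each target after delay d, an inhibitory spike −g·j_exc.
Exact exponential integration per time step dt; threshold crossing resets
the membrane and clamps it for the absolute refractory period (inputs
arriving while refractory are discarded). Full-scale defaults are the
canonical values tau_m = 20 ms, V_th = 20 mV above rest, V_reset = rest,
t_ref = 2 ms, d = 1.5 ms, j_exc = 0.1 mV, g = 5, dt = 0.1 ms.

Every neuron receives an independent background Poisson stream (weight
j_exc) whose rate is **calibrated by bisection** (per network, 1 s probe
runs) so the baseline population rate sits at 5 spikes/s within the 2–10
spikes/s asynchronous-irregular band; the tolerance is 2% of target so
that baseline spike counts are comparable across networks. Background,
stimulus and initial-condition randomness use separate seeded streams, so
adding a stimulus never changes the background realization.

The single-neuron implementation is validated against the closed-form f–I
curve rate = 1/(t_ref + tau·ln((RI−V_reset)/(RI−V_th))) to within 1%.

## Stimulation-grid study (desk scale)

The full-scale design (100 networks x 10,000 neurons x 30 subpopulations
of 250) is scaled to run on one CPU in minutes: 10 multifractal networks
of 2,000 excitatory + 500 inhibitory neurons at mean degree 50, five ER
controls, 10 disjoint groups of 100 excitatory neurons stratified by
out-degree (sorted, equally spaced block starts — disjoint by
construction, group means strictly increasing), one trial per group,
identical 30 ms Poisson stimulus per group, responses measured over a
100 ms window from stimulus onset (PSTH at 5 ms bins; total network-wide
spike count). Because the recurrent in-degree (~50) is ~20x below the
full-scale regime, the synaptic weight is raised to j_exc = 0.7 mV
(roughly preserving J x K) so that recurrent propagation, not only the
external drive, shapes the response.

Two variance-control choices matter at this scale:

- **Common random numbers**: all groups of a network are simulated with
  the same background/initial-condition realization (and the unstimulated
  baseline run shares it too). Response differences within a network are
  then attributable to the stimulated set alone. Per-network correlations
  rise from ~0.6 to ~0.9 with this paired design.
- **Probe strength by purpose.** The correlation grid uses a strong probe
  (4,500 events/s x 0.7 mV, ~10 direct spikes per target) so each group's
  response is reliably supra-noise in a single trial. The response-spread
  experiment uses a weak probe (800 events/s, ~17 mV over 30 ms —
  subthreshold on its own, firing only neurons the network has already
  depolarized) so that the *absence of propagation* from weakly embedded
  groups is not masked by the stimulated group's own direct spikes: their
  evoked count is then statistically indistinguishable from baseline,
  while strongly embedded groups ignite avalanches of hundreds of spikes.
  Each is a declared calibration, configurable in `GridSpec`.

The spread experiment generates five networks from a fixed strongly
core–periphery measure (diag [0.95, 0.6], off-diag 0.03, lengths
[0.25, 0.75], m = 3; SWI ~ 2.9), keeps those with SWI > 1, and reports the
best max/min ratio of evoked responses (count above the identically seeded
unstimulated baseline, floored at one spike), mirroring a single example
network rather than an ensemble average.

## Thought-experiment protocol

Build the modular-hub network, calibrate background (j_exc = 0.3 mV at
this 900-neuron scale), then three 3 s conditions: (1) baseline; (2) hub
epochs — the 30 hubs receive 12,000 events/s drive during three 200 ms
windows; (3) direct stimulation of the whole small subnetwork with the
same drive. Reported: small-subnetwork rate inside the epoch windows
(baseline vs hub condition), mean pairwise Pearson correlation of 50 ms
binned counts over 50 random small-subnetwork pairs (same pairs in both
conditions), and the large-subnetwork mean-rate change between baseline
and condition (3). Because no edge leaves the small subnetwork and the
background stream is independent of the stimulus stream, the large
subnetwork's spike trains in condition (3) are *identical* to baseline —
the measured change is exactly zero, comfortably inside the 5% tolerance
that allows for shared-background implementations.

## Cascade model

Threshold theta = 3 input units; a regularly firing node emits 1 unit per
out-edge, a bursting node B = 4, the externally driven seed S = 5; inputs
accumulate across tiers; each node emits exactly once, at the tier after
activation. These are the smallest integers realizing the intended
narrative on the toy fixture: with regular firing the cascade from node 5
(out-degree 8) activates 9 nodes and that from node 1 (out-degree 4) only
5; with bursting, node 1 recruits all 14 nodes while node 5 still reaches
only its sinks. An independent fixed-point recomputation oracle verifies
the tiered implementation on random digraphs.

## What the synthetic data do and do not show

All inputs are generated here; nothing is fit to recordings. The generator
reproduces the *structural* features the argument needs (heterogeneous
out-degree, assortative cores, small-world indices above 1, matched ER
controls) but not distance-dependent cortical connectivity, synaptic
weight diversity, or conductance dynamics; the LIF networks operate in a
calibrated asynchronous-irregular regime, not in a state fit to in vivo
statistics. Passing tests therefore demonstrate the structure–impact
dissociation within this model class, not quantitative statements about
cortex.

## Numerical choices and degenerate inputs

Time step 0.1 ms with exact exponential decay (f–I error < 1%; spike times
quantized to the grid, delays at least one step). Edge cases: empty edge
sets are rejected where a metric is undefined (path length), return zeros
with a warning where a convention exists (clustering of degree-<2 graphs);
constant metrics cannot be stratified (error); zero-variance inputs to a
correlation raise rather than returning NaN. Stratification ties break by
node id; raster sorting appends silent nodes in id order. The max/min
spread floors evoked counts at one spike to keep the ratio finite when a
weak group evokes nothing.

## Known limitations

- Single-trial responses at 2,500 neurons carry avalanche-size noise of
  ~100 spikes; the pooled correlation consequently sits around 0.70–0.90
  depending on the master seed, whereas per-network correlations are
  stable (~0.8–0.95). The full-scale grid (opt-in via the CLI) averages
  this out but takes hours.
- The generating-measure parameters of the original 100-network ensemble
  are not recoverable; the default ensemble is a stand-in spanning the
  same qualitative range (SWI below and above 1), not a replication.
- How many of the 100 ensemble networks come out small-world depends on
  those unrecoverable parameters; no particular count is asserted.
- The cascade model is the only place bursting exists; the LIF module
  simulates regular (non-bursting) neurons.
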