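# Methods

This note documents the models, algorithms, default parameters and design
choices behind `spikeconn`. The package has three layers: a ground-truth
simulator of spiking networks, six inference algorithms that estimate
directed synaptic connectivity from spike trains plus an ensemble
classifier over their outputs, and an evaluation/topology layer.

## Output contract of every inference method

Each method maps a recording (per-unit spike times plus duration) to two
N x N matrices over ordered neuron pairs, with row = presynaptic `i`,
column = postsynaptic `j`:

* a **score graph** `S`, where `s_{i->j}` quantifies the confidence that a
  monosynaptic connection `i -> j` exists (the scale is method-specific: an
  absolute z-score, a -log10 p-value, or a class probability), and
* a **weight graph** `W`, where `w_{i->j}` is a signed coupling-strength
  estimate (positive = putatively excitatory, negative = inhibitory).

Diagonals are undefined (NaN). Scores that overflow to non-finite values
are clipped into the finite [0.1%, 99.9%] quantile range of the method's
own score distribution (NaN maps to the lower bound: absence of evidence);
the ensemble classifier requires finite inputs and this rule keeps extreme
-log p values from dominating.

## Ground-truth simulator

The benchmark network is an Erdos-Renyi directed graph of N leaky
integrate-and-fire neurons (default 300; 50:50 excitatory/inhibitory;
connection probability 0.05). Synaptic magnitudes are log-normal with
coefficient of variation 1 — the heavy-tailed distribution reported for
cortical synapses — signed by the presynaptic type.

Membrane dynamics are integrated by forward Euler at 0.1 ms:

    tau_m dV/dt = -(V - V_rest) + R (I_syn + I_input + mu_noise) + noise,

with a spike emitted at threshold crossing, reset, and a 2 ms absolute
refractory period; synapses are delayed (1.5 ms) exponential currents
(tau_syn = 2 ms). Defaults: tau_m = 20 ms, V_rest = V_reset = -65 mV,
V_thresh = -50 mV, R = 100 MOhm. These are standard cortical-culture
values; all are exposed in `LifParams`. The white-noise term is an
additive voltage perturbation `R sigma_noise sqrt(dt/tau_m) xi_t`, so
`mu_noise` and `sigma_noise` are both in nA. The integrator was validated
against the closed-form LIF f-I curve (rate within 2% over a 5-point
current sweep).

Synaptic weight scales default to 0.25 nA (excitatory) and 1.0 nA
(inhibitory; the 4x ratio balances a 50:50 E/I network). With R = 100 MOhm
and tau_syn/tau_m = 0.1 this corresponds to unitary EPSPs of roughly
2-3 mV — the upper range observed in dense cultures. The choice is
deliberate: desk-scale benchmark recordings are minutes long rather than
an hour, and weaker synapses would make every method operate at chance,
which is not the detectability regime the benchmark is meant to probe.
Real cultures contain many weaker synapses; absolute APS/MCC numbers from
the desk-scale benchmark therefore should not be read as field estimates
— only the comparisons between methods, regimes and durations are
meaningful.

### External input and dynamical regimes

The network is driven by an external population (default 30 units) that
contacts each LIF neuron with probability 0.1. Three input modes exist:

* `poisson` — homogeneous Poisson units;
* `bursty` — the default stand-in for an empirical culture recording:
  all input units share a doubly-stochastic rate equal to a 2 Hz baseline
  plus 120 ms boxcar bursts (60 Hz amplitude). Burst onsets form a renewal
  process with a 500 ms refractory gap, so the realized rate of
  *distinguishable* population bursts equals the nominal burst rate (a
  plain Poisson event process loses ~20% of bursts to merging);
* `file` — pass-through of a user-supplied recording, preserving the
  original empirical-input pathway when such a recording is available.

A *regime* is summarized by three statistics: the population **burst
rate**, the **mean firing rate**, and the **CV of the population rate**
(1 s bins). Bursts are detected on the 10 ms-binned, 50 ms-Gaussian-
smoothed population rate as excursions above baseline + 4 sigma, where
baseline is the median and sigma is the RMS deviation of the lower half
from the median (a robust noise scale that does not trigger on Poisson
fluctuations); excursions separated by < 100 ms are merged. Because "CV"
could denote either the population-rate CV or the mean per-unit ISI CV,
`RegimeStats` reports both (`cv`, `cv_isi`); calibration matches burst and
firing rate only.

The shipped presets pin the three benchmark regimes — high (burst 1 Hz,
rate 1.6 Hz, CV 0.3), intermediate (0.4, 1.1, 0.4) and low (0.2, 1.3,
0.2) — plus a Poisson-input variant with an 80:20 E/I ratio and
connection probability 0.02. In this generator the burst statistics of
the drive are set by the input's burst process (the network reliably
follows its input bursts), and `calibrate_noise` searches
(mu_noise, sigma_noise) by bisection on short probe simulations until the
mean firing rate (and the detected burst rate) are within tolerance
(default 15%). Presets ship with the noise configuration found during
development as a warm start; calibration re-verifies it at run time.

## Inference algorithms

Defaults below follow the published defaults of the source methods; the
benchmark study itself left per-method settings to supplementary material,
so every value here is exposed in configuration and recorded in each
result's `params`.

* **CI (coincidence index)** — windowed CCG integral. For each ordered
  pair, the number of coincidences `N_c` with lag in (0.5, 5] ms is
  z-scored against `n_surrogates` (default 50) copies of the recording
  jittered by +-10 ms. `s = |z|`; `w = (N_c - mu_surr)` per presynaptic
  spike (signed excess transmission).
* **sCCG (smoothed cross-correlogram)** — the CCG (T_max 50 ms, 1 ms
  bins) is convolved with a partially hollow Gaussian (sigma 10 ms, hollow
  fraction 0.6, kernel renormalized at the edges) to estimate the slow
  co-modulation baseline without absorbing the fast synaptic feature. The
  windowed count `C_w` is tested against the baseline expectation
  `Lambda_w` under a Poisson model, two-sided:
  `s = -log10 min(p_excess, p_deficit)`; `w = (C_w - Lambda_w)/n_pre`.
* **dSTTC (directed spike-time tiling coefficient)** — rate-robust
  coincidence measure `d = 1/2 [(P+ - T+)/(1 - P+T+) + (P- - T-)/(1 - P-T-)]`
  with dt = 5 ms, where P+ is the fraction of i-spikes followed by a
  j-spike within dt and T+ the fraction of time tiled by post-j windows
  (P-/T- mirror it backwards); scored against jitter surrogates.
* **GLMCC** — a Poisson GLM fitted to each unordered pair's CCG:
  `count(tau) ~ Poisson(exp(a(tau) + J_fwd f(tau) + J_bwd f(-tau)))` with
  synaptic kernel `f(tau) = exp(-(tau - d)/tau_syn)` (d = 1 ms,
  tau_syn = 4 ms), a first-difference smoothness penalty (20) on the
  per-lag background `a`, and a tiny ridge on `J`. Newton iterations with
  backtracking; `s = |J|/se(J)` (penalized-information Wald), `w = J`.
  Pairs with fewer than 50 pooled CCG counts are skipped (s = w = 0).
* **TE (delayed transfer entropy)** — plug-in transfer entropy on 1 ms
  binarized trains with one history bin, maximized over source delays
  1-20 ms, computed sparsely from lag histograms between occupied-bin
  index sets. `s` is the TE z-scored against jitter surrogates; because
  TE is unsigned, `w` is the TE magnitude signed by the sCCG windowed
  excess/deficit so that inhibitory couplings carry negative weights (an
  artifact convention).
* **GLMPP (population point-process GLM)** — per target neuron, an
  L2-penalized Poisson GLM (5 ms bins) whose log-rate is an intercept +
  raised-cosine self-history filters (3 bases over 100 ms) + one coupling
  filter per source (3 log-spaced raised-cosine bases over 50 ms;
  strictly causal). Fitted by Newton/IRLS with step halving (the
  penalized likelihood is non-decreasing by construction); ridge bumps
  retry singular Hessians. `w_{i->j}` is the net area of the fitted
  coupling filter; `s_{i->j} = -log10 p` of the group Wald chi-square test
  on the source's coefficients. Whether the original pipeline used L1 or
  L2 and which basis family is unknown; L2 with raised cosines is the
  standard reconstruction.

## Ensemble classifier (eANN)

The 12 per-pair features are the (s, w) of the six methods in a fixed
column order; remaining non-finite entries are imputed to the column
median. The classifier is a feed-forward network 12 -> 10 -> 10 -> 3
(ReLU hidden layers, softmax output) over classes {no connection,
excitatory, inhibitory}. Training sets contain all true connections (10%
of rows, labelled from the presynaptic type) plus uniformly sampled
unconnected pairs. Features are z-normalized with pooled training
statistics stored inside the model, so prediction is self-contained. The
optimizer (Adam, rate 1e-3, batch 256, up to 500 epochs, early stopping on
a 10% validation split with patience 25) is not specified by the source
study and is a configuration decision here. The connectivity score is
`s = max(p_E, p_I)`; the signed weight is defined as `w = p_E - p_I` so
that downstream tooling gets a weight graph (the source study defines only
the score for the ensemble). The ensemble is trained once and reused
across all evaluations.

**Shapley explanations** are interventional: the value of a feature
coalition is the background-mean model output with coalition features
taken from the explained row. Exact mode enumerates all 2^12 coalitions
(local accuracy holds to machine precision); sampled mode is a seeded
permutation estimate whose error at 2000 permutations is below 0.01 on
this feature dimension.

## Evaluation

The ranking task over all ordered off-diagonal pairs is scored by the
average precision score (APS; step-wise integral of the precision-recall
curve over all distinct score values, no interpolation) and by the
Matthews correlation coefficient at the best threshold (ties broken toward
the densest graph). Per-class (E/I) variants restrict the positives to one
class while keeping all negatives. Significance thresholds at level alpha
pool all off-diagonal scores from jitter-surrogate re-runs and take the
empirical (1 - alpha) quantile; the pooled (rather than per-pair) null is
deliberate — a per-pair null at alpha = 0.001 would need thousands of
surrogates per pair.

## Topology

Thresholded graphs are characterized by density, mean directed (Fagiolo)
clustering, global efficiency (mean 1/shortest-path over ordered pairs;
1/inf = 0), Louvain modularity on the symmetrized graph (best of 10 seeded
restarts), and a small-world index (C/C_rand)/(L/L_rand) with reference
values averaged over 20 degree-matched rewired graphs. The 13 connected
directed triad classes are numbered 1 (divergence) through 13 (fully
reciprocal clique) in the standard ordering used in cortical-microcircuit
motif studies; `MOTIF_PATTERNS` ships an explicit adjacency-pattern table
pinning each ID, and the census is tested against brute-force subgraph
enumeration. Motif over-representation is assessed against degree-
preserving double-edge-swap surrogates with Benjamini-Hochberg correction
across the 13 classes.

## Desk-scale benchmark protocol

The full-scale study design (25 training simulations of 300 neurons for
1 h each) is impractical on a single CPU, so the shipped benchmark runs a
reduced protocol with the same structure:

* training corpus: 4 noise configurations x 1 network, 30 neurons,
  connection probability 0.07 (kept below the 10% positive-fraction
  training rule), 300 s, common bursty input realization;
* held-out evaluation: 3 intermediate-regime simulations with fresh
  network wiring and a *different* input realization;
* regime comparison: low-burst (0.2 Hz) vs high-burst (1 Hz) input with
  noise chosen so that mean rates match (~1.3-1.5 Hz both) — otherwise
  the comparison would confound burstiness with the amount of data;
* duration comparison: 60 s vs 300 s of the same recording.

What passing these tests shows — and what it does not: the synthetic
generator reproduces population bursts, rate diversity, log-normal
weights and E/I balance, but not refractory-period violations from spike
sorting, electrode subsampling of a larger culture, non-stationary
development, or conduction-delay heterogeneity. Results on real
recordings will be worse than desk-scale numbers suggest, and the
benchmark's value is in the *relative* standing of methods.

## Numerical choices and degenerate inputs

* Spike times are float64 seconds; all window/bin parameters are ms.
* Jitter surrogates reflect at recording boundaries (preserves edge
  rates) and resolve exact ties by an ulp-scale nudge to keep trains
  strictly increasing.
* dSTTC returns a term of 1 when 1 - PT = 0 (degenerate full tiling).
* Empty spike trains yield all-zero CCGs with a warning; a recording with
  zero spikes yields all-zero regime statistics with a warning.
* TE requires at least 1000 bins; shorter inputs are an error.
* GLMCC/GLMPP non-convergence flags the pair/target (s = w = 0) rather
  than failing the run; pipeline-level method failures are isolated and
  reported as missing cells.

### A note on TE and bursting

Raw transfer-entropy estimates inflate for *all* pairs when networks
burst, which degrades TE-based reconstructions on bursty data. The TE
score in this package is z-scored against 10 ms jitter surrogates; the
jitter preserves burst-scale (~100 ms) comodulation, so the null already
absorbs burst-induced coincidences. A consequence the acceptance tests
make explicit: in this package TE's APS does **not** drop in the
high-burst regime (at matched mean rates it is, if anything, higher,
because bursts concentrate informative spikes) — the classical
degradation of TE under bursting applies to uncorrected TE scores, not to
the surrogate-corrected score used here. GLMPP, whose score has no such
correction, does degrade with bursting as expected.

## Known limitations

* The eANN predicts the existence and sign of connections, not synaptic
  strength magnitudes.
* GLMPP does not model unobserved common input; spurious couplings from
  shared hidden drive are expected (as in the original formulation).
* The bursty input is a statistical stand-in for an empirical recording;
  `file` mode exists precisely so real recordings can replace it.
* Desk-scale simulations use 30-neuron networks; topology statistics on
  such small graphs (especially modularity and small-world index) are
  noisy and are reported, not tested, at this scale.
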