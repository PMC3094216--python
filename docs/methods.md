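# Methods

This note documents the models, algorithms and numerical choices behind
`seizhmm`, the assumptions they rest on, and what the synthetic benchmarks
do and do not establish.

## Signal model and preprocessing

Input is a single channel of extracellular field potential sampled at
≥800 Hz (typical acquisition is 1000–1024 Hz; nothing is hard-coded to a
rate).  Preprocessing subtracts the mean, applies a zero-phase FIR notch at
the mains frequency and all harmonics below Nyquist (a ~1 s linear-phase
`firwin2` kernel with ±1.5 Hz stop bands, applied by centered convolution),
and rescales to max |x| = 1.  Normalization makes the feature scale
independent of amplifier gain.  Consequences worth knowing:

* ~0.5 s at each recording edge carries filter transients;
* the notch has finite transition bands (±3 Hz per harmonic), so
  preprocessing is only *approximately* idempotent — repeated application
  changes a broadband signal by &lt;5 % RMS (tested);
* constant signals and recordings shorter than 2 s are rejected.

## Wavelet features

The observation vector is built from a continuous wavelet transform with
the analytic Morlet wavelet, center-frequency parameter ω₀ = 6 (the common
convention; the scale–frequency map is f = ω₀·fs/(2π·s)).  Implementation
uses PyWavelets' complex Morlet `cmorB-C` with B = 2, C = ω₀/2π, which
equals the analytic Morlet up to normalization.  For each of seven bands
(delta handled as 0.5–4 Hz to keep scales bounded) a log-spaced grid of 8
scales spans the band — comfortably more than the ~6 per band needed to
sample the narrowest band — and the per-window feature is the **mean
absolute coefficient** over the band's scales and the window's samples.
Mean |coefficient| is the standard magnitude summary and is monotone in
band power; per-band normalization constants are irrelevant downstream
because features are z-scored before mixture fitting.  Bands above Nyquist
are dropped with a warning.  The 14-D variant appends Δc, the first
difference of c between consecutive windows, with Δc₁ = 0 so features and
labels stay aligned.

## Gaussian-mixture HMM

States follow a first-order, time-homogeneous Markov chain; each state
emits from a full-covariance Gaussian mixture (diagonal available via
`diag_cov=True` for high-D stability).  Inference uses per-step-normalized
(scaled) forward–backward recursions; emission log-densities are computed
via Cholesky factors and rescaled by their per-window maximum before
exponentiation, so sequences of ~10⁵ windows run without underflow.  The
scaling constants accumulate the exact log-likelihood; the suite verifies
it against an exhaustive path-sum oracle to &lt;1e-8 and against an
independent HMM library.

Training (Baum–Welch):

* **Initialization.**  "Random initialization" underdetermines a
  reproducible scheme, so: cluster the pooled windows into Q groups with
  k-means, place each state's M component means by k-means++ *within* its
  group, per-state covariance from the group, uniform weights, uniform
  transitions with small symmetric noise, uniform initial distribution.
  Keeping a state's components in the same region of feature space matters:
  random groupings of Q·M global centers routinely strand EM in local
  optima where components sit in the wrong state.
* **Multi-sequence EM.**  Sufficient statistics are summed over sequences
  before the M-step; this is the default mode for model selection.  Fitting
  a single long sequence drives the initial distribution to one-hot on that
  sequence's first state, which charges a held-out sequence starting
  elsewhere a large, topology-dependent first-window penalty — enough to
  swamp a 0.25 AICc band.
* **Regularization.**  Covariances are symmetrized and floored by
  1e-6 × the per-dimension data variance on the diagonal each M-step, with
  escalating jitter if a Cholesky still fails.  A component whose
  responsibility mass falls below 1e-8 is re-seeded at a random observation
  (logged) with the global covariance.
* **Convergence and restarts.**  Stop when the relative LL improvement
  drops below 1e-4 (default) or at `max_iter` (200).  `n_restarts` (default
  5) independent initializations are run; the best final LL wins.  The LL
  trace of each run is monotone to within 1e-8 (tested over 50 seeded
  fits); re-seeding of empty components can in principle break monotonicity
  but does not occur in the test conditions.
* **Decoding** is by argmax of the marginal posterior γ per window (ties to
  the lowest index), matching how the state trace is used for stage
  assignment; Viterbi is deliberately not the primary path.

The initial distribution π is not part of the original formulation as
published; it is initialized uniform and re-estimated, the standard
Baum–Welch completion.  Feature z-scoring uses training-set statistics and
is stored on the model, so decoding new data reuses the same scaler.
Models serialize to JSON losslessly (Python floats round-trip bit-exactly).

## Feature and topology selection

**mRMR.**  Relevance V_F is the one-way ANOVA F-statistic of a feature
grouped by the binary chronic/non-chronic target; redundancy W_c the mean
absolute Pearson correlation with the other candidates (defined as 1 for a
singleton set so the quotient reduces to V_F).  Features are ranked by
V_F/W_c in one pass against the full candidate set (the MIQ-style variant
that yields a single ranked table) rather than greedy incremental
selection.  The correlation measure and the number of features to keep
(`top(k)`, default 2) are choices, not derivations: both F-statistic and
|Pearson| are invariant to affine feature rescaling, which the suite
checks.  Zero-variance features get quotient 0 and rank last.

**AICc.**  K = 3QM + Q² parameters per topology;
AICc = −2·LL + 2K + 2K(K+1)/(n−K−1), evaluated on held-out sequences whose
pooled window count is n.  The correction is always applied (it vanishes as
n grows) and requires n &gt; K+1; undersized cells are skipped with a
warning.  After rescaling to the grid minimum, the selected topology is the
minimum-K entry with ΔAICc &lt; 0.25, ties broken by smaller Q then M.
Whether the LL entering AICc should come from training, validation or test
data is ambiguous in the source formulation; held-out evaluation is the
default here and the training set is used when no evaluation set is given.

## Chronic-interval marking and state assignment

The preferred anchor is an annotation file.  The automatic surrogate is a
short-time largest-Lyapunov-exponent trace (Rosenstein's method): per
sliding window (default 5 s, hop 1 s), delay-embed (m = 7; delay at the
first autocorrelation zero crossing), pair each point with its nearest
neighbor outside a Theiler window of one mean period, track the mean log
divergence over a 0.1 s horizon and take the least-squares slope.  The
estimator reproduces ln 2 on the fully chaotic logistic map to within a few
percent and ≈0 on periodic signals.  Onset is the first sustained
(≥5 windows) excursion of λ below its own 20th-percentile band — "drop" is
the default direction, consistent with the lowered complexity of
synchronized ictal rhythms — and the interval ends at the first sustained
recovery.  Both direction and thresholds are configurable; a trace with no
sustained transition raises rather than guessing.

Assignment anchors the state with the highest mean γ inside the chronic
interval as *chronic* (a warning fires if no state clearly dominates).
Walking backward through the decoded trace from onset, newly encountered
states become *late_tonic* then *early_tonic*; the earliest pre-chronic
state is always *interictal*.  With exactly one pre-chronic state the
early/late split is meaningless and the state is labelled generic *tonic*.
States first appearing after chronic offset are *postictal*; never-visited
states inherit the label of their strongest transition-matrix neighbor
(interictal as the final fallback).  The procedure is deterministic and
equivariant under state relabelling (tested).

## Detection statistics

An event is detected (TP) if any chronic-labelled window starts within
30 s after the annotated onset; specificity counts non-chronic labels among
windows ending ≥30 s before any onset, with seizure-free records
contributing all windows.  AcSOT is the first chronic call inside the
1-minute horizon centered on the onset, ΔT = EcSOT − AcSOT (positive =
early).  The optimality index combines them as
O = ½(TP+TN)·(1 − min(|ΔT|, d)/d), normalized to [0, 1]; the source
formulation cites but does not print its equation, so this form — chosen
for its bounds, monotone delay penalty, and agreement with "larger is
better" — is isolated behind a single function to be swappable.  A missed
event zeroes the delay factor.  Aggregate O is the mean of per-event O
values computed with dataset-level TP/TN fractions.

## Synthetic data

`simulate_hmm_features` draws exact samples from a given model (ancestral
sampling, single seeded generator) and is the oracle for inference and
recovery tests.  `simulate_sle_lfp` concatenates stages of band-limited
noise: per band, white noise is 4th-order-Butterworth bandpassed, RMS
normalized, weighted by the stage's seven-band amplitude profile and
summed; Poisson-timed Morlet-like bursts (Gaussian-enveloped oscillations,
50–150 ms, 2–4× noise amplitude) add the broadband spike transients a
detector must tolerate; a stage gain scales the sum.  Ground-truth
intervals are exact by construction.

The default five-stage recipe fixes durations at the time scale of in
vitro low-Mg²⁺ events — interictal 60 s, early tonic 30 s, late tonic
20 s, chronic 74 s, postictal 30 s, hence EcSOT = 110 s — and uses spectral
profiles chosen once as plausible stage phenomenology (slow-wave dominated
baseline and postictal, power shifting through theta/alpha into a
beta-heavy, high-amplitude chronic discharge).  No quantitative per-stage
spectra were available to copy, so these profiles are a modelling choice.
What passing synthetic benchmarks shows: the full chain (preprocessing,
CWT features, EM, assignment, metrics) is internally correct and detects
stage transitions when stages differ spectrally at realistic magnitudes.
What it does not show: performance on real slice or clinical recordings,
whose stage boundaries are gradual, nonstationary within stage, and
contaminated by artifacts the generator does not emulate.

## Problem sizes and determinism

All randomness flows from explicit integer seeds (numpy `SeedSequence`
spawning); simulators are bit-reproducible.  The bundled studies use
desk-scale sizes chosen to make the statistical assertions sharp: 100
random small models against the exhaustive oracle; 50 seeded fits for EM
monotonicity; 20 seeds × 5000 windows for two-state recovery (±0.05 on
transitions, ±0.1 on means, ≥90 % success); 20 seeds × (5×300 train,
4×200 eval windows) for topology selection over Q=1..5, M=1..3 (≥70 %
correct (3,2), observed 19/20); ten simulated events for the end-to-end
benchmark (observed TP 100 %, TN ≥95 %, |ΔT| ≤10 s, mean O ≥0.9).

## Known limitations

* Stage durations are geometric under a time-homogeneous chain; real tonic
  and chronic phases have peaked duration distributions (a semi-Markov
  extension is out of scope).
* The Lyapunov onset marker is a reproducible surrogate for expert
  judgment, not a validated clinical rule; annotations are preferred.
* mRMR uses a binary chronic contrast; multi-class relevance and
  mutual-information redundancy are not implemented.
* Full covariances with D = 14 need generous data per component; use
  `diag_cov=True` on short recordings.
* EDF reading requires the optional `mne` dependency; the tested text
  format is two-column CSV.
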