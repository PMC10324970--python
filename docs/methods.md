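# Methods

This note records the models implemented in `semgkit`, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the synthetic benchmark does and does not demonstrate.

## Data model and preprocessing

A trial is a finite matrix (samples × channels) at a fixed sampling rate
with one 0-based gesture label; a trial set shares rate and channel count.
The on-disk dialect is one headerless numeric CSV per trial plus a manifest
(`trial_path,subject_id,label[,fs]`); labels are remapped to a contiguous
index on load and the mapping is kept.

ICA artifact removal uses fixed-point ICA with symmetric (parallel)
decorrelation per trial: channels are centered, whitened and unmixed;
components whose absolute excess kurtosis exceeds a threshold (default 8,
chosen so ordinary band-limited EMG-like components are never touched while
spike-like artifacts with kurtosis in the tens are) are zeroed before
re-projection. With the threshold at infinity the step is an identity up to
round-off, so it degrades safely. ICA is applied per trial (a flag-level
choice; applying it per subject across trials would estimate one unmixing
from more data but assumes a stationary mixing matrix across a session).

Windowing is 0-based with half-open ranges `[i*hop, i*hop + w)`;
`T = floor((n - w)/hop) + 1`. The dynamic-graph default window is a quarter
second with non-overlapping hops, giving T = 4 intervals on 1-s trials —
enough intervals for a temporal profile while leaving ≥ 250 samples per OLS
fit.

## Strategy 1: dynamic graph and graph entropy

The Granger test for "x causes y" compares restricted (own lags) and
unrestricted (own + x lags) least-squares fits through
`F = ((SSR_r - SSR_u)/L) / (SSR_u/(n - 2L - 1))` with the p-value from the
F distribution. The lag order L is selected by BIC over 1..max_lag
(default 8) **on the restricted model only**: the selection then depends
only on the target series, so it cannot be steered by the candidate cause
and the test's size stays at its nominal 5% (measured 0.047–0.056 over
1000 null replicates). Signals above 1 kHz are decimated (anti-aliased) to
1 kHz before fitting to keep the short-window OLS well conditioned.

Edge weights are spurious-correlation coefficients (1 without causality,
1 − |PCC| with it); the Pearson correlation is computed on the same
windowed segments as the Granger fit. Because causality is directional
while the entropy formulas treat the graph as undirected, the two directed
coefficients are symmetrized by their mean (default); `min` and `directed`
modes are available. Entropies use the natural logarithm with the
`0·ln 0 = 0` convention; per-vertex and per-interval entropies are
concatenated into a vector of length `T(1 + n_channels)`. No
multiple-testing correction is applied across channel pairs — each pair is
tested at α = 0.05 on its own, which is the convention the weight
definition presumes.

## Strategy 2: LTSA / LLC with a stacked-RBM + ELM classifier

The reducers consume one row per trial; by default the row is the
concatenation of per-channel RMS, variance, waveform length and
zero-crossing count (4·n_channels dimensions) — classic amplitude
descriptors that any practitioner computes anyway, chosen because the
reduction stage needs a fixed-length vector and the source material leaves
this mapping open.

LTSA builds, per point, the neighbourhood consisting of the point itself
plus its k nearest others (self-inclusion guarantees every point is
constrained by at least one neighbourhood; with exclusive neighbourhoods a
point outside everyone's k-NN would be unconstrained and corrupt the null
space). Local tangent coordinates come from the SVD of the centered
neighbourhood; the alignment matrix accumulates `I − GGᵀ` with
`G = [1/√m, V_d]`. Because the bottom eigenspace is exactly degenerate on
flat data (the constant vector and the true coordinates share eigenvalue
0), the constant direction is deflated explicitly from the d+1 bottom
eigenvectors instead of trusting eigenvalue order. Embeddings are defined
up to orthogonal transforms, so all tests compare via Procrustes residuals.

LLC fits a mixture of probabilistic PCA models by EM (responsibilities via
exact Gaussian densities; M-step via the closed-form PPCA solution of each
component's weighted covariance, which keeps the log-likelihood
non-decreasing), then aligns the responsibility-weighted local coordinates
(with a homogeneous column per model) through
`(UᵀMU) L = λ (UᵀU) L`, `M = (I−W)ᵀ(I−W)` with LLE reconstruction weights
W. Eigenvalues below 1e-10 of the trace are treated as null space. Empty
components trigger up to three seeded re-initializations.

The classifier stacks RBMs trained greedily with CD-1. Visible data are
min-max scaled to [0, 1] and treated as probabilities (no sampling of the
data layer); the negative phase samples the hidden layer and the visible
reconstruction, taking hidden probabilities from the sampled
reconstruction — this keeps the expected update zero when the data
distribution equals the model distribution. The ELM readout is the
minimum-norm least-squares solution β = H⁺T on one-hot targets; fine-tuning
is plain gradient descent on squared error with step-halving (so the
training loss is non-increasing by construction), after which β is
re-solved. Topology search runs global-best PSO over integer-encoded
(depth, width-index) coordinates with validation error as the objective;
the swarm default is 20 particles (a 50-particle preset is exposed).
Because LTSA/LLC have no out-of-sample extension (deliberately out of
scope), the benchmark computes the label-free embedding on the full set and
cross-validates only the classifier on the embedded coordinates; for the
reduced 60-trial benchmark the embedding neighbourhood is k = 15, since k
must exceed the target dimension d = 10 with some margin to give stable
tangent estimates.

## Strategy 3: EWT, differential entropy, HFCM

Boundary padding forecasts each end by nearest-neighbour regression: the
next sample is the mean successor of the k most similar length-k history
windows (k = 5). Spectral boundaries are the minima of the smoothed FFT
magnitude spectrum between the n_bands largest modes ("auto" keeps modes
above 10% of the peak). The filter bank is Meyer-type with transition
half-width γ·ω at each boundary and the standard seventh-order polynomial
transition profile; admissibility requires γ < min (ω₂−ω₁)/(ω₂+ω₁) over
adjacent boundaries (Nyquist included), and the feature pipeline clamps the
default γ = 0.2 to half that bound when detected boundaries sit close
together. The squared filter responses form an exact partition of unity
(tight frame), and each component is the inverse FFT of the spectrum times
one squared response — so the components sum back to the signal to machine
precision while each remains strictly band-limited. On broadband inputs
whose smoothed spectrum yields too few modes, evenly spaced boundaries over
the occupied band are substituted (logged).

Differential entropy is the Gaussian closed form ½ ln(2πe·E/N) with E the
centered energy — equivalently ½ ln(2πeσ̂²) with the biased variance — in
nats. Constant windows are a degenerate-input error.

The HFCM is `S(t+1) = tanh(Σ_l M_l S(t−l+1) + m₀)` over h lags (default 2).
Weights are fitted by ridge least squares on the artanh-linearized targets
(ridge 1e-3 by default, bias unpenalized; states at ±1 are clipped by 1e-6
before artanh). Fitting accepts a list of trajectories pooled into one
regression, because a single free-run trajectory of a contractive map
collapses to its fixed point and cannot identify the weights.

The full feature vector per channel is [HFCM weights and biases over the
band-entropy series, rescaled per node to (−0.9, 0.9)] ++ [mean and SD of
each band's windowed entropy]: length
`n_channels (n_bands² h + n_bands + 2 n_bands)`. Ablation modes drop the
entropy block, the map block, or the band decomposition (whole-signal
entropy series); the pure band-decomposition ablation falls back to band
energy fractions and log energies so it still emits a non-empty vector.

## Strategy 4: LMD, fuzzy C-means, hybrid-kernel LS-SVM

LMD sifting alternates subtracting the smoothed piecewise local mean
(midpoints of successive extrema) and dividing by the smoothed local
magnitude (half-distances), both smoothed by a moving average of span
`odd(fs/100)`. Two stabilizers matter on broadband signals: the magnitude
is floored at 5% of its maximum (otherwise divisions in near-flat regions
amplify without bound), and sifting stops as soon as the envelope deviation
`max|a−1|` stops improving (tolerance 1e-2, cap 30 iterations). The FM part
is normalized into [−1, 1] by transferring any global excess into the
envelope, preserving the product exactly; components are subtracted in
turn, so reconstruction is exact by construction. Per product function the
features are energy, envelope mean and SD, and the mean and SD of the
instantaneous frequency from the analytic-signal phase derivative of the FM
part (5% edge trim); missing functions are zero-padded (3 retained by
default → 15 numbers per channel per function set).

Fuzzy C-means alternates the closed-form center and membership updates from
a random row-normalized membership matrix (fuzzifier m = 2); points
coincident with a center receive crisp membership. Trials are encoded by
their membership degrees concatenated to the raw feature row
(memberships-only mode available); what is clustered is the trial feature
vectors.

The LS-SVM solves `[[0, 1ᵀ], [1, K + I/γ]] [b; α] = [0; y]` (jitter of
1e-10·trace added once if singular); multi-class is one-vs-one majority
vote with ties broken by summed decision values. The hybrid kernel is
`a·exp(−‖p−q‖²/2σ²) + (1−a)·((p·q)+1)^O`; both summands are Mercer kernels,
so the mixture is too. Raw polynomial values grow with the feature
dimension while the RBF is bounded by one, so the pipeline scales rows by
1/√d before the machine (a preprocessing step — the kernel definitions are
untouched); without it the mixture degenerates to whichever summand has the
larger scale. Hyperparameters (a, log σ², log γ, order) are tuned by the
shared PSO on inner cross-validation error.

## Synthetic generator

The generator emulates the study geometry — 15 gesture classes × 24
repetitions, 8 channels, 4 kHz, 1 s — with a reduced preset (5 × 12 at
1 kHz) for quick benchmarks. Per channel it draws Gaussian-driven AR(2)
noise (coefficients 1.0, −0.5) band-passed to 20–450 Hz; class identity is
carried by (i) an "active channel" mask scaling half the channels to RMS
0.35, (ii) two class-specific directed lag-1 couplings with coefficient
`coupling_strength` (default 0.6) injecting true Granger structure, and
(iii) a class-specific 2–5 Hz amplitude envelope of depth `envelope_depth`
(default 0.6); white measurement noise is added at `snr_db` (default 20,
defined on per-channel RMS; −inf yields pure noise for chance-level
checks). Everything derives from one seed and regenerates bit-identically.

Each structural knob exercises one strategy's core assumption: coupling for
the causality graph, the mask and envelope for amplitude/band features, the
AM structure for LMD. The generator does **not** model motor-unit action
potentials, electrode crosstalk, fatigue drift or inter-subject
variability, so passing benchmarks demonstrate that each pipeline detects
the statistical structure it targets — not field-ready decoding accuracy on
laboratory recordings.

## Benchmark sizes and evaluation

The benchmark and the acceptance script run the reduced preset (60 trials,
1 kHz) with stratified 5-fold cross-validation and seeded folds; the tuned
hybrid-vs-linear LS-SVM comparison averages five generator seeds. These
sizes give each pipeline a few hundred windows/fits per run while keeping
the full sweep in the minutes range on one core. Multi-class sensitivity
and specificity are macro-averaged one-vs-rest (micro available); the
"good detection rate" is reported as macro recall — an interpretation,
since the quantity is conventionally shown only graphically. Classes
absent from a fold's truth are skipped with a log message rather than
poisoning the average.

## Known limitations

- Granger edges are bivariate; conditional (multivariate) causality and
  transfer entropy are out of scope, so common-driver effects can create
  edges between both driven channels.
- LTSA/LLC embeddings are transductive (no Nyström extension); the
  strategy-2 benchmark protocol reflects that.
- The ACO/BSO/GSO optimizers named alongside PSO are represented only by
  the shared minimizer interface; PSO is the single concrete implementation.
- LMD envelope estimates degrade near the signal edges (hence the 5% trim)
  and the 5% magnitude floor biases envelopes in near-silent stretches.
- The EWT component definition uses the squared (analysis × synthesis)
  response so that components sum exactly to the input; band edges are
  therefore slightly softer than the raw Meyer response.
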