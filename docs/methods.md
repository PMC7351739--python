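# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limits of what the tests demonstrate.

## Behavioral model (Q-PH family)

The instrumental lick response in the go/no-go reversal task is modeled
as a two-state (odor A / odor B), two-action (lick / restrain)
Q-learning agent with a Pearce–Hall associability term. On every trial
the prediction error is δ = r − Q[s,a] and the associability α relaxes
toward |δ| at rate η ∈ [0, 1], acting as a surprise-driven learning
rate. Three variants are implemented:

* `qph_kappa` — separate learning rates κ₁ (lick) and κ₂ (restrain);
* `qph_eta` — one κ but action-specific η₁/η₂ in the α update;
* `qph_f` — forgetting: the unchosen action of the visited state decays,
  `Q[s,a′] ← Q[s,a′] − κ_F α_F Q[s,a′]`, with
  `α_F ← (1−η) α_F + η Q[s,a′]` (pre-decay value). Setting κ_F = 0
  recovers the hybrid Rescorla–Wagner/Pearce–Hall model exactly
  (machine-precision identity, tested).

Initialization: Q = 0.5 for every state/action pair, α = α_L = α_F = 0.
Rewards are binary (r ∈ {0,1}; reward volume is not modeled, since only
the binary feedback enters the updates). Original and reversal phases
are fit jointly with no latent reset; the contingency change reaches the
agent only through the rewards. The impulsive Pavlovian lick component
is deliberately not generated or modeled — the agent is purely
instrumental.

**Fitting.** Maximum likelihood with softmax choice probabilities
(overflow-safe log-sum-exp), L-BFGS-B within box bounds (rates and η in
[0,1], β in [0,500]; the rate bound is the standard learning-rate range
and keeps Q in [0,1], an invariant under binary rewards that is
property-tested). Default 256 uniform-random restarts (the restart count
is configurable; the best log-likelihood is monotone in it, and the
plateau is reached well below the default); half the β starts are drawn
from [0,20] where the likelihood is typically curved, the other half
span the full bound. Optimality tolerance 10⁻⁶. Model-comparison and
LRT studies use 48–64 restarts per fit: the 3–4-parameter likelihoods
plateau well before that, and it keeps recovery studies tractable. The
nested LRT fits the restricted (κ_F = 0) model first and seeds the full
fit with its solution, so the likelihood ratio is nonnegative by
construction.

**Identifiability.** The associability rate η is weakly identified from
choice data alone at session scale: profile likelihoods over η are flat
to within ~1 log-unit across most of [0,1] for 400-trial sessions
generated at (κ_L=0.4, κ_F=0.1, η=0.3, β=5). The median absolute error
of η̂ across such sessions is accordingly ≈ 0.2 — an intrinsic property
of the likelihood surface (the optimizer demonstrably reaches the
global optimum), not of the optimizer. β and the product-level dynamics
are recovered well. This is a known weakness of Pearce–Hall parameters
estimated from behavior without physiological regressors.

**LRT calibration.** Under the null, κ_F = 0 lies on the boundary of its
parameter space, so the χ²(1) reference (which the comparison
deliberately retains) is conservative: the asymptotic rejection rate at
nominal 5% is 2.5% (a ½χ²₀+½χ²₁ mixture), and finite-sample behavior
sits at ~1–2.5%. Calibration runs use 800-trial sessions to be closer
to the asymptotic regime.

**Model-recovery study conditions.** Generating parameters are chosen
once so each variant expresses its distinguishing mechanism strongly:
κ-variant (0.8, 0.1, 0.5, 6), η-variant (0.8, 0.7, 0.02, 4), forgetting
(0.4, 0.5, 0.4, 5). The η-variant is intrinsically hard to separate
from the κ-variant (action-specific attention and action-specific
learning rates mimic each other closely); its mean-BIC margin is small
but consistent.

## Task simulator

Odor sequences are pseudorandom with at most three consecutive repeats.
The inter-trial interval is uniform in mean ± jitter (10 ± 2 s). The
contingency reverses on the first trial after the trailing fraction
correct over 50 trials reaches 0.8; sessions that never reach criterion
are returned complete with an `incomplete` flag rather than truncated,
mirroring the exclusion workflow for real sessions. The
reward-triggering (third) lick is placed at retrieval onset plus a fixed
0.1 s, a simple stand-in for the unreported lick-latency distribution.

## Spiking simulators

Units are inhomogeneous Poisson: rate = rectify(baseline × drift(t) +
Σ odor kernels), sampled on a 1-ms grid (2 ms in the long
population-study sessions; all rates ≤ 10 Hz, so the per-cell Bernoulli
approximation error is negligible). Kernels are boxcars with amplitude
(possibly negative), latency and duration; a per-trial value trace can
scale a kernel's amplitude by (1 + gain × V), restricted to one odor
where the design calls for it. Rectification at zero is the simplest
contract satisfying nonnegativity; no soft-plus. Directed couplings add
to the target train a spike at source-time + lag + N(0, precision) with
a given (optionally per-trial) efficacy. Laser blocks add a spike per
pulse at latency + N(0, jitter) with probability p_follow.

What these generators do *not* emulate: refractory periods, bursting,
sniff-locked spike timing, biophysical membrane dynamics, correlated
noise beyond the injected couplings, electrode drift or unit loss.
Passing tests therefore demonstrate the correctness and calibration of
the analysis chain on data satisfying its statistical assumptions, not
performance on real recordings.

## Spike detection

Per-sample median subtraction across channels (removes common-mode
signals exactly; with few channels of *independent* noise it slightly
fattens the residual's tails, which is why the SNR fixture is single
channel), 4th-order Butterworth band-pass 300–5000 Hz applied
forward-backward, threshold 7.5 × the raw MAD of the filtered trace (the
Gaussian consistency factor 1.4826 is deliberately omitted; the
multiple applies to the raw MAD), detection of negative-going peaks
(extracellular convention, configurable), greedy 1-ms pruning keeping
the higher peak with exact ties broken toward the earlier sample, and
within a tetrode the timestamp of the highest peak. Waveforms are cut
−10..+21 samples around the peak. The MAD is computed over the whole
trace, per channel. The SNR of a fixture is defined as the *filtered*
template peak over the filtered-noise MAD (the band-pass attenuates the
raw template peak by ~30%, so specifying SNR on the raw peak would be
ambiguous).

## Sniff analysis

Pressure is band-passed 1–50 Hz; inhalation onsets are the
negative-going zero crossings (configurable anchor). The per-trial
statistic is the frequency implied by two full cycles after odor onset
over that implied by the two cycles before; trials with fewer than two
full cycles on either side are dropped and counted.

## Unit classification

Passive rule: SPN iff baseline < 5 Hz, gated on stability (start-to-end
block drift < 10%, any block within 20% of the session mean). The gate
is evaluated on session thirds using a 5-s pre-onset window because at
~1 Hz the sampling noise of short windows would otherwise masquerade as
drift. The first ten odor trials are excluded from response statistics
(habituation). Task rule: < 2 Hz → SPN; > 12 Hz → fast-spiking
(excluded); 2–12 Hz → cholinergic iff ISI CV < 1.2 and < 60 ms ISIs are
≤ 20%; else SPN iff the fraction of > 2 s ISIs exceeds 10⁻⁴; else
fast-spiking.

auROC traces use 200-ms bins stepped by 50 ms over −0.5..1 s around the
event against a control distribution pooling the ten 200-ms bins tiling
the 2 s before the event. The auROC is computed by direct comparison
counting, P(X>Y) + ½P(X=Y), which equals the normalized rank-sum
statistic — the independent oracle used in tests. Responsiveness is a
Friedman test laid out as trials × (baseline bins + sliding bins);
the exact block structure is not uniquely determined by the source
description, and this layout is the documented choice. VTA types are
clustered on the concatenated CS+ and US auROC traces (agglomerative,
L1 metric, average linkage, cut at three), and clusters are mapped to
type I/II/III by least-L1 assignment of cluster means to archetype
templates; type I (CS+ and US excitation) is the dopaminergic class.

Tagging: test cross-correlogram at 1-ms bins over 0–20 ms lags; 10,000
control CCGs with every pulse independently jittered uniformly in
±30 ms; tagged iff two consecutive test bins exceed the 95th percentile
of the pooled bins of all control CCGs (a one-sided, activation-only
criterion). With 20 bins this one-sided rule has a nominal family-wise
false-positive rate of about 5%, and the calibration suite bounds it at
7.5% across rates 0.5–20 Hz.

## Population analysis

Trials are averaged in non-overlapping consecutive groups of three
(remainder dropped from the phase end; the 'pre' phase instead drops its
*initial* trials whenever truncation is needed, keeping the trials
closest to pairing). Sessions are concatenated unit-wise after
truncation to the common minimum group count, either progressively
(k-th with k-th) or as independently permuted realizations (default
300) to verify that trial-matching order does not drive a result.

Deviation from baseline: per trial-group, the baseline vector is the
mean of n_bl consecutive pre-onset bins (behavioral paradigm: 0.4-s
bins, n_bl = 3 from −1.8 s, 12 post-onset bins tested; passive: 0.25-s
bins, n_bl = 4 from −1.75 s, 7 bins tested), compared per post-onset
bin with two-sided t-tests, Benjamini–Hochberg corrected across bins.
Response vectors average the response window (0.6–1.8 s behavioral,
0.5–1.25 s passive). Both metrics are always computed; the Euclidean
metric normalizes by the number of units so values are comparable
across population sizes. The full pairwise-distance tables are emitted
for ANOVA-style analyses, but the package's own summary tests operate
on one mean distance per trial-group — raw pairwise distances share
group vectors, and treating them as independent samples
(pseudo-replication) would inflate significance in the no-effect
control.

Decoding: PCA is fitted once on the pooled response vectors of all four
odor × phase groups so both phases share one space; QDA per phase
under leave-one-out cross-validation; a dimension D is refused when the
QDA parameter count 2(D(D−1)/2 + 2D + 1) − 1 reaches the number of
points in a phase; pre-vs-post accuracy is compared by Fisher's exact
test, BH-corrected across dimensions 3–6. Singular class covariances
fall back to a small regularization (logged). Visualization uses delay
embedding (m = 3, delay 1 bin) with three-factor factor analysis, and
metric MDS to three dimensions; both are plotting aids with no
downstream statistics.

## Assembly detection

Spike trains are binned at ten resolutions Δ ∈ {0.01, 0.015, 0.03,
0.05, 0.08, 0.12, 0.25, 0.35, 0.5, 0.6} s with per-Δ maximum lags
{20, 20, 20, 20, 20, 10, 7, 5, 5, 5} bins; the smallest representable
nonzero lag is one bin of the finest scale, 10 ms. The per-lag statistic
is the coincidence count C(l) = Σ_k min(a_k, b_{k+l}).

The significance machinery is a reimplementation in spirit, not a port:
the null is built from spike-time jitter surrogates — every spike of
*both* trains is displaced uniformly within ± max(4, max_lag + 2) bins
(wrapping at the edges) — which destroys coordination at every tested
lag while preserving slower rate structure. Jittering both trains
matters: conditioning on one train's realized spikes understates the
null variance and inflates the false-positive rate under strong rate
co-modulation. The tested statistic is the reference-lag contrast
D(l) = C(l) − C(l*) with l* = −2 (the reference lag excluded from the
candidate set): slow co-fluctuation raises C at every lag alike, so the
contrast cancels it — including the small rate-smoothing bias the
jitter itself introduces. Family-wise control across lags within a
pair–scale uses the maximum of D over lags recomputed per surrogate
(199 surrogates by default; the empirical p-value floor is 1/200);
Benjamini–Hochberg correction is applied across pairs × scales. The
best lag is the one with the largest standardized excess over the
surrogate ensemble. Pruning keeps, per significant pair, the scale with
the smallest p-value (ties broken by the standardized excess), with an
optional second pass restricted to scales ≤ 250 ms so sharp patterns
are not absorbed by broad ones. Calibration: on independent pairs whose
rates share a 10-fold slow sinusoidal co-modulation, the detection rate
at nominal 5% stays below 7.5%; on coupled pairs (efficacy 0.5, lag
0.2 s, precision 0.05 s, 20-minute recordings) detection exceeds 90%
with the lag recovered within one bin.

A consequence of the reference-lag contrast: a genuine coupling at
exactly l = −2 bins is invisible at that scale (it is absorbed into the
reference). This mirrors the original construction's asymmetry and is
irrelevant for the directional questions asked here (source-leads-target
couplings live at positive lags).

Assembly activity for learning dynamics and regression is the number of
joint-pattern occurrences in the 0–0.7 s window after CS onset; initial
versus late comparisons use the first and last 12 CS trials per phase
(paired Wilcoxon).

## Value regression

Per-trial CS+ activation counts are regressed on V_CS+(t) with a
Poisson GLM, log μ_t = β₀ + β V. Standardization uses the fitted means:
β̄ = β σ(V)/σ(μ̂) (σ over trials; "fitted" resolves an ambiguity in the
source description and is deterministic), and β* = exp(β̄) − 1.
Significance is the per-assembly t-statistic, uncorrected by default
with a BH option across assemblies. The baseline-subtraction control
subtracts per-trial pre-CS activity; because differences can be
negative, the control falls back to an ordinary Gaussian identity-link
fit (standardized identically) whenever the Poisson likelihood no
longer applies — with an all-zero baseline it reduces exactly to the
main fit. β̄ and β* are invariant to affine rescaling of V
(property-tested), so the choice of value units cannot change the
reported couplings.

## Plasticity study conditions

The passive-pairing emulation records, per session, ten units around
two odors (210 pre / 30 pairing / 200 post trials, first ten excluded
as habituation): three excitatory units per odor with weak selectivity
(boxcar kernels 2.8 Hz preferred vs 2.55 Hz non-preferred on a 2-Hz
baseline — weak single-unit selectivity is what makes population
decoding land mid-range before pairing, leaving headroom for an
effect), one inhibited unit per odor, two unresponsive. Eight sessions
are pooled (80 units). The plasticity effect under study multiplies the
paired odor's excitatory kernels by 1.3 in 'post'; the control omits
it. The trial counts are set so that even the worst pseudorandom
odor split leaves more points per phase than the QDA parameter count at
D = 6. The acceptance pattern (paired-odor-only deviation change,
pre↔post distances beyond pre↔pre, larger cross-odor distance, higher
decoding accuracy at every dimension, and a silent control) is
evaluated on the Euclidean metric: with weak responses on a low-rate
baseline the cosine metric is dominated by angular noise and actually
*shrinks* pre↔post distances as responses strengthen, while the
normalized Euclidean metric responds to both direction and magnitude.

## Problem sizes

Recovery and calibration studies use: 50 seeds × 400 trials (η/β
recovery, 256 restarts), 50 sessions per generator (model selection, 64
restarts), 200 null seeds × 800 trials (LRT), 400 null and 25 coupled
seeds (assembly calibration), 12 pairs (directionality), 8 sessions
(plasticity), 200 + 500 seeds (regression), 100 + 200 seeds (tagging).
The acceptance script runs the same computations at moderately smaller
sizes and reports each size alongside its value.

## Known limitations

* η recovery from behavior alone is intrinsically poor (see above); the
  value trace V_CS+ is nonetheless recovered accurately because it is
  constrained by the choice sequence, not by η per se.
* The assembly test's empirical p-values are bounded below by
  1/(n_surrogates+1); studies needing smaller p-values must raise the
  surrogate count.
* The synthetic generators make no attempt at biophysical realism
  (see "Spiking simulators").
* Friedman-test layout for auROC responsiveness and the stability-gate
  estimator are documented choices where the source description is
  underdetermined.
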