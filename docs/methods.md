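# Methods

This note documents the models implemented in `emgsort`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Generative model of a MUAP recording

### Template basis

A unit's multichannel template is a low-rank spatiotemporal product: a
shared matrix of temporal components `W ∈ R^{p×t}` (orthonormal rows,
obtained by PCA of isolated waveforms) and per-unit channel weights
`U0_i ∈ R^{c×p}`. The template of unit `i` is `b (U0_i W)^T w_inv`, where
`b > 0` converts amplitude units (default 1.0, a free scale recorded in the
output metadata) and `w_inv` undoes any channel whitening that was applied
when the basis was extracted from a sorted recording (identity for
synthetic bases; a synthetic SPD option exists to exercise the
un-whitening path).

The synthetic generator (`make_synthetic_basis`) composes each unit's
dominant-channel waveform from 2–3 Gaussian-windowed sinusoids, which
guarantees multiphasic shapes (≥ 2 sign changes), and propagates it across
channels with (a) exponential amplitude decay away from a random dominant
channel and (b) integer conduction delays that grow linearly with channel
distance, up to ±`max_delay` samples. All units share one muscle-level
delay gradient with ±20% per-unit jitter: fibers of different motor units
in the same muscle run in the same direction, and this shared gradient is
what makes a single per-channel delay correction meaningful. `W` is the
PCA basis of the generated waveform collection and `U0` its least-squares
loadings, so basis and templates are exactly consistent. The generator is
a pure function of its arguments, including the seed.

What it does not emulate: volume-conduction geometry, electrode impedance
differences, non-Gaussian or correlated noise, electrode drift, and
movement artifacts. Tests passing on this generator show the algorithms
are correct under the stated statistical model, not that they are robust
to every pathology of real recordings.

### Recruitment model

Thresholds are drawn once per unit as `U1 = θ1·Exp(λ=1) + θ2` (λ fixed at
1; θ1 scales the spread, θ2 the floor), so low-threshold units are common
and high-threshold units rare, as in orderly recruitment. Given a drive
signal `F_t`, unit `u` may fire at sample `t` only while
`F_t > U1[u, t]`; it then fires with probability `sigmoid(F_t − U1[u, t])`
(one Bernoulli draw per sample). Each spike adds a history kernel `K` to
the unit's threshold trace over the next `|K|` samples.

The kernel's functional form is a modeling choice (only its effects are
prescribed): a rectangular plateau spanning the absolute refractory period
(default 1 ms) followed by an exponential tail (default τ = 5 ms),
truncated where it falls below 1% of its amplitude. The plateau amplitude
defaults to 10× the drive's dynamic range, which makes the refractory
period absolute — no generated train can violate 1 ms, which the
evaluation stage relies on. The per-sample Bernoulli at 30 kHz would allow
very high rates on its own; the kernel's plateau and tail are what cap the
attainable rate (`empirical_firing_rates` reports realized rates for a
configuration). The time loop is strictly sequential (numba-compiled); a
plain-Python reference implementation of the same loop, consuming the same
pre-drawn uniforms, serves as the oracle in the test suite.

The built-in drive generator produces half-wave-rectified sinusoidal
bursts (default 2 Hz, emulating locomotor step cycles) plus rectified
low-pass-filtered Gaussian fluctuations; any user array can be substituted.

### Waveform variability, windowing, superposition

Every spike gets independent gains `G ~ N(1, 0.2)` applied elementwise to
the channel weights before reconstruction, so each spike instance has a
unique shape whose expectation is the template. Waveforms are windowed by
a zero-padded Tukey window: pads of `round(0.05·nt)` exact zeros on each
side, a Tukey(α = 0.25) taper over the central 90% whose endpoints are
trimmed so the exact zeros are confined to the pads. The spike sample maps
to window sample `nt//3` (the waveform-alignment convention). Overlapping
spikes sum linearly; spikes whose window crosses a recording edge are
placed truncated rather than dropped, so spike-count bookkeeping stays
exact.

### Noise fitting

Per-channel noise levels are the standardized MAD: `median(|C − m|)/0.6745`
with `m` the full-recording channel medians and `C` a chunked subset
(default 20 evenly spaced 1 s chunks; the whole recording when shorter —
the chunk geometry is a convention, chosen for speed). Additive Gaussian
noise SDs `σ_L` (initialized at 0) are fitted by the Adam update rule
(lr 1, β = (0.9, 0.999), ε = 1e-8 — conventional defaults) on the loss
`mean((σ_S − σ_0)²)`, drawing fresh noise each iteration from a
per-iteration substream so the fit is seed-reproducible. The gradient uses
the analytic sensitivity `dσ_S/dσ_L → 1` (exact when the added noise
dominates); its fixed point `σ_S = σ_0` is precisely what the stop rule
requires. Iteration stops when all channels are within 1% relative of
target or after 3000 iterations. Because the chunked MAD is itself a noisy
estimate, the stop criterion is re-verified on full-length fresh noise
before the converged flag is set, and iteration resumes if that check
fails — so `converged=True` guarantees the returned data satisfies the 1%
bound, not merely one lucky draw. Non-convergence warns and flags, never
silently.

## Preprocessing

Band-pass: zero-phase 4th-order Butterworth, 250–5000 Hz default, applied
forward-backward. Notch: 2nd-order IIR, Q = 30, 60 Hz default (50 Hz
configurable). The filter families are conventional choices; only the
passband is prescribed. Bad channels: a channel is dropped when its robust
deviation statistic (MAD, or SD for the `std` variants) exceeds
`threshold ×` the cross-channel median of that statistic; the default
method string is `mad5`. Whitening is symmetric ZCA from the channel
covariance (optionally restricted to `whitening_range` nearest channels),
eigenvalue-floored with a warning when rank-deficient; the inverse is
returned for simulation round-trips. The channel map is dense, linear and
minimal: positions 0, 2, 4, … µm.

Delay correction: Pearson correlation is computed for every channel pair
at every integer lag within ±2 ms (Pearson specifically, for robustness to
per-channel gain and offset; the lag grid is integer samples). The best
lag per pair is the argmax, ties broken toward smaller |lag| and then
toward the negative lag; the reference channel maximizes the summed best
correlations of its row (ties to the lowest index; per-pair maxima are
summed unnormalized). Applying the plan advances each channel by its best
lag relative to the reference, zero-filling vacated edges.

## Template initialization

Crossing extraction runs on whitened data so thresholds are in channel-SD
units. Candidate peaks are spatiotemporal local maxima of |D| (max-pool
over ±5 samples × ±4 channels), which reduces one multichannel spike to
one peak; a peak is kept only if no other peak lies within ±1 ms on the
same or ±6 neighboring channels. Detection operates on absolute value, so
polarity does not matter. Every `nskip`-th batch (default 2, batch 60000
samples) is scanned. Crossings found at multiple thresholds (default list
6/9/12/15) are de-duplicated exactly by (channel, sample); near-duplicates
within ±0.2 ms on a channel collapse to the largest amplitude (the
tolerance is our choice; only "no duplicates" is prescribed). Waveforms
are single-channel `nt`-sample snippets with the peak at `nt//3`.

Outlier rejection is HDBSCAN (Euclidean, raw sample space,
`min_cluster_size` 20) dropping noise-labeled waveforms; with fewer
waveforms than the minimum cluster size the input passes through with a
warning, and the output is always a subset of the input. Temporal
components are the top `n_pcs = 9` right singular vectors of the waveform
matrix (rank deficits padded with an orthonormal complement, with a
warning). Simple templates are the peak-normalized centers of K-means
(k = 9, k-means++, 10 restarts, fixed seed).

The reference detector replicates each template across channels with a
Gaussian spatial envelope whose SD runs over 1–5 multiples of
`min_template_size` (10 µm default) on the 2 µm map — the decay constant
equals the size in µm, the simplest reading of "spatial size" — restricted
to the `nearest_chans` closest channels and unit-normalized, so
matched-filter outputs are in variance units and are thresholded at
`Th_universal = 9`. Detections are greedy non-maximum suppression winners
over ±half a window in time and the nearest-channel neighborhood, keeping
the best size per detection. The detector deliberately stops here: there
is no learned-template second pass, graph-based split/merge, or drift
correction, so its absolute accuracy on dense data is modest by design.

## Evaluation

Stage 1 (pairing): both spike sets are binned at 10 ms; the binned
accuracy of a (unit, cluster) pair counts per-bin matches as
`min(count_truth, count_sort)` and forms `A = match/(truth + sort − match)`
over summed counts (the binned form is implicit in the procedure; this is
the natural completion). Pairs are assigned greedily in descending
accuracy without replacement — equivalent to the lexicographically best
injective assignment, which the tests verify by exhaustive search on small
instances.

Stage 2 (alignment): exactly 41 shifted copies of the matched cluster
(±20 bins of 0.1 ms) are correlated (Pearson) against the truth binned at
0.1 ms; the correlation-maximizing shift wins, ties toward zero shift.

Stage 3 (matching): shifted spike times are matched one-to-one within
±1 ms, greedily by ascending |Δt|, so when several sorted spikes qualify
only the closest is the true positive and the rest count as false
positives; cross-truth contention is resolved by the same ascending-|Δt|
rule (our completion of the closest-wins principle). Then
`P = N_match/N_sort`, `R = N_match/N_truth`,
`A = N_match/(N_truth + N_sort − N_match)`, with 0/0 defined as 0.

Overlap restriction: a truth spike is "overlapping" when a spike of a
*different* unit lies within half a template window (1 ms for 2 ms
windows, 2 ms for 4 ms windows); same-unit neighbors cannot occur at these
windows because the generator forbids refractory violations. Both sides
are restricted through the matched pairs: the truth subset, and the sorted
spikes attributable to it within the matching tolerance.

Error-rate reduction is `100·(1 − e_new/e_ref)`; sweep summaries take the
mean accuracy across units within each run, then median/mean/SD across
runs.

## Composite quality score

Per cluster, with a 1 ms refractory period throughout:

- `S_T1 = 1 − R_C`, where `R_C` is the violation-based contamination
  estimate `1 − sqrt(1 − N_v T / (N² (t_r − t_c)))` (censored period
  `t_c = 0`, counting unordered spike pairs with ISI ≤ `t_r`), clamped to
  [0, 1] and saturating at 1 when violations exceed what full contamination
  explains. The estimator is validated in tests by recovering a planted
  20% Poisson contamination. Clusters with fewer than 2 spikes score 1
  (nothing to estimate).
- `S_T2 = R_P · (1 − A_C)`: presence ratio over 20 s bins with a 0.5 ×
  mean-count threshold, and amplitude cutoff from a 32-bin histogram
  (Gaussian-smoothed, kernel 1 bin) — the mass beyond where the upper flank
  returns to the first bin's height, clamped to [0, 0.5], with edge-peaked
  (undefined) cases scored 0.5.
- `S_FR = logistic(−(R_F1 − 200)) · logistic(−(R_F2 − 200))`: mean firing
  rate and the 95th–5th percentile firing-rate range (0.5 s bins, linear
  interpolation percentiles), both penalized past 200 Hz — rates no real
  motor unit sustains.
- `S_SNR = 1 − 1/(1 + e^{R_SN − 4})`: 0.5 at SNR 4, the level below which
  sorting quality degrades sharply. SNR is the best channel's peak of the
  mean waveform over the robust noise SD (MAD/0.6745 convention).

The logistic terms are computed in a numerically stable form so extreme
rates underflow to 0 rather than overflowing. The per-cluster composite is
the product of the four components; the overall sort score is the mean of
composites and is embedded in the run-folder name (`.score_<value>` to 4
decimals) for ranking. On simulated sorts with graded degradation the
overall score correlates positively (Spearman) with ground-truth mean
accuracy, which is the property the ranking workflow needs.

## Configuration and sweeps

The YAML configuration mirrors the tool's sections; only the `binary`
dataset type is supported (other recognized types are rejected with a
clear message). Sweeps expand by Cartesian product except within linked
groups (default link: the universal/learned similarity thresholds), whose
lists must be equally long and advance together. Runs archive their
configuration with appended result fields; ranking is descending by score,
stable for ties, unscored folders last with a warning. Sweep combinations
are independent, so they can be distributed across processes; the library
itself stays single-process.

## Problem sizes

The test suite and acceptance script use 20–60 s recordings at 30 kHz with
5–10 units on 8 channels; these sizes give the statistical estimators
(MAD, contamination, Monte-Carlo means) enough samples for their stated
tolerances while keeping runs short. All randomness flows through named
substreams of a single root seed, so every simulation, fit and test is
exactly reproducible.

## Known limitations

- The reference detector omits the learned-template pass, so absolute
  detection accuracy on dense recordings understates what a full sorter
  achieves; comparisons should be relative.
- The contamination estimator assumes a Poisson contaminant independent of
  the true train; correlated contamination (e.g. a split unit) biases it.
- The amplitude-cutoff estimator assumes a symmetric amplitude
  distribution; multimodal clusters can evade it.
- The delay model is one global shift per channel; units whose conduction
  geometry deviates strongly from the shared gradient remain misaligned
  after correction, in the simulator as in the real preprocessing.
- Noise is Gaussian and white per channel; line noise and artifacts must
  be injected by the user if needed.
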