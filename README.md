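# emgsort

Simulation, preprocessing, template initialization and evaluation tools for
spike sorting of **motor-unit action potentials (MUAPs)** recorded with
high-density intramuscular EMG arrays.

Sorting EMG differs from sorting cortical data in three ways: MUAPs
propagate along muscle fibers, so the same event arrives at different
channels up to ~2 ms apart; MUAP waveforms are more complex (multiphasic)
than cortical spikes; and during forceful behavior many units coactivate,
so waveforms overlap constantly. `emgsort` packages the algorithms that
address these problems together with a generative simulator that provides
ground truth to measure them against:

- **Simulator** — per-unit multichannel templates are built from orthonormal
  temporal components `W` and channel weights `U0`; each spike `k` of unit
  `i` gets a unique morphed waveform
  `M_k^i = b ((U0_i ⊙ G_k^i) W)^T w_inv`, `G ~ N(1, 0.2)`,
  windowed by a zero-padded Tukey window (α = 0.25, 90% width) and summed at
  spike times. Spike times come from a recruitment model: thresholds
  `U1 = θ1·Exp(1) + θ2`, per-sample firing probability
  `sigmoid(F_t − U1)` gated by `F_t > U1`, with a post-spike history kernel
  added to the threshold so refractory violations cannot occur. Per-channel
  Gaussian noise is fitted with the Adam rule (lr 1) until every channel's
  robust noise level (MAD/0.6745) is within 1% of its target.
- **Preprocessing** — zero-phase band-pass (250–5000 Hz) and notch filters,
  robust bad-channel rejection, ZCA whitening, a dense 2 µm linear channel
  map, and cross-channel delay estimation/removal by correlation
  maximization over ±2 ms lags.
- **Template initialization** — multi-threshold extraction of time-isolated
  waveforms (default thresholds 6/9/12/15 SD, every 2nd batch), HDBSCAN
  outlier rejection, 9 PCA temporal components, 9 K-means simple templates,
  and a reference convolutional detector with Gaussian spatial envelopes.
- **Evaluation** — three-stage matching of sorter output to ground truth
  (greedy pairing on 10 ms bins, correlation alignment over 41 shifts of
  ±2 ms in 0.1 ms bins, one-to-one spike matching at ±1 ms), yielding
  per-unit precision `P = N_match/N_sort`, recall `R = N_match/N_truth` and
  accuracy `A = N_match/(N_truth + N_sort − N_match)`, plus
  overlap-restricted variants.
- **Composite quality score** — without ground truth, each cluster scores
  `S = S_T1 · S_T2 · S_FR · S_SNR` (contamination, presence/amplitude-cutoff,
  firing-rate validity, SNR components, each in [0, 1]); the mean over
  clusters ranks parameter-sweep runs.

## Worked example

Simulate a rat-like dataset (10 units, 8 channels, 30 kHz) and run the
initialization + detection + evaluation chain:

```bash
$ emgsort simulate --species rat --duration 20 --seed 5 --out rec
wrote rec.bin (600000 samples x 8 ch), 3521 ground-truth spikes

$ emgsort init-templates --recording rec --out tpl.npz
278 isolated waveforms -> 9 templates

$ emgsort detect --recording rec --templates tpl.npz --out phy
1172 detections across 9 templates -> phy

$ emgsort score --recording rec --sort phy | tail -1
overall composite score: 0.6976
```

The evaluator itself is exact: feeding the ground truth back as a "sort"
(with arbitrary cluster relabeling) scores perfectly,

```bash
$ emgsort evaluate --truth rec_ground_truth.csv --sort phy --sampling-rate 30000
 unit  matched_cluster  N_truth  N_match   P   R   A
    0              100      510      510 1.0 1.0 1.0
    1              101       84       84 1.0 1.0 1.0
    ...
mean accuracy: 1.0000
```

where `P`, `R` and `A` are the per-unit precision, recall and accuracy
defined above and `mean accuracy` averages `A` over ground-truth units.
The bundled reference detector stops at the simple-template stage (it has
no learned-template refinement pass), so its accuracy on dense recordings
is intentionally modest — it exists to exercise the evaluator and the
composite score, which is what the test suite checks.

## Layout

| Module | Contents |
| --- | --- |
| `emgsort.basis` | template basis container, synthetic generator, NPZ I/O |
| `emgsort.recruitment` | thresholds, history kernel, spike-train generation |
| `emgsort.waveforms` | morphing, windowing, superposition, noise fitting |
| `emgsort.preprocessing` | filters, bad channels, whitening, delay removal |
| `emgsort.templates` | crossing extraction, HDBSCAN, PCA, K-means, detector |
| `emgsort.evaluation` | three-stage matcher, P/R/A, overlap restriction |
| `emgsort.quality` | component scores, composite score, SNR |
| `emgsort.sweep`, `emgsort.cli` | config, sweep expansion, ranking, CLI |

See `docs/methods.md` for the underlying models, parameter defaults and
known limitations.
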