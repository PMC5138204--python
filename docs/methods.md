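# Methods

## Decoding model

The classification feature for a single trial is the sample covariance of
a *super-trial*: the N-channel, M-sample epoch stacked on top of the
class-average target and non-target epochs (the prototypes), giving a
3N × M matrix whose rows are centered to zero mean over the 0–1000 ms
window. The epoch-only covariance of an ERP is nearly class-blind —
the evoked response is small against background EEG — but the
cross-covariance between the trial and the fixed target prototype is
systematically larger for target trials, so stacking the prototypes
embeds the class information in the 3N × 3N covariance. The prototypes
are fixed rows of every super-trial regardless of the trial's hypothesized
class; only classification assigns a label.

Covariances are treated as points of the SPD manifold with the
affine-invariant metric. δ_R is computed from the generalized
eigenvalues of the pair (implemented via `scipy.linalg.eigvalsh(b, a)`),
which is numerically stable and exactly congruence-invariant. The class
means are Karcher means: fixed-point iteration

    C ← C^{1/2} exp( J⁻¹ Σ_j log(C^{-1/2} C_j C^{-1/2}) ) C^{1/2}

initialized at the arithmetic mean, stopped when the Frobenius norm of the
tangent-space mean falls below 1e-8 or after 50 iterations.
Non-convergence returns the last iterate with a flag and a warning rather
than raising: a slightly unconverged mean still classifies, and aborting a
cross-validation sweep for it would be worse. Matrix log/exp/sqrt go
through symmetric eigendecomposition with re-symmetrization.

Degenerate covariances (short epochs, identical rows) are projected into
the SPD cone by `ensure_spd`: symmetrize, then add a diagonal ridge
raising the minimum eigenvalue to 1e-10 × trace/d. Symmetry is validated
at 1e-10 relative tolerance. The regularization is an implementation
choice of this package; with M ≥ 3N (the shipped paradigms) it almost
never triggers.

## Preprocessing conventions

Band-pass 0.1–40 Hz, 4th-order Butterworth applied forward–backward
(zero phase — phase distortion would shift the P300 latency that the
decimated SWLDA features and prototype cross-terms rely on). Epochs are
the half-open window [onset, onset + round(fs)) samples, 0-based onsets;
events whose epoch would cross the recording edge are dropped with a
warning. Zero-mean is enforced by subtracting each row's mean over the
epoch window; there is no separate pre-stimulus baseline because the
window starts at stimulus onset. Prototypes are estimated once per
training fold and passed to the transformer explicitly, so a test trial
can never contribute to its own prototype.

## SWLDA baseline

Features are 20-ms-bin means of each channel concatenated (8 channels ×
51 bins = 408 features at 256 Hz). Forward-stepwise OLS on ±1 labels:
the candidate with the smallest partial-F p-value enters while p <
p_enter = 0.10; after each entry, included features with p > p_remove =
0.15 are removed; selection stops at 60 features or when nothing can
enter. These are the de-facto defaults of the classical P300 stepwise
discriminant. An empty selection yields an intercept-only model that
predicts the majority class; a score of exactly zero is non-target.

## Evaluation protocol

Five-fold cross-validation over whole selection blocks. For each
averaging depth k ∈ 1..5, consecutive disjoint groups of k same-code
epochs within a block are averaged (leftovers discarded). The two
classifiers are calibrated differently, matching how each is actually
used:

- **SWLDA** is fit once per fold on *single-trial* features. Its score is
  linear, so scoring a k-averaged epoch equals averaging k single-trial
  scores — the canonical usage of the baseline.
- **MDM** is refit at each k on k-averaged training epochs, because the
  covariance is quadratic in the trial: averaging shrinks the noise part
  of the spectrum by ≈1/k, and the class means must live at the same
  noise scale as the test covariances.

One command decision is made per selection round (one k-averaged epoch
per code); the decided command is the argmax of δ_R(C, C̄_nontarget) −
δ_R(C, C̄_target) (MDM) or of the linear score (SWLDA), smallest code on
ties. Accuracies aggregate as mean ± SD over folds, stated in the output
metadata; classifier differences are tested with a two-sided Wilcoxon
rank-sum on per-fold accuracies — exact enumeration when both samples are
tie-free with n ≤ 8, normal approximation with tie correction otherwise.

## Synthetic sessions

The simulator emulates the nine tactile/auditory rigs as named presets
(K = 5 or 6 commands; ISI 150 or 400 ms; stimulus duration 100–150 ms; 8
or 16 channels of the standard centro-parietal 10/10 montage; 256 or
512 Hz). Where a rig's description does not fix ISI or sampling rate, the
presets use 400 ms and 512 Hz, typical for this hardware family. Stimulus
order is shuffled within each sub-round (every code once per sub-round,
no immediate-repeat constraint), giving exactly 1:(K−1) target balance.

The ERP model is deliberately minimal: targets receive a single positive
Gaussian bump — peak 450 ms, standard deviation 80 ms, amplitude 5 µV at
the Pz-like channel, scaled across channels by a smooth Gaussian
topography — and non-targets receive nothing. Background noise is white
Gaussian (σ = 10 µV) plus a 1/f-power component (σ = 10 µV), independent
per channel. These defaults are one fixed choice of realistic study
conditions: single-trial ERP-to-background ratios well below one, so that
single-trial decoding is imperfect and averaging visibly helps.

What the simulator does **not** emulate: spatially correlated noise,
alpha rhythms and other narrow-band structure, latency/amplitude jitter
across trials, non-target evoked responses, session nonstationarity,
artifacts. Passing tests therefore show that the geometry, classifiers
and protocol behave correctly under a controlled generative model — not
that the accuracy figures transfer to recorded EEG. In particular, i.i.d.
trials are kind to the amplitude-based SWLDA; on real nonstationary
sessions the covariance approach's advantage is typically larger.

## Problem sizes

The shipped statistical checks use 5-command, 8-channel, 256 Hz sessions:
5 blocks × 5 repetitions (small-training regime) for the
classifier-comparison and high-SNR checks, 10 blocks for the
averaging-trend check, and 12 repetitions for the chance-level check
(60 selections per session), each over 20 seeds. These sizes were chosen
so that every claim rests on hundreds of command decisions while a full
run of the suite stays in the minutes range; the acceptance script
reports the decision counts (`n`) alongside every value.

## Known limitations

- The Karcher mean assumes reasonably conditioned inputs; extremely
  ill-conditioned covariances (epochs far shorter than 3N samples) lean
  on the diagonal loading and lose geometric fidelity.
- `average_erps` discards leftover epochs (< k per group), so high k with
  few repetitions wastes data and leaves one decision per block.
- The EDF writer targets the subset of EDF needed here (integer sampling
  rates, 1 s records, µV channels); it is not a general-purpose exporter.
- SWLDA p-values are nominal OLS partial-F tests, as in the classical
  method; they are selection heuristics, not valid inference.
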