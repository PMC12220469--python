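# Methods

## Model

A preprocessed calcium-activity matrix **V** (N neurons × T frames,
non-negative) is approximated by the tensor convolution of a pattern
tensor **W** (N × K × L) with an intensity matrix **H** (K × T+L−1):

    U[n, t] = Σ_k Σ_{l=0}^{L−1} W[n, k, l] · H[k, t − l + (L−1)]

Columns of **H** cover virtual times −(L−1)…T−1 (`offset = L−1`), so a
sequence whose activation began before frame 0 still contributes its tail
to the reconstruction.  The fit criterion is the Itakura–Saito (IS)
divergence `D(V, U) = Σ v/u − log(v/u) − 1`.  IS divergence is invariant
to a common positive rescaling of V and U, which is the right property
for calcium traces whose noise is multiplicative (see the noise model
below): bright and dim cells are weighted equally in relative terms.

### Updates and guaranteed descent

**W** and **H** are updated jointly by the standard IS-NMF multiplicative
rules (ratios of the transpose convolutions of `V/U²` and `1/U` against
the current factors).  The joint step is not guaranteed to decrease D, so
after each update the candidate pair is repeatedly replaced by the
midpoint between old and candidate factors until D no longer exceeds its
previous value (at most 50 halvings; if none succeeds the old factors are
kept).  The recorded error trace is therefore non-increasing by
construction, and non-negativity is preserved because every operation is
multiplicative or a convex combination of non-negative arrays.

Numerical guards: a floor ε = 1e−8 is applied inside every ratio and
logarithm (the IS divergence is undefined at exact zeros) and to the
denominators of the multiplicative rules.  The same floor keeps freshly
initialized H entries strictly positive — a multiplicative update can
never revive an exact zero.

### Automatic selection of K

Fitting starts from a deliberately generous K₀ = 20.  For each fitted
sequence the overlap trace `R[k, t] = Σ_{n,l} W[n,k,l] V[n, t+l]` (the
sliding match of the pattern against the recording) is computed, and for
every pair of sequences the maximum Pearson correlation over time shifts
up to ±(L−1) frames is taken as their similarity.  Pairs above the
similarity threshold (default 0.3, calibrated range 0.2–0.4) are merged
iteratively — most-similar pair first, dropping the member whose partial
reconstruction carries less energy — until all pairs fall below the
threshold.  Zero-variance overlap rows are defined to have similarity 0:
a flat trace cannot evidence identity with anything.

The overlap used for this determination is taken against the **full**
original matrix, not the short high-density excerpt used for fitting.
This matters: the maximum-over-shifts statistic has a heavy null on short
smooth traces (on 300-frame excerpts, unrelated sequences reach
similarities of 0.26–0.39, which would over-merge at any threshold in the
calibrated range), whereas on the full recording unrelated sequences sit
near 0.06–0.08.

### Staged compression pipeline

Per restart, with the iteration budget (default 200 accepted updates)
split 30 / 30 / 10 / 30 %:

1. **Mini fit.** V is compressed by binning every L frames (mean);
   factors of window 2 are fitted to it.  This stage exists only to
   score frames.
2. **High-density matrix.** Compressed frames are ranked by the maximum
   mini-intensity; the top 10 % (in chronological order) are restored to
   their original full-resolution columns and concatenated.  Full-window
   factors are fitted to this matrix from a fresh Uniform(0, 1)
   initialization, with H scaled so mean(U) ≈ mean(V).  A fresh start
   (rather than warm-starting from the mini factors) makes surplus
   factors compete for the dominant sequences and end up as mergeable
   duplicates instead of persisting as weak noise factors.
3. **Merge.** K is determined as above; survivors are refined briefly.
4. **Full refinement.** H is re-expanded to the full timeline — fitted
   activations are scattered back to their original positions, all other
   entries start at a small positive level (10 % of the fitted mean) so
   they remain updatable — and the factors are refined on the full V.

The whole pipeline is run for several independent restarts (seeded
`base + restart`) and the restart with the smallest final divergence is
kept.  Reported `error_trace` is the full-resolution stage's trace;
per-stage traces sit in `config["stage_traces"]` (each stage optimizes a
different matrix, so only within-stage traces are comparable).

## Synthetic data generator

Each sequence is driven by one master trace integrating
`dx/dt = −x/τ + δ(r(t) < p)` with unit Euler steps: per frame the trace
decays by `(1 − 1/τ)` and jumps by 1 with probability p.  Every cell of a
sequence shows the master trace delayed by an independent uniform integer
shift in [0, L).  Defaults are the standard study conditions: N_s = 100
cells per sequence, τ = 2.0 frames, p = 0.05, L = 50 frames, T = 3000,
N = K·N_s.  Multiplicative noise `n(t) ~ Gamma(k, 1/k)` has mean 1 and
variance 1/k, so the signal-to-noise ratio E[x²]/E[(x(n−1))²] equals k
exactly; k = 1 is the default noisy condition.

What the generator does *not* emulate: cells shared between sequences,
non-sequence background activity, drifting baselines, slow indicator
kinetics beyond a single exponential, or motion artifacts.  Passing the
recovery benchmarks therefore shows the factorization and K-selection
machinery is correct under the stated noise model, not that every real
recording will separate as cleanly.

The behavioural fixture (`simulate_session`) walks a waypoint-seeking
agent over a Y-maze mask of exactly 190 blocks of 2 cm × 2 cm (trunk with
a port alcove and two mirror-symmetric diagonal arms, consistent with a
12-cm-wide maze), shuttling between arm-tip zones and the lick port, with
rewards delivered at the port with a configurable success probability and
sequence intensities stamped at a configurable lead relative to zone
entries and licks.  It produces matched ground truth for the location
vector, dynamics, decoding and consistency stages; it is a fixture, not a
locomotion model.

## Downstream definitions and choices

* **Preprocessing** — binning every 4 frames (mean; the aggregation
  statistic is configurable since mean keeps the subsequent scaling
  meaningful), per-cell scaling so the nonzero mean is 1, capping at
  nonzero mean + 3 SD computed once on pre-cap values; all-zero cells are
  left untouched; cells with a single nonzero sample cap at the mean.
  Trailing frames that do not fill a bin are dropped.
* **Sharpening** — per sequence, the partial reconstruction U_k is built
  over *extended* time (full convolution), so each activation contributes
  its whole transient regardless of a neuron's lag; w_int is the
  normalized row sum, the reference neuron its argmax, and w_tim the
  correlation-maximizing shift against the reference, re-anchored so the
  earliest active neuron is at 0 and clipped to [0, L).  H is rescaled
  per row by scalar least squares so the sharpened factors reconstruct
  approximately the same U_k.  With the extended-time convention the
  operation is exactly idempotent.
* **Spike intensity** — s = (h − μ)/μ with μ a ±10 s moving average with
  edge-truncated windows (truncation avoids the phase shift a causal
  filter would introduce); frames with μ = 0 give s = 0; values are
  capped at 1 with no lower bound.
* **Location vectors** — mean spike intensity per occupied block at each
  lag τ ∈ [0, L); occupancy-weighted Gaussian smoothing (5×5 kernel,
  σ = 1 block — the kernel footprint is fixed at 25 blocks, σ is a
  choice) with renormalization at the mask boundary; never-visited blocks
  are missing (NaN).  Negative spike intensities are averaged as-is.
* **Gini** — the double-sum formula over all 190 blocks (missing as 0),
  averaged over τ.  If a map contains negative values it is shifted by
  its minimum first, since the formula presumes non-negative shares.
  The exact single-block maximum of this formula is (B−1)/B = 189/190;
  uniform maps give exactly 0.
* **Trajectory distances** — time-averaged Euclidean or Mahalanobis
  distance between per-frame mean trajectories; the Mahalanobis
  covariance comes from the Failure set (default) or the pooled
  (m−1)/(n−1)-weighted combination; a ridge λI (default 1e−8) regularizes
  near-singular frames, and λ = 0 turns singularity into an error.
* **SND / Procrustes** — PCA (top 2 components by default) on the spike
  intensities over the whole recording, component signs fixed by making
  the largest-magnitude loading positive; event trajectories are the
  window preceding each lick (20 s default, configurable).  Procrustes
  alignment mean-centres and Frobenius-normalizes both sets, takes
  R = V Uᵀ from the SVD of X̄ᵀȲ, s = ‖Ỹ‖/‖X̃‖, t = μ_Y − s μ_X R.  The
  printed solution does not constrain det R, so reflections are allowed
  by default; a flag forces det = +1.  Cross-day comparison fits the
  transform on each day's average Failure trajectory against the
  reference day's and applies it unchanged to that day's Success
  trajectories.
* **Balanced decoding error** — Eq. weights: binary targets weight each
  class by |Z|/(2|Z_c|); continuous targets use the closed-form α (frames
  with z ≤ 0.5) and β (frames with z > 0.5) computed from the target's
  moments.  Two analytic identities validate the implementation: the
  constant-0.5 null decoder scores exactly 0.25 per frame on both target
  kinds, and on a 0/1-valued target the continuous criterion equals the
  binary one to machine precision.
* **Decoder** — a two-layer recurrent network (hidden width 8, tanh
  units, linear read-out, logistic output) over the spike-intensity
  window from t−10.0 s to t−0.2 s (50 steps at 0.2 s binning), trained
  by full-batch Adam (lr 1e−2) on the balanced criterion with
  backpropagation through time; training uses the middle 50 % of frames,
  validation the flanks, early stopping at the validation minimum (cap
  500 epochs, patience 50); the run is repeated with distinct seeds and
  the mean best validation error reported.  Optimizer, rate and epoch cap
  are configuration, not contract.
* **Consistency** — population similarity is the cosine of z-scored
  w_int vectors over a shared neuron registry; pathway similarity
  z-scores each location vector once as a whole (per-τ slices of a
  z-scored whole remain comparable across τ, whereas per-slice z-scoring
  would erase between-slice intensity structure) and averages per-τ
  cosines, skipping flat slices; the Y-inverted variant mirrors block
  labels about the maze axis.  The correlation between the two
  similarities across sequence pairs is tested against a null that
  permutes cell identities within each day (independent permutation per
  day and draw); significance is reported as an empirical quantile.

## Problem sizes used in the test suite

The recovery benchmarks run at the standard study conditions (K = 5,
N_s = 100, T = 3000, L = 50, τ = 2.0, p = 0.05, S/N = 1, 200 iterations)
with 3 restarts for the threshold triplet and 2 restarts for the
embedded-count sweep and noise-robustness checks; the noiseless
ground-truth matching check uses a smaller instance (K = 3, N_s = 40,
T = 1200, L = 30).  The decoder property tests use a 2-sequence,
900-frame planted fixture with one repetition.

## Known limitations

* At strongly *decreased* signal-to-noise (gamma shape 1/3, i.e. noise
  variance 3) the sequence count is overestimated: heavy noise lowers all
  pairwise overlap correlations, surplus factors stop merging, and the
  best-of-restarts rule (smallest divergence) favours decompositions with
  more surviving factors.  K recovery is validated at S/N = 1 and S/N = 3;
  below S/N ≈ 1 the detected K should be treated as an upper bound.

* The merge rule ("drop the lower-energy member") is one reading of
  "merged"; summing factors is available behind `merge_mode="sum"`.
* The best-of-restarts rule compares raw final divergences; decompositions
  with more surviving sequences have slightly lower divergence, so with
  very few restarts the selection can favour a spuriously high K.
* K selection happens once, inside the compression pipeline; sequences
  that only become separable at full resolution are not re-split.
* The decoder is intentionally small; it is a contract for "does the
  spike intensity carry this behaviour", not a state-of-the-art decoder.
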