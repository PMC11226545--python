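# Methods

This note documents the models, the numerical choices and the synthetic
data behind `oscflux`, and what the test suite does and does not establish.

## Aperiodic background and burst detection

EEG power spectra mix an aperiodic ("1/f") background with band-limited
oscillations.  We model the background as

    P_ap(f) = 10^offset / (knee + f^χ)

in log10 power.  `offset` is the log10 intercept, `χ ≥ 0` the spectral
exponent, and `knee ≥ 0` lets the spectrum flatten below a corner frequency
(`mode="fixed"` pins knee = 0).

Per participant and channel, every epoch is decomposed with 3-cycle Morlet
wavelets on a 4–40 Hz grid in 0.5 Hz steps.  Sub-Hz steps are needed to
resolve an individual alpha peak; a coarse grid can be requested through
`freq_grid(step=...)`.  Epochs are zero-padded by 0.1 s before convolution
and the padding is stripped afterwards; independently of the padding, all
samples within half a wavelet (n_cycles/2f) of an epoch boundary are marked
invalid and never contribute to spectra or bursts, because zeros are not
data.  Artefact samples (±80 µV rule) are likewise invalid and break burst
runs: a burst interrupted by an artefact is two candidate runs.

The participant/channel background spectrum is the log10 of the
valid-sample-weighted **linear** mean of wavelet power.  The linear mean is
what anchors the detection threshold: single-time wavelet power of
Gaussian-like noise is exponentially distributed — χ²(2) scaled to mean
P_ap(f) — so the mean of log power would sit 0.25 log10 units (Euler–
Mascheroni constant over ln 10) below the distribution mean and miscalibrate
the threshold by a factor ~3.5 in exceedance rate.

**Robust fitting.**  An oscillatory peak must not inflate its own detection
threshold.  Peaks are identified against a Theil–Sen straight-line trend in
log-log space (median of pairwise slopes, 29 % breakdown point): residuals
above 2.5 × the MAD-based noise scale are flagged, and the flagged set is
dilated by ± f/3 Hz around each flagged frequency because a spectral line
seen through a 3-cycle wavelet leaks over roughly σ_f = f/3.  Only positive
residuals are flagged, so genuine knee curvature — which falls *below* a
straight trend — is never discarded.  The requested model is then fit to
the retained points (`fixed` mode is linear least squares; `knee` mode is
bound-constrained Levenberg–Marquardt seeded from the fixed fit).  Earlier
iterations of the fitter (least-squares trend with an SD computed from the
positive residuals, and a bisquare IRLS line) both failed this requirement:
a broad alpha bump either inflated the exclusion threshold or tilted the
consensus line, biasing the knee-mode background up to 2.2× at a 30 % burst
duty cycle.

**Thresholds.**  The power threshold is
`P_ap(f) × Q_χ²(percentile; df=2) / 2` (≈ 2.9957 × model at the default
95th percentile); the duration threshold is `min_cycles / f` (3 cycles,
strict inequality).  A literal `percentile × model` mode exists behind
`literal_amplitude=True` for sensitivity analyses.

**Events.**  Per frequency row, maximal supra-threshold runs longer than
the duration threshold become events.  Qualifying runs are then grown
outward to where power falls below the χ²(2) *median* of the background
(`boundary_percentile=0.5`) — the dual-threshold convention of
envelope-based burst detectors.  Without this, the reported duration of a
genuine burst is biased short by ~2 cycles, because the envelope crosses
the high detection threshold well inside the burst's true extent; with it,
the mean absolute duration error on planted bursts is ~0.8 cycles while
spurious burst-covered time on pure background stays ~0.3 % (the
calibration tests measure both).  `boundary_percentile=None` restores pure
detection-threshold runs.  Events at adjacent frequencies are not merged:
the analysis selects a single individual alpha frequency (IAF) afterwards —
the 8–13 Hz frequency with the longest summed event duration (ties break
toward the lower frequency), per channel.  Per-epoch measures at the IAF:
duration-weighted mean burst power (event-weighted available), burst time
proportion of the valid epoch duration, and arithmetic mean burst duration.

## Semantic distance

Distance is `1 − cosine similarity`, clamped to [0, 1] (a negative
similarity clamps to 1 and is logged) so the scale reads 0 = minimally,
1 = maximally different.  `consecutive` mode scores each response against
its predecessor (the first against the cue; a flag skips it);
`forward_flow` scores against the mean distance to all previous words
including the cue.  The per-participant, per-condition median split labels
values below the median lower and above it higher; ties at the median are
assigned to whichever group is smaller, alternating from "lower" when the
groups are level.  Plain alternation alone cannot guarantee balance (e.g.
four median-valued points below two larger values), and the steered rule
makes |n_lower − n_higher| ≤ 1 an exact invariant, which a property test
asserts over arbitrary distance multisets.

Inclusion rules run in order: epoch level (thinking time ≥ 1 s, artefact
fraction ≤ 20 %), participant level (≥ 10 valid responses, ≥ 5 per
condition), then a group-level rule that removes a participant entirely
when any aggregated measure lies more than 3 SD from the group mean.  The
filter emits a per-rule exclusion count and is idempotent.

## Phase Slope Index

Cross-spectra are Welch estimates: Hann-tapered 1 s segments with 50 %
overlap (δf = 1 Hz, giving 6 alpha-band bins) averaged over all segments of
all epochs, `S_ij(f) = ⟨X_i(f) X_j*(f)⟩`.  Coherency divides by the
auto-spectra; the raw PSI sums `Im(C*_ij(f) C_ij(f+δf))` over band bins
whose successor is still in band (upper-edge bins are dropped, not
wrapped).  With this convention a channel that leads by lag τ produces a
positive phase slope and a positive Ψ̃ toward the lagging channel.

Standardisation follows the jackknife: Ψ̃ is recomputed leaving out one
epoch at a time (epochs are the exchangeable unit; per-epoch segment sums
are cached so the leave-one-out estimates cost one pass),
`SD² = (n−1)/n · Σ (Ψ̃₍ₖ₎ − mean)²`, and `Ψ = Ψ̃ / SD`.  SDs below 1e−12
flag the standardised value missing.

**A calibration caveat measured by the tests:** under *exact* independence
of two channels the raw PSI is a purely quadratic statistic of the
per-segment cross-spectra (its linear term vanishes with the true
coherency), and the jackknife then overestimates the variance by a factor
of ~2 — analytically exact for a product of two independent means, and
reproduced empirically here across epoch counts, segment groupings and bin
counts (null pseudo-z SD ≈ 0.65–0.70).  The standardised PSI is therefore
*conservative* under the null: |Ψ| > 1.96 occurs in well under 2 % of
independent pairs rather than ~5 %.  Directional power is unaffected (a
20 ms, gain-1 alpha-band coupling yields Ψ > 2 in ~96–98 % of runs with 50
× 2 s epochs, with the correct sign in 100 %), and the zero-lag
instantaneous-mixing control is null by construction.

## Cluster permutation test

Edges are ordered channel pairs; the paired t statistic of
`Ψ_B − Ψ_A` across participants is antisymmetric when its inputs are.
Edges with uncorrected p > .05 are discarded.  Each surviving unordered
pair is assigned to the condition with the larger |group-mean PSI| on that
edge, oriented by that condition's mean PSI sign (positive: first channel
drives), and the oriented edges of each condition are partitioned into
strongly connected components (networkx Tarjan; a brute-force
transitive-closure oracle checks the partition exactly on 1000 random
digraphs).  A cluster is the edge set inside one SCC; surviving edges whose
endpoints fall in different SCCs form singleton clusters so isolated
effects are not silently dropped — note that a purely feed-forward effect
(e.g. all edges left→right) contains no directed cycles and is carried
entirely by singleton clusters under strong-component semantics; a
weak-connectivity mode (`scc_mode="weak"`) groups such chains instead.

The cluster statistic is the sum of edge t values.  Each permutation flips
every participant's condition labels independently with probability ½
(paired exchangeability; the participant's own matrices are never altered),
recomputes edge statistics and clusters, and keeps the maximum absolute
cluster statistic; with complete data the edge t values for all iterations
are computed in closed form from sign flips (sum of squares is
flip-invariant).  `t_critical` is the (1 − α/2) quantile of the null
(α = .05 two-tailed by default, 5000 iterations); per-cluster p-values use
the add-one estimator `(1 + #{null ≥ |stat|}) / (1 + n_perm)`, which cannot
return zero.

## Synthetic data

The generators define the study conditions for all tests; every generator
is a pure function of its arguments including the seed.

* **Background**: inverse-FFT shaping of uniformly random phases with the
  target spectrum `10^offset/(knee + f^χ)` — the realised periodogram
  equals the target exactly, which makes spectral recovery checks sharp.
  Defaults `offset = 2, χ = 1.5, knee = 0` at 250 Hz give ~16 µV RMS,
  a realistic scalp-EEG amplitude.
* **Bursts**: sinusoids under a Tukey envelope (one-cycle cosine ramps,
  flat plateau; a full Hann below 2 cycles).  A full-length Hann taper
  would keep a nominally 8-cycle burst above any fixed power threshold for
  barely half its duration, destroying the duration ground truth.  The
  default amplitude semantics are detector-referenced: amplitude a scales
  the burst so its 3-cycle-wavelet response RMS is a × the background's,
  i.e. wavelet power rises by a² over the aperiodic level the χ² threshold
  is anchored to.  (A ±2 Hz band-RMS reference is available via
  `reference="band"`; because a sinusoidal line competes against noise
  integrated over the wavelet's ~6 Hz equivalent bandwidth, band-referenced
  amplitude 3 corresponds to a wavelet SNR of only ~5 and is marginal for
  detection.)
* **Coupling**: the receiver is its own background plus a gain-weighted,
  band-passed (4th-order Butterworth, filtfilt), lag-delayed copy of the
  driver, so the planted direction has a known positive phase slope.  The
  zero-lag mixture applies an instantaneous 2×2 mixing matrix to two
  independent sources as a volume-conduction negative control.
* **Group datasets**: per participant, condition A is independent noise on
  every channel and condition B adds the planted couplings; per-participant
  RNG streams derive from (master seed, participant index).  Defaults used
  by the calibration experiments: 12 epochs × 2 s per condition, 8
  channels (F3/C3/P3/T7 and F4/C4/P4/T8), 20 participants; coupled-pair
  experiments use 50 epochs × 2 s, the epoch count at which the jackknife
  SD is stable.
* **Associations**: word vectors are chained on the unit sphere so each
  consecutive cosine distance is drawn exactly from a clipped normal with
  the target mean and SD (default 0.7 ± 0.1); thinking times are log-normal
  with median 5 s.

What the synthetic data does *not* emulate: volume-conducted source
mixtures across many channels, non-stationary background parameters,
muscle/eye artefact morphology (artefacts enter only via the amplitude
rule), typing periods, or real lexical statistics.  Passing tests
demonstrate correctness and calibration of the chain under these idealised
conditions, not performance on recorded EEG.

## Sizes, tolerances, degenerate inputs

Simulation sizes in tests and in `scripts/acceptance.py` (120 s spectra ×
30 seeds; 200 s calibration; 400 planted bursts; 100 + 200 + 50 PSI pairs;
1000 digraphs; 200 null + 25 planted group datasets at 200 permutations)
were chosen once as the smallest runs whose binomial/regression noise is
well inside the asserted margins; the whole suite runs in a few minutes on
one CPU.  Antisymmetry is asserted at 1e−10, the PSI closed form at 1e−12.
Degenerate inputs are errors, not silences: zero embedding vectors,
epochs shorter than one wavelet or one Welch segment, < 3 epochs for the
jackknife, < 3 participants for paired statistics, bands with < 2 bins,
< 3 peak-free spectrum points.  Missing values propagate as nan with
pairwise exclusion and recorded n.

## Known limitations

* The jackknife pseudo-z is conservative under exact independence (above);
  between-condition contrasts are unaffected because the permutation test
  calibrates itself.
* Burst duration ground-truth recovery is quoted at detector-referenced
  amplitude 3; weaker or band-referenced bursts are detected with shorter
  measured durations.
* The aperiodic fitter models no explicit peak shapes; heavily peak-laden
  spectra (several overlapping bumps spanning most of the grid) could
  starve the background fit of points.
* EDF/BrainVision ingestion relies on mne's readers plus a JSON sidecar
  for epoch boundaries; BIDS layouts are not parsed.
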