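# Methods

`gaitmmse` quantifies the dynamical complexity of muscle *coactivation*
during gait: instead of scoring each surface-EMG channel in isolation, it
treats the muscles of interest as one multivariate process and asks how
irregular their joint activity is, and how that irregularity changes as
progressively finer time-scale content is removed.  The resulting
MMSE curve (multivariate multiscale entropy versus scale factor) is the
unit of analysis; curves are compared between subject groups (for example
children with cerebral palsy against typically developing controls).

## Pipeline overview

1. **Segmentation.**  Heel strikes are detected as peaks in the
   gravity-axis shank accelerometer of each leg.  A gait cycle of one leg
   runs between consecutive ipsilateral strikes; the intervening
   contralateral strike splits it into stance and swing.  All spans are
   0-based, half-open EMG-sample intervals; accelerometer indices map to
   EMG indices by nearest-integer rate-ratio scaling (x10 at 1000/100 Hz).
2. **Decomposition.**  The 16-channel EMG (8 muscles per leg), augmented
   with 6 Gaussian white-noise channels, is decomposed by multivariate
   empirical mode decomposition (MEMD) into mode-aligned intrinsic mode
   functions (IMFs).  The noise channels counteract mode mixing and are
   stripped afterwards.
3. **Scales.**  Cumulative-IMF scales are built: scale n is the sum of
   modes n..N plus the residual, so scale 1 is the raw signal and higher
   scales progressively drop the finest oscillations.  With the default
   6-mode truncation the residual acts as the 7th scale.
4. **Entropy.**  Multivariate sample entropy (MSampEn) is evaluated on
   each scale of each per-cycle segment for each of 14 muscle-combination
   schemes.  Cycle curves average into one curve per subject and scheme;
   subject curves average into group mean +/- SD curves.
5. **Statistics.**  Per scheme, a mixed-design repeated-measures ANOVA
   tests scale (within-subject, 7 levels) and group (between-subject),
   with Bonferroni-corrected pairwise post-hocs at individual scales.

## MEMD

For an n-channel signal v(t), the local mean cannot be defined through
channel-wise extrema.  MEMD projects v(t) along K unit directions on the
(n-1)-sphere, interpolates the multivariate samples at each projection's
maxima with a cubic spline per channel to form one envelope per
direction, and sifts against the average envelope:

    d(t) = v(t) - (1/K) * sum_k e_k(t)

iterated until the sift difference SD = sum||d_prev - d_cur||^2 /
sum||d_prev||^2 drops below 0.2 (hard cap 15 iterations per mode).
Because every channel is decomposed jointly, mode k has a comparable
scale on every channel — the alignment property that makes per-scale
multichannel entropy meaningful.

Direction sets are Hammersley low-discrepancy points pushed through the
hyperspherical angular parameterization with an equal-area (Beta
inverse-CDF) transform per angle, so the directions are quasi-uniform on
the sphere itself rather than clustered at the poles.  They are
deterministic in (n, K).

Choices that matter:

- **K (directions), default 64.**  Smoother average envelopes at higher
  cost; 64 is standard practice for this channel count range.
- **max_modes, default 6.**  Broadband EMG concentrates its energy in the
  first few modes; everything coarser is pooled into the residual, which
  the scale construction treats as the final (7th) scale.
- **Noise amplitude.**  Each helper channel is scaled to the mean SD of
  the EMG channels so it carries comparable energy into every mode.
- **Boundaries.**  Two extrema are mirrored across each end before spline
  fitting to suppress end swings.  Extrema are strict local maxima of the
  projection; plateaus contribute their midpoint.
- **Univariate input** routes to classic EMD (maxima/minima envelope
  average) with the same stoppage rule.

## MSampEn

For channels k = 1..n with embedding dimensions m_k (default 2) and lags
tau_k (default 1), composite delay vectors

    X_m(i) = [x_{1,i}, .., x_{1,i+(m_1-1)tau_1}, ..., x_{n,i}, .., x_{n,i+(m_n-1)tau_n}]

are built for i = 1..N-delta, delta = max(M)*max(tau).  B^m(r) is the
average fraction of vector pairs within Chebyshev distance r (inclusive,
self-matches excluded).  For the (m+1)-point stage the embedding is
extended by one sample in each channel in turn, pooling n*(N-delta)
vectors, and

    MSampEn = -ln( B^{m+1}(r) / B^m(r) ).

With delta = max(M)*max(tau), every origin admits every channel
extension, so the pool is always exactly n*(N-delta).

**Tolerance.**  r = 0.2 * (sum of per-channel SDs of the *raw* segment),
computed once per segment and reused for every scale, so that entropy is
comparable across scales of the same data.  Channels are not normalized
before embedding — the tolerance convention sums raw SDs, which implies
unnormalized amplitudes.

**Degenerate segments.**  A zero match frequency at either stage makes
the logarithm undefined; such scales are *flagged*, excluded pairwise
from curve averages (with the contributing count recorded), and never
zero-filled.

**Estimator fine print**, established against an exhaustive brute-force
enumeration:

- Nonnegativity is exact for n = 1 (the (m+1)-point match set nests in
  the m-point set).  For n > 1 the pooled cross-channel extensions are
  not nested, and the estimator can return negative values: marginally
  (~ -1e-6) for nearly deterministic segments, and more visibly (down to
  ~ -0.07 observed) when matches are sparse (B^m ~ 0.005).  In the
  well-sampled regime it is nonnegative in practice.
- Monotonicity in r likewise holds empirically only when match
  frequencies are well-sampled; with a handful of matching pairs the
  estimate is too noisy to be monotone.
- Channel permutation symmetry is exact for B^m.  The pooled (m+1) stage
  compares extended vectors with different block layouts positionally, so
  the full statistic is permutation-invariant only up to a sub-percent
  cross-extension alignment effect.

## Analysis schemes

Eight muscles per leg: thigh — vastus lateralis (VL), rectus femoris
(RF), semitendinosus (SE), biceps femoris (BF), tensor fasciae latae
(TF); lower leg — tibialis anterior (TA), soleus (SO), lateral
gastrocnemius (LG).  Four strategies give 14 schemes: (1) all 8 muscles
of one leg over the full cycle (2 schemes); (2) all 8 over one phase (4);
(3) the 3 lower-leg muscles over one phase (4); (4) the 5 thigh muscles
over one phase (4).  Enumeration order is deterministic in (strategy,
side, segment); the channel-count sequence is (8,8, 8,8,8,8, 3,3,3,3,
5,5,5,5).

**Orchestration.**  Decomposition precedes slicing: scales are computed
once per decomposition and sliced per cycle/phase/channel subset.  In
`concat` mode (default) all subjects' cycle blocks are concatenated and
decomposed in a single MEMD run, which guarantees scale alignment across
cycles, channels and subjects; `per-subject` mode decomposes each
subject's block separately.  Each subject's block is the contiguous span
covering its accepted cycles (continuous walking tiles it exactly), and
cycle spans are offset into block coordinates.

## Group statistics

`pingouin.mixed_anova` provides the mixed-design ANOVA.  The
within-subject effects (scale, scale x group) are reported both
uncorrected and Greenhouse-Geisser corrected, since entropy-by-scale
data rarely satisfy sphericity.  Subjects with any flagged scale are
excluded listwise (count logged).  Fully degenerate designs (identical
curves everywhere) are reported as F = 0, p = 1 for the group effect
rather than 0/0.  Post-hocs are two-sample t-tests with p_adj = min(1,
p * C(n_groups, 2)).  Under the null the group-effect rejection rate at
alpha = 0.05 measures 0.053 over 1000 simulated cohorts.

## Synthetic data generator

The generator emulates what the analysis assumes about real recordings:

- **EMG** (1 kHz, 16 channels): per muscle, a raised-cosine activation
  burst inside a textbook activation window (phase fraction of the gait
  cycle; e.g. TA in swing through heel strike, SO/LG in mid-to-late
  stance, quadriceps and TF around contact) multiplied by a band-limited
  (20-450 Hz Butterworth, order 4) Gaussian carrier, plus a small tonic
  baseline and sensor noise.  Legs alternate half a cycle out of phase.
- **Coupling**: each carrier in the coupled muscle subset is mixed with a
  per-leg shared drive at weight rho; pairwise carrier correlation grows
  monotonically with rho and vanishes at rho = 0.
- **ACC** (100 Hz, per shank): a smoothed (sigma = 30 ms) pulse at every
  heel strike plus Gaussian noise.
- **Impairment profiles**: `spastic` raises rho to 0.8 and widens/
  strengthens thigh bursts through stance (over-activation, abnormal
  synchronization); `paretic` attenuates lower-leg amplitudes to 0.3 and
  removes their shared drive (insufficient output, loss of couplings).
  These are simulation fixtures reflecting two qualitative mechanisms,
  not claims about any clinical cohort.  Whether the coupling knob
  reproduces the direction of group differences seen in real cohorts is
  an empirical question the test suite deliberately does not assert.
- **Cadence**: cycle duration 0.9 +/- 0.05 s (child-like self-selected
  walking), clipped to [0.6, 1.4] x mean.
- **Determinism**: all randomness flows from one seed through named
  seed-sequence spawns (gait timing, carriers, ACC noise, sensor noise).

What the generator does *not* model: motor-unit physiology, volume
conduction and electrode crosstalk, non-stationary fatigue effects,
within-subject session variability, or genuinely pathological gait
timing.  Passing tests therefore demonstrate that the pipeline recovers
the structure it assumes — not that it would reproduce any particular
clinical effect size.

## Artifact screen

Visually screening cycles for motion artifacts is replaced by an
automated rule: a cycle is dropped when any channel's peak |amplitude|
within it exceeds z x that channel's global SD.  Clean burst-modulated
gait EMG has a crest factor of roughly 9-13 against its global SD
(bursts over a quiet baseline), so the default is z = 20: above clean
data, far below the tens-of-SD spikes the rule exists to catch.

## Problem sizes

Simulation-backed checks run at sizes chosen to exercise the full stack
while keeping the suite fast: the end-to-end pipeline check uses a
2-subject cohort with 2 cycles per subject; the decreasing-trend check
uses 50 seeds of 4-channel, 2500-sample broadband EMG; cycle recovery
uses 50 simulated subjects with 8 cycles each; ANOVA calibration uses
200 null and 100 offset cohorts of 8 subjects per group.  Entropy match
counting is an exact numba kernel; its cost grows quadratically in
segment length, which is the dominant cost of the full pipeline.

## Known limitations

- IMF counts depend on data length and content; the package fixes the
  *analyzed* scale count by truncation (6 modes + residual), not the
  intrinsic mode count.
- The MSampEn estimator caveats above (sparse-match negativity,
  approximate permutation symmetry).
- The artifact screen is a stand-in for expert visual inspection and
  only catches amplitude excursions.
- `concat` mode assumes all subjects share channel layout and rate, and
  its single decomposition mixes subjects' spectral content; this is the
  alignment guarantee, but it means one subject's scales are not
  independent of the rest of the cohort.
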