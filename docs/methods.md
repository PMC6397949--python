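# Methods

`blinksync` implements a behavioral-coupling analysis for dyadic
(hyperscanning-style) experiments in which two participants view each
other's faces under a blocked design — real-time mutual viewing (LIVE), a
20 s-delayed replay of the partner's face (REPLAY), and a blank-screen
baseline (REST) — together with a synthetic dyad generator that provides
ground-truth inputs for every stage.

## Block design

The canonical session has 4 runs of 510 s each.  A run opens with 30 s of
REST, followed by 24 pseudorandomly ordered 20 s blocks, 8 per condition.
The 1 s blank that separates consecutive face presentations is counted
inside the preceding block's final second, so blocks tile the run exactly
and the arithmetic 30 + 24 × 20 = 510 s holds; at a repetition time of 1 s
this is 510 volumes per run.  Only the final 15 s of each block are
analysed (the first 5 s absorb luminance instability around condition
switches), giving 450 motion-energy samples per block at 30 Hz and 32
analysis windows per condition per participant across the session.

## Motion energy and blink detection

Motion energy at frame k+1 is the mean over a rectangular eye-region window
of |I_{k+1} − I_k|.  The difference value is stamped on the later frame, so
a blink can never appear to precede itself.  Each block's sub-series is
linearly detrended (ordinary least squares on an intercept-plus-slope
design) before autoregressive modelling; detrending is idempotent and maps
constant series to exact zeros.

Blinks are detected on the raw (non-detrended) series as local maxima whose
prominence exceeds a threshold, greedily pruned so no two events are closer
than 0.2 s — the lower bound of a blink's 200–400 ms duration; on a
conflict the taller peak wins, on an exact tie the earlier.  The default
threshold is 5 × the median absolute deviation of the block series, an
automatic stand-in for the visual verification a human rater would do.  On
noise-free rendered footage the MAD is exactly zero, so the detector falls
back to half the series maximum; a fully silent series yields no events.

## Spectral causality (noise contribution ratio)

Two detrended series x(t), y(t) are modelled jointly as a bivariate
autoregression of order N (Eqs. with coefficients a_i, b_i, c_i, d_i and
innovations u_x, u_y), estimated by per-equation ordinary least squares on
the shared lag design — exactly the normal-equations solution, which the
tests verify against an independent Gram-matrix solve.  Residual variances
use the number of regression rows as denominator.  N is selected by
minimising the multivariate Gaussian AIC, n·ln det Σ̂ + 2(4N + 2), over
N = 1…10 with every candidate evaluated on the common sample
t = max_order+1…T so likelihoods are comparable; ties go to the smallest N.
On blink motion energy the criterion usually selects N near the cap:
the pulse autocorrelation is rich at 30 Hz, and the cap (10 lags = 333 ms)
is part of the method's definition.

With A_k the 2×2 lag-k coefficient matrix, the transfer matrix is
H(f) = [I − Σ_k A_k e^{−2πifk/fs}]^{−1}, computed by direct inversion of
the 2×2 characteristic matrix per frequency on a uniform 513-point grid
over [0, fs/2].  This is mathematically identical to Fourier-transforming
the impulse response; the tests check it against a 2048-term truncated
impulse-response oracle to 1e−6.  The spectrum of x splits into
|H11|²σ²_ux + |H12|²σ²_uy, and the noise contribution ratio

    NCR_{y→x}(f) = |H12(f)|² σ²_uy / (|H11(f)|² σ²_ux + |H12(f)|² σ²_uy)

is the fraction of x's power at f driven by y's innovations — in [0, 1] by
construction, identically 0 when all b_i = 0.  Its trapezoidal integral
over [0, fs/2] (ΣNCR, units Hz) is the scalar directional-influence index;
a constant ratio c integrates to c·fs/2 exactly.  The formula presumes
independent innovations: the residual cross-correlation is always reported
and a warning is logged above |0.2|, but the ratio is computed from the
marginal variances as defined.  Unstable fits (companion spectral radius
≥ 1) and singular designs (e.g. a block with no blinks) are skipped with a
logged warning and excluded from the participant mean rather than
poisoning it.

Per participant and condition, the 32 block values are averaged.  Four
quantities are computed: face-to-face influence in LIVE, REPLAY and REST,
and screen-to-face in REPLAY, where the "screen" series is the partner's
own series shifted forward by the 20 s replay delay.  Enhancements subtract
the REST value from each of the others.

Finite-sample note: estimated ΣNCR has a positive baseline even for
independent series (regression noise leaks into the cross terms), and the
size of that baseline falls with the number of events per block.  Because
coupling also raises the event rate, conditions can differ slightly in
baseline bias; contrasts between equal-rate conditions are unbiased, and
the permutation calibration below shows the condition contrast holds its
nominal size under the null.

## Repeated-measures inference

One-way (and two-way with interaction) within-subject ANOVA is computed by
direct sums-of-squares decomposition with the subject-by-effect interaction
as each effect's error term; no sphericity correction is applied, matching
the uncorrected degrees of freedom convention.  Effect size is the
generalized η² (effect SS over effect SS plus all subject-related SS); the
implementation is verified to 1e−8 against both a hand decomposition and an
independent dummy-coded extra-sum-of-squares fit, and against `pingouin`.
Post hoc comparisons are classical paired t-tests with Bonferroni
adjustment (p_adj = min(1, m·p)) and 95% pairwise confidence intervals
mean ± t_{0.975,df}·SE(diff).  Degenerate pairs (zero-variance differences)
report t = 0, p = 1 rather than NaN.  The outlier rule removes a
participant entirely if any of their condition values lies beyond
mean ± 2 SD of that condition's values across participants (sample SD,
candidate included) — the rule is applied per condition, and removal
precedes re-running the ANOVA.

## Interbrain synchronization

Paired voxel series (volumes × voxels, equal run lengths, shared voxel
identifiers standing in for identical template coordinates) are processed
per run: the first 10 volumes are dropped (magnetization stabilisation
bookkeeping: 4 × 500 = 2000 analyzed volumes under the canonical design),
then a GLM with per-condition boxcars convolved with the canonical
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6), a run intercept
and a discrete-cosine high-pass basis (128 s cutoff) is projected out.
Task regressors are sampled at the actual acquisition times of the retained
volumes, which makes the projection idempotent.  Volumes are then assigned
to conditions by the half-open rule [onset, onset + duration) and
concatenated in temporal order — 640 volumes each for LIVE and REPLAY —
before computing per-voxel Pearson correlations between partners, clamped
and Fisher-transformed (z = atanh r, null SD ≈ 1/√(n−3)).  Condition
differences across dyads are tested with a per-voxel paired t map with
uncorrected p-values; cluster-level family-wise inference is out of scope.

## Synthetic dyad generator

Blink trains are mutually exciting point processes simulated by Ogata
thinning, exact in continuous time: participant i's hazard is
r₀(1 + g_{ji} Σ K(t − s_j)) over partner events s_j, with a hard refractory
period after each own blink (0.5 s default, ≥ the blink duration so
rendered blinks never overlap).  With zero coupling the gaps are
refractory + Exponential(r₀), which the tests verify by Kolmogorov–Smirnov.
Defaults: baseline 20 blinks/min (a typical adult spontaneous rate; the
refractory makes the realised rate r₀/(1 + r₀τ) ≈ 17/min), blink duration
0.3 s.

K is a raised-cosine bump of width 0.25 s centred 0.25 s after the partner
event.  The latency/width defaults are deliberately inside the causality
model's history window: 10 lags at 30 Hz span 333 ms, so an excitation
centred much later (e.g. at 0.5 s) is structurally invisible to the
estimator and no amount of data recovers it.  A quarter-second reactive
latency is physiologically plausible for visually triggered blinks and
makes the ground-truth coupling identifiable by the method under study;
both parameters are configurable.

Coupling is gated by the schedule when one is supplied: during LIVE the
excitation source is the partner's actual events, during REPLAY the
partner's events shifted by the 20 s replay delay (what the screen shows),
during REST none — reproducing the experiment's information-flow structure,
including the screen-to-face path being the only true path in REPLAY.

Rendering draws each blink as an eyelid band sweeping down and back up over
the eye region (closure profile sin²(πφ), fractional row coverage so the
sweep is smooth), darkening covered rows by 30 intensity units on a 0–255
scale against a constant background.  Frames outside blinks are
bit-identical, so motion energy is exactly zero there — the
renderer/extractor closure the tests rely on.  The analysis pipeline
renders only the frames each analysis window needs (verified identical to
slicing a full-session render), so whole sessions never materialise in
memory; default synthetic frames are 16 × 24 pixels because the pulse
shape, not the pixel count, carries the signal, and full 480 × 640
rendering is available through the same interface.

Voxel-pair simulation builds series = task + loading·latent + noise per
voxel, with loading = √(ρ/(1−ρ)) against unit noise so the task-free
correlation equals ρ in expectation; a per-condition latent component
restricted to one condition's volumes plants condition-specific
synchronization.  Noise is white Gaussian; the generator does not emulate
scanner physics, spatial structure, autocorrelated BOLD noise, head motion,
or real facial appearance — so passing tests demonstrate correctness of
the analysis chain and identifiability under the stated model, not
performance on real recordings.

## Validation experiments and problem sizes

The canned experiments (`blinksync.experiments`) use sizes chosen to give
stable Monte-Carlo estimates at desk scale: the coupling-gain sweep pairs
gain levels {0, 0.5, 1, 2} by common random numbers across 100 seeds with
32 analysis blocks per dyad (matching the per-condition block count of the
canonical design); the directional-asymmetry check uses 50 dyads of 64
blocks at the strongest gain; null calibration runs a two-sided
permutation test (199 permutations) of the mean block-ΣNCR difference
between two arbitrarily labelled condition groups over 200 uncoupled
dyads; the Fisher-variance check uses 2000 voxel pairs of 640 volumes; the
video round trip uses 100 rendered 30 s sessions.  Determinism: every
stage is reproducible from its seed; cohort runs derive per-dyad,
per-stage substreams from one master seed and write a manifest (config
hash, seed, versions) sufficient to replay the run.

## Known limitations

- The NCR estimate is positively biased at 450-sample blocks; the analysis
  is about contrasts and ordering, not absolute ΣNCR values.
- AIC on blink motion energy typically saturates at the order cap; the cap
  is treated as part of the method's definition.
- The innovation-independence assumption behind the NCR formula is only
  monitored (residual correlation warning), not corrected.
- Voxel correspondence is by shared identifier; spatial normalisation,
  smoothing and cluster inference belong to upstream neuroimaging tools.
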