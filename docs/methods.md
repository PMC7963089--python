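# Methods notes

## The task and what the pipeline measures

Six landmarks sit on a circle of radius 7° of visual angle around the
screen centre; with six landmarks the chord between neighbours equals the
radius, so adjacent landmarks are also 7° apart.  After a random fixation
period (uniform on 1400–2100 ms) the target steps to the adjacent landmark
every SOA (400 or 600 ms) for 12 s — 30 or 20 steps — moving clockwise or
counterclockwise.  On most trials a task-irrelevant rectangular contour
("inducer") covers three adjacent landmarks.  Subjects either synchronize
saccades with the target stream (predictive condition, latency ≈ 0 within
±20 % of the SOA) or react to it (latency > 100 ms).

The analysis asks whether the inter-saccadic interval (ISI) depends on the
target's position *relative* to the inducer.  Labels In1–In3 count targets
from the first covered landmark entered along the motion direction;
Out1–Out3 continue outside.  Because the inducer's location is randomized
(or balanced) over the six possible placements, timing structure tied to
absolute screen location averages out of this sorting — the
counterbalancing that the validation battery checks explicitly.

## Conventions the task description leaves open

* Landmark 0 is at 90° (screen-up); indices increase counterclockwise.
  An inducer location is the index of the middle covered landmark.
* Inducer presence follows deterministic cycles with the no-inducer trial
  first (`[none, I, I]`, `[none, I×6]`), which reproduces the 66/34 split
  at 100 trials and 6-of-7 exactly; a Bernoulli draw would not.
* Step indexing is 1-based ("the 4th or later target").
* ISIs are onset-to-onset differences of the *retained* saccades; the 3°
  capture rule is used only to assign landings to landmarks.  Whether the
  original analysis used onset-to-onset or target-entry times offline is
  not decidable from its description; onset-to-onset is the definition
  implemented here.
* The "two-next target or opposite direction" exclusion is judged from the
  assigned landing landmark relative to the scheduled target (landing one
  step beyond the target, or two steps behind it, along the motion
  direction); landings that capture no landmark do not trigger it.
* A reactive latency exactly equal to the SOA is retained (the exclusion
  is strict); the boundary had to be fixed and inclusive retention is the
  weaker assumption.

## The synthetic-session generator

The saccade to step k of a trial gets latency

    lat_k = base + abs_location_offset[target_k] + direction_offset·1{cw}
          + inducer terms + phase noise,

onset_k = target-onset_k + lat_k, and ISIs are onset differences.  Landing
points scatter isotropically (SD 0.3°) around the target landmark.

**Inducer terms.**  `boundary_delay = (k, d)` adds a one-shot delay d to
the saccade at relative position k (both In_k and Out_k — the boundary is
crossed twice per lap, and the observed subjects delayed at the same
relative position inside and outside).  Because the next saccade
re-synchronizes, the interval ending at position k lengthens by d while
the following interval shortens by d; the category-mean pattern
(−d, 0, +d) over positions 1–3 is what the sequence resultant picks up,
pointing at position k.  `io_offset = δ` instead applies the periodic
triangular latency profile δ·(1, 2, 3, 2, 1, 0)/3 over In1..Out3, which is
the unique bounded per-step profile making every inside interval δ/3
longer and every outside interval δ/3 shorter — the stationary
"slower-inside" phenotype.  A naive one-shot offset on inside saccades
would instead concentrate the effect at the two boundary crossings and
load the 3 × 2 decomposition on the interaction term, which matches no
observed phenotype.

**Phase noise.**  Timing noise is modelled as slow phase drift: a boxcar
moving average of i.i.d. Gaussian innovations over `phase_drift_window`
steps (default 32, longer than the longest trial), scaled so the marginal
latency SD is `latency_sd_ms` (default 30 ms).  The resulting triangular
latency autocovariance has vanishing second differences, so within-trial
ISIs are exactly i.i.d. Gaussian — the exchangeability that the
label-shuffling permutation null assumes, making the nominal 5 % level
exact for the simulated sessions.  This is a deliberate design choice with
a real limitation attached: under fully re-synchronizing i.i.d. latency
noise (`phase_drift_window = 1`), or any Wing–Kristofferson-style motor
noise, ISI_k = SOA + lat_k − lat_{k−1} is MA(1) with lag-1 autocorrelation
−1/2, and shuffling individual ISIs is then *anticonservative* for the
sequence statistic (the resultant's geometry weights adjacent-category
differences, |u_k − u_{k+1}|² = 3 against the null's implied 2, a 3/2
variance inflation) and conservative for the inside–outside statistic
(2/3 deflation).  Real saccade sequences plausibly contain such a motor
component, so permutation p-values for the sequence mode on real data
should be read as optimistic; a trial-level randomization of the inducer
location would be the robust alternative.  Other idealizations: no serial
correlation across trials, no trial aborts, no blinks or measurement noise
in rendered traces, Gaussian (not skewed) latencies — passing the
validation battery therefore demonstrates correctness of the machinery on
data satisfying its assumptions, not robustness to every property of real
recordings.

**Named phenotypes.**  `NULL` (no inducer effect), `BOUNDARY_DELAY_3` and
`MIDDLE_DELAY_2` (50-ms one-shot delay at relative positions 3 and 2), and
`INSIDE_SLOW` (io_offset 50 ms, i.e. inside intervals +16.7 ms each).
The 50-ms effect size mirrors the magnitude of the strongest observed
session-level modulations at the 600-ms SOA.

## Event extraction

Angular speed is the central-difference derivative of (x, y), combined as
√(ẋ² + ẏ²) and boxcar-smoothed over 5 samples at 1 kHz (endpoints
replicated) — enough to suppress single-sample spikes without shifting
onsets by more than ~1 ms.  Onsets are upward crossings of 50 °/s,
linearly interpolated between bracketing samples, separated by a 50-ms
refractory period; the landing is the position at the first sub-threshold
sample.  Rendered saccades are raised-cosine position ramps of 30 ms
(peak speed A·π/0.06 ≈ 367 °/s for a 7° amplitude), and the render/detect
round trip recovers ≥ 99 % of injected onsets within 2 ms at 1 kHz.

## Statistics: numerical conventions

* Sequence directions θ₁ = 90°, θ₂ = 210°, θ₃ = 330° (any rigid rotation
  is equivalent; this one puts position 1 upward).  In_k and Out_k share
  θ_k, so equal means cancel exactly.
* Permutations relabel single ISIs pooled within the session (the
  stratified variant — shuffling within absolute-location × direction
  strata — is available as an option).  Category means are recomputed per
  shuffle.
* Significance thresholds use conservative order-statistic percentiles
  (`higher` for the 95th/97.5th, `lower` for the 2.5th): with n_perm
  permutations the exact level is ≤ (⌊0.05(n+1)⌋)/(n+1); linear
  interpolation would be slightly anticonservative.  Ties at a threshold
  are not significant.  p-values use (1 + #{null ≥ observed})/(n_perm+1).
* Orientation classification takes the θ_k nearest the resultant; an
  exact tie returns the lower index with a warning; a zero-length
  resultant is an error.
* Categories with fewer than 5 ISIs warn; an empty category is an error.
* The mean-squares decomposition operates on unweighted cell means with
  the df-derived factors (df_seq = 2, df_io = 1, df_int = 2 explain the ½
  factors).  Inside the interaction bracket, SS_seq = 2Σᵢ(X̄ᵢ. − X̄)² and
  SS_io = 3Σⱼ(X̄.ⱼ − X̄)² carry their level-count weights — the standard
  definition, under which the bracket is the classical interaction SS of
  the 3 × 2 layout and vanishes identically for additive cells.  Negative
  interaction values can only arise from floating-point cancellation and
  are clamped to zero (warning beyond 1e-9 relative).  Normalized shares
  sum to 1 within 1e-12; ternary vertices are sequence = (0, 0),
  inside-outside = (1, 0), interaction = (½, √3/2).
* The per-session two-way ANOVA on individual ISIs is the classical
  count-weighted fixed-effects fit (statsmodels OLS, type-II sums of
  squares — a documented choice for unbalanced cells, not a claim about
  the original analysis).

## Validation battery problem sizes

The validation routines (`saccsync.validation`, exercised by the test
suite and `scripts/acceptance.py`) use: 500 null sessions of 30 inducer
trials with 200 permutations each for calibration; 50 replicate 200-trial
sessions per phenotype for recovery; 100 rendered trials at 1 kHz for the
detection round trip; 120 within-session-balanced trials for the
counterbalancing check; 30 replicates per phenotype for dominant-component
classification.  These sizes put Monte-Carlo error well inside the asserted
margins while keeping the whole battery at a few minutes on one core.

## Known limitations

* The generator emulates phenotype *means*; it does not model latency
  skew, post-error corrections, fatigue, or SOA-dependent latency shifts.
* The label-shuffling null's exchangeability assumption vs. motor-noise
  ISI autocorrelation (above) is the main caveat when applying the
  sequence-mode permutation test to real recordings.
* The reactive condition is simulated only through `base_latency_ms`;
  reactive latency distributions (and their exclusion-rule interplay) are
  not matched to any particular subject.
* No microsaccade handling, blink interpolation, or main-sequence checks;
  vendor eye-tracker formats are out of scope behind the CSV contract.
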