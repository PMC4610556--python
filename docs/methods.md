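# Methods

## Problem and model overview

`drowsefuse` recognizes a driver's fatigue state — non-fatigue (NF),
moderate fatigue (MF) or severe fatigue (SF) — once per minute from two
non-intrusive measurement sources: facial expression (camera frames) and
vehicle operation (steering, lane geometry, GPS speed). The method is a
two-level fusion pipeline:

1. **Feature level.** Eight windowed features are computed from the raw
   streams. Two Takagi–Sugeno fuzzy neural networks (T-SFNN) map them to
   raw per-state scores: a 3-input facial network over (bf, ecd, yf) and a
   4-input vehicle network over (pns, sdsa, fald, sdvs).
2. **Decision level.** Each score vector is normalised into a *dynamic*
   basic probability assignment (BPA) over the frame Θ = {NF, MF, SF} and
   fused by Dempster's rule, gated by a conflict threshold; the result is
   then fused again with the previous step's decision-level mass, making
   the recognizer recursive in time. A thresholded argmax rule emits the
   decision, falling back to the previous decision when the evidence is
   not decisive.

The dynamic BPA is the essential difference from static expert-weighted
fusion: the weight of each source changes with the measurements at every
step, and the temporal recursion carries support for the current state
through transient sensor dropouts (the motivating case is GPS loss in a
tunnel silencing the vehicle source).

## Feature definitions and windows

All facial and lane features use 60 s windows; steering and speed features
use 10 s windows. One recognition step is one minute; the 10 s features are
evaluated on the final 10 s of that minute. Windows are half-open
`[start, start + len)`, timestamps in seconds, and incomplete trailing
windows are dropped. A stream is taken to cover one sampling interval past
its last timestamp, so an exactly-60 s stream yields one window.

| feature | definition | notes |
|---|---|---|
| bf | closed-eye frames / total frames | blink frequency |
| ecd | frames inside closed runs ≥ 2 s / total frames | PERCLOS-like; a run counts all of its frames once its duration reaches the 2 s threshold, preserving ecd ∈ [0, 1] and bf ≥ ecd |
| meol | mean eyelid aperture (px) | |
| yf | frames with mouth h/w ≥ T_m / total | T_m defaults to 0.5 (configurable); zero-width frames are excluded and logged |
| pns | samples with \|steering rate\| ≤ 0.1 °/s / total | if the stream carries no rate channel, the rate is the first difference of the angle over the sampling interval |
| sdsa | population SD (1/N) of steering angle (°) | |
| fald | frames whose lane index ξ = (π/2 − θ_L)/(θ_R − π/2) departs / total | default *symmetric* rule: ξ > λ_L (left) or ξ < 1/λ_R (right), λ_L = λ_R = 1.2; a *literal* one-sided mode (ξ above either threshold) is selectable; θ_R = π/2 frames are indeterminate and excluded |
| sdvs | population SD (1/N) of GPS speed (km/h) | |

Both SDs deliberately use the 1/N (population) normalisation, matching the
feature definitions this pipeline standardises on.

## T-SFNN

Five layers: input → Gaussian fuzzification → product rule firing →
normalisation → linear output:

    μ_ij = exp(−(x_i − c_ij)² / σ_ij²),  α_j = Π_i μ_ij,
    ᾱ_j = α_j / Σ_j α_j,                 y_k = Σ_j w_kj ᾱ_j.

Firing strengths are computed in log space with the per-sample maximum
subtracted before exponentiation, so inputs far from every rule center
normalise correctly instead of producing 0/0.

**Structure learning.** Chiu-style subtractive clustering on the min-max
scaled inputs (accept radius r_a = 0.5, squash radius 1.5 r_a, accept/reject
ratios 0.5/0.15 — the classic constants) picks data points as rule centers;
the cluster count becomes both the rule count m and the number of
linguistic values per input. This reduces the trainable-parameter count
from the full grid's `2nL + r·Lⁿ` to `2nm + rm` (for the reference
configurations: 99 → 27 for the facial network, 267 → 33 for the vehicle
network). Initial widths are the coordinate-wise half-gap between the
first center and its nearest neighbour (floored when degenerate); initial
weights are uniform in [0, 1] under the training seed.

**Parameter learning.** Global-best particle swarm optimisation over the
flattened (c, σ, w) vector minimises the fitness
`f = (1/N) Σ_samples Σ_outputs (y − ŷ)²`. Defaults: swarm 30,
c1 = c2 = 2.0, inertia decayed linearly 0.9 → 0.4, velocities clamped to
20 % of each coordinate's bound range, bounds c ∈ [min − σ, max + σ] of the
data, σ ∈ [10⁻³, data range], w ∈ [−2, 2], stop at fitness ≤ 10⁻⁴ or
2000 iterations. Width coordinates are clamped to the positivity floor
throughout. Because gbest swarms occasionally converge prematurely on this
landscape, the trainer re-scatters the whole swarm after 75 iterations
without a material (0.1 % relative) improvement, archiving the best
solution outside the swarm so the stalled basin cannot recapture the fresh
particles; the archive makes the reported best-fitness trace monotone.
Training is bit-reproducible for a fixed seed. No gradient refinement is
used.

## Evidence fusion

BPAs live on the four focal sets {NF}, {MF}, {SF} and Θ itself (the
combination rules never allocate mass to two-element subsets). Raw network
outputs are clamped at zero and normalised (`m(A_i) = y_i/Σy_i`); an
all-non-positive output is *uninformative* and the recognizer substitutes
the vacuous mass (all mass on Θ, the neutral element) for that source.

Dempster's rule with conflict degree K:

    K = Σ_{X∩Y=∅} m₁(X) m₂(Y),
    m(B) = (1 − K)⁻¹ Σ_{X∩Y=B} m₁(X) m₂(Y).

When K < k_T (default 0.9) the original BPAs are combined directly.
Otherwise each piece of evidence i is discounted by a belief factor before
combining: pairwise confidence `c_ij = K_ij · d_ij` with
`d_ij = ‖m_i − m_j‖/√2` (Euclidean over the four focal coordinates),
averaged into c_i, and `η_i = (1 − c_i)·e^{c_i}` — equal to 1 at no
conflict, 0 at total conflict, strictly decreasing between. Discounting
multiplies singleton masses by η and moves the removed mass to Θ, which
keeps the rule defined even under complete singleton conflict.

Two conventions exist for averaging c_ij: over all n pieces (which
includes the identically-zero self term) or over the n − 1 others. The
default averages over the others, since the self term only dilutes the
conflict signal; the inclusive convention is selectable
(`FusionConfig.pairwise_mean_over_others`).

k_T = 0.9 is the package default because the worked-example row with
K = 0.835 was demonstrably combined *without* correction, placing the
reference threshold above 0.835.

## Decision rule and recursion

With m(A_F) the largest singleton mass and m(A_S) the runner-up, the
decision is A_F iff `m(A_F) − m(A_S) > ε_T1` **and** `m(A_F) > ε_T2`
(defaults 0.2 and 0.5); otherwise the previous decision is retained. Exact
ties fail the margin test, so the fixed NF < MF < SF tie order never
affects outcomes. The defaults reproduce every self-consistent decision of
the published worked example; both thresholds are configurable.

Per step: first fusion of the two source BPAs, normalisation of the
intermediate result (retained for procedural fidelity although Dempster
output is already normalised), second fusion with the previous step's
decision-level mass, decision. At t = 0 the previous mass is vacuous and
the previous decision NF — sessions are assumed to start alert. If both
sources are uninformative in a step, the previous decision is emitted
unchanged. The temporal fusion uses the same k_T-gated combination as the
first fusion.

## Ground-truth assessment

Three independent assessments label each window; a window enters the
ground-truth set only on unanimity:

* **Observers** score 0 (NF) / 1 (MF) / 2 (SF); the floor of the mean of
  three scores maps back to a state.
* **EEG**: the drowsiness ratio `r = (P_α + P_θ)/P_β` of Welch band powers
  (2 s Hann segments, 50 % overlap, PSD integrated over the band) with
  thresholds r < 3 → NF, 3 ≤ r < 4 → MF, r ≥ 4 → SF. Band edges default to
  the conventional θ 4–8 Hz, α 8–13 Hz, β 13–22 Hz; the band map is
  configurable, including the variant that swaps the θ and α ranges.
* **SSS**: Stanford Sleepiness Scale 1–2 → NF, 3–5 → MF, 6–7 → SF.

## Feature screening

Each candidate feature is KS-tested against a normal with the sample's own
mean and SD; the default critical value is the asymptotic `1.36/√n` at
α = 0.05 with estimated parameters plugged in uncorrected. This is known to
be conservative (simulated rejection of a uniform sample at n = 500 is
≈ 91 %); a Lilliefors-style Monte-Carlo critical value that accounts for
the estimation is available (`lilliefors=True`) and restores essentially
full power. Non-normal features are log-transformed (shifted by 1 − min
first if non-positive values occur) and re-tested. The Pearson correlation
with the 0/1/2 ordinal fatigue labels is then screened by
`t = r·√((n−2)/(1−r²))` against the two-sided Student-t critical value —
a magnitude test, so negatively correlated features survive on equal terms.
No multiple-testing correction is applied.

## Synthetic data generator

No public dataset accompanies this problem, so the package carries two
generators with known ground truth.

The **feature-table generator** draws the eight features from per-state
Gaussians (means monotone increasing in fatigue for bf, ecd, yf, pns,
fald, sdvs and decreasing for meol, sdsa, matching the correlation signs
the screening expects) and encodes targets as 0.8 for the true state's
output and 0.1 for the other two. Adjacent state means are separated by at
least 1.5 within-state SDs. Selected features can be made state-independent
(pooled mean) to benchmark the screening.

The **raw-stream generator** synthesises frame and vehicle streams under a
Markov state path (default: strong self-transitions with one-step moves)
such that the feature extractors recover the configured distributions:

* eye closures are placed as explicit non-overlapping runs — long runs
  (2–4 s) realise the ecd fraction and short runs top the closed-frame
  count up to bf; totals below one minimal run are rounded to zero or one
  run with probability preserving the mean;
* yawns are 3–6 s mouth-ratio excursions above the threshold;
* per-window fraction targets carry Gaussian noise whose SD shrinks to
  `target/2` near zero so boundary clipping cannot bias the mean;
* non-steering is a per-sample Bernoulli on a dedicated steering-rate
  channel, while the angle channel is an independent Gaussian series scaled
  to the target sdsa — the two channels are deliberately decoupled so each
  feature is calibrated exactly (a physical stream would derive the rate
  from the angle; the extractors still support that path);
* lane departures are per-frame Bernoulli events realised through the
  lane-line geometry (departing ξ drawn from [1.3, 2.0] or its reciprocal
  band, normal driving from [0.9, 1.1]); speed is white Gaussian.

Expected per-state feature means account for the exact Gaussian
small-sample bias of the population SD,
`E[S]/σ = √(2/N)·Γ(N/2)/Γ((N−1)/2)`, evaluated at the 100 samples of the
10 s sub-window. Round-trip calibration (extracted per-state means within
3 standard errors of these expectations) is tested over pooled seeds.

What the generator does **not** emulate: measurement noise correlated
across features, gradual within-state drift, head-pose or illumination
artefacts in the facial channel, autocorrelated steering dynamics, or
class-conditional distributions estimated from real drivers. Passing the
end-to-end benchmark therefore demonstrates that the pipeline recovers
states whose feature distributions are separated by ≳ 1.5 SD under clean
conditions — not field accuracy.

## Benchmarks and problem sizes

The repository's own verification budget is sized for a single CPU:

* Dempster combination is checked against a brute-force focal-set
  enumeration on 1000 random mass pairs.
* PSO parameter recovery retrains a known 2-input/2-rule/2-output network
  from 200 noiseless samples to fitness ≤ 10⁻³ (typically reaching
  ~10⁻⁶ in a few seconds).
* End-to-end recovery trains both networks once on a 360-row table
  (120 rows per state) and evaluates 20 independently seeded 50-window
  sessions; the mean decision accuracy criterion is ≥ 80 % (observed
  ≈ 89 %, errors concentrated at state transitions where the recursion
  lags one window).
* The embedded worked-example tables are replayed at ±0.005, the
  tolerance implied by their 3-decimal printed inputs. Three printed rows
  are internally inconsistent (their numbers cannot be re-derived from
  their own printed inputs); they are flagged in the fixture and excluded
  from numeric assertions, and a test verifies the flags by automated
  re-derivation.

## Known limitations

* The vision front end (eye/mouth/lane detection from video) and EEG
  acquisition are out of scope; raw numeric streams are the input
  boundary.
* Field-study performance figures are not reproducible from synthetic
  data and are not claimed.
* The PSO is a standard global-best variant with a restart heuristic; no
  claim is made of matching any particular "improved" PSO's trajectory,
  and reported iteration counts are machine- and seed-specific.
* λ_L/λ_R, T_m, k_T, ε_T1 and ε_T2 have no published reference values;
  the defaults documented above are the package's own choices and all are
  configurable.
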