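# Methods

`stripeburst` analyzes single-nucleus MS2/MCP fluorescence traces from the
*even-skipped* (*eve*) stripe region of the cellularizing *Drosophila*
blastoderm (nuclear cycle 14, "nc14") and infers the kinetics of
transcriptional bursting — the stochastic switching of promoters between a
quiescent OFF state and an ON state that loads RNA polymerases — together
with the dynamic geometry of the seven stripes.  This note records the
models, the choices behind their implementation, and what the synthetic
data does and does not establish.

## Forward model: promoter states to fluorescence

Time is discretized at the analysis frame interval Δt = 20 s.  In each
frame a promoter is OFF or ON; an ON promoter loads polymerases at rate *r*
(calibration into absolute polymerase counts is not attempted, so *r* is
expressed directly in fluorescence AU/min).  The polymerases loaded in one
frame contribute a fluorescence pulse of height (r/60)·Δt that persists for
the transit time t_elong — the time a polymerase needs to traverse the
reporter — i.e. for w = round(t_elong/Δt) frames (half-frame ties round
up).  With t_elong = 140 s, w = 7.  Fluorescence is therefore a w-frame
moving sum of the promoter-ON counts:

    F_t = (r/60)·Δt · Σ_{i=0..w−1} s_{t−i},     s_t ∈ {0, …, n_promoters}

After DNA replication two sister-chromatid promoters contribute; they are
assumed to emit additively (s_t up to 2, pulse height doubled when both are
ON).  Pulses are full-height for their whole residence: no partial weight is
given to the frames in which a polymerase is still transcribing the stem-loop
cassette itself.  That refinement would scale early pulse frames by the
fraction of loops synthesized; at w = 7 it affects mainly the first frame of
each pulse and was left out in favor of the simpler rectangular pulse.

Under stationarity the mean fluorescence obeys

    ⟨F⟩ = n_promoters · r · (t_elong/60) · k_on/(k_on + k_off),

which the simulation reproduces (checked to Monte-Carlo error at 10,000
frames).

## Transit-time estimator

Every loading event raises the signal at some time t and lowers it at
t + t_elong.  For each nucleus the frame differences D_{n,t} = F_{n,t+1} −
F_{n,t} are formed; for each displacement d = 1…20 frames, a single Pearson
correlation is computed between the concatenated-over-nuclei vectors
(…, D_{n,t}, …) and (…, D_{n,t+d}, …) (pairs never span nuclei; pairs with a
missing member are dropped).  The correlation minimum marks t_elong = Δt ·
argmin_d ρ(d); ties break toward smaller d.  Uncertainty comes from 100
bootstrap replicates over random 80% subsets of nuclei.

Differenced i.i.d. measurement noise is anticorrelated at lag 1
(cov = −σ²), so a trace set dominated by quiet frames can show a spurious
minimum at d = 1.  Real trace tables contain fluorescence only where a spot
was detected; synthetic tables record noise in quiet frames too.  The
pipeline's transit stage therefore emulates detection before estimating:
nuclei with fewer than 25% of frames above the activity threshold are
dropped and sub-threshold frames are masked as missing.  With that, the
estimator recovers w exactly on every synthetic seed tried; the
module-level estimator is unmodified and still exhibits (and is tested
for) the d = 1 hazard.

## Compound-state hidden Markov model

The promoter-count chain s_t is first-order Markov with per-frame K×K
transition matrix A (K = 2 for one promoter, K = 3 for sisters; the full
matrix is estimated, including direct 0↔2 transitions, making no assumption
about sister-chromatid coupling).  The observed fluorescence depends on the
whole window (s_{t−w+1} … s_t), so the window is embedded as a *compound
state*.  Compound states form a shift register: each of the K^w states has
exactly K successors (drop the oldest symbol, append the new one) with
probability A[s_t, s_{t+1}], and the Gaussian emission mean of a state is
its window ON-count times the single-promoter pulse.  Emission noise is
homoscedastic Gaussian with sd σ.  Missing frames contribute emission
likelihood 1.  Traces begin at detection onset, so the pre-trace history is
fixed to all-OFF and a base-state initial distribution π is estimated for
the first frame only; this avoids an unidentifiable initial-history
distribution.

Forward/backward and Viterbi exploit the shift-register structure: all
predecessors of a state share their last symbol, so predecessor sums reduce
to a reshape-and-sum over the oldest symbol, and the backward step is a
(K^{w−1}, K) × (K, K) matrix product.  Recursions are scaled per frame,
batched across traces (padded, sorted by length), and chunked to bound the
(T, n, K^w) arrays; the 3⁷ = 2187-state model runs in plain numpy.  At
w = 1 the factorization is undefined and standard dense-HMM recursions are
used.

**EM.**  Baum–Welch estimates (A, π, r, σ) shared across a trace set.  The
M-step for r is a weighted least-squares fit of observed fluorescence
against window ON-counts (emission means constrained to integer multiples
of the pulse); σ follows in closed form.  Convergence: |Δ log-lik| <
1e−4 per 1000 observed frames, at most 500 iterations; σ is floored at
1e−3 × data sd; the best of 5 random restarts (data-scaled, seeded) is
kept.  The log-likelihood trajectory is non-decreasing up to the σ floor.
Fits require ≥ 1000 observed frames (configurable).

**Effective two-state parameters.**  The per-frame A is converted to a
continuous-time generator Q = logm(A)/Δt, projected onto valid generators
(negative off-diagonals clipped, diagonal rebalanced); if the matrix
logarithm is not real the linear approximation (A − I)/Δt is used and
flagged.  The locus is ON when ≥ 1 promoter is ON, giving
k_on = Q[0,1] + Q[0,2], k_off = the occupancy-weighted rate from the ON
states back to 0, and r_eff = the occupancy-weighted mean of r and 2r.
For K = 2 this is the identity.

**A known bias.**  A two-state fit to data whose ON periods mix single- and
double-promoter emission levels (or whose groups mix different true r) is
mis-specified; the likelihood then prefers a "fast flicker" optimum with
inflated switching rates and r.  This is visible when fitting K = 2 to
two-sister synthetic data and in low-SNR fluorescence bins, and it is why
lumping consistency (3-state simulate → 2-state refit) is only asserted on
lumpable chains with rare double occupancy.  For sister-chromatid data the
K = 3 model is the appropriate choice; the two-state recovery experiments
use single-promoter traces so the fitted model is well-specified.

**Binned inference.**  For spatial profiles, nuclei are grouped by stripe
and by quantile bin of per-nucleus mean fluorescence (5 bins by default;
the bin count is a free choice).  Groups under 1000 observed frames are
skipped.  Within a group, EM runs on bootstrap subsets assembled by drawing
nuclei with replacement until ~3000 data points; the reported estimate is
the subset mean and the SE the subset sd.  Inference windows span each
trace's observed extent.

## Stripe geometry

Active nucleus-frames (fluorescence above a detection threshold) from
25 min onward are clustered per movie in overlapping 428 s windows
(step 214 s, 50% overlap; the window length follows the quantitative
methods figure rather than the rounded six-minute caption) with a Gaussian
mixture, one component per stripe, tied covariance.  Component means are
initialized at x-quantiles — stripes separate along the AP (image-x) axis,
and a k-means initialization can lock onto the larger y-variance.
Components are matched across windows by anterior→posterior rank (stripes
never cross); a nucleus-frame keeps a label only if a majority of its
covering windows agree.

Stripe orientation is the slope through the median (x, y) of the bottom
(y < 128) and top (y > 128) half-images.  Per window, the intercept of the
fixed-slope line (x at y = 128) is the mean of x − slope·(y − 128); an
ordinary least-squares fit of window intercepts against the window's mean
point time (exact for linear motion, unlike the window midpoint) gives the
linear position model x(t).  Every nucleus-frame — bursting or not — is
assigned to the nearest predicted stripe line at its frame time (positions
frozen at their 25-min values earlier, before all stripes exist); ties go
anterior; a nucleus's consensus stripe is its modal frame label.
Reorientation moves each nucleus to its stripe line's position at y = 128
while preserving its x-offset (corrected x = x − slope·(y − 128)), and the
movie pole coordinates map corrected x linearly to AP fraction.  Movies are
registered by shifting each (movie, stripe) additively so all copies of a
stripe share the cross-movie mean AP at the 35-min anchor; registration is
exact at the anchor by construction.  Robustness is quantified by
bootstrapping movies with replacement and reporting the sd of the
registered-center displacement.

## Spatial-kinetic metrics

A burst is a maximal run of decoded frames with s ≥ 1.  The kinetic
fingerprint catalogues every burst's start time, duration, registered AP
position and peak promoter count.  Maps over (time, AP) use left-closed 1%
egg-length bins at exact percent edges: instantaneous fraction-ON, mean
fluorescence, and the cumulative fraction of nuclei whose first burst
started by t (never-ON nuclei count 0 throughout).  Activity-difference
events evaluate, at each burst start, the ON fraction over the following
10 min minus the preceding 10 min; events without full windows on both
sides are dropped rather than renormalized to avoid edge bias.  Stripe
centers over time are, by default, the mean registered AP of the stripe's
bursting assigned nuclei (the fitted position model's intercept is exposed
as an alternative and is more robust when baseline activity surrounds the
stripe); the treadmilling velocity is the least-squares slope of center
vs time over the late (post-25 min) window, in % EL per minute, negative
anterior.  Parameter-vs-AP profiles weight each fluorescence bin's
parameters by the number of that bin's nuclei present at each AP position.

## Synthetic embryo generator

The generator emulates the study design: several movies, each imaging a
1024×256 px field covering a contiguous block of stripes (4 stripe-widths
of margin), ~50 min of nc14 at 20 s resolution.  Defaults follow the
study's measured scales: k_on^peak = k_off = 0.60 events/min, r^peak =
67 AU/min, t_elong = 140 s, two sister promoters.  Invented defaults, fixed
once: measurement noise sd 15 AU (~10% of the stationary core mean, a
signal-to-noise comparable to published example traces); interstripe
baseline k_on = 0.05/min and r = 20 AU/min (the study reports no
quantitative interstripe level; these are illustrative); 60% of interstripe
nuclei silenced outright ("never-ON"); transcription onset at 5 min;
nuclear drift 1 px/min in a random direction per nucleus (under the
4.5 px/min tracking filter).

Promoter telegraph paths are sampled exactly on the frame grid: each
frame's state is drawn from the analytic interval transition probabilities
(for piecewise-constant rates), so sampled paths are exactly Markov with
A = expm(QΔt) — the identity the EM recovery experiments rely on.  Sister
promoters are independent by default; a correlation knob can share their
per-frame random draws.  k_on and r (never k_off) are spatially modulated:
baseline plus Gaussian stripe bumps (sd 1.5% EL, centers 33–74% EL).
Treadmilling moves the bump centers anteriorly from 25 min at a velocity
scaling linearly from zero (stripe 1) to 1% EL per 3 min (stripe 7), so
anterior stripes hold position while the last stripe shifts ~8% EL — the
observed pattern.  Ground truth (paths, per-frame rates, stripe labels) is
emitted row-aligned with the trace table, and regeneration under a fixed
seed is byte-identical.

What the generator does **not** emulate: image formation and segmentation
(no pixels), spot-detection dropout (fluorescence is recorded in quiet
frames, with the transit-stage consequence described above), mitotic waves
and nuclear divisions, gap-gene regulatory logic, polymerase traffic
exclusion, and MS2-loop maturation kinetics.  Passing recovery tests on
this generator demonstrates correctness of the estimators under the model's
own assumptions — not robustness to the full complexity of live-imaging
data.

## Problem sizes and numerical choices

Recovery experiments use 200 traces × 60 min (36,000 frames), the scale at
which the difference-autocorrelation minimum and EM estimates are stable;
binned-inference demonstrations use a single-stripe, single-promoter embryo
(~220 nuclei, 3 bins, 8 bootstrap subsets), chosen as the smallest
configuration where the k_on gradient and k_off flatness are well-posed.
Bootstrap SEs from few subsets are themselves noisy, so flatness is tested
as absence of a linear trend with SEs moderated by flooring at the median
SE.  Degenerate inputs are handled explicitly: all-zero traces give a
defined likelihood but an undefined difference correlation (signaled);
reducible fitted chains are lumped on their reachable component with a
warning; empty half-images yield slope 0 with a warning; a single usable
time window yields a constant, flagged position model.

## Known limitations

- Two-state fits of multi-level or heterogeneous-rate data carry the
  flicker bias described above; interpret pooled K = 2 fits of
  sister-chromatid data as effective time-averages, not mechanism.
- The stripe position model is linear in time; curved trajectories would
  need a higher-order model.
- The burst-center stripe trajectory is diluted by baseline bursting in
  the interstripe; the position-model velocity is the more robust readout
  at the generator's baseline settings.
- The speed filter uses path length, the stricter reading of "average
  rate"; net-displacement speeds would drop fewer nuclei.
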