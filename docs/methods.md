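# Methods

## Generative model

Each molecule carries a donor/acceptor pair and is described by a
continuous-time two-state conformational process (folded ⇌ unfolded,
rates k_unfold and k_fold in s⁻¹) plus two independent photobleaching
clocks, one per fluorophore. Sampled at the camera interval Δt the
conformational process becomes a discrete Markov chain with per-frame
switching probabilities p = 1 − exp(−k·Δt) — the exact exponential
embedding. The linear form p = k·Δt is not usable here: the largest
realistic refolding rates (≈ 6.5 s⁻¹ at Δt = 0.2 s) would give p > 1.
Photobleaching of either dye sends the molecule to an absorbing *dark*
state; the simulator keeps recording background frames afterwards, since
detecting and removing that tail is the job of the analysis.

One consequence of the per-rate embedding is worth stating explicitly:
the discrete chain's stationary folded fraction is
p_fold/(p_fold + p_unfold), which approaches the familiar rate ratio
k_fold/(k_fold + k_unfold) only as Δt → 0. At Δt = 0.2 s and
(k_fold, k_unfold) = (2.40, 0.298) s⁻¹ the two differ by 0.021 (0.868 vs
0.890) because the embedding compresses the faster rate more. Folded
fractions measured on simulated data therefore track
`TransitionModel.stationary_folded_fraction(dt=Δt)`, and the consistency
tests anchor on that quantity.

Emissions: under donor excitation the FRET pair emits a mean total of
`total_state` photons split (1−E, E) between donor and acceptor channels,
with E fixed per state by the Förster relation E = 1/(1 + (R/R₀)⁶) at
R₀ = 4.59 nm — E_folded ≈ 0.980 (R = 2.4 nm) and E_unfolded ≈ 0.0104
(R = 9.8 nm). Acceptor-direct excitation frames (one per
`alternation_period` frames; strict alternation by default) report the
acceptor's presence directly. Counts are Gaussian with variance =
dispersion·mean + read-noise², a shot-noise-like model that is simple and
sufficient for exercising classifiers; negative draws clip to zero.

Default study conditions (fixed once, not revisited): Δt = 0.2 s, 60 s
movies, k_fold = 2.40 s⁻¹, k_unfold = 0.298 s⁻¹, bleach rates 0.04 s⁻¹
per dye (mean usable trajectory ≈ 12.5 s, typical of TIRF dyes under
continuous excitation), 600 photons/frame total, background 20
counts/channel, read noise SD 10, direct-acceptor signal 300. This puts
the two populations ≈ 20 noise-SDs apart in each channel — a clean but
not unrealistic SNR for surface smFRET. Contaminants are opt-in:
aggregates at 2–5× brightness and donor-only objects lacking the
acceptor.

What the generator does **not** emulate: camera point-spread functions
and spot overlap, spectral crosstalk beyond a single linear coefficient,
acceptor blinking and other dye photophysics, intensity drift, partially
folded intermediates, and any spatial structure. Tests passing on this
generator therefore demonstrate correctness of the estimators under the
stated statistical model, not robustness to every pathology of real
movies.

## Quality control

Background is estimated robustly (median/MAD) from the donor channel
during acceptor-direct excitation, which carries no fluorophore signal
absent crosstalk. Bleach detection is a change point per channel: the
signal's suffix must sit below background + 4 SD (width-3 median filter
first) for at least 3 frames. The threshold is deliberately loose —
genuine signal sits tens of SDs above background, while a 100-frame dark
tail contains enough background draws that a 2-SD cut would be broken by
pure noise in a sizable fraction of trajectories. Because the change
point cannot be localized more finely than the ALEX check spacing, two
extra guard frames before the detected point are dropped: frames of
ambiguous fluorophore status otherwise masquerade as unfolding events and
bias k_unfold upward by several percent.

Single-label detection asks whether a channel's dark suffix covers the
*entire* record — an object that never showed acceptor (or donor) signal
— which separates missing labels from mid-trajectory photobleaching.
Aggregates are flagged by per-trajectory median total intensity above the
population median + 5 MAD, floored at 1.5× the median: on a homogeneous
population the MAD collapses to the per-trajectory noise scale, and
without the floor borderline noise would be flagged while true aggregates
start at 2× brightness. Trajectories with ≥ 4 donor-excitation frames
after truncation are analyzed. All cutoffs are parameters.

## Threshold classification and ϕ_F

Observations are all donor-excitation frames surviving QC, pooled across
trajectories. The heatmap spans [0, 99.5th percentile] per axis with
64 bins; out-of-range points land in edge bins so counts are conserved.
The threshold is a straight line parametrized by its normal angle and
offset; its objective is the mean histogram count over bins whose centers
lie within a one-bin-wide perpendicular band of the line, i.e. the
integrated density along the line, normalized so long oblique bands are
not penalized. Nelder–Mead minimizes this from the perpendicular bisector
of the two strongest smoothed modes; lines failing to keep one mode on
each side are penalized out of the search. ϕ_F is the mean over five fits
from jittered random starts (±0.3 rad, ±20% of the mode separation), its
SD the reported threshold sensitivity; trials that fail to separate the
modes are dropped, with at least three required. Points exactly on the
line count as unfolded — an explicit tie-break that matters only for
noiseless synthetic data.

## Hidden-Markov kinetics

The three hidden states are folded, unfolded and dark; the dark row of
the transition matrix is pinned absorbing (configurable) and its
emissions pinned near background. Folded/unfolded emissions are diagonal
2D Gaussians initialized from the threshold-classification clusters.
Baum–Welch runs on *every camera frame*: acceptor-excitation check frames
enter as uninformative observations (unit likelihood for all states).
This is the crux of rate estimation under ALEX — informative frames are
2Δt apart, and estimating exit probabilities at that lag while dividing
by Δt would miss double transitions inside the gaps and bias fast rates
by tens of percent. Stepping the latent chain per frame makes the fitted
matrix a true per-frame matrix, and k = −ln(1 − p)/Δt then inverts the
generator's embedding exactly. Transition probabilities use
posterior-weighted expected counts (default) or hard counts along Viterbi
paths (exposed alternative; it systematically under-counts brief
excursions, which is why it is not the default). Rates condition on
staying alive — transitions into dark are photobleaching, not
conformational exchange. Convergence: |Δ mean log-likelihood| < 10⁻⁶,
at most 500 iterations; the likelihood trace is retained and must be
non-decreasing.

Standard errors are the square root of the Cramér–Rao lower bound of the
per-interval Bernoulli state exit, Var(p̂) = p(1−p)/n, propagated through
the log embedding: SE_k = √(p(1−p)/n) / ((1−p)·T). They are evaluated at
the interval where exits are actually *observed*: with interleaved check
frames, T is the informative-frame spacing L·Δt, p the lag-L exit
probability implied by the fitted per-frame matrix, and n the posterior
occupancy of informative frames. For all-informative data this reduces to
the plain per-frame formula. The distinction matters at fast rates: at
k_fold ≈ 6.5 s⁻¹ the per-frame formula understates the estimator's
replicate-to-replicate scatter by roughly 2×, while the observation-level
form calibrates within the factor-2 band across 50 replicate
simulations.

## Distances and fluctuations

Apparent efficiency E = I_A/(I_A + γ·I_D) with γ = 1 (proximity ratio; no
detection-factor or crosstalk correction is applied, γ is exposed for
generality) after subtracting per-channel backgrounds (5th percentile
across the dataset by default). E is clipped to [0.005, 0.995] before
inverting R = R₀(1/E − 1)^(1/6) to keep distances finite; observations
with both channels at background are dropped. Dwells are maximal
constant-state runs of the decoded donor-excitation frames; runs shorter
than 3 frames are excluded (a fluctuation needs a few points), dark runs
ignored. RMSF is the population SD of R within one dwell; each dwell is
one fluctuation event. The standard error of the per-state mean RMSF
comes from a block jackknife: events are shuffled (seeded) into 10
near-equal blocks, and SE = √((n−1)/n · Σ(θ̂₍ᵢ₎ − θ̄)²) over the
delete-one-block means, falling back to delete-one over events when fewer
than 10 exist.

Note that RMSF here reflects photon noise propagated through the Förster
relation as well as genuine conformational motion; on synthetic data it
is entirely the former, which is exactly what makes it a sharp test of
the propagation (unfolded-state RMSF exceeds folded-state RMSF because
dR/dE explodes at low E).

## Self-avoiding walk

The unfolded chain between labeling positions 4 and 175 is 171 freely
jointed segments of 0.38 nm (Cα–Cα) with hard-core excluded volume
(bead radius 0.19 nm, so non-bonded beads may not come closer than one
bond length), plus one 1.0 nm terminal segment per end for the dye
linkers; the reported distance is between the two terminal (dye) beads.

Sampling design: naive build-and-discard sampling is exact but its
acceptance decays like ~(3/4)^n from next-nearest-neighbor collisions
alone — about 10⁻²¹ at n = 171 — and per-step retry growth samples the
biased kinetic-growth ensemble. The ensemble statistics therefore come
from a pivot Markov chain: a random bead, a uniform random rotation of
one arm, accepted iff no hard-core overlap results. Its stationary
distribution is exactly uniform over self-avoiding configurations.
Retry-based growth is used only to produce a valid starting
configuration; 5,000 burn-in moves erase it (acceptance ≈ 0.47 at
n = 171), and one distance is recorded every 10 moves until 10,000
samples accumulate. Residual autocorrelation inflates the Monte-Carlo
error of the mean slightly but cannot bias it. Internal checks: with
excluded volume off the sampler reproduces ⟨R²⟩ = n·b² exactly (ideal
chain), and regressing ln⟨R⟩ on ln n over n = 25–400 recovers the 3D
SAW Flory exponent ν ≈ 0.588. With defaults the model predicts a mean
dye separation of ≈ 9.8 nm.

## Problem sizes

The test suite simulates 1,500 trajectories per kinetic condition (the
scale of the analyzed experimental datasets), 400 bleach-free
trajectories for folded-fraction consistency, 50 replicates of 150
trajectories for error-bar calibration, and 10,000 SAW samples; the whole
suite runs in a few minutes on one core.

## Known limitations

- The HMM assumes Gaussian per-state emissions and a global emission
  model across molecules; per-molecule brightness variation is absorbed
  into the state variances.
- Dark-state handling presumes QC truncation upstream; on untruncated
  data the post-acceptor-bleach regime (donor-only emission) is not
  distinguishable from the unfolded state by the FRET channels alone.
- The CRLB treats each state exit as an independent Bernoulli trial and
  ignores parameter uncertainty in the emission model.
- ϕ_F from thresholding and from HMM occupancy agree on well-separated
  data but can diverge when populations overlap; both are reported.
- The SAW model has no chain stiffness, solvent quality dependence, or
  dye-orientation (κ²) physics; its excluded-volume radius and linker
  lengths are declared geometric defaults, not fitted quantities.
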