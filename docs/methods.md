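# Methods

This note documents the models, numerical choices and limitations of the
package, in the spirit of a methods supplement.

## Kinetic model and trace simulation

Promoter conformation in the initiation complex is modelled as a
continuous-time Markov chain over ordered states (closed, open, scrunched)
with generator matrix `Q` (off-diagonal first-order rate constants in s⁻¹,
diagonal = minus row sum).  The default scheme is the linear chain
closed ↔ open ↔ scrunched with no direct closed↔scrunched transitions.
Named conditions:

| condition  | k(c→o) | k(o→c) | k(o→s) | k(s→o) | Keq |
|------------|--------|--------|--------|--------|-----|
| `wt_pos2`  | 0.2    | 0.4    | 0.6    | 0.1    | 6   |
| `d12_pos2` | 0.2    | 0.4    | 0.6    | 0.4    | 1.5 |

(all s⁻¹; Keq = k(o→s)/k(s→o)).  State FRET means default to 0.14 (closed /
free DNA), 0.38 (open), 0.56 (scrunched) with per-state emission σ = 0.06 —
the reported peak positions of the −16/+16-labeled promoter.  The published
record does not state frame rate, trace length or noise level of the
recordings; the package defaults to 0.1 s/frame (typical EMCCD smFRET
acquisition), 400–600 frames per trace and σ = 0.06, all configurable, and
all rates scale explicitly with the frame interval.

Trajectories are simulated by exact-jump (Gillespie) sampling and integrated
onto the frame grid as fractional occupancies, so a frame containing a
sub-frame transition carries the occupancy-weighted mixture of state means
(motion blur) rather than a discretised jump.  This reproduces the broadened
histograms of fast-switching complexes.

### Rendering and the leakage convention

Per frame, the apparent FRET value is the occupancy-weighted state mean plus
Gaussian noise with occupancy-blended variance.  Detected intensities are
defined as the exact algebraic inverse of the downstream correction formula
at total intensity T:

    I_D = T(1−E)/(1+l),   I_A = T(E+l)/(1+l),   l = leakage (0.08)

so that `(I_A − l·I_D)/(I_D + I_A) = E` identically.  This is a convention,
not a physical crosstalk model: it guarantees the noiseless round trip holds
to machine precision for any leakage, which is the property the correction
step is tested against.  Channel backgrounds and Gaussian detection noise
are added afterwards.  Emission noise is Gaussian per channel, not Poisson,
matching the Gaussian-emission HMM downstream; EMCCD excess-noise models are
out of scope.

Photobleaching is a single exponential step per dye.  After acceptor bleach
a frame renders at E = 0 (donor-only signal plus leakage); after donor
bleach both channels fall to background.  Acceptor direct-excitation check
frames (default 5) are prepended and appended, lighting the acceptor channel
only while that dye survives.

## Trace processing

Correction subtracts per-channel constant backgrounds, excludes check
frames, and drops frames whose total intensity falls below a floor (default
10% of the per-trace median total — this removes post-donor-bleach tails).
The record states "background-subtracted" without a procedure; a constant
per-channel background (supplied, or estimated externally) is used.
Corrected E outside the soft band [−0.2, 1.2] is flagged, never clipped —
noise legitimately pushes E slightly outside [0, 1].

QC filters are independent per-trace predicates (hence order-independent):
(a) acceptor present in the check frames (threshold defaults to 10% of the
median trace intensity); (b) at most one photobleaching drop on total
intensity, counted by binary-segmentation change-point detection (minimum
segment 5 frames, mean-shift z-threshold 5, noise from first differences) —
under the exact-inverse rendering an acceptor bleach leaves total intensity
unchanged, so this filter specifically catches multi-donor molecules, while
acceptor presence/loss is handled by the check frames; (c) optionally, the
trace must visit a mid-FRET band at least once (default open mean ± 2σ =
[0.26, 0.50]), the filter used to restrict histograms to molecules that
formed an open complex.

Histograms pool non-overlapping five-frame window means (whether the
original analysis used overlapping windows is unstated; non-overlapping is
the default and the window is configurable), dropping trailing partial
windows, with 40 uniform bins on [−0.2, 1.2].

## Gaussian mixtures

Fits run maximum-likelihood EM on pooled window means with per-component
variance (a width is reported for a specific population, so variances are
not shared), a σ floor of 1e-3, quantile-spaced initial means, common
initial σ = data sd / K, and 10 seeded restarts keeping the best
likelihood.  Fixed means are held exactly (their M-step update is skipped);
fixed values are assigned to the nearest initial components.  Components are
reported sorted by mean; width is Gaussian σ, with FWHM as a derived
convenience (whether reported widths elsewhere are σ or FWHM is unstated; σ
is chosen here).  Model order (1–3) is user-specified per condition; no
automatic selection (BIC etc.) is applied.  A histogram-curve least-squares
backend (sum of Gaussians fitted to the binned density) is available and
agrees with EM on well-separated mixtures to ±0.01 in the means.

## Hidden Markov analysis

One global three-state model per condition is fitted by maximum-likelihood
Baum–Welch over the pooled multi-trace likelihood — a deliberate deviation
from variational-Bayes smFRET tools: maximum likelihood is deterministic,
dependency-free and adequate for rate recovery, but it does not regularise
state number, so fitting more states than the data support can split a
population rather than starve the extra state (a starved state keeps its
previous emission parameters and an identity transition row).  State number
is fixed at 3 per condition; per-trace heterogeneous models are out of
scope.

Numerics: scaled forward–backward recursions batched over equal-length
traces; emission densities rescaled per frame to avoid underflow; emission
variance floored at 1e-4; monotone likelihood asserted at every EM
iteration; convergence at relative log-likelihood change < 1e-8; 4 seeded
restarts by default.  Viterbi decoding runs in log space with ties broken
toward the lower (lower-FRET) state index.

Transition-density plots place one point per state change at (departing
mean, arriving mean), self-transitions excluded, on a 2-D histogram grid.

Rate conversion defaults to the matrix logarithm `K = log(P)/Δt`, exact for
a time-homogeneous chain; the result is projected to a valid generator
(negative off-diagonals floored at zero and flagged when nonnegligible), and
a non-real logarithm falls back to the linear approximation
`k_ij = p_ij/Δt` with a warning.  The linear method is also available
directly; at k·Δt ≈ 0.3 it already misestimates rates by >10%, which the
matrix logarithm corrects.  Recovery bias grows in the missed-transition
regime k·Δt > 0.5, where frame averaging hides transitions from any
frame-based estimator.

## Ensemble fits

All fits use unweighted nonlinear least squares (no weighting scheme is
given for the two-replicate error bars; per-point weights are accepted),
with uncertainties as asymptotic standard errors from the fit covariance —
no bootstrap.  Concentration units are tagged on datasets and checked at
fit time; a nM/μM mismatch raises an error rather than silently converting.

The printed tight-binding closed form contains a `D_b` symbol defined
nowhere; it is interpreted as the total DNA concentration `D_t` (the
standard quadratic form).  The forward model exposes an optional `D_b`
argument so the literal printed variant can be evaluated for comparison.
As `D_t → 0` the quadratic model reduces to the hyperbola (relative
deviation < 1% when `D_t ≤ K_d/100`), which is verified by test.

Multi-band gel quantification converts each product band as
`R_band/(R_total + A)·[ATP]` with `R_total` the sum of all product bands, so
band amounts are additive and bounded by `[ATP]`; the single-band formula is
the one-band special case and a per-band denominator is available.  The
abortive sum covers 3–7-mer bands only (2-mers report initiation itself,
not hybrid-clash abortion).

Bubble-collapse time courses are shown but not fitted to a stated model in
the record; a single exponential is this package's choice, with a
no-collapse verdict when |amplitude| < 2 × its standard error.

## What the synthetic data do and do not emulate

The generators reproduce: multi-state Markov dynamics with sub-frame motion
blur, Gaussian channel noise, constant backgrounds, donor leakage,
single-step photobleaching, check-frame structure, and noiseless or noisy
titrations from each ensemble forward model.  They do not emulate: Poisson
or EMCCD excess noise, intensity non-uniformity across the field of view,
spectral fluctuations or blinking, baseline drift, aggregates or partially
labeled molecules (beyond the constructed multi-donor QC cases), or
correlated titration errors.  Passing tests therefore demonstrate that the
estimators recover known truths under the stated noise model, not that they
are robust to every artifact of real recordings.

## Problem sizes

The simulation studies use 60 traces × 500 frames (single-state), 100–150
traces × 600 frames (two/three-state mixtures and HMM recovery, matching the
~150–184-trace scale of the original per-condition analysis) at 0.1 s/frame
with σ = 0.06.  At these sizes the recovered scrunching Keq lands within a
few percent of truth, comfortably inside the 20% acceptance band, and the
whole acceptance run completes in well under a minute.
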