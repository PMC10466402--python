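# Methods

This note documents the models and procedures implemented in
`smfret_curate`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic tests do and do
not demonstrate about real data.

## Data model and conventions

Coordinates are in pixels with the centre of pixel (0, 0) at (0.0, 0.0);
frames are 0-based integers; intensities are ROI photon-count sums in
camera units.  A `DonorAcceptorTrajectory` is an acceptor-channel track
(the acceptor is tracked; the donor position is mapped from it) with
per-frame donor/acceptor ROI intensities.  Trajectories shorter than 20
frames are removed (`min_track_frames`, default 20), matching the minimum
imposed by upstream motion-state analysis.  Channel registration is assumed
done upstream; an optional user-supplied 2×3 affine transform can be
applied to donor positions at load, but fitting such a transform is out of
scope.  Frames whose ROI cannot be evaluated (window crossing the image
border, tracker gaps) carry NaN intensities and are excluded from every
mean and FRET value — intensities are never interpolated or fabricated.

## ROI intensities

`roi_sum` sums raw pixel values in a (2·h+1)² window (default h = 2, i.e.
5×5 px) centred on the nearest-integer pixel of the subpixel position.
Rounding is half-away-from-zero; banker's rounding would displace the
window by one pixel for exactly-half coordinates.  Windows that would cross
the image border return an invalid marker rather than a padded or clipped
sum, which would bias intensities downward asymmetrically.  No local
background subtraction is applied by default (a constant per-pixel offset
is available via the `background` argument); the raw-sum convention keeps
the intensity scale of trajectories and detection tables commensurate.

## Crossing-over detection

For trajectory *i* at frame *t* the per-channel density ρᵢᶜʰ(t) counts the
detections of channel *ch* lying strictly within `d_min_px` (default 6 px —
chosen so that the search radius fully covers a neighbouring 5×5 ROI plus
the surrounding Airy-disk spill) of the trajectory's acceptor position.
Both channel searches are centred on the acceptor position because the
donor ROI is mapped from the acceptor localisation.  Decisions:

* **Strict inequality**: a detection at exactly d_min is not counted.
* **Keep condition**: ρ_acceptor ≤ 1 and ρ_donor ≤ 1.  The pair's own
  detection, where present, is the one allowed count.
* **ρ = 0 frames are kept.**  At high FRET the donor is quenched below the
  tracker's detection floor and legitimately produces no donor detection;
  likewise a tracker gap leaves ρ_acceptor = 0.  An absent own-detection is
  not evidence of interference.
* Densities are pure per-frame lookups — no temporal smoothing — so the
  keep mask is exactly reproducible by a brute-force distance recount,
  which the test suite verifies on hundreds of simulated scenes.

Lookups use a per-frame k-d tree; a radius query is post-filtered with an
exact distance comparison so the strict boundary is honoured in floating
point.  `summarize_crossovers` tabulates frames with multi-particle
densities per channel and trajectories with an acceptor-channel crossing
within the last `end_window` frames (default 5), the signature of a
crossing that may have terminated tracking.

## FRET efficiency

E(t) = (Iₐ − α·I_d − δ·I_tot) / (γ·I_d + Iₐ − α·I_d − δ·I_tot), evaluated
on kept frames only.  I_tot is taken as Iₐ + I_d (raw ROI sums); this is a
documented convention, overridable only by changing the correction inputs,
since the total enters only through the small δ term.  α, δ, γ are
instrument-specific and default to the identity (α = δ = 0, γ = 1), which
reduces E to the uncorrected ratio Iₐ/(Iₐ+I_d).  Corrected values are
deliberately **not clipped** to [0, 1]: clipping would pile probability
mass at the boundaries and distort the downstream Gaussian fits (histograms
span [−0.2, 1.2] for display).  Zero-denominator frames are excluded, not
zeroed.  The per-trajectory summary for intensity space is the *adjusted
mean* — the mean ROI intensity over kept frames — which stands in for a
full idealization of the trace; trace idealization itself is out of scope.

## Bleach detection and the auROC statistic

The bleach detector was an open design point; it is implemented as the
largest persistent downward step that lands at the bleached level: a
candidate frame *t* qualifies if the median of the `confirm_window`
(default 5) frames immediately after the step **and** the median of the
whole remaining trace lie below `noise_floor`, while the pre-step median
sits at or above it.  The immediate-window condition rejects large FRET
state transitions (acceptor drops but stays resolvable); the
whole-remainder condition rejects blinking.  The floor defaults to a
per-trace robust estimate (3× the frame-to-frame scatter, MAD-based,
computed from first differences so the step itself does not inflate it) and
can be fixed in config.

auROC compares `window_pre` pre-bleach frames against `window_post`
post-bleach frames (defaults 10/10, the transition frame excluded):
auROC = P(post > pre) + ½·P(post = pre) over all window pairs
(Mann–Whitney U normalised).  1 means a complete rise, 0 a complete drop,
0.5 no step; the statistic is invariant to any strictly increasing
transform of the intensities.

Templates are crossover-free trajectories with a detected bleach,
acceptor auROC ≤ 0.2 and donor auROC ≥ 0.8 (operationalising "close to 0"
and "close to 1"; both configurable).  Correlated co-bleachers — both
channels fall together, e.g. a complex dissolving — fail the donor
criterion.  An empty template set is a hard error instructing cutoff
relaxation, because thresholds cannot be inferred without templates.

## Intensity thresholds and region classification

From the selected templates: `donor_max` is the maximum per-frame donor
intensity in any template's post-bleach window (the donor's intrinsic
ceiling, revealed when FRET stops); `acceptor_min` the minimum over
templates of the pre-bleach adjusted mean acceptor intensity (the floor at
which an acceptor is resolvable above noise); `total_max` their sum.
The per-frame maximum is used raw, not smoothed.  A trajectory is rejected
when its mean acceptor is ≤ acceptor_min or its total mean intensity is
≥ total_max (strict interior acceptance); otherwise the uncorrected ratio
r = Iₐ/(Iₐ+I_d) assigns high (r > 0.7), medium (0.3 < r ≤ 0.7) or low
(r ≤ 0.3).  Boundary values fall to the lower region, mirroring the strict
inequality that defines the high wedge.  The partition of the accepted
wedge is exhaustive and exclusive.

## State analysis

Accepted kept-frame FRET values are pooled per condition and fit with a
K-component univariate Gaussian mixture (default K = 3) by
expectation–maximization: quantile-spaced initial means, pooled-sd initial
widths, uniform weights, 10 restarts with seeded mean jitter, best final
log-likelihood wins; the fit is deterministic for a fixed seed and the
log-likelihood is asserted non-decreasing at every iteration.  A component
sd collapsing below 10⁻⁴ aborts that restart.  EM on raw values was chosen
over least-squares fits to binned histograms: it uses the data at full
resolution and makes occupancies well-defined.  State occupancies use hard
maximum-posterior assignment (proportions of frames "clustered into" each
state); per-cell proportions partition the pooled values by cell.  Group
comparisons use Welch's two-sided t-test on per-cell proportions (the
unequal-variance form is the safer default when only "independent samples
t-test" is specified); two identical constant groups return (t, p) = (0, 1)
by convention.

## Synthetic scenes

The simulator emulates the data-generating setting the pipeline assumes:
4,000 frames at 25 Hz by default; FRET pairs performing reflecting Brownian
motion (D = 0.05 px²/frame); a discrete-state Markov chain per pair
(defaults: three states at E = 0.25/0.50/0.80, stay probability 0.98) that
partitions a constant pair intensity I₀ = 1,000 between the channels, so
donor and acceptor are anti-correlated by construction and the uncorrected
E equals the planted state mean in expectation; Gaussian intensity noise
(sd 50); single-step acceptor bleaching (hazard 10⁻³/frame) with donor
recovery to I₀; a track-loss hazard (10⁻²/frame) exceeding the bleach
hazard, so tracking is typically lost before photobleaching and mean track
length is ~100 frames; donor-only particles at a configurable density
(default 8 per 100×100 px) so donor detections far outnumber acceptor
detections; and quenched-donor frames (no donor detection below an
intrinsic-donor floor of 120 counts).  Optional couplings: track-loss
hazard decreasing with the FRET level (`track_lifetime_fret_coupling`), so
high-FRET trajectories live longer, and spurious short acceptor tracks for
monomer-like negative controls.

Detection tables are emitted noiselessly from true positions by default
(`localization_error_sd = 0`) so the ground-truth crossing ledger — a
brute-force all-pairs recount of frames where a channel's detection density
around a pair exceeds one — is exact.  `plant_bleach_templates` lays
template (anti-correlated) and co-bleaching (correlated) pairs on a
jittered grid with ≥ 5·d_min spacing, guaranteeing isolation and full auROC
windows around each planted bleach frame.  Image rendering uses an
integrated 2-D Gaussian PSF (sd 1 px) with optional Poisson noise.

What the simulator does **not** emulate: blinking kinetics and other
photophysics beyond single-step bleaching, camera-specific (EMCCD) noise,
motion-state heterogeneity, cellular background structure, and tracker
localisation failure modes.  Passing tests therefore demonstrate the
correctness of the curation logic under the stated statistical assumptions,
not tracker robustness on real images.

## Problem sizes in the test suite

The automated tests run the oracle-equivalence check on 100 scenes of 50
trajectories each (~40,000 frames), the template-recovery check on 50
planted templates plus 10 co-bleachers, mixture recovery on 10,000 draws,
and the exclusion-bias comparison on ten 400-pair cohorts; these sizes give
stable statistics while keeping the default suite fast.  The
exclusion-bias property — frame-level excision preserves a larger
high-FRET fraction than whole-trajectory exclusion when high-FRET pairs
live longer and crossovers strike uniformly per frame — is directional and
stochastic; it is asserted by a one-sided sign test across seeds rather
than per-seed.

## Known limitations

* Bleach detection assumes a single acceptor bleach step; multi-step
  (multi-acceptor) bleaching and donor-bleach events are not modelled.
* The intensity thresholds assume at least some acceptor photobleaching is
  captured; datasets without bleaching need another template criterion
  (e.g. trajectory-level anti-correlation), which is not implemented.
* Densities are computed against tracker detections only; interferers too
  dim or too non-Gaussian for the tracker are invisible to the density and
  are instead mitigated by the intensity thresholds.
* The per-frame density treats all detections equally; no attempt is made
  to re-identify the interloper across frames or re-link tracks across
  dropped segments.
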