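# Methods

## Scope

`alffconn` implements an inter-subject analysis of how the amplitude of
low-frequency fluctuations (ALFF) of resting-state BOLD signals relates to
functional connectivity: preprocessing (volume discarding, nuisance
regression, Gaussian smoothing), ALFF estimation with whole-brain
normalization, temporal-concatenation group spatial ICA with
dual-regression back-reconstruction, spherical-ROI Pearson/Fisher-z
connectivity, the voxel-matched and ROI-wise ALFF×connectivity coupling
statistics with hub identification, and a Monte-Carlo cluster-extent
threshold. A synthetic cohort generator plants sign-controlled coupling so
every stage can be validated against ground truth. Motion correction,
registration, segmentation and spatial normalization are out of scope:
inputs are assumed to share a common space, as the generator produces them.

## Preprocessing

Per subject: the first `n_discard` (default 2) frames are dropped; the six
rigid-body motion parameters plus the leading `n_nuisance_pcs` (default 5)
temporal principal components of each of the white-matter and CSF
compartments are regressed out voxel-wise by least squares (intercept
included); the residual images are smoothed with a Gaussian kernel
(`smooth_fwhm`, default 8 mm, σ = FWHM/(2√(2 ln 2)) per axis, reflective
boundaries). Tissue components are extracted from the post-discard,
pre-regression data — they are regressors and must exist before the
regression that uses them. Components are the orthonormal right singular
vectors of the demeaned voxel×time compartment matrix, ordered by singular
value; a compartment of rank below the request returns the available
components with a warning rather than failing, because small masks can be
low-rank. No global-signal regression and no temporal filtering are applied
(both would change the connectivity null); motion parameters enter as-is
(no derivatives or squares). Masks are aligned by grid shape only; no
resampling or erosion is performed.

## ALFF

Per voxel the linearly detrended series is Fourier-transformed and the
one-sided amplitude `2·|X_k|/T` is averaged over the bins with
`low ≤ f_k ≤ high` (closed interval, DC excluded; default band
0.01–0.08 Hz). With this scaling a pure sinusoid of amplitude A yields an
in-bin amplitude A; the whole-brain normalization (division by the in-mask
mean, out-of-mask voxels set to NaN) cancels any fixed spectral scale, so
the estimator convention only has to be internally consistent. Linear
detrending before the transform is an explicit assumption (the common
toolkit default); the band-edge convention is closed on both ends. Regional
ALFF is the sphere mean over voxels whose centers lie within the ROI
radius — a definition chosen here because "the ROI's ALFF" is ambiguous
between sphere mean and center voxel; sphere mean is consistent with how
the ROI time series are formed.

## Group ICA and back-reconstruction

Two-stage reduction: each subject's (temporally demeaned) data are
projected onto their top `subject_dim` temporal eigenvectors (default
`min(T−1, 30)`), the reduced blocks are concatenated along the reduced time
axis, and a second PCA takes the stack to `group_dim`. FastICA (log-cosh
contrast, parallel fixed-point updates) unmixes the reduced data with
voxels as samples, so the recovered sources are spatial maps; the fit is
deterministic under a seed with up to five re-initializations on
non-convergence, and `k = 1` reduces to the standardized leading component.
Zero-variance voxels are excluded and reinserted as zeros.

Back-reconstruction is dual regression: group maps → per-frame regression
gives subject time courses; the time courses are variance-normalized and
regressed onto the subject's voxel series to give subject maps. The
normalization makes a subject's component amplitude land in the spatial
map — the quantity the inter-subject coupling statistics consume. This is a
deliberate, fully specifiable stand-in for toolbox-specific GICA
back-projection; per-component scales may differ from such toolboxes by a
constant, which leaves inter-subject correlations unchanged. Component sign
and order are arbitrary; every downstream statistic is invariant to
flipping a map together with its time course, and a sign-rectified coupling
view (r multiplied by the sign of the group map per voxel) is provided.

One-sample t maps use t = mean/(sd/√N), df = N−1, two-tailed thresholds
from the t quantile (3.42 at p = 0.001 for N = 79). Zero-variance voxels
with nonzero mean get signed infinity and stay in the suprathreshold mask
(logged); all-zero voxels get t = 0. Automated component identification is
by optimal assignment on absolute spatial correlation (Hungarian
algorithm), replacing visual network identification.

## Connectivity and coupling

ROI series are sphere means (voxel-center membership, surviving voxels when
a sphere is clipped by the grid; a fully empty ROI is an error). Pearson
matrices are symmetric with unit diagonal; Fisher z is `atanh` off-diagonal
with a zero diagonal by convention; |r| = 1 off-diagonal is treated as a
degenerate pair and rejected rather than mapped to infinity.

The core statistics correlate quantities *across subjects*:

* voxel-matched coupling — at each voxel, Pearson correlation over the N
  subjects between the back-reconstructed component value and the
  normalized ALFF; zero-variance voxels are NaN;
* ROI coupling — entry (j, k), j ≠ k, is the correlation over subjects of
  ROI j's ALFF with the Fisher-z edge (j, k). The matrix is generally
  asymmetric: the two regions of a pair relate to their shared edge through
  their own amplitudes. The diagonal is zeroed and excluded from counts.

Significance uses the exact t↔r mapping `r* = t*/√(t*² + df)` with
df = n−2; for n = 79 and two-tailed p = 0.001 this gives 0.3633 (the
conventional rounded figure 0.364 differs by <0.3% and is matched at its
own printed precision). Hubs are ROIs with more than `hub_min_connections`
(default 30) significant couplings, tallied separately for positive and
negative signs; an ROI may be both a positive and a negative hub.

The cluster-extent threshold is a Monte-Carlo simulation: standard normal
fields on the mask grid, smoothed to the nominal FWHM, re-standardized
within the mask, thresholded two-tailed at `voxel_alpha`; the largest
26-connected suprathreshold cluster per iteration forms the null, and the
extent threshold is the smallest size whose exceedance probability is ≤ the
familywise alpha (conservative on ties). The null smoothness is imposed
rather than estimated from residuals — a stated fidelity limit, which is
why the resulting voxel count depends on the mask and smoothness supplied
and is reported alongside, not as, the primary inference.

## Synthetic cohorts

Subject i, voxel v:

    y_iv(t) = Σ_k a_ik · M_kv · s_ik(t) + b_iv · ε_iv(t) + nuisance + baseline

with `M_k` Gaussian-blob network maps (peak 1), `s_ik` band-limited
(0.01–0.08 Hz) unit-variance time courses built in the frequency domain
(flat in-band magnitude, random phases — exact band control), `a_ik`
per-subject network gains, and `ε` white noise with field `b_iv`. Nuisance
structure: six smooth random-walk motion traces sharing a component with a
brain-wide artifact series, and WM/CSF compartments (fixed geometric
blocks — a central ventricle-like block and a surrounding shell) carrying
their own smooth signals; everything is deterministic under the cohort
seed, and a baseline intensity of 100 is added.

Two planting mechanisms control the sign of the ALFF×connectivity coupling:

* `shared_signal_gain` spreads `a_ik` across subjects (relative sd
  0.8·|effect_r|): a high gain raises both the regional amplitude and the
  within-network correlations → positive coupling;
* `private_noise_gain` models a physiological-noise hotspot at one ROI: the
  regional noise floor is elevated (2× the global noise sd by default) and
  spread across subjects, raising that region's amplitude while diluting
  its correlations to network peers → negative coupling. The elevated base
  is what makes the planted effect detectable at the study's sample size;
  without it the effect is marginal at n = 79.

Effect sizes are free parameters of the generator (the phenomenon's true
effect sizes are unknown beyond the significance threshold); the defaults
(effect_r ±0.5, noise sd 0.6, base amplitude 1) are chosen so that planted
signs are recovered reliably at the study's N = 79, which is the
generator's purpose.

Desk-scale geometry: 16×16×12 voxels of 3.44×3.44×3.40 mm (≈55 mm box),
120 time points at TR 2.5 s — small enough for continuous testing. Because
this shrinks head geometry ~2–3×, desk-scale analyses scale the smoothing
kernel with it (4 mm FWHM via `desk_analysis_config()`, matching the
halved 4 mm ROI radius); applying a full-size 8 mm kernel on this grid
blurs neighbouring ROIs together. Full-size defaults (8 mm kernel, 8 mm
ROIs, hub rule >30) remain the `AnalysisConfig` defaults.

The calibration null (`null_cohort_spec`) uses mutually independent
single-blob ROI "networks" with zero across-subject amplitude spread, and
disables the brain-wide artifact term. Both choices follow from what "fully
null" must mean for this statistic: (1) with a shared within-network
signal, finite-length estimation couples a subject's realized noise energy
into both the regional ALFF and the pairwise correlation estimates — a real
mechanical dependence, not an implementation false positive; (2) a global
artifact whose realized energy varies by subject couples every region's
amplitude to every correlation — the physiological-noise confound itself.
A null for calibrating the false-positive rate can contain neither.
Corollary, observed and intended: in cohorts that *do* contain a
fixed-amplitude shared network, the non-planted network peers can surface
as extra positive hubs through the realized-energy channel; planted-hub
recovery is unaffected.

What the generator does not emulate: hemodynamic response convolution,
cardiac/respiratory quasi-periodic waveforms (approximated by the private
noise and compartment terms), spatial autocorrelation of the noise beyond
the analysis smoothing, subject-specific anatomy or registration error.
Passing tests therefore show that the statistics behave correctly under the
stated generative model, not that real-data confounds are handled.

## Numerical choices

* Band membership and sphere membership are closed inequalities; ROI sphere
  membership uses voxel centers, no partial-volume weighting.
* Regression uses `lstsq` on the full design with an explicit intercept;
  rank deficiency is an error naming the collinear columns.
* The ICA restart schedule derives seeds as `seed + 1000·attempt`.
* Cluster connectivity is 26-neighbour; the extent threshold resolves ties
  conservatively (smallest k with exceedance ≤ alpha).
* Degenerate inputs fail loudly: empty masks/ROIs, zero-variance series,
  |r| = 1 pairs, bands with no frequency bins, all-zero ALFF maps.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run the desk-scale grid with the
study's subject count where the statistic's power matters: Type-I
calibration uses 79 subjects × 40 ROIs over 20 (suite) or 12 (script) null
cohorts; hub recovery uses 79 subjects over 50 (suite) or 24 (script)
cohorts; oracle-equivalence checks run on ≤16×16×12×120 instances; the
cluster simulation uses 1000 iterations. These sizes are the package's
validation conditions; larger grids change runtimes, not the logic.

## Known limitations

* Dual regression is a stand-in for toolbox-specific back-projection;
  per-component map scales are convention-dependent (inter-subject
  correlations are not).
* The cluster-extent simulation imposes the nominal smoothness instead of
  estimating it from residuals, so its voxel threshold is not comparable
  across masks/kernels with published figures that used estimated
  smoothness.
* The ROI coupling statistic's null calibration assumes no true global
  amplitude–connectivity confound; on real data such confounds (motion,
  vascular noise) are expected and the statistic will report them as
  coupling — which is the phenomenon under study, and why nuisance
  regression quality matters.
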