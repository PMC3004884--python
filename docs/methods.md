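# Methods

This note documents the models, algorithms and numerical choices behind
`mrsdss`, and what its synthetic data can and cannot show.

## Signal model and conventions

A single-voxel ¹H FID is modelled as a sum of exponentially damped complex
sinusoids plus complex Gaussian noise,

    x(t) = Σ_j a_j e^{iφ_j} e^{(−d_j + 2πi f_j) t} + ε(t),

where each metabolite resonance contributes one component with damping
d_j = π·FWHM_j (lorentzian lineshape). The transmitter is assumed to sit on
the water resonance, so an offset frequency f maps to chemical shift
ppm = 4.7 − f/f₀ with f₀ the transmitter frequency in MHz (63.87 at 1.5 T).
The canonical spectral grid is endpoint-inclusive and uniform: 512 points
from 7.1 to −2.7 ppm, step 9.8/511 ≈ 0.01918 ppm. The source material fixes
the point count and both endpoints but not the spacing convention; the
endpoint-inclusive choice honours "first point at 7.1 ppm" with no dangling
half-bin and is isolated in `PpmAxis` should another convention ever be
needed.

## HLSVD water removal

The water filter fits the FID with a rank-k (default k = 10) subspace
model: the signal is arranged in a Hankel matrix with L = min(N/2, 256)
rows, a full SVD extracts the k-dimensional signal subspace, and the
shift-invariance property of that subspace (least-squares propagator
between the subspace with its first/last row dropped) yields the complex
poles z_j = e^{(−d_j + 2πi f_j)Δt}. Growing poles (|z| > 1) are discarded
as unphysical. Amplitudes and phases come from a linear least-squares fit
of the poles to the full signal. Components whose frequency maps into the
water band (4.33–5.07 ppm, i.e. ±0.37 ppm around water — a configurable
choice, since no band is stated in the source protocol) are subtracted in
the time domain. A full SVD is used rather than a Lanczos iteration: at
N = 2048 the Hankel SVD costs well under a second and is simpler to reason
about; the fitted model is identical.

On noiseless sums of ≤ 10 components the reconstruction is exact to
machine precision (residual energy < 1e-27 observed; < 1e-6 asserted).

## Apodization, transform, phasing, baseline

Line broadening multiplies the FID by e^{−π·lb·t} (lb = 1 Hz by default),
which adds exactly lb to every lorentzian FWHM. The spectrum is the
FFT of the apodized FID with the frequency axis converted to ppm as above.

Zero-order phasing chooses the constant phase φ maximising the integral of
Re(e^{iφ}S) over the metabolite band 0.5–4.2 ppm. Because that integral is
Re(e^{iφ}ΣS), the maximiser has the closed form φ = −arg(ΣS) — no search
is needed and the optimum is exact. First-order (frequency-dependent)
phasing is deliberately not implemented: acquisitions that need it are the
province of manual processing.

Baseline correction subtracts the mean intensity over the regions −2 to −1
and 9 to 11 ppm (both sides of the water peak). On the canonical axis,
which ends at 7.1 ppm, the 9–11 ppm region is empty, so only in-range
points contribute; it is an error only when *every* region misses the
working axis. In the full pipeline the baseline step runs on the
pre-interpolation axis (where both regions exist for typical sweep widths)
— the stage order is water filter → apodize → transform → phase → baseline
→ resample → align.

## Automatic alignment

The aligner shifts the spectrum by whole grid points, zero-filling one
border and dropping the same number of points at the other (positive shift
moves features toward higher index / lower ppm; the sign convention is
documented here and pinned by tests, since the source describes only the
mechanics). Reference selection follows the published flow chart: locate
the tallest peak (TP) in 0–4.5 ppm, then try creatine (3.03), choline
(3.21) and lipid (1.29 ppm) in that order. A candidate qualifies if a
*strict* local maximum (greater than both contiguous neighbours — a
monotone ramp has none) exists within ±5 points of its nominal position
and its SNR is at least SNR(TP)/5. If no candidate qualifies the spectrum
is left unchanged. Two readings of the "five times" SNR test are possible;
read literally it would reject nearly every candidate and the procedure
could never terminate at a non-TP reference, so the acceptance direction
(candidate SNR ≥ SNR(TP)/5) is implemented, with the factor exposed as
`ProcessingParams.tp_ratio`. Equal-height peaks in a window tie-break to
the smaller index (higher ppm), making the search deterministic.

SNR is defined as peak height (after baseline correction) over the
standard deviation of the 9–11 ppm noise region, falling back to
−2.7 … −1.7 ppm on the canonical axis where 9–11 ppm does not exist. The
exact SNR formula of the original quality-control protocol is published
elsewhere; this definition is the package's own and is used consistently.

## Quality control

The water linewidth is the FWHM of the tallest peak of the **power**
spectrum (|S|²) of the unsuppressed-water FID, with the two half-height
crossings interpolated linearly between bracketing samples on a zero-filled
(64k) frequency grid. The power spectrum is chosen because it is
phase-independent *and*, for a lorentzian of damping d, its FWHM equals
d/π Hz — identical to the perfectly phased absorption line — whereas the
magnitude spectrum would inflate every width by √3. The estimator tracks
the closed form within 2% across 5–30 Hz lines. Thresholds: SNR > 10,
linewidth < 8 Hz; archival cases without a water file are judged on SNR
alone.

## Classification

Feature space: canonical intensities restricted to 4.05–0.01 ppm (210
columns of the 512-grid under the endpoint-inclusive convention — the
count is asserted by brute-force enumeration in the tests), unit-Euclidean
normalised by default (the source protocol does not state a normalisation;
"none" is available). Concatenated-TE vectors are the restricted short
vector followed by the restricted long vector, each half normalised
independently.

Sequential forward selection greedily adds the column that maximises the
training accuracy of a Fisher LDA refit on the augmented set; candidates
with |Pearson r| > 0.8 against any selected column are skipped as
redundant; ties break to the lower column index; selection stops at the
feature cap (default 13, the one count the source states) or when no
admissible candidate improves the criterion. The published selection
criterion is not given in formulas; greedy training accuracy plus the
correlation filter is the simplest faithful reading, and both knobs are
parameters. On easily separable data the criterion saturates early and few
features are selected — by design.

Fisher LDA solves the generalized eigenproblem S_b w = λ S_w w with the
within-class scatter shrunk by λ_r = 1e-6·tr(S_w)/d on the diagonal so
p > n slices stay invertible, keeps the top two eigenvectors (orientation
fixed by making each axis's largest component positive), and stores the
projected class means. With two classes the second eigenvalue is ~0 and
the second axis is plot-only; with a single feature it is identically
zero. Prediction is nearest class mean in the 2D latent space under
Euclidean distance, ties to the first-declared class. Under that geometry
the "true" class boundaries are exactly the perpendicular bisectors of the
latent means; they are emitted both as line equations and as polygonal
regions (half-plane intersections clipped to a padded bounding box,
computed with shapely). With equal priors and a shared isotropic latent
covariance these coincide with the Bayes boundaries of the Gaussian model.
Inside the selection loop all candidate eigenproblems are solved in one
batched Cholesky-reduction pass, which keeps a full bootstrap with
re-selection at B = 200 in seconds.

Evaluation is a stratified out-of-bag bootstrap: every class is resampled
with replacement to its own size (so no class can vanish), the whole
trainer — including feature selection — is refit per replicate, and the
rows never drawn are scored. Reported accuracy is the mean OOB accuracy;
the confusion matrix aggregates all OOB predictions. Everything is
deterministic given the seed.

The peak-ratio rule plots Cho/NAA (3.21/2.01 ppm, short TE) against
mI/NAA (3.55/2.01 ppm, long TE) using windowed peak maxima. To keep
denominators positive (inverted long-TE lactate can push spectra negative)
all heights are offset by −(minimum intensity over every spectrum in the
active set), floored at zero, and the offset is recomputed whenever the
set changes. The decision polyline of the original rule is published
elsewhere and ships unset; users may configure their own, in which case
points above/below it are labelled. The myo-inositol position defaults to
3.55 ppm (configurable). Manual overviews plot per-case heights at two
chosen shifts, or in ratio mode the offset-corrected ratio a/b against its
reciprocal — a documented convention chosen so that equal shifts collapse
onto (1, 1) and pure rescalings coincide.

## Synthetic data

The generator draws class-conditional FIDs: per-metabolite amplitudes
~ N(mean, sd) truncated at zero, lorentzian linewidth 4 Hz, a residual
water component at the carrier (amplitude 40, linewidth 6 Hz), complex
Gaussian noise of sd 0.05, at 2048 points / 2500 Hz / 63.87 MHz. Long-TE
profiles attenuate lipids and myo-inositol and invert lactate's phase. The
default superclass profiles (meningioma: high Cho, low NAA; aggressive:
dominant lipids; low-grade glial: moderate NAA/Cho; normal: high NAA;
pseudotumoural: reduced NAA, mild Cho; tumoural: elevated Cho) are
*invented caricatures* of the qualitative MRS literature. They produce
much cleaner class structure than clinical cohorts: no patient motion, no
coil or shim variation, no overlapping histologies, no J-coupled
multiplets beyond a single inverted lactate line. Passing the pipeline
recovery tests therefore shows the machinery is correct and the class
signal survives processing — it says nothing about clinical accuracy,
which would require the original patient databases.

Problem sizes used by the test suite — a 3-class cohort of 60 cases per
class at short TE, bootstrap B = 200, boundary audits at 10,000 points —
were chosen as the smallest sets at which the qualitative claims are
stable across seeds.

## Known limitations

- No first-order phasing, eddy-current correction or frequency-domain
  water removal; vendor binary formats and DICOM are out of scope.
- The SNR formula, SFS validation criterion, v3.0 feature-count rule and
  ratio-rule thresholds of the original system are published in companion
  papers and are represented here by documented, configurable choices.
- The case store is single-process; concurrent writers are not arbitrated.
- Published clinical accuracy tables cannot be reproduced without the
  original clinical datasets and are not attempted.
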