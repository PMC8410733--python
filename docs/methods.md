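# Methods

`pedpet` is a desk-scale re-creation of a virtual dose-reduction experiment
for paediatric whole-body [18F]FDG-PET: simulate TOF list-mode data from
digital phantoms, delete events to emulate a lower injected activity,
reconstruct with four algorithm variants, and quantify what the time-of-flight
and resolution models buy at each count level.  This note records the models,
the parameters that matter, and the design decisions taken where the design
was genuinely open.

## Phantoms and the body-size proxy

Phantoms are single 2-D slices: an elliptical body (aspect ratio 0.8) of
uniform background uptake (default 5 kBq/ml), a liver-like disc in the upper
left body quadrant that hosts the background VOI, and focal disc lesions at a
configurable lesion-to-background uptake ratio (the clinical cohort spans
roughly 2–14).  Attenuation is uniform water, mu = 0.096 1/cm at 511 keV;
CT-derived maps are out of scope and the attenuation map is treated as known.
A voxel belongs to a region iff its centre lies inside the analytic shape, so
region means on the noiseless maps are exact by construction while line
integrals through the voxelized rim carry up to about half a voxel of
quantization error per ray (the angle-averaged radial profile of a disc
matches the analytic chord to better than 1 %).

Body size is parameterized by an effective diameter D = k·sqrt(BMI) with
k = 220/sqrt(19) mm per sqrt(kg/m^2), i.e. the cohort-typical BMI of
19 kg/m^2 maps to a 220 mm body.  The mapping is strictly monotone; it is a
geometric stand-in that lets gain-versus-BMI trends be studied with phantoms
whose BMI ladder matches the embedded 29-patient cohort (BMI 12.6–28.2
kg/m^2).

The default grid is 200 x 200 voxels of 4.073 mm (the clinical in-plane
matrix); tests and studies run on 64–128 px grids of the same voxel size,
which preserves every algorithmic ingredient at a fraction of the cost.

## Scanner model and list-mode simulation

The scanner is a 2-D parallel-beam tomograph: LORs are (angle, radial-bin)
pairs, default 56 angles over 180 degrees and 100 radial bins of 4.073 mm
(gain studies use 84 angles so that bodies up to 350 mm stay above angular
Nyquist).  The projector computes exact ray/pixel intersection lengths
(Siddon tracing, numba-compiled) and is materialized as a scipy sparse
matrix; the back projector is its transpose, so adjointness is exact by
construction rather than approximate.

Timing resolution is 555 ps FWHM, giving a spatial localisation kernel of
c·dt/2 = 83.2 mm FWHM along the LOR.  TOF bins are 200 ps wide (30 mm along
the LOR; the container requires bin width <= resolution/2).  Binning adds
bin-width^2/12 of variance to the measured position spread, about +3 % on the
FWHM-equivalent at these settings.  The TOF system matrix carries one row per
(LOR, TOF bin), each Siddon entry spread over the bins with Gaussian-integral
weights truncated at 3 sigma (kernel weights below 1e-6 dropped).

`simulate_listmode` draws per-LOR Poisson counts with mean proportional to
the attenuated forward projection, normalised so the total expectation equals
`target_prompts` (default 5e5 per slice at 100 % activity — the paper-silent
calibration choice, exposed in the API).  Each prompt's emission position is
drawn along its LOR proportional to intersection-length x activity, blurred
with the Gaussian timing kernel, and discretised to a TOF bin.  Prompts are
shuffled into random time order and interleaved with one time record per
second of the 120-s (2-min bed) acquisition.  Scatter, randoms, dead time and
decay are not simulated: the stream is constructed inside the linear
(sub-NEC-peak) regime where event thinning is statistically equivalent to a
lower injected activity, rather than modelling the effects that would break
that equivalence.  The header records a `count_scale` (counts per kBq/ml/mm)
so reconstructions return calibrated kBq/ml and SUV round trips are exact in
expectation.

The `.plm` file format is a magic number, a JSON header (geometry, duration,
count level, count scale, patient metadata, declared record/prompt counts)
and packed 13-byte little-endian records.  Readers verify the magic, record
kinds and declared counts, raising distinct errors for truncation, unknown
kinds and count mismatch.

## Virtual dose reduction

Thinning draws one RANECU deviate per prompt, in stream order, and deletes
the prompt iff the deviate exceeds the retention threshold S; time and tag
records always survive.  RANECU is L'Ecuyer's combined multiplicative LCG
(multipliers 40014 mod 2147483563 and 40692 mod 2147483399; difference mapped
into [1, 2147483562]; scale 4.656613e-10), implemented directly from the
recurrence and checked bit-for-bit against an independently coded oracle.
Strict inequality is used for deletion — the boundary case has measure zero
but the convention is fixed and documented.

The standard level set {0.75, 0.50, 0.35, 0.20, 0.10} is produced by
independent thinnings of the *original* stream (never nested), each with its
own seed pair derived from a base seed by mixing the level index into both
components with fixed odd multipliers.  Retained counts are Binomial(N, S);
the suite verifies the 5-sigma band at N = 1e6, a chi-square goodness of fit
over 200 repetitions, the product law for composed thinnings, and the per-bin
binomial equivalence of thinning before versus after histogramming.

## Reconstruction

All four variants (OSEM, TOF, PSF, PSF+TOF) share a multiplicative EM update
over angle-interleaved subsets (14 by default, bit-reversed visiting order),
with the per-LOR attenuation survival factor and the count scale folded into
the system model.  Events are histogrammed into (TOF-binned) sinograms before
reconstruction — equivalent to event-by-event EM for binned TOF and far
cheaper.  The PSF model is an image-space isotropic Gaussian (default
4.5 mm FWHM) applied inside both the forward and the transposed projection
with zero-padded boundaries, keeping the operator pair exactly adjoint; the
vendor's spatially variant detector-space PSF is out of scope and only
qualitative PSF behaviour (faster contrast convergence, lower noise with
TOF) is claimed.  A 5-mm FWHM Gaussian post-filter (edge-replicating, so
flat images are invariant) is applied to the final image and to every
per-iteration snapshot.

Numerical choices: the initial image is a uniform positive constant; voxels
with zero sensitivity are frozen at zero; update ratios where the forward
model is below 1e-30 are set to zero; zero-count inputs return a flagged
all-zero image instead of raising.  Iteration defaults follow the clinical
protocol — 5 iterations for non-TOF, 3 for TOF, 14 subsets — and are
config-exposed.  Full-data EM (subsets = 1) is verified to never decrease the
Poisson log-likelihood and to leave the image unchanged when the data equal
the forward model of the initial image.

## Figures of merit

Contrast = Mean_lesion / Mean_background; Noise = SD/Mean in the 20-mm liver
background VOI; SNR = Mean/SD within a VOI; CNR = (Mean_lesion −
Mean_background)/SD_background; SUVmean = concentration (kBq/ml) divided by
injected activity per body weight (MBq/kg == kBq/ml at 1 g/ml density).  All
SDs are sample SDs (n − 1; the convention was open and is fixed here).
TOF gains are ratios of a figure of merit between matched pairs (TOF vs OSEM,
PSF+TOF vs PSF); the gain functions refuse pairs that differ in count level,
grid or pairing.  The CNR gain formula is the SNR-gain analogue (only the SNR
version is written out in the source protocol; the analogy is the obvious
reading).  VOIs are discs ("spherical" maps to circular in a single slice),
voxelized by the centre-inside rule; sub-voxel diameters are an error rather
than a silent single-voxel VOI.

## Convergence analysis and iteration selection

Convergence curves (contrast, noise, SUVmean per iteration, 1–8) come from
per-iteration snapshots of a single reconstruction.  Iteration selection uses
a matched-contrast rule: the smallest iteration whose contrast reaches 95 %
of the non-TOF partner's 8-iteration plateau (the clinical selection was
visual; 95 % is the fixed numeric surrogate).  On noiseless full-data EM the
TOF variant reaches the plateau no later than OSEM, reproducing the
faster-TOF-convergence ordering that motivated the 5/3 protocol split.
Selection is performed once at 100 % counts and reused at reduced counts.

## TOF-gain-versus-size studies

At strictly matched iteration counts TOF is *further* converged than OSEM and
therefore noisier; the matched-contrast pairing is the meaningful comparison,
and the gain studies use near-converged reconstructions at 16 (non-TOF) vs 10
(TOF) iterations — the clinical 5:3 ratio preserved, run deep enough that the
body-size dependence of the TOF noise advantage is expressed rather than
truncated by early stopping.  The size ladder simulates 8 independent
acquisitions ("virtual subjects") for each body diameter in {150, 200, 250,
300, 350} mm at 84 angles, evaluates the liver-VOI SNR gain per acquisition,
and fits OLS gain-versus-diameter over all 40 points.  At 100 % counts the
slope is positive; at 10 % counts the underlying trend shrinks roughly
threefold (ensemble means over 24 replicates: gain 1.12 -> 1.34 at 100 %,
1.13 -> 1.20 at 10 %) and the fitted slope's 95 % CI includes zero — the
desk-scale analogue of losing the TOF benefit at low count levels.

Because a 20-mm VOI holds only ~19 voxels, single-image noise estimates are
volatile; ordering and scaling checks (PSF+TOF noise never above OSEM; SNR
proportional to sqrt(count level) within 15 %) average the figure of merit
over a ring of five disjoint 20-mm background VOIs.  The VOI size itself is
never changed.

## Reader study machinery

The schedule generator arranges 29 patients x 3 reading days with a
per-patient random permutation of the count levels {50, 75, 100 %}
(Latin-square style — the constraints were stated, the mechanism was open)
and a per-day random order: 87 presentations, each patient once per day and
once per level.  Score tables (reader, patient, level, question, score 1–5)
are summarised per question/level/reader with sample SDs; missing cells are
listed, never imputed.  Normality is tested with the D'Agostino-Pearson K^2
omnibus (scipy's `normaltest` is exactly this statistic; the suite checks it
against an independently coded textbook-formula oracle to 1e-10) and level
comparisons use Pearson correlation on patient-matched scores with two-tailed
t-distribution p values and GraphPad-style significance bands.  Clinical
score *values* are not reproducible and are never asserted; the reports
reproduce the table layouts.  The "inter-reader agreement" table actually
holds each reader's own between-level correlations; the function is named
`per_reader_correlations` and its docstring notes the naming mismatch.
An optional simulated-reader model (latent quality = standardized
log SNR − 2·noise + reader bias + Gaussian reader noise, fixed cutpoints to
1–5) makes the stage testable without humans: scores are monotone in count
level and inter-reader correlation rises as the reader noise vanishes.

## Dosage cards

EANM: recommended activity = 25.9 MBq baseline x the class-B weight multiple
at the nearest card row (3–68 kg; the published card values are embedded as
named constants and validated against the 68 kg -> 14.0 -> 362.6 MBq anchor),
floored at 26 MBq; weights above 68 kg use the card maximum.  North-American
consensus: weight x 3.7–5.2 MBq/kg, same 26 MBq floor (68 kg at 5.2 ->
353.6 MBq).  The cohort comparison divides each patient's injected activity
by the EANM recommendation and scales linearly with each virtual count level;
on the embedded cohort, patients above 30 kg sit below 75 % of the
recommendation (median check).

The embedded cohort table reproduces the published rows verbatim.  Its
activity-concentration column is stored as MBq/kg (recomputed as
injected/weight; the printed column header has the units inverted), and BMI
rows that disagree with weight/height^2 beyond rounding (heights are printed
to 0.1 m) are flagged by `check_cohort_consistency`, never corrected.

## Problem sizes and what passing means

The suite and studies run at 64–128 px grids, 28–84 angles and 2e4–5e5
prompts — sizes chosen so the whole pipeline (including the 24-cell
experiment matrix and the two-level gain ladder) executes in minutes on one
CPU.  The simulator omits scatter, randoms, dead time, 3-D geometry, detector
normalization and anatomical texture; passing tests therefore demonstrate the
correctness and internal consistency of the algorithms and the qualitative
orderings (TOF converges faster, PSF+TOF is least noisy, the TOF gain grows
with body size and fades at low counts) — not clinical image quality, and
never numeric equality with vendor reconstructions.
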