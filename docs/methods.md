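# Methods

This note records the models, conventions and numerical choices behind
`ktrq`, and what the synthetic-data tests do and do not establish about
real microscopy data.

## Acquisition model

All times are minutes from the start of the movie, frames on a fixed grid
(`times[j] = j * frame_interval`). The default schedule mirrors the
experimental template the package targets: 6-min frames, a 4-h untreated
baseline, ligand addition at the end of the baseline, 15 h of
post-treatment imaging, then MEK-inhibitor (MEKi) addition. Event times are
snapped to the nearest frame. The schedule also carries a post-MEKi
recording period (`meki_duration`, default 90 min) whose *tail*
(`meki_window`, default 30 min) defines the per-cell ERK-activity floor:
the MEKi response is modeled as an exponential relaxation with a 12-min
time constant, so a 90-min recording leaves the 30-min tail within ~1% of
the floor. A movie with no MEKi tail (4 h + 15 h) has exactly 190 frames.

## Trace generator

Single-cell ERK activity is simulated as

    a_i(t) = baseline + A_i * f_class(t - t_ligand) + eps_i(t)

with three unit-height response shapes chosen as the simplest forms with
the qualitative behavior of the three ligand classes:

* class 1 (transient): `f1(s) = (s/tau_r) exp(1 - s/tau_r)` — a pulse with
  unit peak at `s = tau_r` (default 18 min);
* class 2 (waning): `f2(s) = exp(-s/tau_d)(1 - exp(-s/tau_r))` — rapid rise
  (default `tau_r` 12 min) with slow decay (default `tau_d` 240 min);
* class 3 (sustained): `f3(s) = 1 - exp(-s/tau_r)` — saturating plateau
  (default `tau_r` 30 min);
* class 0 (non-inducer): no response.

These kinetic constants are illustrative defaults for generating test
data with known truth; they are not estimates of any particular ligand's
biology. A cell responds with probability
`p(dose) = pmax / (1 + (ec50/dose)^hill)` (the standard Hill/logistic
pharmacology form; defaults `pmax` 0.8, EC50 10 ng/mL, Hill 1, doses in the
1–100 ng/mL regime). Per-cell amplitudes are gamma-distributed (mean 1.5
ratio units, CV 0.2 — a clear response against the default measurement
noise without saturating the rendered 16-bit range). Baseline is 1.0 and
the MEKi floor 0.2 ratio units, giving the ~5-fold dynamic range typical of
translocation reporters. Noise is additive iid Gaussian per frame
(sigma = 0.1, an SNR of ~15 versus the mean amplitude); an AR(1) option
with matched marginal variance exists to probe the effect of temporal
autocorrelation on the paired test, which assumes independent differences —
the iid generator is the one used for calibration claims.

## Movie and section renderers

Cells are rendered as concentric disks (nucleus radius 8 px inside a
cytoplasm disk of 14 px), placed by rejection sampling with a minimum
spacing of 48 px and moved by a reflected random walk tethered within 8 px
of the seed position (steps uniform, ±2 px per axis per frame). The tether
guarantees that any two cells remain separated and that per-frame motion
stays below a third of the nearest-neighbor spacing, the regime in which
greedy nearest-neighbor tracking is provably unambiguous. In the ERKTR
channel the nucleus has fixed intensity (1000 counts) and the cytoplasm
`activity * 1000`, so the rendered ratio equals the true activity exactly
before noise; optional Gaussian "photon" noise (default 30 counts) is added
per pixel. No point-spread function, illumination gradients, textures or 3D
structure are modeled — passing tests demonstrate correctness of the
measurement code under the renderer's geometry, not robustness to optical
artifacts of real microscopes.

Tissue sections are rendered at the working resolution of 0.32 µm/px
(16-bit): a DAPI-positive lung region (an ellipse scaled to the requested
fill fraction, or a centered rectangle when the fraction exceeds the
inscribed-ellipse maximum of π/4), vimentin-positive tumor disks placed
fully inside the lung with a minimum edge-to-edge separation, and a marker
channel with a gamma-distributed per-tumor level. Ground truth (lung area,
count, areas, per-tumor marker p90) is recomputed from the rendered masks
and image, so it is self-consistent by construction.

## Live-cell measurement pipeline

Nuclear segmentation: median background subtraction, Gaussian smoothing
(sigma 1 px), Otsu threshold, hole filling, distance-transform watershed
seeded at local maxima at least 7 px apart (to split touching nuclei), and
a 30-px² minimum-area filter. Cytoplasmic rings are the 3-px dilation of
each nucleus minus all nuclear pixels, with contested pixels assigned to
the nearest nucleus (ties to the lower label); ring width and the area
filter are scaled to the renderer's default nucleus and exposed as options.
Background is the per-frame median of pixels in neither compartment —
robust and parameter-free. Tracking is greedy nearest-neighbor linking,
closest pairs first, refusing links longer than `max_disp`; there is no gap
closing, mitosis handling or lineage reconstruction. Compartment means use
the arithmetic mean (median would also be defensible; mean is the default
and the renderer's truth is defined in terms of it). The activity ratio
defaults to cytoplasm/nucleus so that the reported activity *increases*
with ERK activity (the reporter exits the nucleus when phosphorylated); the
reciprocal orientation is available, and the two are exact reciprocals on
the same valid frames. Frames with fewer than 5 pixels in either
compartment or a non-positive denominator after background subtraction are
flagged invalid rather than propagating NaNs.

## Responder analysis

Normalization references each trace to its MEKi floor window mean *m*:
`divide` (default) maps the floor to exactly 1, `subtract` to exactly 0.
Cells with unusable floors (*m* ≤ 0 in divide mode) are dropped with a
counted warning. Amplitude and AUC transform between the two modes by the
per-cell affine map (scale 1/*m* versus shift −*m*).

The per-cell test pairs the last *k* valid frames up to and including the
treatment frame with the first *k* valid frames after it (*k* = the
smaller window count; 1-h windows by default, i.e. 10 frames at 6-min
spacing), matched in order, and applies a two-sided paired t-test to the
differences. A cell is a responder when *P* < 0.005 **and** the post mean
exceeds the pre mean (`increase_only`; `any` accepts both directions).
Zero-variance differences report *P* = 1; fewer than 3 valid frames in
either window makes the call indeterminate and excludes the cell from the
fraction denominator. No multiplicity correction is applied across cells
(the fixed 0.005 level *is* the per-cell criterion), and no autocorrelation
correction is applied: under AR(1) noise the realized false-positive rate
inflates above the nominal level, which the generator's AR(1) switch makes
easy to demonstrate.

Amplitude is the maximum of (activity − b₀) within 1 h of treatment, with
b₀ the mean over the 1-h pre-window — the natural reference symmetric with
the pairing window. The 12-h AUC is the trapezoidal integral of
(activity − b₀) over [treatment, treatment + 12 h], reported in
activity·hours, unclipped (a net-negative excursion yields a negative
AUC); invalid frames are linearly interpolated and a >25% invalid fraction
flags the value low-confidence. Amplitude and AUC are attached only to
cells called responders. On the 6-min grid the trapezoid rule reproduces
the closed-form integrals of the class shapes to well under 1%.

Responder fractions carry Wilson 95% intervals (never outside [0, 1],
always containing the point estimate). The dose–response summary is a
bounded least-squares Hill fit in log-EC50; flat ladders (spread < 0.02)
skip the optimizer and report the mean fraction as the plateau with an
`ec50_unidentifiable` flag, and non-monotone ladders are fitted but
flagged.

Response-class assignment operates on the ensemble-mean baseline-subtracted
responder response r(t) over the 12-h window via two scale-free statistics:
persistence `P = r(12 h) / max r` and normalized duration
`D = AUC / (max r · 12 h)`. Class 3 when `P ≥ 0.5`, class 1 when
`D ≤ 0.25`, otherwise class 2. The thresholds sit in the wide gaps between
the statistics of the three default kinetics (class 1: D ≈ 0.07;
class 2: D ≈ 0.37, P ≈ 0.06; class 3: P ≈ 1), so assignment is insensitive
to their exact placement at the default SNR; they are an operational rule,
not an inference about any particular dataset. At least 20 responder traces
are required, and a non-positive mean response is unclassifiable.

## Histology quantification

Auto-threshold means Otsu. Because Otsu always splits a histogram, a
signal-free channel would otherwise segment its noise: a class-separation
guard requires the above/below-threshold means to differ by at least 4
pooled within-class SDs (pure Gaussian noise separates by ~1.6 SDs
regardless of its variance, real staining by orders of magnitude more), so
blank channels yield empty masks. Tissue segmentation adds morphological
closing (radius 2 px), hole filling (vessels and airways count as lung),
and a 1000-px² minimum component size; operator corrections enter only as
explicit union/subtraction mask layers, never silently. Tumor segmentation
is Otsu restricted to tissue pixels, a 50-px² minimum area, and 8-connected
labeling. Burden is 100 · tumor area / lung area — the bounded-percentage
direction of the ratio. Marker quantification records the 90th percentile
(linear interpolation between order statistics, fixed for
bit-reproducibility) of the marker channel within the vimentin mask, pooled
or per tumor — both scopes are provided since either aggregation is
defensible. Downscaling for speed is area-weighted (bilinear) rescaling
applied before analysis. Bland–Altman agreement reports bias = mean of
(automated − manual) and limits bias ± 1.96·SD with the n−1 denominator.

## Reporting layer

Fold increase is experimental/control mean, fold decrease control/
experimental (their product is identically 1); organoid percent survival is
100 · post/pre count; group summaries are mean ± SEM with SEM = SD/√n
(ddof 1); Benjamini–Hochberg adjustment is the original step-up
`q(i) = min_{j≥i} p(j)·m/j` capped at 1 and returned in input order. Note
that BH is *not* idempotent — re-adjusting adjusted values generally
inflates them further — so adjusted values are computed once from raw
p-values. The pipeline driver threads a single seed through every stage and
embeds seed and package version in each output, making reruns of one config
byte-identical.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use: 2,000 null cells for
test calibration (the realized responder rate under `increase_only` is
≈ alpha/2, comfortably within the [0, 0.012] band); 100 replicates of
1,000 cells at dose 30 ng/mL (true fraction 0.60) for recovery and CI
coverage; one 20-cell, 190-frame rendered movie (noiseless and at default
photon noise) for extraction fidelity and tracking; 300 ensembles of 100
cells (100 per class) for class assignment; 30 rendered sections with 0–40
tumors for count/burden recovery; and 1,000 random p-vectors plus random
paired vectors and masked images for oracle equivalence of BH,
Bland–Altman and the percentile. These sizes give tight binomial/analytic
error bars while keeping a full run around a minute on one CPU.

## Known limitations

* The renderers are geometric idealizations; no PSF, shading, debris,
  z-drift, photobleaching, cell division or death. Results on real data
  depend on segmentation quality in ways the synthetic tests cannot probe.
* The paired t-test treats frame-to-frame noise as independent; temporally
  correlated noise inflates the realized false-positive rate.
* Greedy nearest-neighbor tracking is only guaranteed correct when motion
  per frame is small relative to cell spacing; dense or fast-moving fields
  need a proper assignment solver, which is out of scope.
* The class-assignment thresholds are calibrated to the generator's
  kinetics; borderline biology (e.g. slowly waning responses with 12-h
  persistence near 0.5) will land on whichever side of the rule it falls.
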