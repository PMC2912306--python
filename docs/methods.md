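# Methods

This note documents the models, algorithms and numerical choices behind
gcmspipe, the parameters that matter, and what the synthetic benchmark does
and does not demonstrate.

## Raw data model

Scans are stored at nominal (integer) mass: on load every profile m/z is
rounded half-up and intensities summed on collisions, which is the
appropriate model for the GC-quadrupole instrument class the package
targets. Retention times are seconds internally; the mzML reader converts
minute-valued scan start times. Scans are *not* resampled to a uniform grid
at load — operations that need a common grid (the statistical scan) perform
their own alignment. A run keeps a dense scans × channels intensity matrix
over the union of observed channels, so EIC extraction is a column slice and
the TIC a row sum; the conservation identity Σ_m EIC(m) = TIC holds exactly
by construction and is asserted in tests.

High-resolution / accurate-mass data is out of scope.

## Peak detection

The detector works per EIC on a moving-average-smoothed copy of the trace
(window `smoothing_window`, default 3 scans — enough to stabilise
near-baseline derivatives at typical 0.25 s scan intervals without
distorting 1–2 s-sigma peaks). The slope is the first difference of the
smoothed trace divided by the scan interval.

Boundary rules (these are the package's own definitions):

* **start** — first scan where slope ≥ `min_slope` holds for two consecutive
  intervals;
* **falling phase** — first subsequent scan with slope ≤ −`min_slope`;
* **end** — the earlier of (a) the first local minimum of the smoothed trace
  after the falling phase begins, or (b) the first point where the slope has
  decayed back above −`min_slope` for two consecutive intervals.

Rule (b) makes the boundaries symmetric: on an isolated Gaussian the peak
closes at the mirror image of where it opened, so the captured area is
insensitive to the baseline level. An end rule tied to a fraction of the
peak amplitude was considered and rejected: cutting at 5 % of amplitude
truncates a Gaussian at ±2.45 σ and the chord correction then removes ~10 %
of the area, which is incompatible with percent-level area accuracy. With
rule (b) and a permissive slope threshold, areas of isolated Gaussians match
the closed form h·σ·√(2π) to well under 1 % across two decades of height
(verified over 200 randomized cases). On overlapping peaks rule (a) fires
first and splits them at the saddle.

The apex is the raw-intensity maximum between the boundaries; plateau ties
go to the earliest scan so output is deterministic. Height is the raw apex
intensity. The area is the trapezoidal integral minus the chord joining the
boundary intensities (`baseline_correct=False` disables the subtraction).
The purity factor uses the *uncorrected* window: (area above the horizontal
line through the window minimum) / (area below it); a zero minimum gives
infinite purity, clamped to the sentinel 1e9 in peak-list files. Useful
purity thresholds are therefore ≥ 1 (raising the threshold from ~2 to ~6
prunes baseline-riding signals first).

Five thresholds gate a candidate: `min_slope` (default 50 counts/s),
`min_height` (500), `min_width` (1 s, measured start→end), `min_area`
(1000 counts·s at the detector; the *matcher* applies its own, stricter
import filter), `min_purity` (2). Raising any of the four post-filters
provably never increases the peak count; the same monotonicity is
property-tested for `min_slope`.

## Retention-index calibration

A calibration is ≥ 2 (rt, RI) anchors, strictly increasing in both
coordinates. Conversion is piecewise-linear in rt; the terminal segments
extend linearly outside the anchor range and such values carry an
extrapolation flag (extrapolated peaks remain matchable by default,
`allow_extrapolated_ri`). Linear interpolation is used rather than the
isothermal logarithmic Kovats form because the calibration input is a bare
rt/RI table from temperature-programmed runs, where piecewise-linear use is
standard. The inverse map (used by imputation) is exact for piecewise-linear
calibrations. Internal calibration locates each spiked standard as the
largest detected peak on its target channel inside a user-supplied rt
window; a window with no peak is an error naming the standard.

## MSRI library matching

Libraries store, per analyte: RI, a unit-mass spectrum scaled to base peak
999, an ordered quantifier-ion list and annotations. AMDIS `.MSL` records
import with the base peak as default quantifier (overridable via a sidecar
table); records lacking an RI are flagged and excluded from matching.

Matching proceeds per run:

1. peaks below `min_peak_area` are dropped (25,000 default = low-sensitivity
   preset; 5,000 = high-sensitivity). Lowering this bound only adds
   candidate peaks, so every match that passes under LS also passes under HS
   (tested);
2. remaining peaks are grouped by apex RI into half-open 0.1-RI bins
   (`bin_index = floor(RI/0.1)`, with an 1e-9 guard against float
   representation of decimal RIs); one peak per m/z per bin, largest area
   wins, conflicts logged;
3. every library entry whose RI is within `ri_tolerance` (default 2.0 RI
   units) of the bin midpoint is tried, once per quantifier ion. The bin
   midpoint (not the quantifier-peak RI) is the comparison point; an entry
   may therefore be attempted against several adjacent bins, and winner
   selection resolves the duplicates;
4. no quantifier ion in the bin → the attempt aborts. Otherwise qualifier
   areas are predicted from the quantifier area and the library spectrum.
   Peak area (not height) is the intensity proxy throughout, since areas are
   what detection reports and quantification uses;
5. because qualifier EICs can apex a fraction of a scan away from the
   quantifier, peaks within `gather_window` (1.0 RI unit) of the quantifier
   apex are gathered from the whole (area-filtered) peak list into the bin;
6. ions with library intensity below 20/999 are not used as qualifiers
   (noise-dominated); a qualifier is *found* if its relative deviation
   |A−E|/E is within 2 × `max_avg_deviation`; qualifiers absent from the
   augmented bin count against the found fraction but not toward the mean
   deviation (they are missing, not deviant);
7. the attempt passes when found ≥ max(`min_qualifiers_absolute` = 2,
   ⌈`min_qualifier_fraction` = 0.6 × expected⌉) *and* the mean deviation
   over qualifiers present ≤ `max_avg_deviation` = 0.35. Entries with fewer
   qualifier-eligible ions than the absolute minimum cannot pass.

Per analyte per run the winner is the passed attempt with the lowest mean
deviation; ties break toward the larger quantifier area, then the earlier
bin, making reports byte-deterministic. A scoring utility classifies winners
against simulation ground truth as true/false positives and negatives, with
*ambiguous* reserved for winners whose quantifier peak is claimed by more
than one analyte.

Spectral deconvolution of co-eluting components and dot-product spectrum
scoring are deliberately out of scope: the matcher operates on EIC peaks
with quantifier/qualifier logic.

## Data matrix, imputation, normalization

The matrix cell is the winner's reported intensity; provenance
(`matched` / `imputed_from_raw` / `missing`) is tracked per cell. Missing
cells are filled *before* normalization by re-integrating raw data: the mean
integration start and end RIs of the winner peaks across matched runs
(averaged in RI space, robust to retention drift) are mapped into the
missing run's time axis through its calibration, and the raw
quantifier-channel EIC is summed (trapezoid, *uncorrected* — the imputed
value is a plain signal sum, so it includes the local baseline). When the
winning quantifier differs across runs the modal quantifier is used
(smaller m/z on ties). Analytes never matched anywhere stay missing with a
warning. Statistical imputation (k-NN, minimum value) is intentionally not
offered.

Normalization divides each sample by its internal-standard value, keeps the
standard's row at 1.0 and is idempotent; an optional per-sample scalar
factor table (mass/volume) is available separately and off by default.

## Statistics

Welch's t statistic, Welch–Satterthwaite df and two-sided p are computed
from the textbook formulas (scipy supplies only the t distribution); the
implementation agrees with `scipy.stats.ttest_ind(equal_var=False)` to 1e-9
in tests. Zero variance in both groups returns p = 1 on equal means and
p = 0 otherwise. Table rows with < 2 replicates in a group are flagged
untestable. Benjamini–Hochberg q-values are opt-in; raw p-values are the
default report. Sorting is stable (mergesort).

PCA is an SVD of the centered (optionally unit-variance-scaled) sample ×
analyte matrix; variance fractions are s²/Σs² and sum to exactly 1. Analytes
missing in more than half the samples are dropped with a warning; remaining
missing cells are filled with the analyte mean before centering.

Hierarchical clustering uses Pearson correlation across samples
(pairwise-complete), distance 1 − r, average linkage. Zero-variance analytes
are excluded with a warning; exclusion patterns (internal standards,
unknowns) are glob-style. The default flat cut is at the largest gap between
consecutive merge heights — the "natural clusters" reading; an explicit
cluster count can be forced.

The statistical scan compares TICs by default (a single EIC can be scanned
instead via the ``channel`` argument): runs are linearly interpolated onto a
common grid spanning the union rt range at the median scan interval, each
grid point gets a Welch p and mean intensity ratio, and points with
p < alpha (default 0.05) and fold change > `min_ratio` (default 2.0, folded
symmetrically so swapping sides changes nothing) merge into maximal
contiguous regions. No multiple-testing correction is applied — the scan is
a visual locator, not an inference procedure.

## Synthetic data

The generator emulates unit-resolution chromatograms of derivatized
standard mixtures. Each analyte gets a true rt, Gaussian peak shape
(sigma 1.2–2.0 s; an exponentially-modified Gaussian is available for
tailing), a random 5–20-ion spectrum over m/z 70–600 with base peak 999 and
the two most intense ions as quantifiers, and a linear response factor
(4–9 × 10⁵ area counts per concentration unit, chosen so mid-dilution peaks
sit near 10 × the default matcher area filter). Channel intensity is the
concentration-weighted sum of analyte shapes, times multiplicative noise
(CV 5 % default), plus a baseline offset (30 counts) and additive detector
noise (sd 10), clipped at zero. Scan interval 0.25 s. Shapes are evaluated
within ±8.5 σ of each apex.

The mixing design: 85 analytes (plus a ribitol-surrogate internal standard
at fixed concentration, placed mid-run) are laid along the rt axis with
random ≥ 3 s gaps and assigned to three sub-mixtures round-robin, which
guarantees > 4 σ separation within a sub-mixture while allowing co-elution
across sub-mixtures; sub-mixture sizes are therefore 29/28/28. Each
repetition draws an independent random order of the 8-point two-fold
dilution series per sub-mixture (the dilution factor is a choice; the
design's defining property is a shared randomized pattern per sub-mixture);
5 repetitions give 40 samples in which every analyte is present. Truth
tables carry each injected peak's channel, ±4 σ bounds, noiseless area and
concentration.

What the generator does *not* emulate: derivatization chemistry and
time-dependent analyte loss, retention drift between runs, spectral skew,
detector saturation, and electron-impact fragment correlations (spectra are
random). Pipeline results on this benchmark therefore demonstrate the
correctness of the algorithms under realistic signal arithmetic, noise and
co-elution — not robustness to every artefact of real instruments.

## Benchmark problem sizes and expectations

The quantitative benchmark (`gcmspipe.validation.run_mixing_benchmark`)
simulates the full 40-run, 85-analyte experiment at 5 % CV and processes it
end to end with detection thresholds (`min_slope` 100, `min_height` 1000)
sitting well below the smallest quantifier peaks of the series. On this
synthetic system the per-analyte concentration:signal R² (internal standard
excluded; analytes with under 3 reported values score 0) averages ≈ 0.99
with essentially all analytes above 0.8, and the largest-gap correlation
clustering resolves exactly the three sub-mixtures. The residual scatter
comes from the multiplicative noise, the IS normalization noise, and
quantifier-channel interference between co-eluting analytes that share a
fragment mass.

## Known limitations

* Nominal-mass only; no accurate-mass support.
* The matcher assumes one peak per m/z per 0.1-RI bin; heavily overlapped
  isomers sharing all channels are not deconvoluted.
* `run_pipeline` drives external calibration from files; internal
  calibration is API-only.
* Imputation integrates the winning quantifier channel only.
* The mzML writer emits the minimal subset the reader (and common tools)
  need: MS1 spectra, 64-bit uncompressed arrays.
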