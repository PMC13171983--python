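# Methods

This note documents the models, conventions and defaults behind
`ccmscan`, what the synthetic-data generator does and does not emulate,
and the design choices made where more than one convention is defensible.

## Exact masses and adducts

Neutral monoisotopic masses are sums of fixed isotope masses
(H 1.00782503207, C 12 exactly, ¹³C 13.0033548378, N 14.0030740048,
O 15.9949146196, P 30.97376163, S 31.97207100 Da). Uniform ¹³C labels
are expressed in the formula itself (`13C6H13O9P` = six ¹³C), so a
labelled internal standard is just another formula. Adduct m/z uses the
proton mass 1.007276466 Da directly (equivalent to ±H atom ∓ electron),
charge fixed at |z| = 1; the panel contains no multiply charged or
metal adducts, and isotope-pattern simulation is out of scope because
matching targets monoisotopic ions only. Values are displayed rounded
half-even to five decimals; full precision is kept internally. The
packaged panel reproduces all 173 stored theoretical m/z from their
formulas to ≤ 5×10⁻⁵ Da (one historically inconsistent printed pair for
cystathionine is stored formula-derived, as documented in the fixture
header).

## Panel and internal-standard assignment

The panel is a TSV with one row per compound; loading validates
formulas, retention times, the two-proton [M+H]⁺/[M−H]⁻ spacing, IS
references, a closed pathway vocabulary, and (lintable, overridable)
membership of every LOD in the ladder label set. IS resolution is per
polarity: the panel-assigned IS is used when it carries an ion in that
mode; otherwise the nearest-retention-time IS of that mode is
substituted and flagged `fallback`, so reports can always distinguish
table-assigned from fallback normalization. Analytes with no IS in a
polarity are flagged `unnormalizable` and passed through.

## Targeted extraction

An EIC holds all centroids within the ppm gate (default ±5 ppm) and the
RT window (default ±0.5 min around the library RT; chosen so that the
0.72 min G6P/F6P separation stays resolvable while the 0.22 min Leu/Ile
pair deliberately collides). Centroids sharing a scan time are summed.
Integration: apex = maximum intensity (earlier RT wins ties);
boundaries = nearest flanking local minima, falling back to apex ± 3σ̂
(σ̂ = FWHM/2.355) when the trace is monotone to the window edge; area by
trapezoid; noise = 1.4826 × median absolute deviation of the off-peak
points (all points when fewer than three are off-peak); S/N =
apex/noise with detection at S/N ≥ 3. A second apex outside the
boundaries at ≥ 50% of the main height marks the measurement
ambiguous. Isobar groups (entries sharing m/z within the gate) are
resolved per sample by nearest library RT; when several library RTs sit
within the RT tolerance of one apex and fewer resolvable apices exist,
all contenders are flagged ambiguous rather than force-assigned. The
S/N = 3 convention cannot reject a lucky extreme of a long pure-noise
window (max of ~100 robust-scaled noise points approaches 3); the gate
is a detection convention, not a false-discovery guarantee.

## Calibration and LOD

The ladder is the exact geometric series 20/2ᵏ µM, k = 0…8, with
bench-style display labels (20, 10, 5, 2.5, 1.25, 0.6, 0.3, 0.15,
0.08), and the floor is compared against labels so the ninth level
0.078125 µM is admitted by a printed floor of 0.08. The linear range is
selected by exhaustive search over contiguous runs of the
concentration-sorted detected levels: longest run of ≥ 5 points whose
ordinary least-squares fit has r² strictly > 0.95, ties broken toward
the run containing lower concentrations (saturation bias at the top is
worse than noise at the bottom). OLS is unweighted by default; a 1/x
weighting switch exists but is off, since nothing in the workflow's
definition prescribes it. The LOD rule is a documented convention —
the lowest ladder level at which the compound is detected (S/N ≥ 3)
with every higher level also detected — chosen because it always lands
on a ladder label and is monotone under detection loss; it is not
claimed to equal any particular lab's LOD procedure.
Back-calculation inverts the fitted line and flags responses outside
the selected range's response span.

## Normalization and QC

"Stability" of an IS is its coefficient of variation (sample SD/mean,
%) across samples, passing strictly below 22%. Normalization divides
each analyte by its resolved IS area in the same sample and polarity —
an algebraic identity then guarantees that any per-sample
multiplicative factor common to analyte and IS cancels exactly; a
missing IS area makes the analyte missing in that sample (no
zero-imputation anywhere before statistics). Note that with 20%
preparation scatter the raw IS CV sits near the 22% screen by
construction, so the orchestrated pipeline always applies the
designated IS and *reports* the screen rather than aborting; the strict
pre-condition (refuse unstable IS unless forced) is enforced when
`normalize` is called directly. QC metrics are the CV across pooled-QC
injections and the OLS slope of response versus injection order
expressed as %/injection. Preparation factors for absolute
back-calculation are estimated per sample as the median over IS
channels of area relative to the channel median (the IS is spiked at a
constant nominal level).

## Statistics

Min–max scaling maps each metabolite to [0, 1] over non-missing values
(constant columns to 0, flagged). PCA centers columns, does not scale
variances, and decomposes by SVD; metabolites with any missing value
are dropped listwise from PCA but kept in univariate tests when both
groups have ≥ 3 values. The two-sample test is Welch's (unequal
variances, Welch–Satterthwaite df, two-sided) — the common default of
general-purpose statistical environments — with a pooled-variance
variant available; degenerate zero-variance comparisons return p = 1
(equal means) or p = 0 (different means). Multiple testing uses the
Benjamini–Hochberg step-up, q(i) = min over j ≥ i of p(j)·m/j clipped at
1, computed within the family of actually tested metabolites.
Significance is adjusted p < 0.05; top-10 selection takes the lowest
adjusted p among significant hits with deterministic tie-breaks (|t|
descending, then name), and an `include` override can display a
borderline metabolite without loosening the threshold. The RT–logD
helper is a plain OLS with named-outlier exclusion; logD values are an
external input (they come from structure-based predictors, which this
package does not reimplement).

## Synthetic data: what it emulates and what it does not

The generator emits, per compound and injection, a Gaussian peak at the
library RT (σ = 0.05 min, sampled at 0.01 min) whose area is
response-factor × concentration, centroid m/z jittered around the
theoretical value (SD 1 ppm), and a sparse half-normal baseline
(SD 30 counts) across a ±0.45 min window. Per-compound response factors
are lognormal around 3000 counts·min/µM (log-SD 0.5) and are drawn once
per seed so calibration and study runs share them. Study design:
control + five inhibitor conditions, N = 4 replicates, randomized
injection order, a pooled QC (mean composition of all conditions)
opening the sequence and recurring every 6 study injections; every
injection carries all internal standards at a constant 5 µM-equivalent
level; each sample has a lognormal preparation factor (log-SD 0.2,
≈ 20% CV) multiplying all its channels; optional multiplicative drift
per injection (default 0). Baseline study concentrations are lognormal
around 2 µM clipped to [0.3, 10] µM, i.e. inside the calibration range.
Fold-change maps encode only the qualitative directions expected from
each inhibitor's mechanism (glycolysis block: glucose up, TCA and
hexosamine intermediates down; fatty-acid-oxidation block: fumarate,
malate, NADPH up, creatine down; complex-I inhibition: TCA and sugar
donors up; pyruvate-carrier block: pyruvate, malate, NAD⁺ up, G6P down;
succinate-dehydrogenase block: succinate up, fumarate, glutamate,
glutathione, G6P down) with illustrative magnitudes of 0.5–4×.

Not emulated: HILIC peak tailing and RT drift, ion suppression and
matrix effects, detector saturation, isotopologue fine structure, and
realistic injection-to-injection analytical noise beyond the baseline
term. Consequently the simulated data are cleaner than real
acquisitions (post-normalization QC CVs of a fraction of a percent,
near-perfect calibration linearity). Passing tests therefore
demonstrate that the *processing logic* is correct — gates, selection
rules, normalization algebra, statistics — not that real-instrument
performance figures are reproduced. Quantities that depend on vendor
integration internals (absolute areas) or on supplementary data not
shipped here (experimental logD tables) are intentionally not asserted
against any published figure.

## Problem sizes and determinism

Default checks run one study (29 injections × ~87 ion channels) and one
9-level ladder per seed, brute-force oracles on hundreds of random
fixtures, and 5000-replicate null calibrations — sizes chosen so the
whole suite executes in minutes on a laptop core while still giving
sub-percent Monte-Carlo error on the checked rates. All randomness
flows through `numpy.random.default_rng` seeded from a single integer;
identical seeds give byte-identical simulator output.
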