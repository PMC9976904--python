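# Methods

## Motif scanning

R10 ("AG5") motifs are 10-nt windows whose bases all come from {A,G}, with
a composition cap (`composition_cap`, default 7) on the count of each base
so that homopolymers and near-homopolymers (A₁₀, G₁₀, 8+ of one base) are
excluded; the cap is configurable because a cap of 8 is also a defensible
reading of "excluding more than 8". GC5 motifs are the analogous windows
over {G,C}. Non-overlap is resolved greedily left-to-right within each
annotated region: the scan advances one base at a time and jumps past each
accepted window, which is deterministic and order-independent. Hits are
then filtered to lie at least `min_edge_distance` (50) nt from both
boundaries of their region; since the three regions partition the
transcript, transcript ends coincide with region boundaries. The internal
alphabet is DNA (U→T on input); purine means {A,G}.

Primary-transcript selection keeps, per gene, the most abundant transcript
with `len_5utr > 100` (strict), with abundance ties broken to the
lexicographically smallest transcript id. Reactivity coverage and 5'-end
coverage are carried as plain fields with pass-through default thresholds
(0), because the original thresholds live in a prior data set; both
conditions must pass when thresholds are set.

## Reactivity windows

Offset windows sit at inclusive nucleotide distances 31–50 from the motif
edge: downstream the window covers the 20 positions 3' of the motif's last
base, upstream the mirror 5' of its first base; all coordinates are
0-based half-open internally and in output tables. Window means are taken
over positions defined (A/C) in both profiles, require `min_defined` (5)
defined positions (fewer yields an undefined delta rather than a noisy
mean), and windows extending past the transcript are flagged invalid, not
dropped. ΔDMS = mean(treated) − mean(control); because DMS reactivity
measures single-strandedness, ΔDMS < 0 is classified as gain of structure,
ΔDMS > 0 as loss, and exactly 0 is excluded.

Random windows are drawn per transcript and region from the 10-nt-step
grid (20-nt windows, same 50-nt edge constraint), uniformly without
replacement under the pipeline seed, one per motif, and motif/random
window pairs from the same transcript feed the paired two-sided Wilcoxon
test. Random "motifs" are scored as full 20-nt windows (not trimmed to
10 nt); their offset windows are measured from their own edges.

## Statistics

OLS is solved in closed form; the slope test is the F(1, n−2) statistic,
identical to the squared-t test (property-tested to 1e-9). Convention for
perfect fits: rss = 0 with a nonzero slope reports p = 0 (the F statistic
diverges); rss = 0 with slope exactly 0 reports p = 1, since a perfectly
flat fit carries no evidence against a zero slope. Wilcoxon tests drop
zero differences (Wilcoxon's method) and use the exact null distribution
up to n = 25 (falling back to the normal approximation when ties preclude
exactness), the normal approximation above. The FDR procedure is
Benjamini–Hochberg (the named procedure behind "standard" FDRs is an
assumption, flagged here). The two-sample t-test defaults to Welch.

## pSILAC

Peptide rows are combined per channel by median over identical peptide
sequences, then across peptides per protein by a configurable operator
(default sum; median available) — the combining operator is not dictated
by the data model. Peptides mapping to several protein groups are excluded
and counted. F_H points ≤ 0 (the t = 0 sample) are excluded before the log
transform; replicates enter the fit as separate points (configurable
philosophy, but this is the implemented default). The fit-quality filter
requires slope p < 0.1 in *both* conditions. The rate-difference test is a
two-sided z-test on k_treated − k_control using the two fits' slope
standard errors — chosen as the minimal-assumption option since the
underlying test behind the published FDRs is unstated — followed by BH
across proteins; labels: FDR < 0.1 dependent, > 0.7 independent, else
unclassified. Upstream batch normalisation is out of scope; the synthetic
generator emits already-normalised intensities, and a per-channel
median-centring would be the natural pre-step on real exports.

## Enzymology

Hill fits initialise y_max at the response maximum, K₁/₂ by interpolating
the half-max crossing, h = 1, with bounds h ∈ (0, 6] and K₁/₂ within the
tested range × [0.01, 100]; the prediction at K₁/₂ equals y_max/2 by
construction. Progress curves offer both readings of "initial rate":
A·k_obs from the exponential fit and an early-window linear slope
(`linear_initial`, default 5 points). Progress signals are assumed already
normalised to fraction unwound via user 0%/100% controls. ATPase coupling
is fixed 1:1 NADH:ATP (PK/LDH regeneration); ε(NADH) defaults to
0.62 mM⁻¹ absorbance and is a parameter. The mixing-model family is
limited to the noncooperative line (1 − f) and the n-subunit poisoning
model (1 − f)ⁿ, n selected by least squares over n = 1..8 with per-n SSE
reported; intermediate cooperativity is out of scope. The reporter
maximum-slope window defaults to 5 consecutive readings (unstated in the
assay description; configurable).

## Synthetic data

The generators define the study conditions the tests run under.
Transcripts draw region lengths uniformly (5'UTR 150–300 nt so the
>100-nt filter is satisfiable, CDS 300–900, 3'UTR 150–300), background
bases uniform over {A,C,G,T} (purine fraction adjustable), and plant
motifs that satisfy every scanner rule. Each planted motif receives
pyrimidine flanking bases; any purine window overlapping a planted motif
would have to include a flank, so no spurious hit can straddle one and the
greedy scanner provably recovers every planted motif (the closure the
tests assert). Reactivities are truncated-at-zero normals (mean 0.5,
sd 0.1) at A/C positions; the treated condition shifts the mean by the
effect (−0.15) only inside the downstream 31–50 window of planted motifs,
mirroring the one-sided localisation of the real signal. What this does
*not* emulate: coverage heterogeneity, correlated noise along the
transcript, isoform ambiguity, or reactivity normalisation artefacts — so
green tests certify the statistics and bookkeeping, not robustness to
those real-data features.

The pSILAC generator uses k ~ U(0.02, 0.2)/h, 4 replicates at 0/2/4/8 h,
a dependent subset (25%) with k halved, and independent multiplicative
lognormal noise (mean 1, CV 10%) on each intensity channel. Its default
generation mode is the exact log-linear form F_H = 0.1·e^(k·t): the fitted
model *is* that linearisation, and under the mechanistic curve
F_H = 1 − e^(−k·t) the fitted slope is an apparent rate nearly independent
of k at small k·t (ln(k·t) has slope 1/t), so rate-recovery and
classification properties are only meaningful in the log-linear regime.
The mechanistic mode is provided for realism (F_H(0) = 0, dropped by the
fitter) and covered by tests. The intercept 0.1 keeps F_H within (0, 0.5]
across the rate range, comparable to the mechanistic curve at mid-course.

Under these conditions the planted-cohort classification reaches ~0.70
sensitivity at ~0.07 empirical FDR: with two noisy channels,
sd(ln F_H) ≈ (1 − F)·√2·CV ≈ 0.12, the slope SE is ≈ 0.010 per condition,
and BH at FDR 0.1 cannot resolve rate halvings below |Δk| ≈ 0.033, which
is the detection-theoretic ceiling of the prescribed procedure; slower
planted proteins additionally fall to the p < 0.1 fit filter. This is a
known limitation, measured (not asserted away) by the acceptance suite.

## Problem sizes and numerics

The property simulations use a 300-motif cohort (100 genes × 3 5'UTR
motifs) for planted-effect power (100 seeds), a 34-gene null cohort for
the type-I run (500 seeds), and 50 seeds × 500 proteins for the pSILAC
cohort — sizes chosen so each property has negligible Monte-Carlo error
while the whole suite stays light. Curve fits use
`scipy.optimize.curve_fit` with analytic initial guesses; noise-free
recoveries are exact to the asserted tolerances (Hill 1e-6, rates 1e-9).
All randomness flows through `numpy.random.Generator` seeded per run;
fixed seeds give byte-identical generator output.
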