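# Methods

This note documents the models behind each module, the parameter choices
that matter, what the synthetic generators do and do not emulate, and the
numerical conventions a user should know before trusting a number.

## Current-clamp simulation and feature extraction

**Membrane model.** Subthreshold sweeps follow the single-exponential RC
response V(t) = V<sub>rest</sub> + IR(1 − e<sup>−t/τ</sup>) with
τ = R<sub>in</sub>C<sub>m</sub> (units: MΩ · nF → ms). Suprathreshold
sweeps are the same passive trace, capped 1 mV below spike threshold, with
stereotyped AP templates pasted at spike times from a deterministic
adapting renewal model: the first inter-spike interval shortens linearly
with drive above rheobase (gain `fi_gain_hz_per_pa`, base rate 5 Hz at
rheobase), later ISIs lengthen geometrically toward
`adaptation_ratio × ISI₁` with rate constant 2 spikes. First-spike latency
is the RC charge time to the rheobase-defined initiation level, saturating
at ≈ 6.9 τ at exactly rheobase. This is deliberately not a biophysical
model: every quantity the extractor measures (threshold, amplitude,
half-width, AHP, latency, ISIs) has an exact planted value, which is the
point — the pipeline tests feature *extraction*, not channel kinetics.

**AP template.** A ramp approaches threshold at ≈ 10–14 mV/ms (below the
detection criterion), the upstroke and downstroke form a triangle solved so
the width at threshold + amplitude/2 equals the requested half-width, the
trace bottoms at threshold − AHP, and recovers with a 15 ms exponential.

**Noise.** Membrane noise is Ornstein–Uhlenbeck with a 2 ms correlation
time and stationary SD `noise_sd_mV` (default 0.2 mV). White noise at
20 kHz would carry ≈ 5 mV/ms of slope noise and corrupt dV/dt spike
detection at the standard 20 mV/ms criterion, which no real recording
does — the membrane low-pass filters its noise, and the simulator follows.

**Extraction conventions.** Spike threshold is the voltage at the first
sample where dV/dt crosses 20 mV/ms before a ≥ 20 mV-prominence peak
(configurable; the criterion is the common patch-clamp convention).
AHP = threshold − minimum within 50 ms after the peak; the AHP of an AP
whose window crosses the step offset is contaminated by the off-relaxation,
so waveform features are measured on the rheobase sweep's first AP.
R<sub>in</sub> is the slope of steady-state deflection (last 20% of the
step) versus current over spike-free hyperpolarizing sweeps; τ is a
Levenberg–Marquardt single-exponential fit to the onset transient of the
largest hyperpolarizing step; C<sub>m</sub> = τ/R<sub>in</sub>. Firing
features use the largest suprathreshold step: f<sub>inst</sub> = 1/ISI₁,
f<sub>steady</sub> = 1/mean(last 3 ISIs), adaptation = ISI<sub>last</sub>/ISI₁.
The 13-parameter set covers every intrinsic-membrane and AP-kinetics
quantity named in the study design's comparison panels; the exact
membership of such lists varies between labs, so it is configurable.
Missing values are NaN plus an explicit flag (left-censored rheobase,
no-suprathreshold-step, etc.).

**Recovery.** On 50 simulated cells at 0.2 mV noise the extractor recovers
R<sub>in</sub> and τ within 5% and C<sub>m</sub> within 10% per cell
(acceptance suite; observed maxima ≈ 1% and ≈ 5%).

## Expression simulation and analysis

**Generator.** Counts follow a minimal hierarchical model: per-gene
baseline expression (log-normal σ = 1 across genes; planted markers pinned
at the population median so their fold-changes are measurable), cluster
log₂ fold-changes on planted markers, a per-donor log-normal random effect
(6 donors, σ = 0.05), log-normal library sizes (mean 20k, σ = 0.3), Poisson
sampling, and expression-dependent Bernoulli dropout: a measurement with
expected count λ survives with probability
(1 − rate)<sup>exp(−λ)</sup>, so dropout concentrates on lowly expressed
genes and `dropout_rate` (default 0.2) is the zero-expression dropout
probability. Flat dropout was rejected during design: zeroing 20% of
well-covered measurements makes the four clusters unrecoverable by any
standard recipe and matches no QC-passing full-length scRNA-seq cohort.
The donor σ was set so subtype variance dominates donor variance, the
structure reported for the study cohort; at σ = 0.15 the clustering is
donor-driven instead. ERCC rows are Poisson with fixed per-spike means,
independent of cluster and cell. Defaults mirror the study cohort: 53 INT,
90 PY1, 27 PY2 (13.7%), 27 PY3 = 197 cells; PY2 carries the
senescence + SASP + neurofilament panel at log₂FC 2 and LMNB1 at −1.

**What the generator does not emulate:** UMI/read conversion, gene length
and GC bias, doublets, ambient RNA, batch structure beyond one donor
effect, and mean–variance overdispersion beyond Poisson-lognormal. Passing
tests therefore show the pipeline's statistics behave correctly under the
assumed data model, not that the model captures every artifact of tissue
patch-seq.

**Pipeline conventions.** Normalization is counts-per-10k then log1p, with
spike-ins excluded from the size factor (all-zero cells stay zero; the
transform is not idempotent and expects raw counts). Clustering selects 500
genes by mean-binned normalized dispersion, then k-means (k = 4, 10 inits)
on 20 centred principal components. Components are deliberately not
variance-scaled: unit-scaling gives the ~460 noise genes the same weight as
the informative minority and measurably degrades recovery; dispersion
ranking already equalizes depth. A Leiden graph-community path is available
behind `method="leiden"`. The marker test is a tie-corrected one-vs-rest
rank-sum (exact enumeration when the cohort has ≤ 12 cells, normal
approximation with continuity correction otherwise), fold-change on
expm1-scale means with a 10⁻⁹ pseudocount, BH adjustment across genes
within each cluster, and the marker rule padj < 0.05 ∧ FC > 1.5.
Constant genes get p = 1 by convention. Annotation scores each reference
panel per cluster as (+1) per significantly enriched and (−1) per
significantly depleted panel gene — shared identity programs (e.g.
pan-pyramidal genes) cannot clear the one-vs-rest fold-change bar when
their class is the majority, but depletion of the opposing panel is equally
diagnostic; ties give "ambiguous". Enrichment is the weighted KS running
sum (weight |z|), with a gene-label permutation null, NES = ES divided by
the mean |null ES| of the same sign, and p = (1 + #{|null| ≥ |ES|, same
sign}) / (1 + #same-sign).

## FISH simulation and quantification

**Generator.** Somas are axis-aligned ellipsoids (analytic volume
4/3·π·abc) on a jittered grid spaced ≥ 2.1 maximal semi-axes, so somas
never overlap. The PY2 class (fraction 2369/7688 ≈ 0.308) is ~1.25× larger
per axis and carries ~2.5× the density of NFKBIA, CDKN1A, CCL2, NEFM and
NEFH (CUX2 near-equal), with per-gene spot counts Poisson(density ×
pre-expansion volume) and spots uniform inside the expanded soma.
Coordinates are post-expansion µm at EF = 2; `volume` mode rasterizes DAPI,
label and spot channels at (0.4, 0.23, 0.23) µm voxels (z, y, x) with
σ = 1 voxel Gaussian spots. PSF anisotropy, optical sectioning, expansion
inhomogeneity and segmentation errors at soma contacts are out of scope.

**Quantification conventions.** Spot detection is scale-normalized
Laplacian-of-Gaussian (per-axis σ from the stated voxel anisotropy —
required, no default), 3³ local maxima above threshold, centre-of-mass
subvoxel refinement. Soma segmentation is Otsu + Euclidean distance
transform + watershed with a minimum-volume filter; externally provided
masks bypass it. Spot assignment uses the containing voxel (0-based z-y-x
indexing, half-open bounds) on labelled volumes, or exact ellipsoid
membership (nearest-centres candidate search) on analytic soma tables;
every spot ends up with exactly one label (0 = background). Volumes are
reported pre-expansion via the cube law V/EF³ — the scale on which planted
densities are defined — with the post-expansion value retained for audit.
The 2-class molecular split is k-means (k = 2) on per-gene z-scored log1p
densities; the cluster with higher mean CDKN1A + NFKBIA density is named
PY2, so the classification is purely transcriptional and soma size is a
read-out, not an input. A silhouette below 0.25 raises a no-split warning:
Monte-Carlo calibration on the 6-gene panel puts single-class samples at
0.12–0.16 and genuinely two-class samples at ≈ 0.65. The density slope is
the through-origin least squares Σcv/Σv² (zero volume ⇒ zero expected
count); an ordinary two-parameter fit is intentionally not the default.
Per-sample paired comparisons gate on Shapiro–Wilk normality of the
differences at α = 0.05: paired t when not rejected, otherwise the exact
two-sided Wilcoxon signed-rank (exact null for n ≤ 25); identical pairs
return p = 1.

## Group statistics

All four tests are implemented from first principles (scipy supplies only
distribution tails and midranks) so that enumeration oracles can check
them exhaustively. Fisher's exact test uses the probability-mass rule for
the two-sided p (sum of hypergeometric probabilities ≤ the observed
table's) and the Haldane–Anscombe 0.5 correction, flagged, for the odds
ratio when a zero cell exists. Mann–Whitney switches to full enumeration
over group assignments at total n ≤ 12 (exact under ties) and otherwise
uses the tie-corrected normal approximation with continuity correction.
Kruskal–Wallis applies the tie correction 1 − Σ(t³−t)/(n³−n); Dunn's z uses
the pooled-rank variance with tie term, and the pairwise family adjustment
defaults to Bonferroni (Holm/Šidák available) — adjusted p never falls
below raw p. The log-rank test is the Mantel–Cox observed-vs-expected sum
over distinct event times with hypergeometric variance, 1 df; Kaplan–Meier
curves are the product-limit estimator with right censoring. Percentages
in marker-fraction reports are computed per sample and then summarized as
mean ± SEM across samples, matching per-sample reporting conventions;
samples with an empty denominator are flagged and excluded.

**Calibration.** The acceptance suite verifies that each test's null
rejection rate at α = 0.05 lies in [0.035, 0.065] over 2,000 replicates.
Null sample sizes (binomial 150-per-row tables for Fisher, 30 + 30 for
Mann–Whitney, 3 × 25 for Kruskal–Wallis, 40 + 40 with 8% censoring for
log-rank) are chosen large enough that the discrete p-value supports are
near-continuous: an exact test on tiny samples is conservative by
construction and its sub-nominal rejection rate would say nothing about
implementation correctness.

## Problem sizes

The test and acceptance workloads use the cohort sizes the analyses are
designed around: 197-cell / ~2,100-gene expression matrices (20 replicate
cohorts for the recovery property), 50 simulated patched cells, 500–7,688
FISH neurons (the full 7,688 with ~2.1 M spots runs end to end in the
acceptance script), 2,000-replicate null calibrations, and 300–400
replicate power estimates for the 18-vs-10 survival design.

## Known limitations

Exact Mann–Whitney enumeration is combinatorial and capped at n = 12; the
GSEA-style enrichment permutes gene labels (not sample labels), which is
the appropriate null for a pre-ranked list but ignores inter-gene
correlation; Welch's ANOVA (via pingouin) flags rather than tests features
with a zero-variance group; the k-means clustering paths assume roughly
convex clusters in PC space — the Leiden path is the escape hatch; and the
soma segmenter is tuned for well-separated somas, as produced by the
generator, not for dense tissue contact surfaces.
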