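# Methods

This note documents the models, numerical choices and defaults behind
`synscreen`, and what the synthetic-data generators do — and do not —
emulate.

## Growth-curve metrics

Raw plate-reader curves (OD600 every 15 min, 96 points ≈ 24 h by default)
are smoothed with a centred moving median followed by a moving mean
(default window 5 points, truncated at the edges). The median stage
removes isolated mis-reads; the mean stage the residual jitter. Smoothing
with any window preserves constant curves and, on monotone data, commutes
with affine rescaling — which is why area ratios of smoothed curves are
unbiased.

**AUC and inhibition ratio.** The area under a curve is the trapezoidal
integral of max(OD − baseline, 0). The baseline defaults to the well's
first reading, removing the inoculum/blank offset; whether an upstream
blank should instead be subtracted is reader-specific and left to the
caller. The inhibition ratio W divides the drug well's area by the no-drug
control's, each with its own baseline, over their common time span (the
two curves must overlap over ≥90% of the control span). Control areas
below 1e-6 OD·min are refused as degenerate.

**Average generation time (AvgG).** AvgG is minutes per doubling over the
exponential phase of y = log2(max(OD, 1e-3)). The span is anchored at the
global maximum of the first finite difference of y (earliest on ties) and
extended on each side to the nearest zero-crossing of the second finite
difference — the lag→log and log→stationary inflections of a lagged
culture. Two deliberate choices:

* *No baseline subtraction inside the log.* Subtracting the inoculum OD
  before taking logs makes the earliest increments look like enormous
  relative growth (the denominator approaches zero) and destroys the
  exponential-phase slope; the raw OD with a small floor is used instead.
* *Shoulder fallback.* A lag-free logistic has strictly concave log-OD, so
  no second-difference zero-crossing exists; the span then extends to the
  furthest point whose slope still exceeds 90% of the maximum. On
  noiseless logistics this recovers ln 2/r within ~5% across
  r ∈ [0.003, 0.02] min⁻¹ (tested).

Curves whose total rise is < 0.05 OD are `no_growth`; spans with
non-positive log-rise are `censored`. Mutant fitness is
(AvgG_wt,drug/AvgG_mut,drug)/(AvgG_wt,ctrl/AvgG_mut,ctrl), which cancels
constitutive haploinsufficiency and lands on the 1.0 = wild-type scale of
the packaged fitness table; any `no_growth` input propagates as fitness 0
with a warning flag.

## Checkerboard synergy scoring

ε = W_AB − W_A·W_B per dual-dose cell, margins taken from the zero-dose
row/column. AvgS averages dual-drug cells only — the margins are
identically ~0 and would dilute the score. Thresholds follow the screen
design: AvgS < −0.05 (6×6), min-cell ε < −0.20 (4×4); both strict.

The three confirmatory models are not fully determined by the screening
literature, so the standard forms are adopted, all thresholds
configurable:

* **Loewe / combination index.** For dual cells with W_AB ≤ 0.8,
  CI = d_A/D_A(W_AB) + d_B/D_B(W_AB), where D_X(w) interpolates the
  single-agent margin linearly in effect against log dose (zero dose is
  never placed on the log axis; cells whose effect the margins do not
  span, or with non-monotone margins, are skipped). Call = median CI over
  evaluable cells < 0.9; no evaluable cell → indeterminate, reported
  false. A sham self-combination has CI = 1 by construction and is never
  called.
* **HSA.** Any dual cell beating its better single agent by > 0.10 growth
  units.
* **Potentiation.** The interpolated w = 0.5 crossing dose of either drug
  must fall ≥ 2-fold in the presence of the lowest non-zero dose of the
  partner; protective (increasing) or non-bracketing axes are skipped.

A consensus synergy call requires all four models. Note the sham
self-combination built from a single Hill curve: with Hill slope 1 the
combination is also Bliss-consistent (AvgS ≈ +0.014, antagonistic side);
steeper slopes curve the self-combination below independence (slope 2:
AvgS ≈ −0.084), which is precisely why Bliss alone over-calls synergy and
the Loewe/HSA/potentiation filters exist. Loewe correctly rejects the
sham at every slope tested.

## Drug–gene interaction calling

"≥10% fitness defect" is read inclusively (fitness ≤ 0.90) — this
reproduces the published count of 76 negatives on the packaged table —
and ">30%" exclusively (fitness < 0.70). Re-counting the packaged table at
the stringent cutoff yields 25 cells; the published count of 23 is not
recoverable from the printed values, and this package reports the
recount. Mutants whose no-drug fitness deviates from 1 by more than 0.2
(e.g. the actin heterozygote) are flagged for exclusion before calling.
The enrichment test is an upper-tail hypergeometric with the universe
defaulting to all tested cells (110 here); the universe is configurable
because the original analysis does not state it, so the p-value this
package reports for the 17-of-18 overlap (p ≈ 0.007) is its own, not a
reproduction of the published 0.003.

## Synergy prediction

A sensitivity threshold of log2(control/treatment) ≥ 1 (or Z ≥ 2 for
Z-scored profiles) defines a profile's sensitive set. Predictions are
deduplicated per unordered pair keeping the direction with the stronger
rationale score (lexicographic tie-break). Profile-similarity approaches
are out of scope; the target map is an input, one primary target per
drug.

## HIP–HOP combination profiles

Pipeline order is fixed: saturation correction → quantile normalization →
log2 → supervised batch removal → tag selection → robust Z.

* **Saturation.** Features saturate as y = c·x/(c+x); the correction
  inverts this below 0.95·c and winsorises (and flags) values above. The
  default ceiling is 0.95 × the maximum observed intensity, configurable
  for scanners with a known ceiling.
* **Quantile normalization** maps every array rank-for-rank onto the mean
  order-statistic profile; arrays must share a probe count.
* **Batch removal** fits, per probe across arrays, an additive treatment +
  batch (chip date) model by least squares and subtracts the sum-to-zero
  batch component, leaving treatment contrasts untouched. Designs where a
  batch contains a single treatment level are refused as confounded; a
  single batch is a no-op.
* **Tag selection** keeps, per strain, the barcode (up/down) with the
  lower replicate-feature coefficient of variation averaged across
  arrays; ties prefer the uptag, degenerate (non-positive-mean) tags are
  disqualified.
* **Robust Z** = (median − x)/(1.4826·MAD) against the control-probe
  distribution (all strains of the table serve as fallback when fewer
  than three control probes exist); 1.4826 makes the MAD estimate a
  Gaussian σ. Positive Z = depleted. A zero control MAD is an error, not
  a silent division.

Combination-specific strains: Z ≥ 2.0 in the combination screen
(inclusive) and Z < 2.0 (strict) in *all four* single-agent screens —
both IC20 and combo-dose screens gate, the conservative reading — and are
reported separately for the essential-heterozygote (HIP) and
nonessential-homozygote (HOP) panels. The sensitivity ε defaults to the
product form z_AB − z_A·z_B with z_A, z_B from the combo-dose screens;
the additive variant z_AB − (z_A + z_B) is available as `mode="sum"`
because the two forms circulate interchangeably and neither is asserted
as canonical here. Clustering uses 1 − Pearson distance with average
linkage and label-sorted, hence deterministic, leaf order; dendrograms
export as Newick.

## Gene-set enrichment

Preranked weighted-KS GSEA: genes ranked by descending score (default:
product-mode sensitivity ε), hits increment the running sum by
|score|^p/Σ|score|^p (p = 1 default; p = 0 recovers the classic KS
statistic), misses decrement by 1/(N−|S|); ES is the signed maximum
deviation. Sets are GMT collections filtered strictly to 6–199 members
inside the scored universe. Significance comes from gene-label
permutations (1,000 by default): p is the fraction of same-sign permuted
ES at least as extreme, with a +1 correction, conditioned on the observed
sign — this conditioning is what keeps null p-values uniform on (0, 1] —
and NES divides ES by the mean |permuted ES| of that sign. Results tables
carry Benjamini–Hochberg q-values. Everything is deterministic under a
fixed seed.

## Synthetic data: what it emulates, and what it does not

**Checkerboards.** Single-agent responses are Hill curves
W(d) = 1/(1+(d/IC50)^h); ladders are built at the IC0/2/5/10/20/50 (6×6)
or IC0/10/20/50 (4×4) inhibition levels. The combination's relative
growth is the Bliss product plus a planted δ, clamped to [0, 1.2]. Each
well's OD curve is the control logistic's rise scaled in amplitude:
od(t) = x0 + W·(od_ctrl(t) − x0). This models yield (plateau) inhibition
at a fixed intrinsic rate; it was chosen over rate inhibition because it
makes the AUC-ratio pipeline recover the planted W exactly, so the
ground truth is directly comparable to measured ε. Real drugs also slow
growth rates and lengthen lags, which this generator does not emulate —
passing tests show the scoring chain is unbiased for yield-type
inhibition, not that AUC ratios equal the "true" effect under arbitrary
kinetics. Defaults: 96 points × 15 min, inoculum OD 0.0625, capacity 1.0,
rate 0.0077 min⁻¹ (≈90-min doubling, typical for rich-medium yeast),
additive Gaussian OD noise (default off; 0.02 in the noisy-recovery
studies).

**Five-screen barcode sets.** 200 strains (half HIP, half HOP panel),
2 tags × 5 replicate features, two chip-date batches (+0.5 log2 shift)
with one replicate array per treatment per batch, control probes spanning
a σ = 1 log2 ladder (this σ is the robust-Z scale), strain abundance
σ = 0.25 log2, feature noise σ = 0.1 log2, and a 16-bit saturation
transfer applied to the emitted intensities. Spiked combination-specific
strains are depleted by spike_z × control σ in the combination screen
only. Crucially, each single-agent screen also depletes its own disjoint
decoy strain set of the same size: single agents at bioactive doses have
their own hit lists in real screens, and this keeps the per-array
intensity distributions exchangeable — the assumption quantile
normalization rests on. Without it (a depletion signature in one screen
only, at 10% of a 200-strain pool) quantile normalization attenuates the
planted effect by more than half; with it, recovery is essentially exact.
Real microarray spatial artifacts, probe cross-hybridisation and
sequencing-style count noise are not modelled.

**Prediction worlds.** Each drug targets one distinct gene; true pairs
plant a sensitivity of drug B's target (score 3.0, threshold 1.0) in drug
A's profile; decoy sensitivities on non-true pairs at a configurable rate
degrade precision; Gaussian score noise is optional. Noise-free,
precision = recall = 1 by construction — the test of interest is the
degradation behaviour, not the clean case.

## Problem sizes and determinism

The shipped studies use a 6×6 checkerboard (36 wells × 96 timepoints),
50-seed noisy-recovery sweeps, 200-strain/20-spike five-screen sets, an
8-gene exhaustively-enumerable GSEA universe plus a 60-gene/40,000-draw
permutation-calibration study, and enumeration oracles for universes ≤ 12
— sizes chosen so every ground truth is either analytic or exhaustively
enumerable. All generators and permutation machinery are driven by
explicit integer seeds and are bit-reproducible.

## Known limitations

* AvgG's shoulder fallback biases ~+5% on lag-free logistics (the secant
  sits on a concave curve); real lagged curves with genuine inflections
  do not pay this bias.
* Loewe CI and potentiation need margins that actually span the effect
  levels; shallow matrices return indeterminate (false), never a guess.
* The hypergeometric universe and the GSEA weighting/permutation count
  are analysis conventions, not measurements; both are configurable and
  their defaults documented above.
* The enrichment p for the 17-of-18 overlap depends on the universe
  convention and is reported as this package computes it.
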