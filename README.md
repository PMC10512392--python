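# synscreen

Analysis toolkit for drug-combination synergy screening in budding yeast:
checkerboard growth-curve scoring, drug–gene interaction calling on
heterozygote fitness tables, chemogenomics-based synergy prediction, and
HIP–HOP barcode-screen combination profiling.

## Who this is for

Chemical-genomics labs that screen drug pairs against *Saccharomyces
cerevisiae* (or any plate-reader-friendly microbe) and want a tested,
scriptable path from raw OD600 time series and barcode-array intensity
tables to synergy calls, combination-specific sensitive strains, and
gene-set enrichment signatures — without reassembling the statistics by
hand for every screen.

## The models at the core

**Bliss independence on growth ratios.** Each well of an n×n dose
checkerboard is reduced to a relative growth
*W* = AUC(drug)/AUC(control) (areas under smoothed, baseline-corrected
OD600 curves). If two drugs act independently, the combined effect is
multiplicative, so the deviation per dual-dose cell is

    ε = W_AB − W_A · W_B

with ε < 0 synergy and ε > 0 antagonism. The matrix summary **AvgS** is
the mean ε over dual-drug cells; AvgS < −0.05 flags a 6×6 screen as
Bliss-synergistic (smaller 4×4 screens use min-cell ε < −0.20). Because
Bliss alone over-calls, three confirmatory models are applied — Loewe
additivity (combination index from log-interpolated equi-effective doses),
highest single agent, and potentiation (≥2-fold shift of the interpolated
midpoint dose) — and only the four-model consensus is called synergistic.

**Drug–gene interactions.** Heterozygous deletion mutants of known drug
targets are grown in each drug; fitness is the wild-type-normalised ratio
of average generation times (AvgG), so 1.0 means no interaction. Cells
with fitness ≤ 0.90 (a ≥10% defect) are negative interactions, split into
*expected* (mutant is the drug's own target) and *novel*; overlap with a
predicted-interaction set is tested with an upper-tail hypergeometric.

**Synergy prediction.** If drug A's chemogenomic profile sensitises the
target gene of drug B (and A does not target that gene itself), A+B is
predicted synergistic; enrichment over the random-pair background rate is
the hit-rate ratio.

**HIP–HOP combination profiles.** Barcode intensities pass through a fixed
chain — saturation correction, quantile normalization, log2, supervised
batch (chip-date) removal, per-strain tag selection by lowest CV — and
become robust Z fitness defects, *z = (median − x)/(1.4826·MAD)* against
control probes (positive = depleted). A strain is **combination-specific**
when z ≥ 2 in the A+B screen and z < 2 in all four single-agent screens.
The per-strain sensitivity ε = z_AB − z_A·z_B ranks genes for preranked
gene-set enrichment (weighted-KS, gene-label permutations) over GO-style
sets of 6–199 members, and profiles are clustered on 1 − Pearson distance.

## Worked example

Simulate a 6×6 checkerboard with a planted Bliss interaction of −0.15 and
score it:

```sh
$ synscreen simulate --kind dose-matrix --delta -0.15 --seed 5 --out demo
$ synscreen synergy --plate demo/plate.csv --plate-map demo/plate_map.tsv --out demo_out
drugA+drugB: AvgS=-0.1500 min_eps=-0.1500 consensus=no
```

The growth→AUC→ε pipeline recovers the planted interaction exactly
(AvgS = −0.150): the pair is Bliss-synergistic. `demo_out/call.json` shows
the four models individually — here Bliss, Loewe and HSA agree but the
uniform −0.15 offset is too mild to shift either midpoint dose 2-fold, so
potentiation (and therefore the consensus) stays negative:

```json
{"bliss": true, "loewe": true, "hsa": true,
 "potentiation": false, "consensus": false, "avg_s": -0.15, ...}
```

Re-analyse the packaged heterozygote fitness table (10 mutants × 11
drugs) at the ≥10% defect cutoff:

```sh
$ synscreen druggene --out report.tsv
76 negative interactions at cutoff 0.9 (<=): 10 expected, 66 novel
```

76 of the 110 mutant×drug cells show a ≥10% fitness defect; 10 of these
are the mutants' own known drug targets, the other 66 are novel negative
interactions.

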