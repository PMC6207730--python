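# Methods

This note documents the models, parameter choices and numerical decisions
behind `plantmir`, and what the synthetic-data validation does and does not
demonstrate.

## Inverted-repeat discovery

An inverted repeat is scored as a local alignment between a left arm and
the reverse complement of a right arm. The dynamic program fills cells
(i, j) — "the innermost alignment column pairs position i with position j"
— with transitions for a pair column (match +3 / mismatch −3), a gap in
either arm (−7 per gap position), or a fresh local start. `N` never
matches. Cells must keep a loop of ≥ 3 nt between the arms; origin arrays
carry the outermost coordinates of the optimal path so the total extent
(arm + loop + arm) can be bounded at 336 nt without traceback.

The scan runs in windows of twice the maximum extent with a stride of one
extent, so any repeat within the extent bound lies wholly inside at least
one window. Per window, the best-scoring end cell is kept per origin;
across windows, candidates are deduplicated by coordinates and reduced to
non-overlapping local-score maxima, ties broken by higher score, then
smaller span, then leftmost start. One known approximation: when a path
longer than the extent bound shadows a shorter sub-alignment sharing its
cells, the sub-alignment's origin is not recovered; with the default
penalties such paths require implausibly sustained complementarity and the
exhaustive-oracle suite (quadratic DP, sequences ≤ 200 nt) never exhibits
a discrepancy.

Defaults (+3/−3/−7, floor 25, extent 336, loop ≥ 3) reproduce the
conventional plant pre-miRNA operating point; all are config fields.

## Folding engines

Two backends satisfy one contract (sequence → dot-bracket + MFE):

* **Built-in model** — exact optimum of a base-pair-weighted Nussinov DP:
  CG −3, AU −2, GU −1 kcal/mol, hairpin loops ≥ 3 nt, no pseudoknots.
  It is deliberately simple: deterministic, dependency-free, and exactly
  testable by brute-force structure enumeration (the suite checks 500
  random sequences ≤ 14 nt). Its energies are systematically more negative
  than nearest-neighbor values because every pair scores independently.
* **ViennaRNA** — nearest-neighbor MFE plus ensemble quantities (ensemble
  free energy, diversity, MFE-structure frequency) when the `RNA` bindings
  import. Ensemble descriptors are never emulated by the built-in model;
  they are reported as missing instead.

The pipeline default is the built-in model so that results are identical on
any installation; pass `engine="vienna"` for nearest-neighbor energies.

## Descriptors and the filter cascade

AMFE = MFE/length × 100; MFEI = |AMFE| / GC% with GC% on the percent scale.
MFEI is reported as a positive magnitude, the convention in plant pre-miRNA
tables; values ≥ 0.85 discriminate pre-miRNAs from other ncRNA and mRNA
hairpins. GC bounds [20%, 65%] are inclusive at both ends; the MFE cutoff
is −18 kcal/mol (values at the cutoff pass); both are config fields, as is
the MFEI floor. When GC% is zero MFEI is undefined and the candidate fails
the MFEI rule with a warning. G/C and A/U ratios are reported as G%/C% and
A%/U% (infinite when the denominator is absent).

All filter rules are evaluated independently and every failure is recorded,
so a verdict explains itself. Mature homology is substitution-only Hamming
comparison of every equal-length window against each reference (≤ 5
mismatches; best window per reference, leftmost on ties), with the hit arm
assigned 5p/3p by window midpoint versus loop midpoint. The exclusion
screen is an ungapped sliding comparison at ≥ 90% identity over the shorter
length — a deliberate simplification standing in for covariance-model and
repeat-library screens, adequate for exact or near-exact contaminant
copies only.

### Strand resolution

Hairpins are quasi-palindromic, so a mature reference usually also matches
the reverse complement of its locus within 5 substitutions. Candidates are
therefore extracted on both strands and resolved by homology: the strand
whose best hit has strictly fewer mismatches wins; genuine ties emit both
records. The simulator guarantees resolvability by planting at least one
stem mutation inside the mirrored mature window.

## Genomic annotation

Intragenic means ≥ 1 bp overlap with any gene feature, strand-agnostic —
partial overlaps count, matching the coarse "within genes" convention of
catalog reports. Multi-locus grouping requires exact sequence identity.
Clustering is single-linkage per chromosome on the inter-locus gap
(next.start − prev.end − 1) with an inclusive 10 kb bound; strand is
ignored for membership and a cluster containing both strands is flagged
antiparallel. Whether a gap of exactly 10,000 bp clusters is a genuine
convention ambiguity; inclusive was chosen and pinned by tests.

## Target prediction

The expectation score is additive over duplex columns: match 0, G:U wobble
0.5, mismatch 1, gap 2, all doubled at miRNA positions 2–13 (1-based from
the 5′ end). The aligner is an exact semi-global DP (full miRNA consumed,
transcript ends free, ≤ 2 gap columns) over states (miRNA consumed,
reversed-window consumed, gaps used); a gap consuming a transcript base is
charged at the upcoming miRNA position. Ties prefer fewer gaps, then the
leftmost transcript window. The HSP length (19) is carried in the config
for interface completeness; scoring covers the full 19–24-nt mature, which
the HSP bound is meant to guarantee. Hits are kept at expectation ≤ 3.0
(inclusive), ranked per miRNA with deterministic lexicographic tie-breaks,
and capped at 200. Translational inhibition is called when positions 10–11
carry a mismatch, gap, or an adjacent target bulge; otherwise cleavage.

Target-site accessibility (UPE) is a pluggable stage: the default scorer
folds the site with 17 nt upstream / 13 nt downstream flanks and reports
the energy cost of blocking the site from pairing (≤ 25 kcal/mol to pass).
It is off unless an accessibility engine is supplied, because published
web-service accessibility algorithms are not specified to implementation
level; all penalty constants are config fields.

## Stem-loop RT-qPCR

The RT primer is a fixed 44-nt universal backbone (a canonical published
stem-loop backbone ships as the default; any 44-mer can be supplied)
extended by the reverse complement of the miRNA's last 6 nt — 50 nt total.
The forward primer is the miRNA minus those 6 nt (DNA alphabet), 5′-padded
with 5–7 GC-biased bases drawn from a generator seeded by (seed, miRNA id);
the smallest pad reaching the target Tm (default 60 °C, nearest-neighbor
with standard salt correction; a Wallace-rule fallback is selectable) is
used, else the maximum pad with a warning. The reverse primer is the
reverse complement of a designated backbone segment (positions 11–26 by
default) and is identical for every assay.

Efficiency is estimated by least squares on Cq versus log10(relative
concentration); E = 10^(−1/slope) − 1, held internally as a proportion.
Relative expression is the efficiency-corrected comparative Cq ratio with
replicate Cq averaged arithmetically first and the normalisation factor
taken as the geometric mean of the reference-gene ratios. The ratio is
exactly reciprocal under swapping baseline and test conditions.

## Group statistics

U is computed by rank summation with midranks. The two-sided p-value uses
exact enumeration of group assignments when the pooled sample is ≤ 16 with
no ties (p = 2·P(U ≤ min(U_a, U_b)), capped at 1), else the normal
approximation with tie correction and a 0.5 continuity correction;
degenerate pooled samples give p = 1. Alpha defaults to 0.1 and is
configurable — surveys in this area quote significance at either 0.1 or
0.05, so the threshold is explicit rather than assumed. No multiplicity
adjustment is applied by default; Benjamini–Hochberg is available.

## Synthetic data: what it emulates, and what it does not

The simulator produces a multi-chromosome genome at ~38% GC carrying
hairpin precursors (70–300 nt; arms ~90% complementary; 21-nt 5p/3p matures
at mirrored offsets) whose coordinates, strands, gene context, cluster
structure and extra verbatim copies are recorded in a machine-readable
truth table. Counts follow a fixed rounding rule: round(frac × n)
precursors are intragenic (covered exactly by generated gene features) or
clustered (groups of 2–3 at gaps well inside 10 kb; the first pair forced
antiparallel). Every planted hairpin is rejection-sampled until it passes
the full filter cascade under the built-in folding engine and is detectable
by the repeat scanner, so 100% recovery is the correct answer, not an
aspiration. Unclustered loci are spaced ≥ 12 kb so no accidental clusters
arise.

The background is a first-order Markov chain at the same GC but strongly
purine-skewed, with complement-following transitions damped: Watson–Crick
partners rarely co-occur, so the background can barely seed hairpins.
Residual inverted repeats are then explicitly scrubbed (locally mutated and
re-scanned until none overlaps any non-planted region), and designated
decoy regions are re-verified hairpin-free. This is the one place the
simulation is deliberately unrealistic: real intergenic DNA is
strand-balanced and riddled with incidental inverted repeats, and a real
genome scan at these thresholds relies on homology plus repeat/ncRNA
screens to prune them. Passing the round trip therefore demonstrates
correctness of the machinery — recovery, strand resolution, filtering,
annotation arithmetic — not the false-discovery behaviour of the method on
real chromatin.

Target transcripts embed sites built by editing the exact reverse
complement of a mature at recorded positions (mismatch or wobble), so each
designed expectation is reproducible from the penalty table independent of
any aligner. qPCR tables are generated from the assay model itself
(dilution Cq from the efficiency, condition shifts from the designed fold),
which is why noiseless round trips recover settings to numerical precision;
recovering values under realistic Cq noise is a statistical question the
tests only touch at zero noise.

## Problem sizes

The validation suite uses one 80-kb chromosome with 6 precursors for unit
round trips and 2 × 250 kb with 20 precursors for the end-to-end check;
oracle suites use 500 folding sequences (≤ 14 nt), 200 duplex pairs
(≤ 30 nt) and 1,000 Mann–Whitney null simulations. These sizes exercise
every code path, including window stitching across chromosome-scale scans,
while keeping a full run of suite plus acceptance script under two minutes
on one core.

## Known limitations

- The built-in energy model ranks structures by weighted pair counts only;
  AMFE/MFEI magnitudes from it are not comparable to nearest-neighbor
  values (use the ViennaRNA backend for those).
- Mature homology is substitution-only; indel-divergent or
  wobble-equivalent matures are missed by design.
- The exclusion screen is not a covariance-model or repeat-library search.
- The duplex aligner allows at most two gap columns, which the penalty
  scheme (2 per gap, doubled in the seed) makes effectively binding anyway.
- Primer design does not screen for genome-wide specificity, dimers or
  hairpins beyond the designed backbone.
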