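# Methods

`beanmap` re-implements, as a tested library, the analysis chain used to
characterise recombination rate (R) and linkage disequilibrium (LD) in the
common-bean genome from a gene-based SNP array: linkage-map construction in
an advanced-selfing RIL population, physical anchoring of markers by
sequence similarity, Marey-map estimation of the recombination landscape
with pericentromeric-plateau (pCENR) detection, genepool-stratified
diversity and LD statistics, and sliding-window gene-density correlations.
Because the original genotype calls are not publicly deposited, a
synthetic-data module generates RIL populations and structured diversity
panels with known truth; every downstream stage is validated against that
truth.

## Linkage mapping

Two-point statistics treat a line as informative for a marker pair only when
both calls are parental (A/B); heterozygous and missing calls are excluded
pairwise.  The observed recombinant-line fraction R̂ = n_R / n overstates the
per-meiosis fraction in a selfing RIL, so the Haldane–Waddington relation
R = 2r/(1+2r) is inverted, r̂ = R̂/(2(1−R̂)) capped at 0.5, before any map
distance is computed.  LOD = n_R·log10(2R̂) + (n−n_R)·log10(2(1−R̂)), with
the R̂ = 0 limit n·log10 2.

Grouping is single-linkage transitive closure over pairs with LOD ≥ 6.0 and
r̂ ≤ 0.4 (both configurable).  Ordering minimises the sum of adjacent
recombination fractions (SARF): greedy nearest-neighbour construction from
the tightest pair, 2-opt refinement, then exhaustive re-optimisation of
sliding 4-marker windows; all tie-breaks resolve toward the lower marker
index and the returned order starts at the smaller terminal index, so the
result is deterministic.  On six-marker instances the heuristic attains the
brute-force SARF optimum (tested).  Map positions are cumulative Kosambi
distances, d = 25·ln((1+2r)/(1−2r)) cM, of adjacent corrected fractions;
r ≥ 0.5 is capped (default 50 cM) with a warning.

Linkage groups are assigned to chromosomes by the strict-majority label of
their anchor markers; ties and duplicate chromosome claims are reported, not
resolved.  The "initial vs refined" map distinction is realised as two runs:
all markers, versus the subset retaining at least one neighbour at
LOD ≥ 6 (`high_lod_markers`).  The map summary defines the mean inter-marker
distance as total length / total marker count, which is the convention that
reproduces the published 1.35 cM (refined) and 1.8 cM (initial) figures.
The marker-count chi-square uses a uniform expectation across groups; a
length-proportional expectation would be equally defensible but is not what
the summary reports.

## Physical anchoring

Markers are placed at the midpoint of their lowest-E-value hit.  With the
best hit at E_1 and next-best at E_2, a marker is a *singleton* when
E_1 ≤ 1e-30 and (no second hit or E_2/E_1 ≥ 1e10), *multiple* when the
separation is smaller, *unplaced* when no hit clears the threshold.  The
separation is multiplicative because E-values live on a log scale; a
subtractive reading is degenerate at small E.

For synthetic genomes a built-in matcher substitutes for an external
aligner: exact 11-mer seeds, per-diagonal ungapped scoring with the default
nucleotide reward/penalty +2/−3, maximum-scoring segment by a linear scan,
and E = K·m·n·exp(−λS) with the ungapped constants λ = 0.625, K = 0.41.
Under these constants a perfect 121-bp hit has E ≈ 1e-58 against a 1-Mb
genome, comfortably below the 1e-30 threshold, and a paralogous copy with a
few substitutions lands well inside the 1e10 separation window, so the
singleton/multiple classification exercises the same decision boundaries as
a production aligner.  The matcher is not a general-purpose aligner (no
gaps, no composition adjustment); real analyses should import 12-column
tabular hits instead.

Marker–gene intersection uses 0-based half-open intervals and counts any
overlap of ≥ 1 bp, the same semantics as the standard interval-intersection
tools; a containment mode is available for windows.

## Marey maps and the recombination landscape

Per labelled chromosome, map positions are joined with physical placements
(singletons only), oriented so cM increases with bp, and points breaking
monotonicity by more than a tolerance against the isotonic regression of cM
on bp are flagged (never dropped).  The curve is a least-squares polynomial
of cM on bp whose fitted values are projected onto the nearest
non-decreasing sequence (isotonic adjustment) over a 512-point grid, so the
local recombination rate — the derivative of the adjusted fit in cM/Mb — is
never negative and integrates to the fitted genetic length.

The default polynomial degree is 7.  A cubic can describe a smooth sigmoid
but cannot express a 20-Mb flat plateau between two steep arms: on the
reference-like landscape its fitted derivative bottoms out near 0.7 cM/Mb,
several-fold above any sensible plateau floor, so plateau detection fails
for every chromosome; degree 5 still under-covers the plateau edges.  Degree
7 tracks the three-segment shape while the isotonic projection suppresses
its residual wiggles.  The degree remains a parameter for atypical data.

pCENR intervals are maximal grid intervals where the local rate falls below
a floor, by default 10% of the genome-wide mean rate (total cM / total Mb).
The largest interval per chromosome is primary.  Note the floor semantics:
a plateau suppressed only 10-fold relative to its arms sits *above* a
10%-of-mean floor by construction, so detecting such mild suppression
requires passing an explicit floor (e.g. half the arm rate).

The landscape summary reports per-chromosome G/P ratios (cM/Mb, rounded
half-up to 2 decimals), bp/cM, the genome-wide ratio computed from summed
totals (deliberately distinct from the mean ± population SD of the
per-chromosome ratios — the two answer different questions), and the Pearson
correlation of genetic vs physical lengths.  `summarize_landscape` accepts
an explicit printed totals row because published map tables are not always
internally consistent with their own columns: in the reference table this
package emulates, the per-chromosome refined distances sum to 1046.9 cM
while the printed total is 1097.5 cM, and the genome-level statistics
(2.13 cM/Mb, 99.8 cM mean group length, 1.35 cM spacing) all derive from the
printed total.

## Diversity statistics and the neutral spectrum

Inbred lines are counted as single alleles; residual heterozygous calls are
excluded.  For minor/major frequencies p, q over n sampled alleles:
MAF = min(p,q); PIC = 1 − (p² + q²) − 2p²q²; π = n/(n−1)·2pq per site
(array genotypes, so π is per SNP site, not per surveyed bp).  The folded
SFS is the MAF histogram over markers (10 equal bins on [0, 0.5] by
default; monomorphic markers occupy the first bin but are excluded from
PIC/π summaries).

The neutral expectation samples each marker's derived count i ∈ {1..n−1}
with probability ∝ 1/i — the standard constant-size coalescent frequency
spectrum — folds and bins it, 5,000 repetitions by default.  Because markers
are exchangeable this is drawn as a multinomial over bin probabilities,
which is exact and fast.  This is equivalent in expectation to simulating
genealogies for unlinked sites, but it is conditioned on polymorphism, not
on θ.  The comparison rescales the envelope to the observed marker total and
flags consistency when every bin lies inside the 95% envelope.

## Linkage disequilibrium

Markers enter LD analysis when MAF > 0.05 (strict, computed from integer
allele counts so the boundary is exact) and call rate ≥ 0.80.  For a pair
with haplotype counts (n11, n12, n21, n22): D = p11 − pA·pB;
D′ = |D|/D_max with D_max = min(pA·qB, qA·pB) for D > 0 and
min(pA·pB, qA·qB) otherwise; r² = D²/(pA·qA·pB·qB); the relation r² ≤ D′²
holds identically and is asserted across all simulated panels.  Two-sided
p-values use Fisher's exact test (point-probability method; delegated to
scipy and cross-checked against exhaustive hypergeometric enumeration in the
tests).

Decay curves are fitted to r² vs distance over same-group pairs with
p < 0.001.  That screen induces a selection floor: with n lines a pair is
significant only when r² exceeds roughly χ²_crit/n (≈ 0.15 at n = 71), so
screened long-distance points hover at the floor regardless of true decay.
An exponential with a free offset would asymptote at the floor and never
reach a 0.1 threshold; the offset-free tendency line a·exp(−b·d) — the form
shown in the source study's decay figures — decays through it.  `ld_decay`
fits both that exponential and a second-degree polynomial, selects the
exponential when an F-test against the constant model is significant at
0.05, and reports the smallest distance at which the selected curve reaches
the threshold (default r² = 0.1).  The exponential crossing is analytic and
flagged `extrapolated` when it lies beyond the observed distance range;
polynomial crossings are only searched within the observed range.  Binned
mean r² values are exported alongside for plotting, since published decay
distances may come from either curves or bins.

## Sliding windows

Windows start at 0 and advance by `step` (defaults 1 Mb / 200 kb); a
chromosome shorter than one window yields a single truncated, flagged
window.  Gene count uses any-overlap semantics (containment by flag); window
recombination rate is the fitted cM difference across the window divided by
its size (cM/bp); mean r² (in %) uses only pairs with both markers inside
the window.  Overlapping windows are statistically dependent; correlation
results carry that caveat in their metadata rather than a correction,
reproducing the upstream procedure.

## Synthetic data: what it emulates and what it does not

**Genome.** `default_genome()` reproduces the published dimensions of the 11
common-bean chromosomes (31.9–59.7 Mb; refined linkage-group lengths summing
to 1046.9 cM) with a piecewise-constant crossover intensity: a
pericentromeric plateau at 5% of the arm intensity spanning the central 40%
of each chromosome, a terminal plateau for the telocentric ninth chromosome,
and an offset 5–15 Mb plateau for the short sixth chromosome.  Markers are
allocated across chromosomes in the published SNP-count proportions
(default) or proportional to genetic length (`allocation="map_length"`), and
placed evenly on the genetic scale with ±15% jitter — gene-based markers sit
in recombining euchromatin and are evenly distributed on the map, which also
makes the marker order statistically recoverable at realistic population
sizes (tighter jitter than ±15% of the spacing does not change results;
much looser jitter creates sub-0.7-cM gaps that no two-point method can
order at 200 lines).  Plateaus therefore hold few markers, as in the real
array.

**RIL population.** Two inbred parents, F1, then selfing to F11 (default),
80 lines by default (the population size used for mapping is not published;
80 is typical for this material and the parameter is free).  Crossovers
follow a Poisson process on the genetic scale without interference; at
marker resolution this is simulated exactly as independent Bernoulli phase
flips across adjacent marker intervals with the Haldane probability of the
interval.  Kosambi is applied only at the estimation stage, mirroring the
analysis convention.  Natural residual heterozygosity (≈2^−(k−1)) is kept
as H calls and topped up to the configured rate (default 0.5%); missing
calls default to 1%.

**Diversity panel.** 71 + 115 genotypes in two genepools by default.
Allele frequencies follow a hierarchical Balding–Nichols drift model:
ancestral ~ U(0.1, 0.9), pool frequencies at divergence F = 0.3, race
frequencies within pools at drift 0.02 (2 races, "reduced" substructure)
and 0.4 (4 races, "extensive" substructure).  Within a race, each inbred
genotype thresholds a latent stationary AR(1) Gaussian whose correlation
decays as exp(−d/L) with L = 10 Mb (~20 cM on the ~2 cM/Mb landscape), so
nearby markers show strong LD that decays exponentially while unlinked
background LD comes only from the configured structure.  An earlier
template-mosaic design was abandoned: with T founder templates per race,
short-range r² is capped at ~1/T while template-sampling noise creates an
artificial unlinked within-pool r² floor of the same order, so strong local
LD and a low genome-wide background cannot coexist in that model.

**Not modelled:** domestication bottlenecks, selection, gene conversion,
crossover interference, genotyping-error structure beyond uniform missing/H
rates, and sequence-level realism beyond uniform random bases with embedded
marker contexts and optionally diverged paralog copies.  Passing tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to real-data artefacts such as segregation
distortion or batch effects.

## Validation studies and problem sizes

`beanmap.evaluation` packages the self-validation studies, and
`scripts/acceptance.py` recomputes them from scratch:

- *Reference-table arithmetic* uses the printed per-chromosome columns and
  totals row; exact to the printed precision.
- *Parameter recovery* simulates 700 markers on the 11-chromosome genome
  (map-length allocation) with 200 F11 lines, then scores linkage-group
  count, preserved true adjacencies, and pCENR Jaccard overlap.  Plateaus
  less than half covered by the marker span (the telocentric chromosome)
  are reported but not scored, since no detector can recover an interval
  outside the data — the study this emulates likewise found no plateau for
  that chromosome.
- *Oracle equivalence* checks Fisher p-values against exhaustive
  enumeration (margins ≤ 12), the ordering heuristic against brute force
  (6 markers), and interval intersection against an O(n·m) scan.
- *Directional reproduction* simulates five panel seeds with stronger
  substructure in pool 2 and compares fitted decay distances, and
  correlates windowed gene density with the fitted recombination rate on a
  genome whose gene density follows the crossover landscape.
- The *neutral SFS* check (n = 10, 10,000 markers, 5,000 reps) compares
  simulated folded bin means to the harmonic-spectrum closed form in units
  of the Monte-Carlo standard error.

The full suite runs in a few minutes on one CPU; the end-to-end pipeline
demo uses a scaled genome (3 × 6 Mb, 40 markers/chromosome, 150 lines) so
that the sequence-search stage stays fast while every stage is exercised.

## Known limitations

- The ordering heuristic optimises SARF; when noise makes a locally wrong
  order attain a lower SARF than the truth (sub-0.7-cM marker gaps at
  ≤200 lines), no search can recover the true order and multipoint
  likelihood methods would be needed (out of scope).
- Single-polynomial Marey fits smooth plateau edges; detected pCENR
  boundaries are biased inward by roughly the local inter-marker gap.
- The decay-to-threshold distance depends on the fitted family; with the
  p < 0.001 screen it is a property of the tendency line, not of any
  individual marker pair, and may be an extrapolation (flagged).
- Fisher p-values are not corrected for multiple testing anywhere,
  matching the upstream procedure of a raw p < 0.001 screen.
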