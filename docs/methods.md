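# Methods

`physmap` re-creates, at desk scale, the computational core of BAC-based
physical mapping of a flow-sorted cereal chromosome arm: in silico HICF
(high-information-content fingerprinting) of clone inserts, a
Sulston-score clone-overlap network, linear-topology contig assembly with
staged exclusion of questionable clones and overlaps, minimal-tiling-path
(MTP) selection, and three-way anchoring of contigs to the chromosome.
Every stage runs on synthetic chromosomes with known ground truth, so the
whole pipeline is testable without any external data.

## The fingerprint model

A clone insert is digested in silico with four labeled 6-cutters (BamHI
GGATCC, EcoRI GAATTC, XbaI TCTAGA, XhoI CTCGAG) and the unlabeled
4-cutter HaeIII (GGCC).  All site positions are merged into one set of
fragment borders.  A fragment becomes a band iff at least one border is a
labeled-enzyme site and its raw length lies in [50, 500] bp.  Band values
are encoded on a single integer scale:

    value = raw_length x 30 + offset(enzyme),
    offsets: BamHI 0, EcoRI 15,000, XbaI 30,000, XhoI 45,000,

so the four channels occupy the disjoint intervals 1,500-15,000,
16,500-30,000, 31,500-45,000 and 46,500-60,000.  Two conventions the
encoding leaves open are fixed as follows and flagged as assumptions:

* a fragment with **both** ends at labeled sites emits **one** band,
  labeled by the earlier enzyme in the order BamHI < EcoRI < XbaI < XhoI
  (avoids double counting; the alternative would emit two);
* HaeIII-HaeIII fragments emit nothing (no fluorescent label);
* duplicate values within one clone are kept as a multiset, mirroring
  repeated capillary peaks;
* sites are located on the given strand only (the recognition sequences
  are palindromes, so cut positions are strand-symmetric for this
  purpose).

Fingerprints with fewer than 18 or more than 207 bands are discarded as
low quality, the same window used for real SNaPshot data.

## Overlap scoring and the gel-space calibration

Two sorted band lists are matched greedily left to right; a pair matches
iff `|a - b| <= t` and each band is used at most once (on sorted lists
with a symmetric tolerance this greedy matching is maximal; the test
suite verifies greedy == optimal by exhaustive matching).  The chance
that two clones with `nL <= nH` bands share at least `s` bands is the
Sulston score

    p = (2t + 1) / G,   q = 1 - (1 - p)^nH,   score = P(X >= s),
    X ~ Binomial(nL, q),

computed via `binom.logsf` with a log-sum-exp fallback for tails below
the double-precision floor (near-identical 150-band clones score around
1e-380 and must remain ordered).  The `2t + 1` form keeps `t = 0` (exact
integer matching, the natural choice for in silico bands) well defined.
Monte-Carlo validation (100,000 replicates of uniform band placement)
shows 3-standard-error agreement at `s = 1` and a systematically
*conservative* tail for `s >= 2`: the binomial form never understates
the chance probability, i.e. never inflates significance.

**Gel space G.**  The score model assumes band values fall uniformly on
`G` distinguishable slots.  In silico values are quantised — 451 integer
raw lengths per channel, ~1,800 achievable values in total, with a
non-uniform length distribution — so two unrelated ~140-band clones
share ~13 values by chance, and `G = 60,000` (the nominal scale span)
wildly understates chance matching.  `effective_gel_space` therefore
calibrates `G = (2t + 1) / p_hat` where `p_hat` is the empirical
probability that two randomly drawn bands match, estimated from the
pooled band-value frequencies (`p_hat = sum_v f_v^2` at `t = 0`).  This
is the in silico analogue of the "gellen" calibration of fingerprinting
software.  At GC 0.46 the calibrated `G` is ~830-1,000; because pooled
frequencies also count truly duplicated bands of overlapping clones, the
estimate errs conservative (real chance sharing is lower), which costs a
little sensitivity and buys specificity — on a clean 2 Mb / 10x library
the calibrated network contains zero spurious edges.  The default
`MatchParams.gel_space` stays 60,000 for the bare scoring operation; the
pipeline calibrates from the retained fingerprints unless
`calibrate_gel_space` is disabled.  Calibration should use a library-scale
band sample; estimating it from a handful of heavily overlapping clones
double-counts their true shared bands.

Network construction uses an inverted band-value index at `t = 0` (any
pair with a greedy match shares an exact value, so the prefilter cannot
drop a qualifying pair) and falls back to all pairs for `t > 0`.  All
cutoff comparisons are inclusive (`score <= cutoff`).

## Linear-topology assembly

A component of the overlap network is accepted as a contig only if it has
*linear topology*: some clone ordering exists in which

1. consecutive clones are connected by a significant overlap, and
2. for every overlap edge, each clone ordered between its endpoints
   overlaps at least one endpoint (true interval graphs always satisfy
   this in left-endpoint order; an edge "jumping over" strangers
   indicates a false join).

Violations are blamed on the clones gluing unrelated neighbours (common
neighbours of a disconnected consecutive pair; endpoints of a jumping
edge), which is what makes chimeric and repeat-rich clones identifiable.
An exhaustive all-permutations oracle checks the heuristic on graphs with
n <= 9 in the test suite.

Clone order is found by spectral seriation — the Fiedler vector of the
Laplacian weighted by `-log10(score)` — with a greedy end-extension
order as an alternative candidate and an adjacent-swap hill climb as
refinement.  Spectral seriation was chosen over pure greedy extension
because on dense 10x overlap graphs the greedy path zig-zags locally
(measured |Spearman| vs truth ~0.02) while the Fiedler order recovers
the true clone order essentially exactly (|Spearman| > 0.999).

Cleaning proceeds in logged stages, mirroring the published LTC
protocol's cutoffs: (1) Q-overlaps — edges above 1e-15 — are dropped;
(2) for components that are still non-linear, conflicts are re-detected
on the sub-network of overlaps at 1e-25 and the most-blamed clones are
removed (Q-clones); (3) the same at 1e-30 (splitting large
over-connected groups); (4) clones with more than 500 overlaps below
1e-50 are removed as promiscuous.  Components that remain non-linear are
split at articulation clones.  Every removal carries its stage in the
report, and the audit identity `clones in contigs + singletons +
excluded = network input` is asserted in the tests.

Contigs with >= 6 clones are *reliable*; 2-5 clones *questionable*.
Contig ids are assigned in decreasing size order; orientation is
reported up to reversal.

**Consensus bands and length.**  Matched bands are merged across clones
by union-find; each merged chain is one consensus band, and estimated
length = consensus bands x 1.2 kb (the published consensus-band length
convention).  Merging spans *all* significantly overlapping pairs within
the contig, not just order-adjacent pairs: insert lengths vary between
100 and 200 kb, so clone i and i+2 routinely share bands that a short
clone i+1 misses, and adjacent-only merging double-counts them (~30%
length inflation; with full merging the consensus count of a 2 Mb test
region is 2,243 vs 2,345 bands in the region's own digest).  Note the
1.2 kb/band convention itself overestimates synthetic physical length by
~40% (the generator's band density is ~1.17 bands/kb at GC 0.46), which
is why simulated coverage percentages land around 130% and simulated
mean depth around 7.5x for a 10x library — the same direction of bias as
the >100% coverage reported for real LTC assemblies.  Depth = clones x
122 kb / estimated length; rescaled by the true physical span the tests
recover the nominal library coverage within 25%.

**MTP selection.**  Greedy left-to-right over the contig order: from the
current MTP clone, take the farthest clone whose overlap satisfies the
mode's constraints; first and last clones are always included.  LTC mode
requires score <= 1e-15 and >= 30% of the smaller clone's bands shared
(the published 1e-15..1e-33 / 30-50% window, taken at its permissive
end); FPC mode requires score <= 1e-30, >= 12 shared bands and >= 30 new
bands of advance.  When nothing qualifies the immediate neighbour is
taken and a warning emitted.

**Scaffolds and validation.**  Contigs are merged end-to-end when a
single linking clone or single terminal-terminal overlap below 1e-15
joins them, or when the same marker hits terminal clones of exactly two
contigs (rule a).  Three-way candidates and ends with competing partners
block merging and are logged.  Marker validation flags: rule b — marker
in a multi-clone group of one contig plus one isolated clone elsewhere
flags the isolated clone as presumably chimeric; rule c — marker in >= 2
multi-clone groups is non-unique; rule d — two mapped markers of one
scaffold separated by more than 10 cM (threshold configurable; the
source protocol says only "considerable distance") flag the scaffold,
and on request the split is applied at the junction with the weakest
evidence (single-clone < single-overlap < marker).

## Anchoring

Stage 1 screens plate/row/column pools of the 384-well library with
markers of known position: a clone is positive iff its insert contains
the marker locus; positives are intersected plate by plate, and a plate
with >= 2 positive rows and >= 2 positive columns yields an ambiguous
candidate set rather than hits (at desk scale, where one plate holds the
whole library, deep-coverage markers are inherently ambiguous — the
114-plate real library deconvolves far more often).  Stage 2 consumes
markers with deletion-bin or external map positions; bin assignment
returns every bin whose fraction interval contains the position, and the
default bin table intentionally keeps the two overlapping printed bins
(5BS8 0.56-0.71 and 5BS1 0.67-0.71) — positions in the overlap zone get
both.  Stage 3 fingerprints 100-kb windows (50-kb step, final window
right-flush) of a reference pseudomolecule and anchors each MTP clone to
its best window at score <= 1e-15, ties to the leftmost window.  A
contig's position is the median window midpoint of its anchored clones
(median is robust to a single mis-anchored clone); >= 2 anchored clones
give an orientation (sign of the order-position correlation), >= 3
mutually consistent clones (span < 2x estimated length) mark a *key*
contig.  Coverage is accumulated per stage with each contig counted at
the earliest stage that anchors it; percentages are rounded half-up.

## The synthetic-data generator

The generator emulates the study conditions of an arm-specific BAC
library: chromosome of GC 0.46; exact tandem-repeat blocks written over
the backbone (subtelomeric heterochromatin analogue); marker loci placed
uniformly outside repeats with an exact per-type count of
`round(density x Mb)`; a HindIII partial-digest library with inserts
size-selected to 100-200 kb around a 122 kb mean (target length drawn
from a truncated normal, endpoints snapped to real AAGCTT positions);
10% of clones drawn from an independent random decoy sequence of equal
GC (flow-sorting contamination is non-homologous); 26% of clones given
corrupted fingerprints — bands randomly deleted or duplicated until the
count leaves [18, 207] — matching the useful-fingerprint fraction
(73.7%) of the real data; and a diverged reference produced by
independent per-base substitution (default 0.01/bp).  Clone starts are
sampled uniformly per bp of mappable DNA: each allowed start site is
weighted by the stretch of positions nearest to it, capped at one tenth
of the minimum insert so that site deserts (HindIII-free repeat blocks,
sequence ends) do not pile clones onto their boundary sites.  Regions no
size-selected insert can reach are reported as unmappable.  All
randomness flows from one integer seed; a fixed seed reproduces every
output byte for byte.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: electrophoresis sizing noise,
partial-digest band dropout, vector background, chimeric (co-ligated)
inserts, realistic transposable-element landscapes, and biased genome
composition.  Two consequences are worth naming.  First, exact-integer
band matching is far more robust to reference divergence than in vitro
fingerprinting: the anchored fraction of MTP clones stays at 1.0 over
divergence rates 0-0.02 and only starts to fall near 0.05, so the tests
assert a non-increasing anchored fraction plus a strictly decreasing
shared-band signal rather than a strictly decreasing fraction (the real
protocol anchored ~50% at ~0.01 substitutions/bp because sizing noise
compounds divergence).  Second, the chance-match structure of synthetic
bands required the gel-space calibration described above.

## Numerical and procedural choices

* Coordinates are 0-based, half-open everywhere; positions of a
  recognition site are its start offset.
* Cutoff comparisons inclusive; percentage rounding half-up to integers;
  fold ratios to one decimal.
* N50/L50 are computed over reliable contigs only by default (matching
  the "contigs > 5 clones" convention of the published tables) on
  estimated lengths.
* Fiedler-vector ties broken by stable sort on node id; all orderings,
  ids and reports are deterministic for a fixed seed.
* Degenerate inputs: empty band lists fingerprint to empty; references
  shorter than one window are rejected; zero-length contigs cannot be
  given a depth; a marker hitting no clone yields an empty (valid) hit
  set.

## Problem sizes used in the tests

The acceptance checks run a 5 Mb / 10x clean library (~410 clones) for
parameter recovery and self-anchoring, a 3-4 Mb grid for the divergence
response, and a 10 Mb / 10x library with 10% contamination, 26% quality
dropout and a 600 kb subtelomeric repeat block for the end-to-end smoke
run; the whole suite completes in a few minutes on one CPU.  These sizes
were chosen as the smallest at which the statistical structure of the
full-size problem (dense overlap graphs, multi-contig assemblies,
repeat-induced fragmentation) is clearly expressed.
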