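# Methods

This note documents the models, conventions and design choices behind
`trescan`, and what the synthetic validation does and does not establish
about real data.

## Coordinates and formats

All coordinates are 0-based half-open. BED input is taken verbatim;
refFlat `txStart` is already 0-based; readers for 1-based peak-table
dialects convert at the boundary (`one_based=True`). Contig names match
exactly and case-sensitively — there is no "chr" aliasing. The TSS of a
gene model is `txStart` on the + strand and `txEnd` on the − strand.

## Motif grammar and scanning

Motifs are written in a half-site grammar: a bare IUPAC pattern
(`AGGTCA`, `AGGnCA`), a dyad `LEFT-k-RIGHT` with a fixed spacer of `k`
unconstrained bases, or a spacer range `LEFT-a..b-RIGHT`. Scanning rules,
chosen once and applied everywhere:

- Both strands are scanned; a minus-strand occurrence is a match of the
  reverse-complemented pattern on the given sequence, reported at its
  plus-strand footprint.
- A pattern whose IUPAC string equals its own reverse complement
  describes one biological site per footprint, so such footprints are
  reported once (strand +). This is the only de-duplication; a
  non-palindromic pattern that happens to match both strands at one
  position is reported twice, once per orientation.
- All overlapping matches count. Occurrence statistics are raw counts;
  greedy masking would understate rates.
- `N`/`n` in a pattern matches any genome base including `N`; every other
  IUPAC code matches only its defined base set and never `N` — an unknown
  base should not satisfy a specific-base requirement.
- Spacer bases are unconstrained (including `N`): the grammar defines a
  spacer only by its length. For a spacer range, every width is scanned
  and each match records the spacer it used; no cross-width
  de-duplication is applied.
- Scanning is per extracted region (or per contig for genome-wide
  backgrounds), so matches never straddle region or contig boundaries.

The scanner is validated against a per-position brute-force oracle on
10,000 randomized (sequence, pattern/dyad) cases.

## Occurrence and enrichment

For a region set, `rate_per_bp = total hits / total bp` and
`fraction_with_hit` counts regions with at least one hit (hits attributed
to the region they start in). Fold enrichment is the ratio of per-bp
rates, not of region fractions, because region fractions depend on region
length; the report emits the pieces of both readings. Region bp for
explicit backgrounds is counted with overlaps merged; per-condition peak
lists are expected non-overlapping (peak-caller convention) and counted
as-is.

Two background conventions are supported. Report-style folds use the
whole genome including the peaks: at mammalian scale peaks are a
negligible genome fraction, and this matches the "overall representation"
convention of published occurrence tables. `exclude_foreground=True`
removes the peaks from the denominator; this is the correct contrast when
the foreground occupies a non-trivial share of the scanned sequence, as
it does in the desk-scale synthetic studies (~12% of the genome), and is
what the planted-enrichment validation measures — the generator defines
its background planting rate over non-peak sequence, so peaks-versus-rest
is the planted quantity. The two denominators coincide as the peak
fraction tends to zero.

Co-localization z-scores compare the observed in-peak hit count with a
null built by dropping equally many length-matched intervals uniformly on
the genome; placements whose longest N-run exceeds half the placed length
are resampled, since assembly-gap-like N runs would deflate the null.

## Consensus and PWM

The consensus procedure anchors each top-ranked peak sequence (ranked by
score, ties broken by coordinate for determinism) on its best half-site
seed match: the match closest to the peak midpoint, because ChIP signal
is midpoint-centred; ties prefer the plus strand, then the leftmost
match. Minus-strand matches are reverse-complemented into seed
orientation, making the matrix invariant to flipping the input sequences.
A window of `flank5 + |seed| + flank3` bases around the re-oriented match
is stacked into the position frequency matrix; windows that would exceed
the region, or contain `N`, are skipped. This seeded alignment is a
deterministic replacement for EM-style de-novo discovery: it cannot find
motifs unrelated to the seed, which is out of scope here.

IUPAC reduction per column: the plurality base if its frequency is at
least `major_threshold` (default 0.6), otherwise the smallest degenerate
code whose base set covers at least `coverage_threshold` (default 0.8) of
the column. The PWM uses log2 odds with a scalar pseudocount λ (default
1.0) split across bases by the background composition — 0.25 per base
under a uniform background — so log odds stay finite. The default
background is the scanned genome's observed composition; PWM scanning
reports windows scoring at least `score_fraction` (default 0.8) of the
matrix maximum on either strand.

## Feature annotation

Every base of the genome receives exactly one class under the precedence
promoter > 5′UTR > 3′UTR > exon > intron > downstream > intergenic,
painted per contig in increasing precedence so the highest claim wins.
Peaks are classified at their midpoint, which makes peak-class fractions
a partition (they sum to 100%) and directly comparable to genome bp
fractions; per-peak classes and per-base labels share the single painted
array, which the tests cross-check against an independent per-base
oracle. Promoter means the 5 kb window upstream of the TSS; downstream
means the 5 kb window past the transcript end (both strand-aware and
configurable — the 5 kb downstream default mirrors the promoter window,
as no separate convention is established). UTRs are the exonic sequence
outside the CDS on the appropriate side for the strand.

TSS profiles bin peak midpoints by signed distance to the nearest TSS
(upstream negative, orientation-corrected), default ±10 kb in 200 bp
bins; peaks beyond the window are excluded.

Condition overlap calls a peak shared if it overlaps a peak of the other
condition by at least `min_overlap_frac` of both lengths (default: any
≥ 1 bp overlap — "completely unchanged" is operationalized as positional
overlap, an interpretation that the flag can tighten). The unchanged
fraction is (shared in A + shared in B) / (|A| + |B|).

## Expression and association

Normalization is `log2(intensity + 50)` followed by quantile
normalization: each sample's sorted values are replaced by the
cross-sample rank means, ties sharing the mean of their rank means. The
offset of 50 stabilizes the log at low bead intensities.

Regulated genes are called with a moderated two-sample t: per-gene pooled
variances are shrunk toward an empirical-Bayes prior (prior df and scale
fitted across genes by the method of moments on log variances), and the t
statistic is referred to the augmented degrees of freedom. At bead-array
replicate counts (3 vs 3) a plain per-gene Welch t has so few degrees of
freedom that planted 1.5-log2 effects with sd 0.25 cannot clear a BH
threshold reliably (~18–35% recovery in simulation); variance moderation
is the standard remedy in that regime and recovers ≥ 94% in the same
simulations while keeping the null false-call rate at the BH level. A
plain Welch t remains available via `method="welch"`. P-values are
BH-adjusted across all genes; `induced` requires linear fold ≥ 1.7 (on
`2^(mean_b − mean_a)`) and adjusted p < 0.05, `repressed` symmetric.

For binding association, the "unaffected" class is a clean null —
adjusted p ≥ 0.5 and |fold| < 1.1 — rather than everything
non-significant. A gene counts at distance d if the gap between its TSS
and the nearest peak edge is ≤ d (a peak spanning the TSS has gap 0);
fractions are per gene, not per peak, and are monotone in d by
construction. The strong-regulation table uses a 2.5-fold floor (a
2.55-fold variant of this cutoff appears in some presentations of such
analyses; the floor is a parameter).

Quantile normalization interacts with planted effects in a way worth
noting: a group difference survives QN only through rank differences, so
a shifted gene already at the extreme ranks is flattened and measured
folds shrink toward zero for such genes. The noise-free fold-recovery
test therefore uses a design whose columns are permutations of each other
(a QN fixed point), where recovery is exact; the stochastic simulations
cover the realistic regime.

## Synthetic studies

The generator emulates the statistical structure of a two-condition
nuclear-receptor ChIP + expression study: an i.i.d. genome at
mammalian-like composition (41% GC), non-overlapping gene models with
exon/UTR anatomy, motif instances planted at a background rate outside
peaks and a higher rate inside them, two peak sets with a controlled
shared fraction, and a two-group expression matrix with planted log2
effects. Defaults (the study conditions of every test that does not
override them): 2 contigs × 1 Mb; 300 genes of 1–4 kb; 400 peaks of
200–500 bp per condition, 30% shared; a DR-4 element
(`AGGTCA-4-AGGTCA`) planted at 1e-4 per bp outside and 1e-3 per bp
inside peaks (a 10× contrast); 40 induced / 20 repressed / 240 null
genes at ±1.5 log2 with sd 0.25 and 3 replicates per group; half of the
induced genes receive a motif-bearing shared peak within 25 kb of the
TSS (those guaranteed instances are drawn from, not added to, the
in-peak planting budget). One global seed feeds a named sub-stream per
stage, so identical configurations reproduce the bundle byte-for-byte.

Peaks — shared and condition-unique alike — are placed in one mutually
non-overlapping pool, so the planted shared fraction is recovered
exactly rather than inflated by accidental overlaps between the
"unique" peaks of the two conditions.

What the generator does not emulate: read-level ChIP signal (fragments,
duplicates, mappability), chromatin state, GC-biased or repeat-structured
backgrounds, correlated gene expression, and realistic genome/peak scale.
Passing tests therefore show that the algorithms recover planted
structure under the stated statistical model, not that the defaults
reproduce any particular organism's numbers. Two desk-scale artifacts are
worth flagging: at 2 Mb with 300 genes the 5 kb promoter/downstream
windows tile most of the genome (the intergenic fraction is near zero,
unlike a mammalian genome's ~50%), and with ~680 peaks on 2 Mb almost
every gene has a peak within 25 kb, so the TSS-distance association
contrast is only identifiable on a sparser configuration. The
association-scale study used by the tests and the acceptance script
spaces 24 genes ≥ 52 kb apart (farther than the 25 kb cutoff plus the
maximal peak reach from a proximal gene) and places only the planted
proximal peaks, making "50% of induced genes, 0% of null genes" exact by
construction.

## Problem sizes and numerical choices

The validation suite runs at desk scale: 10,000 randomized scanner
cases; 20 seeded studies for planted-enrichment recovery (plus 10 null
configurations); 1,500 regions per length for the i.i.d. closed-form
check; 200 sampled sites for consensus recovery; 1,000 genes (100
planted) for differential-call power; 5,000 uniformly placed peaks for
the null-annotation check. Monte-Carlo tolerances are 3 binomial
standard errors unless a test states otherwise (4 SE for the closed-form
check, which is itself an independence approximation). Ties are broken
deterministically everywhere (coordinate order for peak ranking,
plus-strand-then-leftmost for seed matches, stable sorts in
normalization), and degenerate cases are flagged rather than raised
where a pipeline should continue: zero background rate gives NaN fold,
an empty region set gives NaN fractions, a zero-variance gene gives
p = 1.

## Known limitations

- The seeded-alignment consensus cannot discover motifs unrelated to its
  seed and uses one window per peak; weak secondary sites are invisible.
- The moderated t assumes roughly exchangeable per-gene variances on the
  normalized scale; strong mean-variance trends would call for a
  trend-aware prior.
- Classifying peaks by midpoint ignores peaks spanning class boundaries;
  any-overlap classification would not partition and is deliberately not
  offered.
- The permutation null for co-localization matches placement lengths but
  not sequence composition; GC-matched backgrounds are out of scope.
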