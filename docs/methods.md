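# Methods

## The RE1 composite-motif model

REST/NRSF binds a 21-bp element composed of two conserved half sites — a
9-nt left segment and a 10-nt right segment — separated by a 2-bp
non-conserved gap. `re1scan` treats an RE1 occurrence as either one
whole-motif match or a *composite* of two half-segment matches, and
classifies composites by three geometric degrees of freedom:

* **gap length** between the segments (0–49 bp; exactly 2 bp in the
  canonical form, any other value is `altered_gap`);
* **relative orientation**: both segments on the same strand (reading order
  preserved = canonical/altered-gap; reversed = `flipped`), or on opposite
  strands (`convergent` when the upstream member is on '+', i.e. the
  segments point toward each other, `divergent` when it is on '−');
* **completeness**: a lone half site is `left_only` / `right_only`.

The convergent/divergent toward/away semantics follow the common usage in
the REST literature; the geometry table is a single function
(`composite.classify_pair`) and can be swapped out.

## Scoring

Position frequency matrices are converted to log₂-odds with FIMO-style
regularisation: a total pseudocount of 0.1 apportioned by the background and
weighted by `nsites` (default 20 when the MEME file omits it); the
background defaults to uniform 0.25 when absent. Window score = sum of
per-position log-odds (bits); the consensus attains the maximum. Minus-strand
scores come from scanning the forward sequence with the reverse-complemented
matrix, so all reported coordinates are forward-strand. Windows containing
non-ACGT characters are skipped; case is ignored.

Filters, all configurable through `composite.Thresholds`:

| parameter | default | unit | role |
|---|---|---|---|
| `score_fraction` | 0.84 | fraction of max score | primary hit filter (boundary kept) |
| `min_pair_gap` / `max_pair_gap` | 0 / 49 | bp | admissible inter-segment gap |
| `canonical_gap` | 2 | bp | gap of the canonical form |
| `l_only_min_score` / `r_only_min_score` | 15 / 16 | bits | floors for lone half sites |
| `min_recurrence` | 2 | experiments | excludes singleton peaks |
| `upstream_window` | 1000 | bp | promoter-proximal annotation window |

The half-only floors are absolute score constants; their derivation from
empirical score distributions is outside this package's scope.

An exact null distribution of the window score under the background model is
available (`motif_model.score_distribution`): per-position scores are
discretized to multiples of 0.001 bits and convolved across positions
(dynamic programming), giving the exact pmf on the rounded grid. When a
p-value is requested for a score computed in exact arithmetic, a slack of
half a step per position absorbs the rounding, so `p_value(max_score)` is
always positive and p-values are non-increasing in score. The score-fraction
filter, not the p-value, is the primary criterion; the p-value machinery is
provided for diagnostics.

## Interval semantics

Coordinates are 0-based half-open throughout (BED native). Merging unions
intervals that overlap **or abut** (distance-0 merge); an experiment supports
a merged region iff any of its raw peaks overlaps it by ≥ 1 bp. Exclusion
removes a peak entirely on any ≥ 1 bp overlap with a blacklist/HOT interval;
book-ended peak/exclusion pairs do not count as overlap. Chromosome names
are compared as exact strings.

## Pairing and deduplication

Half-segment pairing is greedy: candidate (left, right) pairs with an
admissible gap are ranked by descending combined score, ties broken by
smaller gap then leftmost coordinate; each hit joins at most one pair. Greedy
ranking is deterministic and locally optimal; it can differ from a global
maximum-weight matching on adversarial overlapping candidates, which the
test suite bounds rather than forbids. Canonical sites can be found both by
the whole-motif scan and as a gap-2 pair; when both fire on the same locus
(≥ 50 % reciprocal overlap) the whole-motif call wins, preventing double
counting. Pairs never span peak boundaries, because the search space is the
per-peak sequence.

A peak's single occupancy label gives canonical sites precedence; otherwise
the highest-scoring non-canonical site sets the subtype (ties resolved by a
fixed subtype order, then leftmost).

## Annotation

The simplified annotator collapses gene context to four labels with
precedence exonic > intronic > upstream > intergenic, where *upstream* is
the strand-aware 1-kb window 5′ of a TSS (for '−'-strand transcripts,
`[tx_end, tx_end + 1000)`), and membership is ≥ 1 bp overlap of the site
interval. Finer categories (UTR, splicing, downstream…) are deliberately
out of scope; annotation outputs are property-tested, not count-matched to
any external annotation database.

## Profile clustering

The occupancy labels are encoded on a fixed ordinal scale (NoPeak 0 →
canonical 8) and both axes are clustered with Euclidean distance and
complete linkage via `scipy.cluster.hierarchy`; leaf orders of the
dendrograms order the exported matrix. Metric, linkage and encoding are all
arguments. Axes with all-identical vectors keep stable input order. The
canonical artifact is the TSV matrix plus order files; the heatmap image is
a convenience rendering.

## Synthetic data: what it emulates, and what it does not

The generator plants, on an i.i.d. background genome (GC 0.41, single
2-Mb chromosome by default), 180 sites: 60 universal (supported by all
9 experiments = 3 cell lines × 3 replicates), 60 cell-line-specific
(one line's replicates), 30 singleton peaks and 30 motif-free peaks; motif
sites draw a category from a fixed mix (canonical 0.25, altered_gap 0.15,
convergent/divergent/flipped 0.10 each, left/right-only 0.15 each — chosen
once to roughly reflect the observed predominance of canonical and
half-site forms among real REST binding sites). Peaks are ±150 bp around
each site with ±15 bp edge jitter; sites sit on an evenly slotted grid so
peaks of different sites can never merge. Planted motif text uses a
per-base fidelity mixture (consensus with probability 0.95, otherwise a
PFM draw), so a small, controlled fraction of planted sites legitimately
fail the score filters. Eight blacklist regions are generated, half
overlapping planted peaks. All draws come from one seeded generator in a
fixed order; identical configs are byte-identical.

Because the bundled 21-bp matrix is a synthetic stand-in built on the
published RE1 consensus (uniform gap columns, 0.85 consensus probability
elsewhere), and the background is i.i.d. sequence without repeats, CpG
structure or peak-caller noise, passing tests demonstrate the correctness
of the interval algebra, scoring, pairing/classification and clustering
machinery — not performance on real genomes, where motif information
content, repeat-driven false positives and irregular peak shapes differ.

## Problem sizes and numerical choices

The standard study (2-Mb genome, 180 sites, 9 experiments) runs the full
pipeline in a few seconds; unit tests use a reduced study (400 kb,
24 sites). Score comparisons use a 1e-9 absolute tolerance; the score-null
step is 0.001 bits. Degenerate inputs fail loudly: motifs whose maximum
score is non-positive are rejected (a fraction-of-maximum filter would be
meaningless), as are malformed BED lines, unknown chromosomes and
out-of-range coordinates.

## Known limitations

* Greedy pairing is not guaranteed to be a maximum-weight matching.
* The scanner is not bit-exact with FIMO's integer score scaling; q-values
  are not computed.
* Composite sites spanning more than two segments, and inter-peak
  composites, are out of scope.
* Cluster orderings depend on tie-breaking for highly degenerate
  categorical matrices; only the partition structure is contract-tested on
  tie-free data.
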