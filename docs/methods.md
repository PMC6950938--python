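# Methods

## Scope and model

`tfiiic` identifies and contextualizes *extra-TFIIIC* sites: genomic
positions bound by the TFIIIC complex (assayed through its subunits TFTC-3
and TFTC-5) that lack RNA polymerase III co-occupancy (assayed through the
catalytic subunit RPC-1). In *C. elegans* and other organisms such sites are
candidate chromatin-boundary elements. The pipeline operates downstream of
peak calling: its inputs are peak intervals with fold-enrichment (FE)
scores, input-normalized FE signal in bedGraph, chromosome sizes, an
arm/center domain partition, and feature annotations (TSSs, repeats,
chromatin blocks, lamina-associated subdomains, nuclear-pore sites).

All coordinates are internally 0-based half-open (BED convention); GFF3 is
converted on I/O. Strand is carried but never used in distance or overlap
computations. Non-nuclear chromosomes (mitochondrial) are dropped when a
chromosome-sizes file is read. Uncovered bedGraph bases have FE 0: in
input-normalized enrichment, absence of signal is background.

## Site identification

A TFTC-3 peak becomes a high-confidence TFIIIC site when

1. its peak-level FE score strictly exceeds `fe_min` (default 5), and
2. the peak, extended by `proximity` bp (default 100) on each side,
   intersects at least one TFTC-5 peak. "Within 100 bp" is edge-gap
   distance ≤ 100, inclusive: a TFTC-5 peak starting exactly 100 bases past
   the TFTC-3 peak end still counts.

Each retained peak is reduced to its *center*: the single base with maximal
TFTC-3 FE inside the peak, ties broken leftmost (deterministic and
order-independent). A site is then classified *Pol III-bound* when the
maximum RPC-1 FE within ±`flank` bp (default 250, both endpoint bases
inclusive, clipped at chromosome ends) strictly exceeds `polIII_threshold`
(default 20), and *extra* otherwise. Classification is invariant to how the
FE track is fragmented into runs, and raising the threshold can only grow
the extra class.

## Permutation framework

Significance of overlap, distance and clustering statistics is assessed by
constrained randomization of the 1-bp site centers, in the style of
bedtools shuffle. Three constraint modes: `genome` (uniform over all
allowed bases of all chromosomes, i.e. length-weighted across chromosomes),
`within_chromosome`, and `within_domain` (each site stays in its own
arm/center domain). An optional exclusion set is subtracted from the
allowed universe before sampling; a site whose observed position lies in an
excluded region is still shuffled and keeps its observed value. Collisions
between shuffled points are permitted.

The empirical P-value is the plug-in estimator #{null as extreme}/reps
(default reps = 2000), with ties counting as extreme. When no permutation is
as extreme the result is reported as a bound, "< 1/reps" (0.0005 at 2000
reps); the (k+1)/(N+1) estimator is deliberately not used so that reported
values match the bound-style convention. Two-sided P doubles the smaller
side, capped at 1.

Replicate *r* draws from the deterministic substream `SeedSequence([seed,
r])`, so results are bit-reproducible for a fixed seed and replicates could
be computed in any order.

Distance statistics use the bedtools-closest convention: distance 0 inside
a feature, and a book-ended feature (point at the half-open `end`) is 1
away. The protein-coding-TSS and H3K9-region distance analyses compare
observed nearest distances against a *single* permutation (the null is one
shuffled replicate, not a mean), with a two-sided Mann–Whitney U test
(normal approximation with tie correction — `scipy.stats.mannwhitneyu`,
`method="asymptotic"`, equivalent to R's `wilcox.test` default). The H3K9me3
distance null excludes the enriched regions themselves from the allowed
placement universe, because sites are strongly depleted inside them.

Neighbor-interval (clustering) analysis computes center-to-center distances
between consecutive sites *within* each arm/center domain (no cross-domain
pairs). Each of 2000 within-domain permutations yields one mean interval;
the distribution of the 2000 means is compared with the observed interval
distribution by the same rank-sum test.

## Region segmentation

H3K9me2/H3K9me3-enriched regions are defined by tiling each chromosome
left-to-right into fixed windows (default 1 kb, anchored at coordinate 0;
the final partial window keeps its true width so edge signal is not
diluted), keeping windows whose mean FE strictly exceeds the threshold
(default 2.5), and merging runs of *adjacent* kept windows (inter-window
distance 0 — not within-some-distance merging). Output regions are
disjoint, sorted unions of whole windows. Raising the threshold is monotone:
higher-threshold regions are base-subsets of lower-threshold regions.

## Synthetic data generator

The generator is first-class, tested code that defines the study conditions
for every desk-scale check. It emulates:

- a scaled nematode-style genome — 5 autosomes × 1.6 Mb with
  left-arm/center/right-arm partitions (arm fraction 0.33) plus a 1.7 Mb
  X as a single domain, ~9.7 Mb total. The scale keeps a full run with
  2000-rep permutation tests around a minute while preserving every
  structural feature the analysis touches;
- 504 extra + 525 Pol III-bound planted sites. Extra sites form clusters:
  cluster seeds land in one designated arm per autosome with probability
  0.96, cluster sizes are geometric(0.15), and within-cluster spacing is
  log-normal with median 1207 bp (σ = 0.8; the log-normal family is a
  modeling choice — only the median and "densely clustered" are given
  conditions). Pol III sites fall on the X with probability 0.38 and
  uniformly on autosomes otherwise. A 400-bp minimum separation keeps
  triangular peaks non-overlapping;
- FE tracks with triangular peaks (maximum exactly at the planted center,
  so argmax centering is exact in the noise-free case) of amplitude 15
  (TFTC-3), 12 (TFTC-5) and 40 (RPC-1, Pol III-bound sites only), over a
  half-normal background (default σ = 0.5 FE, piecewise constant on 20-bp
  tiles; FE cannot be negative, hence the folded noise);
- a raw TFTC-3 peak list of 1658 entries: the 1029 real sites plus 400
  low-FE decoys (amplitude 3, with TFTC-5 partners — removed by the FE
  cutoff) and 229 orphan decoys (amplitude 8, no TFTC-5 nearby — removed
  by the proximity rule);
- window-aligned H3K9me2/H3K9me3-like blocks (FE 10, 2–5 windows wide)
  placed adjacent to, but never over, a fraction (0.7) of the extra-site
  clusters: me2-like blocks on the near side with a short gap, me3-like
  blocks on the far side with a longer gap. Window alignment makes exact
  segmentation recovery a meaningful test;
- annotations with recorded memberships: ncRNA TSSs within ±80 bp of 88% of
  Pol III-bound and 4% of extra site centers (classes ~81% tRNA, 11%
  snoRNA), 2000 coding TSSs, repeats covering 44.6% of extra and 8.2% of
  Pol III-bound centers (95.1% of them a CeRep3-like class) plus background
  repeats, LEM-2-like subdomains built to contain a Bernoulli-chosen 88% of
  extra sites (boundaries halfway between covered and uncovered
  neighbours), and nuclear-pore-like points at 41% of Pol III-bound
  centers.

Everything is a pure function of (seed, parameters): the same seed yields
byte-identical files. What the generator does **not** emulate: read-level
sampling noise, ChIP fragment-size smoothing, mappability gaps, copy-number
artifacts, or sequence content (no motifs). Passing tests therefore
demonstrate correctness of the *computations* under known truth, not
robustness to every artifact of real ChIP-seq.

## Numerical and degenerate-input choices

- Strict inequalities everywhere a cutoff is defined ("greater than"):
  FE > 5, Pol III FE > 20, window mean > 2.5.
- Argmax ties → leftmost base.
- A constraint cell with no allowed bases for a hosted site is an error,
  not a silent drop.
- Sites on chromosomes with no features are dropped from distance analyses
  with a warning; if all are dropped, the analysis errors.
- Empty site sets, empty tracks, empty region sets are valid inputs with
  defined outputs (header-only tables, zero tracks, (0, None, []) stats).
- A segmentation window larger than the chromosome degenerates to a single
  whole-chromosome window.
- Signal matrices zero-pad sites whose 2-kb span crosses a chromosome edge
  and flag them per row; 199 windows = (2000 − 20)/10 + 1.

## Known limitations

- Permutation tests are per-test; no multiple-testing correction is applied
  across feature labels or analyses.
- Shuffling is not GC- or length-matched and does not forbid collisions,
  matching plain uniform placement semantics.
- GFF3 attribute parsing retains only ID/type as the label.
- The supplementary-table reader auto-detects 0- vs 1-based center columns
  but falls back to 1-based for a bare `center` column; ambiguous tables
  should pass an explicit flag.
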