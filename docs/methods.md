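# Methods

## Coordinate and scoring conventions

All intervals are 0-based, half-open `[start, end)` (BED convention).
Overlap requires ≥1 shared base; book-ended intervals do not overlap.
Peak position for every distance, profile, and motif computation is the
midpoint `floor((start + end) / 2)`. Rank orderings by peak score break
ties deterministically by (chrom, start) ascending, so truncation and
top-N selection are invariant to input line order.

## Replicate-consistency rule

Given replicates A and B, both lists are truncated to
`n = min(|A|, |B|)` keeping the highest-scoring peaks. The top
`ceil(0.4·n)` peaks of each truncated list are overlapped against the
*other full truncated list*; the check passes when both containment
fractions reach the threshold (default 0.80). Interpreting "the entire
other list" as the truncated rather than raw list follows the order of
operations in the ENCODE-style procedure (truncation precedes overlap);
the raw-list variant is a one-line change via `cross_containment` on
untruncated inputs. Merging consistent replicates is interval-union
merging (transitively overlapping groups collapse to their span, score =
max over members). Re-calling peaks on pooled reads would be the
laboratory-faithful alternative; read-level data is outside this
package's scope, and union merging preserves the downstream analysis
surface.

## Location annotation

TSS is `tx_start` on +, `tx_end − 1` on −. The nearest gene minimizes
|midpoint − TSS| on the peak's chromosome; exact ties resolve to the
lexicographically smallest gene id. Signed distance is negative when the
peak lies on the gene's upstream side. Distance bins use half-open
absolute boundaries [0, 1 kb), [1 kb, 10 kb), [10 kb, 100 kb),
[100 kb, ∞) — published figures give bin labels only, so the boundary
convention is declared here. Context precedence is promoter (|d| < 1 kb)
> exon > intron > intergenic; a first-exon-proximal peak therefore counts
once, as a promoter peak. Because the promoter class absorbs TSS-adjacent
genic peaks, the summary also reports an independent genic partition
(midpoint within any gene body; intron share within it) so both the
distance-bin and the genic statistics are readable without double
counting. Peaks on a chromosome with no annotated gene are reported as
intergenic with an undefined nearest gene and fall in the open-ended
">100kb" bin.

## Signal profiles and chromatin states

Profile matrices bin mean per-base bedGraph coverage into 50-bp bins over
±2 kb (80 columns); published heatmaps never state a binning, and 50 bp
over ±2 kb resolves nucleosome-scale structure while keeping matrices
small. Windows crossing chromosome boundaries are zero-padded so row
count always equals peak count. The two-state clustering uses per-mark
mean signal over the central ±500 bp, log(1+x)-transformed and z-scored
per mark, k-means with k = 2, 10 restarts, and a fixed seed. The cluster
with the higher mean promoter-mark (H3K4me3) feature is labeled I
(promoter-like); ties label cluster 0 as I. Identical feature rows
degenerate to one effective cluster but every peak still receives a
label. No cross-track depth normalization is applied beyond the per-mark
z-score; exported raw-signal matrices are unnormalized. Heatmap rows are
rendered by descending total signal.

## Motif analysis

`consensus_to_pwm` spreads probability uniformly over each IUPAC code's
allowed bases and mixes in a uniform-background pseudocount:
`p = 0.98·p₀ + 0.02·0.25`, giving 0.495/0.005 for two-fold degenerate
columns. Scanning scores every window on both strands with
log₂(p/background) and keeps windows at ≥ `threshold_frac` (default 0.8)
of the maximum achievable score; windows containing N are skipped. The
0.8 default is a conventional stringency for consensus-derived PWMs —
one strong-column mismatch in a short motif drops a window below it —
and occurrence fractions should be read as threshold-dependent. Per-peak
occurrence is binary (≥1 hit in the central 200 bp). Density is the
offset histogram of hit starts relative to peak centers (20-bp bins over
±500 bp), normalized to sum to 1 when any hit exists.

## Co-association

The aggregation statistic behind published co-association heatmaps is
not recoverable in detail; this package defines the matrix entry
directly as the colocalization frequency of factor i at factor j's peaks
— the fraction of j's peaks overlapping any i peak (≥1 bp) — with an
alternative center-within-±window mode. The matrix is directional and
not generally symmetric; the diagonal is 1. Rows are clustered with
distance 1 − Pearson r (centered), average linkage. Constant rows have
undefined correlation and take distance 1 to everything by convention.
Factors are sorted lexicographically before linkage so leaf order is
reproducible regardless of manifest order.

## Expression integration

Fold change is a knockdown/control ratio with symmetric cutoffs
(fc ≥ c or fc ≤ 1/c, default c = 1.25) plus FDR < 10⁻⁴; both cutoffs are
configuration options (an FDR of 0.05 is a common alternative reading of
published figure legends, and is supported). The direction partition is
exhaustive and exclusive. Integer percentages round half away from zero,
which reproduces the published worked-example percentages exactly
(1,230/3,402 → 36; 512/854 → 60; 6,348/18,965 → 33).

## Synthetic data generator

The generator emulates the statistical structure the analyses measure:

- **Genome**: 2 chromosomes × 5 Mb of uniform random sequence; 400 genes
  placed in 8 clusters per chromosome (sd 40 kb around evenly spaced
  centers). Clustering leaves TSS deserts so that sites >100 kb from
  every TSS exist; a uniformly gene-dense 10 Mb genome could not host
  the most distal binding class.
- **Reference sites**: 2,000 sites of ±150 bp, planted with an exact
  TSS-distance-bin allocation of (7, 15, 52, 26)% — the distal-biased
  architecture the analyses are designed to detect, with the <1 kb class
  kept under 10%. Placement is by rejection sampling against the real
  nearest-TSS distance, so planted bin labels are correct by
  construction. Site centers keep ≥1.2 kb spacing (≥600 bp for partner
  sites) so neighbouring signal bumps and peak windows barely interact.
- **Co-occupancy**: partner factors (ERalpha 0.41, GATA3 0.34,
  FOXA1 0.31 sharing with the reference) reuse exact reference
  coordinates for a `round(p·n)` subset and are padded to 2,000 sites
  with unique, spaced positions. Directional overlap of the reference
  against each partner is therefore `round(p·n)/n` exactly.
- **Replicates**: each factor's true list with an exact 10% random site
  dropout per replicate and lognormal score jitter (sd 0.10). Expected
  cross-containment is 1 − dropout.
- **Signal**: Gaussian bumps (sd 150 bp, height 10 with lognormal sd
  0.25) at reference sites over block-Poisson background (rate 0.2 per
  500-bp block), discretized to 20-bp bedGraph segments. Promoter-state
  sites (<1 kb bin) get H3K4me3-dominant bumps; distal sites
  H3K4me1/H3K27ac-dominant ones.
- **Motifs**: the consensus TGASTCAY is instantiated (random choice
  among degenerate bases, random strand) in an exact 30% of reference
  sites at offsets ~N(0, 50 bp) truncated to ±90 bp, keeping planted
  instances inside the central 200-bp scan window used for occurrence
  fractions — consistent with positional densities concentrated well
  within ±200 bp of peak centers. Random background sequence adds
  ~1–2 points of chance occurrences at the default scan threshold.
- **Differential expression**: q-values are generated directly (DE genes
  ~10^−U(4.05,10), nulls ~U(0,1)) rather than simulating counts, since
  the integration module consumes q-values only. An exact 36% of
  reference-bound genes are DE with an exact 62% up bias; unbound genes
  use 8% / 50% as a background. Fold changes are drawn strictly beyond
  (inside) the 1.25 cutoff for DE (null) genes, so filtering recovers
  planted directions exactly.

Exact allocation (choosing `round(p·n)` items uniformly) replaces
per-item Bernoulli draws everywhere a fraction is planted. Recovery
tests therefore compare estimates against the configured parameter up to
rounding, not up to binomial noise, making the tests sharp and
seed-robust.

What the generator does **not** emulate: read-level noise and peak-call
uncertainty (peaks are given, not called), GC and mappability structure,
copy-number amplification, correlated chromatin domains, overlapping or
nested co-occupancy beyond pairwise sharing with the reference factor,
and realistic gene-density heterogeneity. Passing recovery tests shows
the analysis code measures what it claims on data with known structure —
not that real datasets satisfy these idealizations.

## Problem sizes and determinism

The default bundle (10 Mb genome, 4 × 2,000 sites, 3 marks, 400 genes)
generates in a few seconds and carries every analysis in well under a
minute on one CPU; pipeline-level tests use a reduced bundle (2 Mb, 200
sites, 80 genes). All randomness flows from one seeded NumPy generator;
identical configurations produce byte-identical bundles, and k-means
uses a fixed seed with 10 restarts.

## Known limitations

- Union-merging of replicate peak lists is a proxy for re-calling peaks
  on pooled reads; merged-peak counts are not comparable across the two
  procedures.
- Motif occurrence fractions depend on the scan threshold and the
  consensus-derived PWM; they are comparable within a run, not across
  tools with different motif models.
- The co-association statistic is peak-based, not signal-aggregation
  based; factors with systematically wider peaks colocalize more under
  overlap mode (the window mode mitigates this).
- Nearest-TSS target assignment is a heuristic; it does not model
  regulatory domains or 3D contacts.
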