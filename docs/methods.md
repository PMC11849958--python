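# Methods

## NAD calling model

The genome is tiled into fixed-width bins (default 100 kb; terminal bins
are truncated, not dropped, so genome-fraction arithmetic stays exact).
Read placements are assigned to exactly one bin by their midpoint, which
conserves the total read count and avoids fractional-overlap ambiguity at
bin boundaries.

Per bin the enrichment ratio is

    r_i = ((no_i + α) / No_total) / ((n_i + α) / N_total)

with pseudocount α = 0.5 by default (keeps every ratio finite and
positive; negligible at realistic counts). The ratio is invariant under
uniform rescaling of either library. By default the ratios are then
divided by their genome-wide median (`background="median"`). The reason:
when a sizeable fraction of the genome is genuinely enriched, the
nucleolar library total is inflated by the enriched territory itself, so
pure library-size scaling pushes background bins below 1 and compresses
k-fold-enriched bins toward k / (1 + f·(k−1)) for enriched fraction f —
with a quarter of the genome at 4-fold, enriched bins land near 2.3,
right at the decision threshold. Dividing by the median re-centres a
typical background bin at r = 1 so a k-fold bin sits near k. The
correction assumes enriched bins are a minority (< 50%); for genomes
where NADs may cover more than half the territory, pass
`background=None` and interpret ratios on the library-size scale.

A bin is NAD-positive iff r ≥ threshold (default 2.0, inclusive:
"two-fold or greater"). The comparison is on the linear ratio; applying
it after log transform is mathematically identical. Runs of positive bins
separated by at most `max_gap_bins` negative bins (default 0) merge into
segments; with the default, segment-covered bp equals positive-bin bp
exactly. Both views are reported: per-bin calls (dots on a karyotype
track) and merged segments (headline "region" counts). Replicate count
tables can be combined with `compute_enrichment_replicates`, which takes
the geometric mean of per-replicate ratios.

Summary statistics: NAD genome fraction (segment bp / assembly bp × 100),
per-chromosome contribution (share of segments and share of bp, each
summing to 1), and directional sharing between two calls
(`shared_nad_fraction(a, b)` = fraction of a's NAD bp inside b's NADs;
equal to 1 for a against itself and asymmetric in general).

## NAG annotation

A gene is a NAG when its body ([start, end), half-open) overlaps the
union of NAD segments by at least `min_overlap` bp (default 1). Gene
bodies rather than promoters are used because NAD segments are
bin-resolution objects two orders of magnitude larger than a promoter;
the threshold is exposed for stricter definitions. Overlap statistics
(covered bp, covered fraction) are recorded per gene. Biotype
composition reports exact per-class fractions plus a protein-coding vs
non-coding rollup. Multi-set comparisons enumerate every non-empty
membership pattern (Venn regions) exactly; counts sum to the union size
by construction.

## Activity integration

Cross-sample "Merged Regions" are the connected components of the
peak-overlap graph, spanned from the most upstream member start to the
most downstream member end. The implementation is a sorted sweep —
interval-overlap components are contiguous in (chrom, start) order — and
is validated in the tests against a brute-force union-find oracle.
Cross-sample peak sharing is the fraction of one sample's peaks lying in
regions that also contain the other sample's peaks.

The promoter window is TSS −2000/+500 bp in transcription orientation
(minus-strand genes flip), a common convention; every promoter-dependent
count inherits this choice, so it is a first-class configuration key.
Peak annotation uses priority promoter > gene body > intergenic, with
competing genes resolved by nearest TSS to the peak midpoint, then
lexicographically smallest gene id. TSS metaprofiles average binary peak
occupancy per bp over genes in a ±2 kb window pooled into 40 bins,
orientation-flipped for minus-strand genes.

A NAG is "active" (triple-marked) when its promoter window carries an
ATAC peak (via the promoter-annotated ATAC peaks), an H3K4me3 peak, and
a Pol II peak. "Double" is the H3K4me3 + Pol II conjunction at gene
level, which makes the count well-defined where raw peak counting would
not be. Missing assay inputs are excluded from the conjunction and
reported, never silently treated as negative evidence.

## RNA compartment enrichment

Gene-level abundances are normalized to counts per million per sample. A
gene is nucleolar-enriched when

    (mean nucleolar CPM + α) / (mean total CPM + α) ≥ 2   (α = 0.5)

with the inclusive boundary. The fold rule is used deliberately instead
of a negative-binomial differential model: the decision criterion being
reproduced is a plain two-fold enrichment, and replicate means over CPM
carry it. NAGs partition exhaustively into nucleolar (enriched),
nuclear-only (not enriched, nuclear CPM ≥ `min_expr`, default 1 CPM —
there is no canonical detection threshold, and 1 CPM is the usual
rule-of-thumb floor), and silent. Repeat association reports, per repeat
class (SINE, LINE, pooled "other"), the fraction of a gene set
overlapping at least one element of that class.

## Synthetic data generator

The generator emulates the structure of a nucleolar sequencing study at
desk scale. Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| genome | 3 chromosomes × 20 Mb | 600 bins of 100 kb; full pipeline in seconds |
| genes | 1000, uniform 5–20 kb, ≥6 kb apart | spacing keeps promoter windows unambiguous |
| protein-coding fraction | 0.87 | typical coding share of NAG sets |
| NAD fraction | 0.25 | nucleolar studies find roughly a quarter of the genome NAD-associated |
| enrichment factor | 4.0 (background 1.0) | comfortably above the 2-fold threshold |
| depth | 100 reads/bin, NB size 10 | overdispersed counts typical of sequencing libraries |
| segment length | geometric, mean 3 bins | multi-bin domains with exponential tails |
| active NAG fraction | 0.13 | about one NAG in eight carries all three marks |
| peak fnr / fpr | 0.05 / 0.01 | mild peak-calling noise |
| retained fraction | 0.10 of active genes | transcripts are predominantly exported |
| retention / export multiplier | 4.0 / 0.25 | two-fold margins on either side of the threshold |
| expression | log-normal ln-mean 3.0, sd 1.0; replicate noise sd 0.25; 3 replicates | right-skewed abundances, triplicate libraries |

Counts are negative-binomial (size parameter `dispersion`; Poisson is the
large-size limit) with the nucleolar mean multiplied by the enrichment
factor inside planted NADs. NAD bins are allocated per chromosome
proportionally to bias weights — set e.g. a 10× weight on one chromosome
to emulate the strong chromosomal concentration of NADs seen in real
nucleolar maps — and planted as whole-bin segments meeting the target
fraction quota exactly at bin resolution. Planted NAGs are recomputed
from planted NADs and gene models (never stored independently), active
genes are a random NAG subset, retained transcripts a random active
subset; all truth is serialized to `truth.json` beside the generated
inputs so tests never reach into generator internals. Every stage draws
from an independent seeded substream, so outputs are byte-identical
across runs and insensitive to call order.

What the generator does **not** emulate: mappability and GC bias,
assembly gaps, copy-number variation, read-level errors, peak-width and
signal-strength distributions of real peak callers, intergenic noise
peaks, and correlated replicate structure. Passing recovery tests
therefore demonstrates the correctness of the pipeline's logic under a
clean noise model, not robustness to every artefact of real libraries.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere; BED native, GTF converted
  on read; touching intervals do not overlap.
- Thresholds (NAD ratio, RNA fold) are inclusive.
- Percent reporting in assembled reports rounds half-up to whole percent.
- Empty libraries, all-zero expression samples, empty NAG sets, and
  zero-segment results raise informative errors rather than returning
  degenerate statistics; unknown chromosomes in read placements raise
  unless explicitly skipped (then warn).
- Pseudocount 0 is allowed only when no zero-count bins exist.

## Known limitations

- Bin-level NAD detection has an irreducible error floor set by the count
  overdispersion: the variance of the log ratio of two NB counts is at
  least 2/size regardless of depth, so at size 10 roughly 7% of bins sit
  on the wrong side of a 2-fold boundary when the true enrichment is
  4-fold. Under the default generator conditions bin-level F1 against
  planted truth plateaus around 0.87–0.89 (the acceptance script reports
  the exact value per seed); recovered genome fraction is nevertheless
  within a few percentage points of the planted fraction because false
  positives and negatives largely cancel.
- The median background correction assumes a minority of enriched bins.
- Gene-level peak association ignores enhancer-range regulation; only
  promoter-window evidence feeds the activity call.
- The RNA partition treats compartments independently; no mixture or
  transport model is fitted.
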