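# Methods notes

This note records the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions that were genuinely open.

## Single-cell preprocessing

QC metrics are computed per cell from the raw UMI matrix: detected genes,
total UMIs, percent mitochondrial (0 for an empty cell), and detected
nuclear genes. The default gates — 200–7,500 genes, 500–75,000 UMIs,
mito < 10%, ≥ 10 nuclear genes — are the snRNA-seq convention this package
targets; feature and UMI ranges are read as inclusive and the mitochondrial
gate as strict, mirroring the "from … to", "between" and "less than"
phrasings these thresholds are usually quoted with. A Smart-seq3 preset
(100–6,000 genes, mito < 10%, no UMI gate) ships as `SMARTSEQ3_QC`.
Filtering is idempotent and preserves cell order and the gene axis.

LogNormalize uses the natural logarithm (the convention of the method of
that name; plain "log-transformed" is base-ambiguous) with a default scale
factor of 10,000. Zero counts map exactly to zero, so the sparsity pattern
is preserved and `expm1` recovers count proportions exactly.

HVG selection follows the variance-stabilizing recipe: a degree-2 local
polynomial regression (tricube weights, span 0.3 as the fraction of
nearest genes) of log10 variance on log10 mean gives each gene an expected
SD; counts are standardized by it, clipped at sqrt(n_cells), and genes are
ranked by sum(z²)/(n−1) of the clipped values. Span and clip are not
canonical constants anywhere, so both are parameters. Scaling uses the
population (n) SD so that small worked examples are exact; constant genes
become all-zero rows.

`embed_and_cluster` (PCA + seeded k-means) is a deterministic utility for
synthetic workflows where truth labels are withheld. It is deliberately
*not* a graph-based clustering and is documented as such; nothing
downstream depends on it.

## Wilcoxon marker detection

The rank-sum p-value is exact whenever both groups have ≤ 25 observations:
midranks are doubled to integers and the null distribution of the rank sum
over all C(n, n₁) group assignments is counted by a subset-sum dynamic
program (counts stay below 2⁵³, so float64 arithmetic is exact). This
handles ties exactly, which the classical no-tie enumeration does not.
Larger groups use the normal approximation with midrank tie correction and
a 0.5 continuity correction (the R convention). The two-sided p is the
probability mass of rank sums at least as far from the null mean as
observed.

Marker criteria: log₂FC > 0.25 computed on expm1 of log-normalized values
with a symmetric pseudocount of 1e-9 (the fold-change scale is otherwise
undefined for log data), adjusted p < 0.05, and expression in more than 25%
of cells. The 25% rule is applied as max(pct_in, pct_out) > 0.25 — the
either-group reading — because a gene lost in the target but common outside
is as much a marker as the converse; this choice is surfaced in `DEGParams`.
Bonferroni is the default adjustment (the convention of the marker-calling
function being re-implemented); BH is selectable. All three criteria are
strict inequalities. Adjustment runs over the tested (pre-filtered) genes
only.

## Label transfer

Scoring uses log-normalized expression, not z-scores: "average expression"
reads most plainly as the normalized scale, and z-scores would let a single
wildly variable marker dominate. A z-score option exists but is off by
default. Markers absent from the query are dropped per subtype, with the
mean taken over the genes actually used — imputing zeros would bias against
subtypes whose markers simply failed to be measured in the query, which
matters for cross-dataset mapping on an intersected gene universe. Exact
score ties go to the first declared reference subtype; the rule is
deterministic and recorded. Subsampling takes floor(fraction × group size)
per group with a minimum of 1, without replacement, seeded.

One ambiguity is worth documenting: similarity scoring can be read at the
cluster level (average marker expression per query cluster) or the cell
level (score every query cell, then aggregate). The cell level is
implemented, since it subsumes the cluster level through the mapping table
and yields per-cell margins as a confidence diagnostic.

## TSS methylation profiles and patterns

Coordinates: bedGraph intervals are 0-based half-open; TSS positions are
1-based and converted internally; all windows are half-open
[tss₀ − flank, tss₀ + flank). A ±2 kb window at 10-bp bins gives exactly
400 bins. A bin's value is the unweighted mean of CpG records overlapping
it (matching tools that average track values rather than reads;
coverage-weighted averaging is a flag away). Minus-strand genes have their
bin order reversed so bin 0 is always 2 kb upstream in gene orientation;
the profile is invariant under coordinate mirroring plus strand flip.
Genes with no covered CpG in a window are missing, never zero, and genes
missing any condition are excluded from clustering (reported) — real
pattern analyses likewise cluster only the covered subset of genes.
A percent-scale bedGraph dialect (values in 0–100) is auto-detected and
rescaled with a notice.

Pattern calling: per-gene (CD, HFD, HFD-CD) triples are centered (subtract
the gene's own mean) so k-means clusters shapes, not absolute methylation
levels — equivalently, pattern labels are invariant to a global additive
shift. Each centroid (a, b, c) is labeled with d = b − a (the HFD effect)
and r = c − a (the residual after switching back): Pattern 1 (reversible)
needs a real effect (|d| > δ) that disappears (|r| ≤ τ|d|); Pattern 2
(irreversible) a real effect that persists (|c − b| ≤ τ|d|); Pattern 3
(switch-specific) no HFD effect but a real switch effect. Pattern 1 is
checked before Pattern 2 when both hold (a fully reversed gene trivially
satisfies neither-moved-after-switch in degenerate cases). Defaults δ = 0.1
(a 10-percentage-point methylation change, the usual threshold for a
biologically meaningful difference) and τ = 1/3. The published analyses
this formalizes describe the three patterns verbally on top of unsupervised
clustering; the (δ, τ) rule makes that reproducible and tunable.

Choice of k: the API default is k = 6, but every shape-recovery analysis in
this package uses k = 8. Geometry forces k ≥ 7: the three patterns each
planted in two directions plus the flat null group give seven distinct
centered prototypes, and with fewer centroids k-means must merge two
prototypes, contaminating centroid labels. Extra clusters beyond 7 only
split pure groups and are harmless.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail on the
set intersected with the universe, BH-adjusted across tested sets. This is
a standard ORA contract, labeled a stand-in: published GO analyses rarely
state their exact backend, so enrichment output is not treated as a
reproduction of any particular figure. Note that enlarging the universe
with genes outside the sets and the list makes a fixed overlap *more*
surprising (p decreases); the tested invariant points that way.

## Synthetic data: what it emulates, and what it does not

The single-cell generator draws counts from a negative binomial
(variance μ + μ²/θ, default θ = 10) because cluster effects are
multiplicative on the mean. Genes get a lognormal mean factor
(mean 1, CV `gene_mean_cv`, default 0.3) so that a mean-variance trend
exists for HVG selection to exploit — with a single shared mean the trend
degenerates to a point and standardized variance is uninformative. Marker
genes keep factor 1 so the planted fold change acts on a known baseline.
Cells get a lognormal library-size multiplier (CV `libsize_cv`, default
0.1) to exercise normalization. Low-quality cells are injected explicitly:
alternating cells with ~5 detected genes (failing the feature and
nuclear-gene minima) and cells with a mitochondrial boost to ~33% of
counts. Defaults (1,200 genes, 3 × 150 cells, 60 markers per cluster at
fold change 4, baseline mean 1, 3% mitochondrial genes) keep ordinary cells
inside the default QC gates.

Not emulated: doublets, ambient RNA, batch effects, realistic gene lengths
or genome coordinates, read-level data. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under clean cluster
structure, not robustness to those artefacts — batch integration in
particular is out of scope, and all simulations are single-batch.

The methylome generator places genes on one synthetic chromosome, CpGs
every `cpg_spacing` bp (default 20) across TSS ± 2 kb, with a plateau
baseline per gene (uniform, bounded so planted shifts cannot clip) minus a
Gaussian dip at the TSS (σ = flank/8) mimicking the canonical promoter
methylation valley. Patterned genes shift up or down with probability 1/2
by `effect_size` in the conditions their pattern prescribes; observed
levels are binomial(coverage, level)/coverage with Poisson coverage
(default mean 30), or the true level exactly in the infinite-coverage
limit. Default pattern fractions (19.6/11.2/13.6% for Patterns 1–3, 55.6%
null) follow the rough proportions reported by diet-switch methylome
studies. Effect sizes above 0.6 are rejected rather than silently clipped,
since clipping would distort the planted offsets.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small instances — hundreds of
genes, tens to low hundreds of cells per cluster, 300 methylome genes —
chosen so each property is measurable with comfortable statistical margin
while the whole suite stays fast on a single CPU. The null calibration of
the marker pipeline uses 500 replicates of 2 × 30 cells × 120 genes;
recovery runs use the configurations stated in their tests. All randomness
flows through explicit integer seeds (numpy `default_rng`); k-means uses
10 restarts with a fixed `random_state`; pipeline manifests record every
seed and parameter, and store paths relative to the output directory so
identical configurations produce bit-identical manifests.

Known limitations: the exact rank-sum path is O(n₁ · Σranks · n) per gene
and is therefore capped at 25 observations per group; the local polynomial
smoother is O(n²) in the number of genes (fine up to a few 10⁴); bigWig
input is not supported (bedGraph text is the contract); and enrichment
results are a generic ORA, not a reproduction of any specific GO pipeline.
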