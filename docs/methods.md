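# Methods

`repdiv` analyses paired-chain single-cell TCR-seq data of regulatory T
cells (or any αβ T cell population): it decides which droplet barcodes
are cells, assigns paired TRA–TRB clonotypes, summarises clonal structure
as Hill-diversity evenness profiles at sample and cluster level, annotates
CDR3β sequences against a pathology-association catalog, and finds
cluster markers conserved across samples. This note records the models,
parameter choices, numerical decisions, and what the synthetic-data
generator does and does not emulate.

## Barcode quality control

Four filters run in a fixed order, each on the survivors of the previous
one; the `QCReport` records kept/removed counts and the threshold per
stage, and the whole cascade is deterministic given its seed.

**1. Ambient-RNA deviation test.** The ambient profile is estimated from
barcodes with at most `ambient_max` (default 100) total UMIs: gene-wise
count sums plus one pseudocount per gene, normalised. Every barcode above
`ambient_max` is scored by the multinomial log-likelihood of its count
vector under that profile (including the multinomial coefficient), and
its p-value is the Monte-Carlo tail probability that a multinomial draw
of the same total has log-likelihood at or below the observed one,
estimated as (r+1)/(n_iters+1) with `n_iters` (default 1000) draws shared
across barcodes of equal total. Benjamini–Hochberg adjustment across
tested barcodes; retention at q < `fdr` (default 0.01). This is a
deliberately simple goodness-of-fit: unlike the full emptyDrops model it
fits no Dirichlet overdispersion and applies no Good–Turing smoothing, so
it is anti-conservative on data whose "real cells" differ from ambient
only through modest overdispersion, and it treats the ambient profile as
known rather than estimated. Its calibration under the exact multinomial
null is tested (retained fraction ≤ FDR within 3 binomial SE).

**2. Barcode-rank knee.** Library sizes are sorted descending and tied
sizes are collapsed to one point at their average rank — without this,
plateaus of duplicated small sizes make the log-rank spacing vanish and
the derivative explode at the tail. On the (log10 rank, log10 size)
curve of unique sizes, log-size is smoothed with a centred moving average
(`window` = 5 points); the steepest segment of the smoothed derivative
locates the drop region, and the threshold is then refined to the
steepest raw segment within one window of it, taking the size at the
upper edge of that segment so the last pre-drop barcode passes. If no
segment is steeper than `slope_floor` (default 1e-3 in log-log slope) the
curve is declared knee-less and the filter is a no-op with a warning.

**3. Robust covariate outliers.** Library size and genes detected are
filtered two-sided, mitochondrial fraction upper-sided, at `n_mads`
(default 3) median absolute deviations from the median, MAD scaled by
1.4826 for normal consistency. Filtering is on the raw scale by default
(a log1p option exists); medians are recomputed on the current survivor
set. A zero MAD (degenerate spread) keeps everything and warns. The
two-sided mask is equivariant under affine maps x → ax + b, a > 0.

**4. Chain-count doublets.** Unique chains per barcode are counted on the
(V gene, CDR3, J gene) triple; a barcode is excluded iff it has more than
one unique TRB or more than two unique TRA. The rule's connective is OR:
either an excess of β chains or of α chains alone marks a presumed
doublet (an AND reading would pass a droplet with three β chains, which
cannot be one cell). Two TRA chains are tolerated here because single T
cells can express two rearranged α chains; the stricter clonotyping rule
below still refuses to assign such cells.

## Clonotypes and frequency vectors

A clonotype is the 6-tuple (TRAV, CDR3α, TRAJ, TRBV, CDR3β, TRBJ). A
barcode is assigned a clonotype iff it has exactly one unique TRA triple
and exactly one unique TRB triple; everything else is recorded as
unassigned with a reason code (`no_tcr`, `no_alpha`, `no_beta`,
`ambiguous_alpha`, `ambiguous_beta`) rather than dropped, so cell
accounting is auditable. CDR3 sequences are compared as upper-cased
amino-acid strings; allele suffixes (`*01`) on V/J names are stripped
before keying by default, since clonotype identity is defined at the gene
level. Frequency vectors are clone counts normalised to sum to one,
ordered by descending count with lexicographic tie-break; zero
frequencies cannot occur by construction. Cluster-level repertoires
treat each cluster of each sample as an independent sample.

## Hill diversity and evenness profiles

For a frequency vector f with n clones,

    D_α(f) = (Σᵢ fᵢ^α)^(1/(1−α)),  α ≥ 0, α ≠ 1,

with D₀ = n (richness) and the α→1 limit D₁ = exp(H), the exponential of
Shannon entropy. The evenness profile is E_α = D_α / D₁ evaluated on the
grid α = 0, 0.2, …, 10.0 (51 points), so E₁ = 1 exactly and values above
1 occur for α < 1. Note the α = 1 point is the Hill number's analytic
limit exp(H), not Shannon entropy itself: only the exponential keeps the
profile dimensionless and pinned to 1 at α = 1. Normalising by D₁
follows the profile definition used here; the richness-normalised variant
(divide by D₀) used elsewhere in the evenness-profile literature is
available through `normalize_at=0`.

Numerics: log D = logsumexp(α·log f)/(1−α) is computed in log space, so
fᵢ^α never underflows even at α = 10 with thousands of clones; invariant
checks (monotonicity of D_α in α, bounds 1 ≤ D_α ≤ n) hold to 1e-9.
Profile comparison declares dominance when one profile's evenness is ≥
the other's at every α > 1 and strictly greater somewhere; the α ≤ 1
region is excluded because both profiles are pinned at α = 1.

The plug-in profile estimate from a finite sample is √n-consistent but
not unbiased: at 10,000 cells its expected sup-norm error over the grid
is roughly 1–2% for realistic clonal shapes (the α = 10 end is noisiest
for even repertoires, the α = 0 richness end for skewed ones with
near-undetectable clones), falling below 1% only around 4× that depth.
Tests assert the 2% floor at 10,000 cells and <1% at 160,000 cells for
the geometric(0.95) reference repertoire.

## Specificity annotation

Clonotype CDR3β sequences are matched exactly (case-normalised amino-acid
identity) against a curated catalog of pathology-associated sequences in
McPAS-TCR format (cdr3b, category, pathology). No fuzzy matching is
attempted — edit-distance rules would be a methodological claim of their
own. A sequence listed under m categories contributes to all m; the
aggregate matched-clone count still counts it once. The counting unit
defaults to unique clonotypes, with cell-level counting available. The
McPAS-TCR database itself is not bundled (licensing); the generator
produces structurally identical mock catalogs for testing.

## Conserved markers

Per sample, each gene is tested between one cluster and the pooled rest
with a two-sided Wilcoxon rank-sum test: midranks, tie-corrected normal
approximation without continuity correction (vectorised across genes),
switching to exact enumeration when both groups have ≤ 8 cells and no
ties. Reported per gene: p, the rank-biserial AUC U/(n_in·n_out), and a
log fold-change ln(mean_in + 1) − ln(mean_out + 1). Per-gene p-values
from k samples are combined as P = 1 − (1 − min p)^k, the tail
probability of the minimum of k independent uniforms (Wilkinson's method
restricted to the first order statistic). Genes are ranked by ascending
combined p, ties broken by mean |AUC − 0.5| descending; genes absent from
some samples are combined over the k samples that contain them and
flagged via the `n_samples` column. BH q-values are an optional output
column; ranked lists themselves are not multiplicity-corrected.
Expression input is assumed already normalised — the package does no
count normalisation of its own.

## Synthetic data

The generator produces every input with ground truth, so each stage is
testable without downloads. Defaults describe the reference conditions
used throughout the tests and the acceptance script.

* **Repertoires** — clone frequencies uniform, geometric(r^i, default
  r = 0.95; the canonical "expanded" scenario, chosen because its Hill
  numbers have closed forms) or power-law(i^−γ); cells drawn
  multinomially; each clone carries distinct TRA/TRB triples from a
  reserved name pool (`SYNTRAV1`, …) so fixtures cannot be mistaken for
  real data; doublets made by merging the chain set of a second drawn
  clone into a cell at rate `doublet_rate` (detectable by chain counting
  only when the partner clone differs — the truth object records both
  flags); chosen CDR3β strings can be spiked to match a catalog.
* **Count matrices** — default 500 real cells over 4 equal clusters and
  5,000 ambient barcodes on 200 genes. Real cells: negative binomial per
  gene (variance μ + dμ², d = 0.5) around gamma-distributed gene means
  scaled to a 2,000-UMI mean library; planted markers multiply means in
  one cluster; the first 10 genes form an `MT-` block holding 5% of the
  mean library, inflated to 60% in designated dying cells. Ambient
  barcodes: multinomial draws from a shuffled power-law profile with
  totals ≤ 100 by construction.
* **Catalogs** — random CDR3β-like strings (C…F, length 10–18) spread
  over categories.

What the generator does *not* emulate, and hence what passing tests do
not show about real data: transcriptome-side doublet signal (doublets
differ only in chain content), ambient contamination inside real cells,
batch effects, gene–gene correlation, UMI saturation, and realistic V(D)J
recombination statistics. Results on real 10x data will be noisier in
exactly the places these simplifications are clean; in particular the
simplified ambient test should be expected to diverge from full
emptyDrops output near the decision boundary, and reproducing any
particular study's post-QC cell counts requires that study's raw
matrices, which are not desk-scale inputs.

## Reference problem sizes

The test suite and acceptance script run, per seed: 500 real cells +
5,000 ambient barcodes through the full cascade; 10,000-cell multinomial
repertoires over 50 clones (20 replicates); 2,000-gene null matrices at
40 vs 80 cells; 10 replicate marker experiments of two 200-gene,
200-cell samples; and 10⁵ Monte-Carlo replicates for the combination
rule. These sizes put binomial/KS error bars well inside the asserted
tolerances while keeping a full run around a minute.
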