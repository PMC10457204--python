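# Methods

This note documents the statistical models and procedures implemented in
`clonolink`, the assumptions behind the synthetic-data generator, the
parameters that matter, and the numerical choices made where the design was
genuinely open. No empirical claim is made here beyond what the test suite
and `scripts/acceptance.py` compute.

## Cell ingestion and gating

Contigs from a 10x-style annotation table are retained when they are
high-confidence, full-length, productive, and assigned to TRA or TRB. Chains
are identified throughout by (locus, V gene, J gene, CDR3): the D segment is
excluded because D calls are unreliable and α chains have none. Gene names
are compared after stripping allele suffixes (`*01`), since annotation of
alleles varies between pipeline versions.

Per barcode, duplicate contig rows (same locus, V, J and CDR3 nucleotide
sequence) are collapsed keeping the highest-UMI copy — a cell's chain set is a
set. Barcodes with two α **and** two β chains, or more than two chains of
either locus, are treated as cell doublets and discarded; genuine T cells can
carry a second α or a second β (allelic inclusion), but not both in duplicate.

Cells are gated by population. MAIT: at least one TRAV1-2 α chain and at
least one β chain. Conventional memory (Tmem): at least one α and one β,
excluding cells bearing a canonical MAIT α (TRAV1-2 with TRAJ33/12/20 and a
12-amino-acid CDR3α, counted exactly as written in the `cdr3` field) as
contaminating MAIT cells. Note the two gates are not formally disjoint: a
TRAV1-2 α with a non-MAIT TRAJ passes both. On repertoires whose TRAV1-2
chains are all canonical the gates partition the cells.

## Clonotype definitions

Six definitions: {nucleotide, functional} × {αβ, α-only, β-only}.

Nucleotide clonotypes are equivalence classes of exact chain-set signatures
(sorted tuples of chain keys with nucleotide CDR3s). Functional clonotypes
use amino-acid CDR3s and tolerate chain dropout: a cell belongs to a clonotype
provided every chain it carries matches the clonotype's chain set. Because
that relation is not transitive (a one-chain cell can be consistent with two
different two-chain clonotypes), assignment needs an explicit algorithm:

1. group cells by exact amino-acid signature ("seed groups");
2. mark signatures that are not a strict subset of any other observed
   signature as *maximal*;
3. merge each non-maximal group into a compatible maximal clonotype —
   compatible means the group's chains are contained in the maximal signature
   and share at least one α and one β with it (at single-locus levels, at
   least one chain). When several maximal clonotypes are compatible the group
   joins the largest (ties: lexicographically smallest signature) and its
   cells carry `ambiguous=True`.

Cells are assigned uniquely; an alternative would be to count ambiguous cells
in every compatible clonotype, which would break the partition property that
the downstream statistics rely on.

Numbering sorts clonotypes by descending size, permuting equal sizes with a
seeded RNG so results are reproducible; ranks use competition ("min") ranking
(sizes 5,3,3,1 → ranks 1,2,2,4).

## Repertoire metrics

The Shannon index is `H = −Σ pᵢ ln pᵢ` in nats. Clonality curves plot the
cumulative cell fraction against clonotype rank (largest first).

Chain-pairing promiscuity counts, per unique focal chain (nucleotide
identity), the distinct partner-locus chains co-occurring with it in any cell;
scopes: per donor-tissue, per donor, or global. Segment usage is reported per
chain or per unique chain (`unique=True`); the unique-chain form is the
natural unit when proportions describe clonotypes rather than cells.

Cross-sample sharing compares chain-set signatures between two clonotype
tables of the same level and reports the percentage of cells per sample whose
signature occurs in both. The shared-clonotype frequency correlation is
Pearson's r on log10 within-sample frequencies of shared clonotypes only —
restricting to shared clonotypes avoids log(0); fewer than three shared
clonotypes is reported as undefined. Publicness is defined on functional
(amino-acid) signatures only; the occupancy of a signature is the number of
donors carrying it, and each donor's cells are binned by occupancy.

Downsampled comparisons sample the larger of two groups without replacement
to the smaller group's size within each stratum (default 100 replicates,
mean reported, replicates retained), so unique-clonotype counts and Shannon
indices are compared at equal depth.

## Clonotype–cluster association

For a clonotype with n cells in a sample clustered into k clusters, the null
is that cells fall into clusters independently with the sample-wide cluster
proportions (computed over all cells, including the tested clonotype's own —
a leave-one-out null is available via `loo_null`). The p-value is the total
null probability of all outcomes as or less likely than the observed one,
with a relative tie tolerance of 1e−12 on the pmf so that enumeration order
cannot change p.

The outcome count ("events") is `C(n+k−1, k−1)`. Below 10⁶ events the test
enumerates all compositions (stars-and-bars, vectorized log-pmf via
`gammaln`); the sorted pmf distribution and its cumulative sums are cached
per (n, null) so a scan of many same-sized clonotypes against one sample
costs one enumeration. At or above 10⁶ events the test draws
`ntrial = min(10·events, 10⁸)` multinomial samples and uses the add-one
estimator `p = (1 + #{as-or-less-likely}) / (ntrial + 1)`, a valid p-value
that cannot be zero (a deliberate deviation from the plain-proportion
estimator some implementations use). Scans accept `max_ntrial` to cap the
Monte-Carlo cost; the validation batteries use 10⁵ trials, whose p-value
floor of ~10⁻⁵ is far below every decision threshold involved. Bonferroni
adjustment multiplies by the number of clonotypes tested in the same
donor-sample (min 20 cells by default).

The size–significance summary is Spearman's rho between clonotype size rank
(1 = largest) and the adjusted p-value; smaller p for bigger clones appears
as positive rho under this sign convention.

## Consensus regulons and activity

A regulon inference run is a map TF → target set. High-confidence regulons
require the TF in strictly more than 80% of runs and at least five
high-confidence targets; a high-confidence target occurs in strictly more
than 80% of the runs containing that TF's regulon (conditional denominator —
the alternative, denominating by all runs, would conflate TF instability with
target instability). The gene-occurrence display matrix reports, per gene and
high-confidence TF, the percentage of all runs containing the gene in the
TF's regulon, keeping TFs whose maximum over the displayed genes exceeds 50%.

The activity score of a gene set in a cell is the area under the recovery
curve — the cumulative count of set genes among the top
`max_rank = ceil(top_fraction · G)` expression ranks — normalized by the
maximal achievable area (all `min(|S|, max_rank)` hits at the top). The
default `top_fraction` is 0.05. Scores depend only on within-cell ranks and
are therefore invariant under monotone transformations of a cell's
expression. Ties are broken at random per cell with a seeded RNG by default;
`tie_method="first"` gives a deterministic stable order for exact
reproducibility.

Differential activity between two cell groups uses a two-sided Mann–Whitney
rank-sum test per regulon with Bonferroni correction over regulons
(significance threshold 0.01) and reports regulons ordered by absolute mean
difference. A hurdle-model test with donor covariates would be a natural
refinement; the rank-sum test was chosen as the simple two-group comparison
this package needs, with per-donor stratification possible by running the
test within donors.

## Coreceptor and pseudotime linkage

Gene-mode coreceptor calls: CD8⁺ if CD8A > 0 or CD8B > 0; CD4⁺ if CD4 > 0;
DN if all three are zero; a cell positive for both is called CD8⁺ with an
ambiguity flag (the CD8 rule is evaluated first). Protein mode: CD8⁺ if
CD8 > 0.3; else CD4⁺ if CD4 > 2.5 and CD8 < 0.2; else DN — thresholds
appropriate for normalized antibody-capture counts.

Pseudotime association uses the Kruskal–Wallis test across TCR-defined groups
(clonotypes with ≥20 cells, or TRBV genes above 1% frequency), per donor and
trajectory; being rank-based it is invariant to affine rescaling of
pseudotime. Cross-trajectory agreement is Spearman's rho of per-group mean
pseudotimes between the two trajectories. The clone-size relationship is
Pearson's r between log10 clonotype frequency and pseudotime, one point per
cell by default (`per_clonotype=True` uses clonotype means).

Differential gene importance between two trajectories takes per-gene rank
tables (1 = most important) and computes `max(rank_A, rank_B) /
min(rank_A, rank_B)` (≥1, symmetric). A gene is flagged differentially
important when its importance FDR is below 0.05 on **either** trajectory and
its rank is within the top 150 on **either** trajectory; the either-trajectory
reading keeps the rule symmetric. The display transform log2(1/rank) is
emitted for plotting.

## Synthetic data: what it emulates and what it does not

The repertoire generator draws, per donor, a pool of clones. Each clone has a
TRAV1-2 α chain (TRAJ usage 0.87/0.06/0.06 for TRAJ33/12/20 plus 0.01 other so
the vector sums to one; CDR3α is a 12-mer with the canonical Tyr near the J
junction), a β chain with TRBV biased toward TRBV6-1/6-4/20-1 and a ×3
TRBV6-4 boost for TRAJ12/TRAJ20 clones, and optionally a second α (rate 0.3)
or second β (rate 0.1) — never both in duplicate, since that chain pattern is
indistinguishable from a doublet. CDR3 nucleotide and amino-acid sequences
are unique across clones by construction, so ground-truth recovery is
well-defined. A configurable number of public α chains recur (same sequence)
as one clone in every donor; public clones are single-α with one guaranteed
captured cell per donor so planted publicness is always observable.

Clone sizes follow a log-series law (p = 0.92), the classic skewed abundance
model for clonal repertoires. Matched tissues share a designated clone pool:
each cell draws from the shared pool with probability ω (default 0.7, the
scale of reported blood–liver sharing) and otherwise from a tissue-private
pool, so the expected cell-weighted sharing equals ω. Capture failures drop a
cell's contigs entirely (rate 1−q, default q = 0.9); chain dropout removes
individual chains at the configured rate but never a cell's last α or β, so
gating viability is preserved and the dropout-tolerance of functional calling
can be tested in isolation. Doublets are synthesized by unioning the chain
sets of two sampled cells; only unions violating the chain-count rule are
counted as detectable.

What the generator does **not** emulate: sequencing-read noise, ambient RNA,
realistic transcriptome-wide counts, CDR3 length/motif biology beyond the
canonical α, allelic-exclusion genetics, or convergent recombination beyond
the planted public chains (public α chains share nucleotide sequence across
donors, a simplification). Tests passing on this generator therefore
demonstrate algorithmic correctness and statistical calibration under the
declared model, not robustness to every artifact of real libraries.

Companion generators plant: cluster labels with Dirichlet-perturbed
per-clonotype proposals (concentration parameter; `forced_cluster` for fully
concentrated planting; `exact_proportions` permutes a fixed label vector so
empirical cluster proportions are identical across simulations); pseudotime
as base + group effect + Gaussian noise with a configurable cross-trajectory
effect correlation; regulon runs with stable TFs (occurrence 0.9, core-target
occurrence 0.95) and decoys (0.5); and expression matrices that satisfy the
coreceptor thresholds exactly and boost regulon targets in designated cells
with a given probability.

All generators are deterministic given their seed.

## Validation experiments and problem sizes

`clonolink.experiments` packages the end-to-end checks run by the test suite
and `scripts/acceptance.py`. Sizes were chosen so the whole battery completes
in about a minute on one core while keeping every statistical check
well-powered:

- clonotype recovery: 5 donors × 2 tissues × 2,000 cells, no noise; both
  partitions must match the planted clones (ARI 1.0; ARI computed from the
  pair-counting contingency table, independent of the calling code).
- dropout tolerance: per-chain dropout 0.3, 3 donors × 2 × 1,500 cells;
  ≥99% of cells correctly assigned under majority mapping, all ambiguity
  flags verified by brute-force subset analysis.
- exact-test oracle: 200 random instances with n ≤ 8, k ≤ 4 against a
  factorial-arithmetic enumeration oracle (agreement to 1e−12).
- Monte-Carlo agreement: 100 forced-MC replicates at 10⁵ trials within 3
  standard errors of the exact p; scan calibration: 100 simulations × 20
  size-20 null clonotypes in 2,000-cell samples with exact cluster
  proportions (raw rejection rate in [0.03, 0.06]).
- power: 40-cell clonotype forced into a 10% cluster among 8, family of 30,
  100 replicates.
- sharing vs capture: nested per-cell capture uniforms over
  q ∈ {0.4, 0.6, 0.8, 1.0}; the monotone trend is probed in a rare-clone-rich
  regime (400 clones, 1,600 cells per tissue) where incomplete capture
  genuinely hides shared clones, and the ω-recovery at q = 1 in a
  well-sampled regime (150 clones) where every shared clone is expected
  several times per tissue; 20 repertoires each.
- parameter recovery: ~6,000 unique chains; all compared proportions within a
  simultaneous (Bonferroni) 95% bound, z < 3 across the ~13 comparisons.
- AUCell oracle: 500 (cell, gene-set) instances against direct step-curve
  integration plus exact boundary cases.
- consensus thresholds: 20 run-sets; the recovered set must always equal the
  set passing the strict thresholds on realized occurrences (a planted TF
  occasionally lands at ≤80/100 runs by binomial chance and is then rightly
  excluded), with planted-exact recovery in ≥90% of sets; exact-0.80
  boundary cases are constructed deterministically.
- pseudotime link: 100 replicates of 10 shifted (1 s.d., 40 cells) and 10
  null clonotypes over a 4,000-cell unshifted background; sensitivity ≥90%,
  false positives ≤10%; cross-trajectory rho under perfectly correlated
  distinct effects ≈ 1.
- importance predicate: 1,000 random (rank, FDR) tuples against a brute-force
  re-evaluation of the selection rule; exact ratio symmetry.

## Known limitations

- Functional-clonotype assignment resolves ambiguity greedily toward the
  largest clonotype; a probabilistic assignment would propagate uncertainty
  but break the partition structure.
- The exact multinomial enumeration holds the full composition distribution
  in memory (~14 MB at n = 20, k = 8); events just below the 10⁶ limit with
  many distinct (n, null) combinations will recompute per combination.
- The rank-sum differential-activity test ignores donor structure unless run
  per donor.
- Cluster-label generation plants bias per clonotype independently; it does
  not model spatial/graph structure among clusters.
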