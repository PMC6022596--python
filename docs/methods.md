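# Methods

`pavcomp` infers gene presence/absence variation (PAV) in a query genome
from whole-genome shotgun reads mapped onto the coding sequences (CDSs) of a
panel of reference species, compares loss/conservation across lineages,
constructs orthologue clusters, tests gene sets for term enrichment over a
GO-style DAG, and scans protein alignments for convergent lineage-specific
substitutions. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data does and does not emulate.

## Presence/absence from read breadth

For each reference CDS the pipeline computes **horizontal coverage**: the
percentage of the CDS length covered by at least one mapped read, i.e.
100 · |∪ᵢ [sᵢ, eᵢ]| / L for hit subject intervals [sᵢ, eᵢ] clipped to
[1, L]. Breadth, not depth: a single deep pile-up on 1% of a gene still
leaves 99% uncovered, which is the signature that distinguishes a residual
repeat match from a retained gene.

Per orthologue group, coverage is first averaged within each species over
that species' member genes (groups are effectively single-copy in the
intended use, so this is usually the identity), then across species. The
group mean m drives the call:

- m < `lost_max` (default **2%**) → **LOST**
- m > `conserved_min` (default **50%**) → **CONSERVED**
- `lost_max` ≤ m ≤ `conserved_min` → **INDETERMINATE**
- no species with data → **NO_DATA**

Both inequalities are strict. Exact-threshold ties (2.0, 50.0) fall into
INDETERMINATE: the thresholds are defined by strict inequalities and the
middle class is surfaced rather than silently binned. A species that simply
has no member gene for a group is excluded from the mean rather than counted
as zero — counting an incomplete reference as zero would conflate reference
incompleteness with query loss. The alternative behaviour is available as
`absent_species_as_zero` for sensitivity analyses.

Hits are used as-is: no per-read best-hit filtering, no mapping-quality
weighting. The e-value filter (default 1e-5) is applied at parse time.

## The built-in read mapper

`naive_map` is a deliberately simple seeded aligner so the whole pipeline
runs self-contained: exact k-mer seeding (default k = 21) on both strands,
each shared k-mer proposing a gapless full-length placement of the read, and
a placement reported when the read lies entirely within the subject and its
whole-read matched fraction is ≥ `min_match_fraction` (default 0.9). There
is no gapped extension and no scoring; reported e-values are a synthetic 0.

Two consequences matter for interpretation. First, by the pigeonhole
principle a placement with at most m mismatches is guaranteed to share an
exact k-mer whenever (m + 1) · k ≤ read length; above that, distant
homologues are found only stochastically, which mimics (crudely) the decay
of seeded-aligner sensitivity with divergence. Second, reads that straddle a
gene boundary in the query genome never map, so a few bases at CDS ends stay
uncovered — irrelevant at the 2%/50% thresholds.

## Orthologue clustering

The similarity graph takes −log₁₀(e-value) edge weights from all-vs-all
protein hits (e-value 0 capped at 1e-200 → weight 200; reciprocal hits
merged by maximum; self-hits dropped). Clustering is plain Markov clustering
(MCL): add self-loops (each node's maximum incident weight; 1 for isolated
nodes), column-normalize, then alternate expansion (matrix squaring) and
inflation (elementwise power, default 1.5, then renormalization), pruning
entries below 1e-5, until the largest elementwise change falls below 1e-8.
Clusters are attractor basins: rows with positive diagonal mass seed
clusters, every node joins the attractors it sends mass to, and overlapping
attractor sets are merged via union–find — the result is always a partition
and is invariant to node ordering. The species-pair weight rescaling that
full OrthoMCL adds is not implemented; cluster *usage* (lineage-specific
selection, downstream set comparisons) is the point here, not the clusterer.
The inflation default follows common practice and is configurable.

Lineage-specific selection keeps clusters containing at least one member in
**every** target species and none in any outgroup species.

## Cross-lineage comparison

Computed calls for the focal species and imported statuses for other
lineages merge into a group × species matrix (missing cells NO_DATA). For a
status of interest S (LOST or CONSERVED) with "opposite" status S̄ (the
other definite call), rows where the focal species holds S split into:
shared by both others (S, S), shared with exactly one (S, S̄), unique to the
focal lineage (S̄, S̄). A row whose non-focal cell is NO_DATA or
INDETERMINATE counts toward the focal total but toward none of the three
categories; the shortfall is reported explicitly as `unclassified` rather
than silently absorbed — published three-way tallies of this kind often do
not sum to the focal total, and the unclassified column is the audit trail
for that gap. `others_only` counts rows where both others hold S but the
focal species holds S̄.

Protein-domain comparison between a focal gene and its reference orthologue
is a set comparison of domain identifiers: IDENTICAL (equal, non-empty),
NO_DOMAINS (focal gene has none), DIFFERENT (anything else).

## Term enrichment

Annotations obey the true-path rule: a gene annotated to a term is
annotated to every is_a ancestor (only is_a edges are traversed). Each term
is tested with the exact upper-tail hypergeometric probability
P(X ≥ k), X ~ Hypergeom(N, K, n) — foreground size n drawn from background
size N with K annotated — via the survival function, no normal
approximation. Raw p-values are reported (a Benjamini–Hochberg q column is
attached but never gates anything), terms with fewer than `min_count`
(default 1) annotated background genes are skipped.

The **elim** variant processes terms children-before-parents and, when a
term's p < `elim_alpha` (default 0.01), removes its annotated genes from all
ancestors before they are tested. This decorrelates the DAG: without it the
ancestors of a genuinely enriched leaf inherit its genes and dominate the
ranking (the synthetic benchmark shows exactly this — classic ranking
places ancestors first, elim recovers the planted leaves).

A note on calibration checks: an exact test on a discrete statistic is
conservative by construction — its attained level at α = 0.05 is below
0.05 by an amount of order the pmf at the critical value. The null
calibration suite therefore simulates in a large-count regime
(N = 500 000, n = 50 000, K ∈ [120 000, 250 000]) where the analytically
computed attained level is 0.0494 and the empirical rejection rate is
expected to sit inside a binomial band around the nominal level. At small
counts (say N = 2000, n = 200) the attained level is ≈ 0.042 and no
correctly implemented exact test can appear "calibrated at 0.05"; that is a
property of discreteness, not an implementation defect.

## Convergent-substitution scan

Given an MSA with a foreground/background taxon partition, a column is
called lineage-specific when (a) the background has a strict-majority
consensus residue present in ≥ `bg_conservation_min` (default 1.0) of
considered background taxa — a tie means no consensus and rejects the
column at any threshold; (b) the foreground is unanimous (default; a strict
foreground majority when relaxed); (c) the foreground residue differs from
the background consensus; (d) gaps either reject the column (default) or,
when allowed, gapped taxa are excluded from the fractions. Columns are
numbered in original alignment coordinates, gaps included. Calls are
monotone in `bg_conservation_min`: relaxing the threshold can only add
sites. Which taxa are foreground, background, or ignored is entirely
caller-specified; the scan imposes no phylogenetic assumptions.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, with recorded
ground truth, fully determined by their seed:

- **Reference panel** — each orthologue group is one random ancestral
  sequence copied into every species and mutated i.i.d. per site at
  `interspecies_divergence` (default 0.05) to a uniformly chosen different
  base; no indels. Under this model two members of one group mismatch per
  site with probability 1 − [(1 − d)² + d²/3], which the tests verify
  against binomial sampling error.
- **Query genome** — exactly round(`loss_fraction` · n_groups) groups are
  deleted outright; each retained group appears once (the first species'
  member mutated at `query_divergence`, default 0.02), separated by i.i.d.
  uniform spacers with length uniform in [0.5×, 1.5×] of
  `intergenic_length` (default 200 bp).
- **Reads** — ceil(depth · G / (2 · read_len)) pairs, fragment starts
  uniform, insert size constant at `insert_mean` (simplifies the depth
  arithmetic), per-base substitution errors at `error_rate`, mate 2
  reverse-complemented, constant placeholder qualities (the pipeline never
  reads qualities).
- **MSAs** — planted columns have one residue across the background and a
  different one across the foreground; every other column is fully
  conserved, except that with probability `background_noise` one taxon is
  mutated — chosen so the column still violates at least one call
  condition at any threshold. The strict scan therefore recovers the
  planted set exactly, which is the round-trip oracle.
- **Annotations** — a single-root DAG of `dag_depth` levels (each term with
  1–2 parents in the level above), genes annotated directly to leaves only;
  planted terms multiply the foreground annotation odds by `effect_odds`.

Deliberately absent: indels and structural variation, GC and coverage
biases, instrument error profiles, quality-score models, paralogy and gene
duplication, codon structure. Passing the recovery benchmarks therefore
shows the inference machinery is correct under its own assumptions — clean
uniform coverage with substitution-only noise — not that the thresholds are
optimal for any particular real sequencing run, where repeats,
cross-mapping paralogues and coverage dropouts move both error rates.

## Benchmark scales

The standard recovery benchmark is 5 species × 300 groups (gene lengths
300–1500 bp), 20% planted loss, 10× read depth at 1% error — a panel small
enough to run in seconds while leaving hundreds of groups per status class.
At these conditions LOST sensitivity and specificity against planted truth
are both ≥ 0.95 (observed: 1.0). The clustering benchmark is a planted
partition of 5 blocks × 20 nodes (intra-edge probability 0.9, inter 0.05)
at inflation 2, scored by adjusted Rand index. Enrichment recovery uses
2000 genes, 30 terms over 3 levels, a 200-gene foreground and odds 8.

## Known limitations

- `naive_map` is intentionally not a production aligner: no gapped
  alignment, no partial (clipped) placements, sensitivity to divergence
  governed by the pigeonhole bound above.
- MCL is dense-matrix; fine into the low thousands of nodes, not for
  proteome-scale all-vs-all graphs.
- Only is_a edges are honoured in the ontology (part_of is out of scope).
- The comparative tallies take imported statuses at face value; no attempt
  is made to harmonize thresholds used by different upstream studies.
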