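# Methods

## The analysis model

cohortnet implements a multivariate, network-based reading of case/control
exome data.  The underlying hypothesis is that a genetically heterogeneous
phenotype is driven not by recurrent variants in single genes but by damaging
variation scattered across a *disease module* — a localized neighborhood of
the protein–protein interactome.  Patients whose damaged genes fall in the
same neighborhood should therefore have similar personal PPI networks even
when they share few or no individual variants.

The stages and their statistical content:

**Variant filters.** Two conjunctive filter stages with fixed, auditable
thresholds.  Quality: a site is removed when three or more variants fall in
any closed 10-bp window of its chromosome (all members of the window fail),
when four or more alignments map equally well (xamb ≥ 4), when depth < 10,
site quality < 30, quality-by-depth < 1.5, or Phred-scaled strand bias
> 200.  Deleteriousness: keep exonic sites with PolyPhen-2 HDIV ≥ 0.957,
SIFT < 0.05, CADD (Phred) > 15 and reference-population MAF < 0.05.
Inequality strictness follows these printed forms exactly, and the boundary
behavior is pinned by tests.  Sites with any missing score are removed under
a distinct `unannotated` reason rather than silently passed; the density
filter operates cohort-wide at site level.  Every stage emits a report with
per-variant failure reasons, so the filter funnel is monotone and fully
reconstructible.

**Genotype test.** Each variant yields a 2×3 table of hom-ref/het/hom-alt
counts for cases vs controls (missing genotypes excluded, tallied per
group).  Conditioned on its margins the table follows the multivariate
hypergeometric law; the two-sided exact p sums the probabilities of all
margin-compatible tables whose probability does not exceed the observed
one.  Probabilities are compared as exact integers (the numerators
`∏_j C(c_j, a_j)`; the common denominator cancels), so ties are resolved
without a floating-point tolerance.  Enumeration is over first-row
compositions, at most `(r₁+1)(r₁+2)/2` tables, so cohort-scale margins
(61/82) enumerate in microseconds; a configurable cap routes pathological
tables to the Monte-Carlo path: sequential hypergeometric sampling of the
first row (the exact fixed-margin null), with the add-one estimator
`p̂ = (1 + hits)/(reps + 1)` (default reps = 100,000, per-variant seed
derived from the master seed and the variant key, recorded in the output).
The exact test is conservative; a type-I-error test at α = 0.05 over a null
synthetic cohort checks this calibration.

**Seed genes.** Per sample, every gene holding ≥1 surviving variant with
genotype 0/1 or 1/1 for that sample is scored by the minimum variant p-value
in the gene and the top k = 60 genes are kept (ties lexicographic).  The
minimum is our aggregation choice: seed selection is about the strongest
evidence per gene, not its total burden.  Samples with no qualifying gene
are logged and excluded downstream.

**Patient networks.** With maximum path length 2, a sample's network is its
mapped seeds plus every interactome protein adjacent to ≥2 distinct seeds
(an *imputed* single intermediary), with seed–seed and seed–imputed edges;
imputed–imputed edges lie on no length-≤2 seed path and are excluded by
default (config-exposed).  The network is then restricted to its largest
connected component (ties: more seeds, then lexicographically smallest node
set) — the analysis targets the sample's dominant shared neighborhood, and
isolated seeds carry no relational information.  Correctness is pinned
against exhaustive enumeration of length-≤2 seed–seed paths.

**Clustering and cluster tests.** The Jaccard distance is computed on
network *node* sets (genes are the biological payload; edge-set distance is
available via config).  UPGMA (average linkage, size-weighted update) is
implemented with deterministic tie-breaking — among equal-distance pairs the
one with the lexicographically smallest (leader, leader) pair merges first —
so dendrograms and Newick files are reproducible byte for byte; cophenetic
distances are validated against an independent average-linkage
implementation.  Every internal dendrogram node with ≥ min_size (default 3)
members is tested with a two-sided 2×2 Fisher exact test of members vs
non-members; nodes with p < α (default 0.05, raw; Bonferroni optional) are
significant, and significant nodes without a significant ancestor
("maximal") are the headline clusters.  With well-separated data this
reproduces a two-cluster headline; all tested nodes are retained in the
output regardless.

**Layered networks, unique genes, separation.** A cluster's layered network
is the union of its members' graphs with per-node/per-edge support counts;
a node's role is `seed` if it is a seed in any member network, else
`imputed`.  Unique genes are node-set differences between two layered
networks, annotated with these roles.  The headline comparison is the
case-dominated vs the control-dominated maximal significant cluster; when
no control-dominated node reaches significance the comparison falls back to
the layered network of the cohort remainder (all clustered samples outside
the case cluster), and the report records which comparison was made.  The
separation score uses unweighted BFS hop distances: `d_AA` and `d_BB` are
mean nearest-other-member distances within each set, `d_AB` the mean over
all |A|+|B| genes of the distance to the nearest gene of the opposite set
(shared genes contribute 0), and `s_AB = d_AB − (d_AA + d_BB)/2`.
Unreachable pairs are excluded from the means and counted — not assigned a
pseudo-distance — and a fully unreachable configuration is reported as
undefined rather than as a number.  Over-representation of a gene set in a
reference list is the one-sided hypergeometric upper tail.

## The synthetic cohort generator

Real cohorts of this design are not publicly deposited, so the generator is
part of the package's contract: it produces inputs with the statistical
structure the analysis assumes, plus ground truth for validation.

*Interactome.* Preferential-attachment growth (each new node attaches to
`attachment_degree = 3` distinct existing nodes with degree-proportional
probability), giving the hub-dominated, scale-free-like topology of curated
interactomes; edge confidences are uniform integers in [150, 999], matching
the span of STRING combined scores.  Defaults: 1,500 genes, 4,491 edges.
The pipeline applies its confidence cutoff (default 400, STRING "medium")
*before* planting the module, so the planted module is connected in the
graph the analysis actually uses.

*Disease module.* `module_size = 15` genes chosen by random-walk expansion
from a uniformly random start node within the largest component — a
connected induced subgraph whose degree bias (walks revisit hubs) mimics the
hub-proximity of curated disease genes.

*Genotypes.* Each case (control) carries, with probability 0.8 (0.05), one
to three heterozygous deleterious variants in distinct random module genes.
Every sample additionally draws `background_variants_per_sample = 150`
variants in random non-module genes, drawn from per-gene pools of
`sites_per_gene = 2` fixed sites so that carriers of a background site are
shared across samples (a crude site-frequency structure).  A background
site passes the deleteriousness filter with probability
`fraction_deleterious_background = 0.05`; failing sites violate exactly one
randomly chosen threshold, which makes every filter decision auditable
against the truth file.  The 0.05 is calibrated by variant load: a real
exome carries on the order of 100 rare deleterious variants across ~20,000
genes (≈0.005 carriers per gene per sample); 150 draws over 1,485
background genes reach the same per-gene rate at a passing fraction of
0.05, i.e. about 7–8 deleterious background genes per sample at this
interactome scale.  Quality fields are drawn so that ~5% of background
sites fail exactly one quality filter (`quality_fail_rate`), plus
`n_density_clusters = 2` decoy triplets within 10-bp windows for the
density filter; planted module sites always pass everything, so the planted
signal survives the funnel by construction.  Non-carrier genotypes are
missing at rate 0.02.

*Determinism.* All randomness flows from one integer seed through tagged
`numpy` SeedSequence streams; identical configurations yield byte-identical
VCF, annotation, phenotype and truth files.

**What the generator does not emulate** — linkage disequilibrium,
population stratification, relatedness, realistic site-frequency spectra,
genes of unequal length or mutability, hom-alt planted genotypes, and any
correlation between background variants and pathways.  Passing tests on
synthetic data therefore demonstrate that the machinery recovers a planted
module under the stated design, not that the biological conclusions of any
particular real-data study are correct.

## Validation strategy and problem sizes

Statistical components are tested against independent oracles: exact
rational-arithmetic enumeration for the 2×2, 2×3 and hypergeometric tests;
an independent average-linkage implementation for UPGMA cophenetic
distances; explicit path enumeration for network construction;
`scipy.sparse.csgraph` all-pairs distances for the separation score.  The
end-to-end check runs the full pipeline at the study design (61/82, 15-gene
module, 80%/5% hit rates, defaults elsewhere) across ten seeds and requires
a significant case-dominated cluster holding a majority of cases, with its
unique-gene set enriched for the planted module (hypergeometric p < 0.01),
in at least eight of the ten.  Simulation sizes (1,500-gene interactome,
~3,000 variant sites per cohort) were chosen so a full pipeline run takes a
few seconds on one CPU while keeping cohort-scale margins in the genotype
test; all counts scale up via `SimulationConfig`.

## Known limitations

- UPGMA on weak or tied similarity structure chains; with very sparse
  patient networks (few qualifying genes per sample) the headline
  case-dominated cluster can be large and only moderately enriched, and a
  control-dominated cluster may not reach significance (hence the
  remainder-comparison fallback).
- The exact 2×3 test conditions on both margins and is conservative at
  small carrier counts; very rare variants cannot reach p < 0.05 at all.
- Seed-gene ranking uses cohort-level p-values, so a sample's seed list is
  not independent of the cohort it is embedded in; per-sample networks
  should not be interpreted in isolation.
- The separation score is reported without a degree-preserving
  randomization null; its sign, not its magnitude, is the interpretable
  output.
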