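# Methods

This note documents the models and procedures implemented in `upsdiverge`,
the assumptions behind them, and the design choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Family annotation

A protein is assigned to a UPS family when all domains of at least one of
the family's required combinations appear among its domain hits. Hits are
pre-filtered at E-value ≤ 1 (the permissive cutoff appropriate for short
protein-protein-interaction domains); coordinates are carried but only
presence/absence decides membership. The shipped rule file
(`upsdiverge/data/family_rules.yaml`) encodes: the eleven RP combinations
(Pro_isomerase; Prot_ATP_ID_OB; RPN1_RON2_N; RPN2_C; Rpn3_C+PCI; RPN5_C+PCI;
RPN6_N+PCI; RPN7+PCI; YfdX+PCI; MitMem_reg+Peptidase_M13_N; VWA_2+UIM — the
two unusual pairings are shipped verbatim, without reinterpretation), the
Cullin requirement of both Cullin and Cullin_Nedd8, single-domain rules for
CP (Proteasome), FBX, BTB, HECT, E1 (ThiF), E2 (UQ_con) and Skp1, and an
editable RING list of RING-type zinc-finger domains with the bacterial
Prok-RING_4 excluded. The RING list is Pfam-version-dependent and therefore
configuration, not code.

Proteins matching several families are resolved by a fixed priority
(Cullin, APC, RP, CP, E1, HECT, E2, Skp1, FBX, RING, BTB): families defined
by rarer or multi-domain combinations outrank the large single-domain E3
families, so e.g. an F-box protein that also carries a BTB domain is FBX.
The order is configurable. Pseudogene status is an input flag, never
computed. Accessory domains (everything outside the assigned family's
defining set) form the subfamily signature used by the duplication and
enrichment stages.

## Orthogroups and age ranks

Edge weights default to −log10(E-value), capped (default 200) so that
E = 0 rows stay finite; a raw-score mode exists for score-based tables.
Reciprocal rows are averaged into one undirected edge. This deliberately
simplifies OrthoMCL's full normalization (between-species weight
correction, reciprocal-best-hit weighting): downstream analyses depend only
on group membership, and the planted-truth recovery tests bound the cost of
the simplification.

The Markov Cluster algorithm is implemented natively: self-loops (each
node's maximum incident weight; 1 for isolated nodes) are added, the matrix
is column-normalized, and expansion (matrix square) alternates with
inflation (entrywise power 1.5, then renormalization) and pruning of
entries below 1e-5 until the maximum entry change falls below 1e-6
(at most 200 iterations; non-convergence raises with the residual).
Clusters are the connected components of the converged matrix's non-zero
structure and always partition the node set. Prune/convergence defaults
follow common MCL practice.

Age ranks follow the nested-presence ladder. In strict mode a group's
non-focal within-family presence must exactly equal a nested set (and no
outgroup/other-family species may be present) to receive that set's rank;
groups private to the focal species are rank 0; a group containing the full
within-family set plus the outgroup or any other-family species is rank A.
The rank-A rule is an operational choice: "conserved in flowering plants"
is read as full within-family presence plus at least one lineage beyond the
family. Everything else is non_ranked, and groups without a focal-species
locus are explicitly not-applicable. A lenient mode (rank = deepest split
represented among the species present) is available behind a flag.

## Duplication classification

Two genes are tandem when they share a subfamily (family + accessory-domain
signature by default; family-only mode available), lie on the same
chromosome with an order-index difference ≤ 11 (i.e. at most 10 intervening
gene loci, counted against the full gene complement — not only UPS genes),
and their spans are within 300 kb measured from the end of the upstream
gene to the start of the downstream gene (the most permissive reading of
"located within 300 kb"). Both members of a qualifying pair are flagged;
the recorded partner is the nearest qualifying neighbor. Intronless status
is decided on the representative transcript with the longest total CDS:
exactly one exon means intronless. Enrichment between two genomes uses the
two-sided Fisher exact test on the 2×2 (genome × tandem/non-tandem or
intronless/intronic) table.

## Pairwise selection estimates and the neutrality test

The NG86 estimator counts synonymous sites by one-step neighbor enumeration
under the standard code, with mutations to stop codons excluded from both
numerator and denominator; multi-position codon differences are averaged
over all minimal mutational pathways, discarding pathways through stop
codons unless every pathway is blocked. Proportions are Jukes–Cantor
corrected, d = −(3/4)·ln(1 − 4p/3); a non-positive argument (saturation)
yields NaN with a defined flag rather than an error.

The ML route fits a GY94-style codon model over the 61 sense codons:
single-nucleotide changes only, rate ∝ π_j · κ^[transition] ·
ω^[nonsynonymous], scaled so one unit of t is one expected substitution per
codon. Codon frequencies are uniform by default (an F3x4 positional
estimate is available by flag). Because the model is reversible, P(t) is
computed through a symmetric eigendecomposition, and the pairwise
log-likelihood is Σ log(π_i P(t)_ij) over compressed site patterns — which
also makes the likelihood invariant to the order of the two sequences.

Optimization is a deterministic multi-start: the likelihood is evaluated on
a fixed 3×3×3 grid over t ∈ {0.05, 0.5, 2}, κ ∈ {0.5, 2, 8}, ω ∈ {0.1, 1,
4} (the ω axis dropped when ω is fixed), and the two best starts are
refined with bounded L-BFGS-B in log-parameter space (t ∈ [1e-6, 50],
κ ∈ [1e-3, 100], ω ∈ [1e-4, 20]). K_a and K_s derive from the scaled rate
matrix: with ρ_S(ω) the synonymous fraction of substitution flux and ρ_S1
the same fraction at ω = 1 (the mutational-opportunity definition of
"sites"), K_s = t·ρ_S(ω̂)/(3·ρ_S1) and K_a = t·ρ_N(ω̂)/(3·ρ_N1), so
K_a/K_s equals ω̂ identically.

The neutrality test runs the fit twice (ω free; ω fixed at 1) and forms
LR = 2(lnL_free − lnL_fixed). By nesting the statistic is non-negative;
tiny negative values from optimizer tolerance are clamped to 0, and a
clearly negative value triggers one re-fit of the free model from the fixed
optimum before clamping. A pair is neutral when LR < 2.71 — the χ²(1) 90th
percentile, i.e. a 5% one-sided test under the boundary mixture that
applies when the null pins ω at the constraint boundary of biological
interest. Saturated pairs (NG86 K_s undefined) are retained for ML fitting
but flagged.

Age trends use Spearman rank correlation with midrank ties — exact
permutation p-values for n ≤ 9, the t-approximation otherwise; the ancient
rank A is excluded by default. Lineage contrasts use the two-sided
Mann–Whitney test (exact for small untied samples, tie-corrected normal
approximation otherwise).

## Comparative statistics

Family sizes between the two species groups are compared per family with
the two-sided rank-sum test (α = 0.05); accessory-domain counts per genome
with the pooled-variance two-sample t-test (α = 0.01; zero-variance ties
are not significant and domains absent everywhere are skipped). No
multiple-testing correction is applied by default, matching the nominal
thresholds this style of analysis reports; Benjamini–Hochberg adjustment is
available by flag. Profile co-clustering uses Manhattan distances with
classical Ward linkage on both axes. scipy's Ward update operates on
squared inputs, so the implementation feeds it the square root of the
Manhattan distances and squares the merge heights — exactly reproducing R's
`hclust(method = "ward.D")` topology with heights on the original scale.
Ward on Manhattan distances formally violates Ward's Euclidean assumption;
it is retained as the field's stated convention for these heatmaps.

## The synthetic-data generator

The generator is first-class, tested code. It plants: a focal species plus
five within-family species in a nested ladder, an outgroup, and (optionally)
a six-species second clade; eleven families seeded with ancestral (rank A)
orthogroups (default 39 total, e.g. 6 FBX, 6 RING); birth events per family
per age step (Poisson, default rate 0.4) placed on the ladder so presence
patterns encode age exactly; per-lineage loss (off by default — loss is the
regime in which recovery becomes inexact, and the exact-recovery tests pin
death_rate = 0); duplication modes drawn as tandem (0.6), retrocopy (0.25)
or dispersed, mirroring the predominance of tandem duplication reported for
the large E3 families; and a 5% pseudogene fraction among young loci.

Genes sit on one chromosome per species at uniform 30 kb start-to-start
spacing. Unrelated background genes (12–20 between consecutive family loci)
provide the full gene complement against which order indices are counted,
so non-tandem family loci are always beyond both tandem thresholds while
planted tandem copies sit adjacent to their template; tandem copies keep
the template's domain architecture (same subfamily by construction), while
dispersed and retro births may gain one accessory domain. Retrocopies are
emitted as single-exon gene models; all other family loci carry 1–5
introns of 100 bp.

Coding sequences (100 codons by default; every locus the same length so
ungapped pairwise identity is well defined) evolve by exact
matrix-exponential sampling per codon along a star topology: each species'
branch is DIVERGENCE_PER_STEP × (ladder depth + 1)/2 with
DIVERGENCE_PER_STEP = 0.12, giving focal-vs-neighbor divergence ≈ 0.24
substitutions/codon and focal-vs-outgroup ≈ 0.54 — comfortably inside the
measurable range of both estimators. ω is set per age class, declining
from 0.8 (rank 0) to 0.1 (rank A), planting the negative age trend the
selection statistics are meant to detect. Each orthogroup draws an
independent ancestral sequence — duplicated groups do not inherit their
template's sequence — so similarity never leaks across orthogroups; the
emitted all-vs-all table reports ungapped identity × length for same-family
pairs above a 30% identity reporting threshold (unrelated pairs sit near
the 6% random-identity background and fall below it, as they would below a
search tool's reporting cutoff).

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: alignment uncertainty and indels (all
sequences are gapless and equal-length), rate variation among sites and
lineages, gene conversion between tandem copies, whole-genome duplications,
realistic intergenic DNA, and cross-family sequence homology. Recovery
results on this generator bound implementation correctness, not the
field-performance of the methods on empirical genomes.

## Problem sizes and numerical choices

The calibration experiments use the operating point of the analyses they
validate: 500-codon pairs at t = 0.5, 200 replicates for likelihood-ratio
size/power, 100 replicates per ω ∈ {0.1, 0.5, 1.0, 2.0} for recovery, and
~20 low-divergence pairs (t ≤ 0.2) for NG86/ML concordance. Clustering and
duplication recovery run on full 13-species simulations (≈ 700 family loci)
and a 20-family × 6-node planted graph. All randomness flows through
explicitly seeded NumPy generators; identical configuration and seed
reproduce byte-identical outputs.

Known limitations: the pairwise ML fit assumes the two-sequence GY94 model
with a single ω (no branch or site models, no multi-nucleotide codon
changes); the MCL implementation is dense and suited to graphs of up to a
few thousand nodes; GFF3 parsing expects gene/mRNA/exon/CDS features with
ID/Parent attributes; and exact Spearman p-values are enumerated only up to
n = 9.
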