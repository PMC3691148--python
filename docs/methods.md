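# Methods

## Signed networks

A `SignedNetwork` is a simple undirected graph with one sign in
{+1, −1} per edge; self-loops are forbidden and each unordered pair
carries exactly one sign. Node identifiers are opaque, case-sensitive
strings — identifier normalization (probe→gene collapsing, symbol
translation) is dataset policy and deliberately out of scope. Edges are
keyed by the lexicographically sorted node pair, which fixes iteration
order and makes all outputs byte-reproducible.

Genetic-interaction input follows the BioGRID tab-delimited layout with
configurable 1-based column indices (defaults: systematic names in
columns 6/7, experimental system in column 12, organism in 16/17,
optional taxon filter). Interaction-type labels are mapped to signs
case-insensitively; the default map sends *synthetic rescue* and
*positive genetic* to +1, *synthetic lethality* and *negative genetic*
to −1, and ignores everything else (physical-interaction records are
simply unmapped). A pair supported by both signs is *ambiguous* and is
removed entirely under the default policy; the parse report counts
ambiguous pairs, self-pairs and unmapped records. Whether identifiers
are systematic names or symbols, and whether to restrict to one taxon,
are exposed as options because public releases differ; defaults are the
systematic-name columns with no taxon filter.

## Coexpression networks

Gene pairs are scored by the Pearson correlation coefficient across
samples and thresholded: PCC ≥ 0.9 gives a positive link, PCC ≤ −0.9 a
negative one, with ties at the threshold included. Genes retaining no
link are excluded from the node set. Missing values are handled with
pairwise-complete observations; pairs with fewer than `min_samples`
(default 10) shared observations, or zero variance on them, are
undefined and excluded. For complete matrices the correlation is
computed blockwise from standardized rows (default 1024 genes per
block) so memory stays linear in the block size; the result is
contractually identical to the naive all-pairs computation, and a test
verifies that. No normalization, log transformation or batch correction
is applied — the input is taken as the analysis-ready matrix.

## Link-clustering coefficients

For edge e = (i, j), excess neighbors exclude the partner:
N(i)∖{j} and N(j)∖{i}. Each common excess neighbor k is classified by
the sign pair (s(i,k), s(j,k)) into c_pp (+,+), c_nn (−,−) or c_hy
(mixed). With d = min(n(i), n(j)):

    LC = (c_pp + c_nn + c_hy) / d        SLC = (c_pp + c_nn) / d
    HLC = c_hy / d     PLC = c_pp / d    NLC = c_nn / d

Dividing every count by the same d is the package's *min_total*
convention; it makes LC = SLC + HLC and SLC = PLC + NLC exact
identities, keeps all five coefficients in [0, 1], and reproduces the
qualitative behavior expected of the sign-specific split (SLC of
negative links and HLC of positive links are exactly zero in balanced
networks). A *min_signed* alternative normalizes each subtype by the
matching sign-specific excess counts — PLC by min(n⁺(i), n⁺(j)), NLC by
min(n⁻(i), n⁻(j)), HLC by min(n⁺(i), n⁻(j)) + min(n⁻(i), n⁺(j))) — and
is available behind the `denominator` flag for sensitivity analysis; it
does not preserve the decomposition identities and is not the default.
When d = 0 (pendant edges) all coefficients are defined as 0 rather
than smoothed with a +1 term, so structural zeros stay exact zeros.

The common-neighbor (CNB) profile examines each negative edge e = (i, j)
through its hybrid common neighbors k: the link pair {(i,k), (j,k)} has
one positive and one negative member, contributing the positive
member's PLC and the negative member's HLC. Per-edge medians (midpoint
convention for even counts) are correlated (Pearson) against the edge's
own HLC across all profiled negative edges; with fewer than 3 rows, or
zero variance on either axis, the correlations are reported as NaN
rather than a number.

## Triad census and the sign-shuffle null

Triangles are enumerated once each by scanning canonical edges (u, v)
with u < v and counting common neighbors w > v, and classified by their
number of negative edges: 0 → T1 (+++), 1 → T3 (++−), 2 → T2 (+−−),
3 → T4 (−−−). T1/T2 are the balanced types; a two-block balanced
network contains only those, while k ≥ 3 blocks additionally allow T4
(weak balance). The null model permutes the multiset of signs over the
fixed topology, preserving M⁺, M⁻ and therefore the total triangle
count exactly. Under this null the three signs of a triangle are a
without-replacement draw from (M⁺, M⁻), so the expected count of the
type with k negatives is total × hypergeom.pmf(k; M, M⁻, 3); the
simulation agrees with this closed form within Monte-Carlo error and
the acceptance suite checks it at 10,000 shuffles. Defaults: 1,000
shuffles; empirical p-values use the add-one convention
p = (1 + #{null ≥ obs})/(n + 1) so p is never 0; fold = observed/mean
is flagged ∞ when the null mean is 0 with a positive observation and
NaN when both are 0. The seed drives a splittable stream
(`SeedSequence.spawn`), one child per shuffle, so results are
independent of evaluation order and exactly reproducible.

## Link communities and partition density

Same-sign links are scored by S_e = PLC_e + NLC_e (equal to SLC_e under
the default convention). "Single-linkage clustering of links ranked in
descending order" is realized as a descending threshold sweep: at each
distinct score value, links with S_e ≥ cutoff are retained and two
retained links are in the same community iff they share a node —
single linkage on the line graph, implemented incrementally with a
union-find that maintains per-component link and node counts, so the
whole sweep costs near-linear time in the number of links. Each level
is scored by partition density

    D = (2/M) Σ_c m_c (m_c − (n_c − 1)) / ((n_c − 2)(n_c − 1)),

with M the number of retained links and D_c defined as 0 for n_c = 2.
An alternative reading of the procedure — Ahn et al.'s pairwise
link-Jaccard dendrogram — exists; the per-link score sweep was chosen
because the score is defined per link, not per link pair, and the
sweep reproduces the dendrogram-cut semantics for that score. The
module cutoff is the score maximizing D; ties go to the largest
(most stringent) cutoff by default so reported modules are minimal,
with an `inclusive` flag for the opposite choice. Modules are the link
communities whose induced gene set has ≥ 3 genes (`min_genes`,
configurable). Link communities are edge-disjoint but may share genes;
the module map assigns a shared gene to all of its modules and uses
each module's own gene count in the density denominators. Intra-module
density is (intra-module links of that sign)/C(n_genes, 2); a meta-edge
exists between two modules iff at least one network link spans them
(one endpoint in each, not internal to either), and carries the
spanning-link count and fraction negative.

## Ranked-context analyses

Links are ranked by a chosen coefficient, descending, with ties broken
by the canonical edge key (stable and deterministic). The cumulative
curve reports, at each grid percentage x (default 1–100 in 1% steps),
the fraction of the top ⌈xn/100⌉ links (at least one) whose binary
annotation is true; at 100% this equals the base rate exactly. The
binned variant splits the ranked links into equal-count bins and
reports the median of a quantitative attribute per bin. Enrichment in
the top fraction builds the 2×2 table (top vs rest × annotated vs not)
and reports Fisher's exact test (two-sided and both one-sided) plus the
odds ratio with the Haldane 0.5 correction when a cell is zero;
degenerate tables (annotation constant) are flagged with p = 1. All
three analyses are rank-based and invariant under strictly monotone
transforms of the coefficient.

## Synthetic data

`balanced_block_network` places a positive edge within each block with
probability p_in and a negative edge between blocks with probability
p_out, then flips each realized sign independently with probability ε
(`sign_noise`). At ε = 0 the construction is exactly balanced, giving
the structural zeros and triad exclusions above as ground truth. The
module-recovery condition uses 4 blocks of 20 genes, p_in = 0.8,
p_out = 0.3, ε = 0.1 — dense enough that blocks are unambiguous
communities, noisy enough that ~10% of signs contradict the partition.

`random_signed_network` draws Erdős–Rényi topology and signs
independently, so every triad fold is 1 in expectation — the natural
self-consistency check for the null.

`planted_module_expression` builds each gene in module m of anti-phase
pair p as x = b·u_m + phase_m·c·z_p + σ·ε, where z_p is the pair's
condition profile (the first pair uses the explicit two-block
condition contrast; later pairs use latent profiles), u_m a
module-private latent profile and ε i.i.d. noise. All latent profiles
are standardized and mutually orthogonalized over the sample axis, so
cross-pair correlations are exactly zero at σ = 0 and the calibration

    b² = (r_w − |r_b|)·σ²/(1 − r_w),   c² = |r_b|·σ²/(1 − r_w)

makes the expected within-module PCC r_w (`within_r`, default 0.95) and
the paired-module PCC r_b (`between_r`, must be ≤ 0 with |r_b| ≤ r_w).
At σ = 0 within-module correlations are exactly 1 and anti-phase
correlations exactly −|r_b|/r_w. Infeasible targets raise. The
orthogonalization requires n_samples ≥ n_pairs + n_modules + 2. What
the generator does *not* emulate: heavy-tailed expression noise,
missing values, correlated noise across samples, overlapping modules
and realistic module-size distributions — so passing recovery tests
demonstrates correctness of the machinery on well-separated structure,
not performance on noisy real matrices.

## Problem sizes and determinism

The test and acceptance conditions use graphs of up to 30 nodes for
oracle equivalence (200 random graphs), a ≤ 50-triangle graph at 10,000
shuffles for the null closed form, 20 seeds of the 4×20 block condition
for module recovery, and 10,000 independence replicates of 10,000-edge
tables (50% base rate, 5% top fraction) for the Fisher type-I
calibration — the table is large enough there that the discreteness of
the exact test costs only ~0.5% of the nominal 5% level. Every
stochastic component takes an explicit seed; generators split seeds per
call and never touch global RNG state.

## Known limitations

* The exact denominators of the sign-specific coefficients admit more
  than one reading; both implemented conventions are documented above
  and the default is the one under which the decomposition identities
  are exact.
* Reconstructing a published CEN from a public expression matrix
  additionally depends on preprocessing (probe collapsing, log
  transformation) that the builder deliberately does not perform.
* Partition density is the only community-quality criterion
  implemented; no overlap-aware alternatives.
* Negative-link clustering is supported (`sign=-1`) but in balanced
  structures its sweep is monotone with no interior maximum — the
  method is designed to find modules among positive links.
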