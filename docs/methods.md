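# Methods

## Problem and data model

`aaflux` reconstructs the history of amino-acid substitutions across many
gene families at once. Inputs are, per family, a protein multiple
alignment and a rooted gene tree whose branch lengths are in Ks units
(synonymous substitutions per 4-fold degenerate site — a neutral-rate
proxy), plus one rooted species tree shared by all families. The output
is a relational database (SQLite, with TSV mirrors) whose core tables are
`families`, `tree_nodes`, `substitutions` (+ `substitution_alternatives`)
and `duplications`; analyses add `flux`, `family_stats` and
`asymmetry_tests`. Alignment columns are 1-based in all output tables and
0-based internally.

Genes are tied to genomes by the id convention `species|gene` (fallback:
prefix before the first underscore); a different mapping can be supplied
via the `species_fn` argument of the readers.

## Indel masking

A column is excluded family-wide iff, in at least one sequence, it lies
inside a maximal run of ≥ 2 consecutive gap characters. Isolated single
gaps are retained and treated as missing data. Only the columns of the
run itself are excluded — not a wider window around it; this is the
minimal reading of an "indel area" and keeps the rule deterministic.

## Parsimony polarization

Each retained column is analysed by unordered (Fitch) parsimony over the
20-residue alphabet on the rooted gene tree, implemented as a unit-cost
Sankoff dynamic program (this handles multifurcations and missing data
uniformly). `-` and `X` are wildcards: zero cost for every state. A
wildcard leaf can always copy its parent at zero cost, so it never
nominates an event on its own terminal branch.

Every most parsimonious reconstruction (MPR) places exactly
`parsimony_score` changes. An event (branch, source → dest) is
**unambiguous** iff it is identical in every MPR. This is decided exactly,
without enumeration, from inside/outside DP marginals: for a branch
(v → c), `J(s, t) = out(v, s) + [s ≠ t] + in(c, t)` is the best total cost
with v = s and c = t; the event (c, s → t) is possible iff J(s, t) equals
the score, and universal iff additionally no same-state pair and no other
event on that branch attains the score. On a rooted tree this subsumes
outgroup polarization; in particular a single change straddling the root
is always ambiguous because its direction flips between the root's two
child branches across co-optimal reconstructions.

Per site the package emits `parsimony_score` records: the universal
events as unambiguous records, and one ambiguous record per remaining
event slot. Because no canonical per-slot attribution exists, all
ambiguous slots of a site share the same alternatives list (the union of
non-universal possible events); record order is branch preorder index,
then residue pair, making output deterministic. Full enumeration of MPR
labelings is also available (`enumerate_mprs`), capped at 10,000 labelings
per site so pathological columns cannot stall the pipeline; the cap never
affects ambiguity classification, which comes from the marginals. The
test suite cross-checks marginals against exhaustive enumeration and the
DP score against a brute-force oracle.

Ambiguity counting: a multi-alternative event contributes one record to
family-level totals; branch-resolved tallies (flux, clade counts) weight
each alternative 1/n_alternatives (`split` mode) or drop ambiguous records
(`exclude` mode), configurable via `ambiguous_weighting`.

## Reconciliation and branch classes

Duplications are found by LCA mapping: M(leaf) = the gene's species;
M(v) = species-tree LCA of the children's images; v is a duplication iff
M(v) = M(child) for some child. With the gene tree taken as correct this
is the standard most-parsimonious placement; a pre-reconciled tree with
`D`-suffixed internal labels can bypass it (`reconcile_from_labels`).

For each duplication, its two child subtrees (child branch included) are
the two clades; clade 1 is the one holding the lexicographically smallest
leaf label. `depth_ks`, the sum of branch lengths from the root down to
and including the duplication's incoming branch, is an explicit age
*proxy* — no absolute dating is attempted. A duplication is *terminal*
when both clades are single terminal branches.

Branches strictly below a duplication node are `duplicated`; all other
branches are `single_copy_in_dup_family` when the family has at least one
duplication, else `single_copy_no_dup_family`. The duplication node's own
incoming branch is single-copy: a substitution there is not more terminal
than the duplication event.

## Metrics

- Flux: D(a) = (C(a) − R(a))/(C(a) + R(a)); per unordered pair,
  D_pair = (N(x→y) − N(y→x))/(N(x→y) + N(y→x)), antisymmetric by
  construction, undefined (and excluded) for pairs with no observations.
  ΣC = ΣR = total counted substitutions for every branch filter.
- Radicality (unambiguous records only): ΔPolarity = polarity(dest) −
  polarity(source) on the Grantham (1974) scale (AAIndex GRAR740102,
  bundled; replaceable by accession file); exchangeability EX(source →
  dest) from a bundled 20×20 matrix. The bundled matrix is a **synthetic**
  stand-in derived deterministically from the polarity scale (header in
  the data file documents the construction); experimental matrices load
  via `exchangeability_path`. All 380 off-diagonal cells are validated at
  load time.
- Ka/Ks: per family and branch class, Ka = n_substitutions / n_unmasked
  sites, Ks = summed branch lengths of the class, Ka/Ks = Ka/Ks. The site
  denominator uses unmasked columns, for consistency with the search
  space actually scanned for substitutions. Zero-Ks classes with
  substitutions yield a null Ka/Ks plus a logged warning.
- Clade asymmetry: per clade, rate = count/clade_Ks (ambiguous split-
  weighted), mean |ΔPolarity| and mean EX over unambiguous records;
  A = |x₁ − x₂|/(x₁ + x₂) ∈ [0, 1], undefined at 0/0. The rate
  denominator is clade Ks (not sites), matching the Ka/Ks logic.
- Category aggregation: families without annotation are excluded; a
  family appears once per annotated reference-species paralog; means and
  standard errors are unweighted across those entries.

## Statistical tests

All p-values are two-sided. Counts asymmetry: χ² heterogeneity with df=1,
expected split proportional to clade Ks by default (`chi2_null = "ks"`;
equal split selectable), no continuity correction (Yates optional).
Radicality asymmetry: Welch t-test (pooled optional), eligible only when
both clades have ≥ 2 unambiguous substitutions; ineligible tests are
reported with NaN p and excluded from the multiplicity count m. Sign
test: exact binomial(½), two-tailed by doubling the smaller tail, capped
at 1. Multiple testing: Benjamini–Hochberg step-up (per FDR level) and
Bonferroni (p ≤ α/m), applied separately per statistic family.
Correlations: Spearman (average ranks on ties) and Pearson with t-based
p-values; constant vectors are flagged undefined.

## Simulator

The generator emulates the study conditions: a random rooted bifurcating
species tree (default 12 species, exponential branch lengths with mean
0.1 Ks), gene lineages duplicating as a Poisson process at 0.05 births
per lineage per Ks unit, and site-independent CTMC sequence evolution
with expected changes per site = `sub_rate` × branch length (default 0.1
per Ks — a realistic Ka/Ks-like intensity). Both duplicate copies always
survive: no gene loss, so LCA reconciliation is an exact oracle and the
Dollo count (per-species copies − 1) equals the number of duplications.
The substitution model is symmetric-uniform or polarity-biased with
rate(x→y) ∝ exp(−strength·(P(y) − P(x))), normalised to unit mean leaving
rate; positive strength favours polar → non-polar changes, reproducing in
silico the negative D-vs-ΔPolarity relation. Root sequences are uniform
over the 20 residues. Events are drawn by per-site Gillespie simulation
and logged with branch and within-branch time; a fixed seed gives
byte-identical output.

What the simulator does **not** model: indel evolution (gap blocks are
injected post hoc to exercise the mask), rate heterogeneity across sites,
selection, gene loss, alignment error. Passing recovery tests therefore
demonstrates the correctness of the inference machinery under the model's
assumptions, not robustness to real-data artefacts.

## Problem sizes and numerical choices

Recovery checks use 50 families of 8 species and 150 sites at
`sub_rate = 0.03` — a regime where ≥ 90 % of variable sites carry exactly
one true event. Sites whose single event lies on one of the root's two
child branches are excluded from the recovery denominator: such events
are provably ambiguous on a rooted tree, so including them would measure
the tree shape, not the implementation. Flux calibration uses 50
symmetric and 30 biased replicates at `sub_rate = 0.25` (dense enough for
all 190 pairs to be observed). The χ² type-I calibration draws 1,000
duplications with Poisson(100) totals split Binomial(½) — a per-
duplication count where the χ² approximation is classically valid — and
compares the rejection rate at α = 0.05 against binomial 99 % bounds.
The convergence check (mean events/site vs rate × tree length) uses a
10,000-site family and a 3-SE band. Oracle equivalence uses 200 random
trees of ≤ 7 leaves over a 5-letter alphabet, where exhaustive
enumeration is instant.

Deterministic tie-breaks throughout: clade ordering by smallest leaf
label, record ordering by site then branch preorder index, unlabeled
internal nodes named by preorder position. Unrooted (basal trifurcation)
trees are rejected rather than auto-rooted, since polarization depends on
the root.

## Known limitations

- LCA reconciliation takes the gene tree as correct; topological error in
  the gene tree converts to spurious duplications (no rearrangement-aware
  reconciliation, no loss inference).
- The bundled exchangeability matrix is synthetic (see above); absolute
  EX values are therefore only meaningful relative to each other until an
  experimental matrix is supplied.
- Ambiguous records enter rates by split weighting; alternative
  conventions change branch-resolved counts (totals are invariant).
- The χ² heterogeneity test is approximate for small clade counts; rows
  with expected counts < 1 are flagged `low_expected`.
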