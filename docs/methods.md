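# Methods

## Filtering model

Similarity hits use the 14-column BLAST tabular dialect (`outfmt "6 std
qlen slen"`). Query coverage is (qend − qstart + 1)/qlen, computed per row;
when a query–subject pair has several HSP rows each is filtered
independently and graph construction later keeps only the best surviving
row per ordered pair (lowest E-value, ties by higher bitscore). All
thresholds are strict inequalities — a hit at exactly E = 1e-5 or exactly
50% coverage is removed — and the boundary behavior is pinned by tests.
Domain (HMM) hits are filtered the same way with E < 1e-15 and HMM coverage
(hmm_to − hmm_from + 1)/hmm_length > 80%.

## Clustering

The similarity graph has one node per protein in the species map (isolated
nodes allowed) and one undirected edge per protein pair with weight equal
to the mean of −log₁₀ max(E, 1e-200) over the one or two directed best
rows. The floor caps the weight at 200 for reported E-values of zero. Each
node gets a self-loop equal to its maximum incident weight (1.0 if
isolated), which damps oscillation in the Markov iteration.

MCL runs on the column-stochastic matrix of this graph: expansion (matrix
squaring), inflation (element-wise power 1.5, column renormalization),
pruning of entries below 1e-8 per column, until the maximum absolute change
falls below 1e-6 or 100 iterations elapse (non-convergence warns and
interprets the current matrix). Because the matrix is block-diagonal over
connected components, the iteration is run per component — an exact
decomposition, since expansion and inflation never mix blocks — which keeps
the dense linear algebra at the size of one family rather than the whole
cohort. Clusters are the attractor systems of the limit matrix: attractors
are nodes with surviving diagonal mass, attractors sharing limit-matrix
support merge into one system, and every other node joins the system
holding the largest share of its column (ties broken by the
lexicographically smallest attractor label, making the partition
deterministic and label-invariant). Inflation 1.5 is the conventional
default of OrthoMCL-style pipelines; the species-pair weight normalization
of full OrthoMCL is deliberately not implemented — the clustering here is
plain MCL on E-value weights, and all recovery results are defined against
this package's own clustering.

Retention keeps clusters with ≥ 2 members from ≥ 2 species (the OGCs) and
reports the count of excluded proteins, so the manifest can check
conservation: excluded + clustered = graph nodes.

## Phyletic classification

The nine group rules are evaluated from the clade content of an OGC's
species set (Cha = KCM ∪ ZCC): the four mixed groups record which of
Chl/Cha/Emb are present; single-lineage sets split into Emb, Chl, and —
within the charophytes — Cha (both grades present), ZCC-only, KCM-only.
The rules are mutually exclusive and exhaustive for any set of ≥ 2 species;
a property test checks exactly one rule fires on 10,000 random subsets.
Sets with fewer than two species are a hard error: retention must run
first. Clade names are a case-sensitive controlled vocabulary; unknown
clades or species are errors, not warnings.

The Venn report collapses Cha, ZCC and KCM into a single charophyte-only
region (the other six groups map 1:1); occupancy counts OGCs, not proteins,
per species and group. The per-group "max species" column reports the
observed maximum distinct species in any OGC of the group.

## Ontology and annotation transfer

OBO 1.2 files are parsed with `obonet`; only `is_a` edges are kept,
obsolete stanzas are dropped, and the package validates what the parser
does not: acyclicity, no `is_a` reference to a term without its own stanza,
and exactly one root per namespace. A term's **level** is 1 + the length of
the shortest `is_a` path to its namespace root (root = level 1). "Level" is
not standardized across GO tooling, so a longest-path convention is
available (`convention="longest"`); the shortest-path default is the common
choice. Terms deeper than the tested level are excluded, not mapped up to
ancestors: transfer is literal (no true-path propagation), and only
directly transferred terms are counted.

Transfer keeps, per query, the hits with E < 1e-10 whose reference carries
at least one GO term; among those, **all** hits tied at the minimum E-value
contribute (the plural reading of "best hits"), and the query receives the
union of their term sets. Queries without qualifying hits stay unannotated
and are excluded from enrichment denominators. Annotation percentages are
rounded half-up to two decimals, the convention that reproduces the
reference table's printed values exactly.

## Enrichment statistics

For tested group T against control C, each level-6 term observed in T gets
an exact binomial upper-tail p-value for k_T successes in n_T trials at
p₀ = k_C/n_C, computed in log space (`gammaln` + `logsumexp`) so that tiny
tails do not underflow. The two-sided variant implements the
point-probability method: sum of P(X = j) over all j with
pmf(j) ≤ pmf(k_T)·(1 + 1e-7). Both match a brute-force pmf enumeration to
≤ 1e-12 relative error for all n ≤ 25 (acceptance suite) and scipy's
`binomtest` to 1e-9 (unit test); scipy is the cross-check, never the
implementation. n_T and n_C count GO-annotated proteins only. Terms absent
from the control (p₀ = 0) are computed but flagged degenerate, never
silently dropped. Adjustment spans all tested terms within one group (one
test family per group): Holm step-down by default, Benjamini–Hochberg as an
option, both implemented from the step formulas and cross-checked against
`statsmodels`. A term is reported over-represented only when p_adj < α
**and** k_T/n_T > p₀ — the direction filter keeps two-sided runs from
reporting depletions as enrichments. The top-N report sorts significant
terms by ascending p_adj, then descending k_T/n_T, then term id.

**Known limitation — small controls.** Treating p₀ = k_C/n_C as a fixed
proportion (a one-sample binomial, not a two-proportion or hypergeometric
test) follows the analysis design this package models. It is well
calibrated only when the control is much larger than the tested group, as
in the original study (≈ 81k annotated control proteins). At the synthetic
cohort's scale (n_C ≈ n_T ≈ 500–650) the ignored sampling noise in p₀
understates the variance of k_T/n_T − p₀ by roughly 1 + n_T/n_C, so
per-term p-values are anti-conservative and the *family-wise*
false-positive rate across all level-6 terms is inflated; the
null-calibration experiment (`ogclust.experiment.null_run`, reported by
`scripts/acceptance.py` as `null_familywise_error_rate`) measures this
directly. The false-positive rate for a *single pre-specified* term remains
controlled (measured ≤ a few percent over 100 no-signal seeds in the test
suite). Users comparing groups of similar size should prefer a
two-proportion test; it is out of scope here because the package
reproduces the published design.

## Synthetic cohort

The generator emulates the study's inputs, not its biology: no sequence
evolution, no reads, no assembly artifacts. Defaults are the study's own
conditions where the study states them, and fixed artifact decisions where
it does not:

* **Panel**: 2 Chl + 2 KCM + 5 ZCC + 5 Emb = 14 species.
* **Group mixture**: the nine-group proportions of the study's cluster
  table (e.g. Chl+Cha+Emb 5031/25485, Cha+Emb 4174/25485, …), so the
  synthetic cohort reproduces the observed group balance.
* **Families**: 300 by default; presence sets are sampled uniformly over
  the sets satisfying the family's group rule, by rejection over
  independent Bernoulli(0.5) presence draws restricted to the clades the
  rule allows (species of forbidden clades carry zero probability under
  the rule, so the restriction is exact, not an approximation). 1–2
  proteins per present species; protein lengths uniform in [200, 1200]
  residues.
* **Hits**: every ordered intra-family pair gets a hit with E log-uniform
  in [1e-180, 1e-20] and coverage in (0.55, 0.95); alignment coordinates
  are synthesized to realize the coverage exactly. Self-hits are emitted
  (real search output contains them) and dropped by the filter. Two decoy
  inter-family hits per family violate the E-value threshold (E log-uniform
  in [1e-4, 1]), the coverage threshold (coverage in (0.05, 0.45)), or
  both, exercising each filter axis.
* **Ontology**: a full binary tree of depth 6 per namespace (single
  namespace by default: 63 terms, 32 at level 6).
* **GO reference**: one reference hit per query with E < 1e-10; each
  reference carries 1–3 background terms drawn uniformly from the non-root,
  non-planted terms, plus the planted level-6 term with probability 0.4 for
  proteins of the planted group (Cha+Emb by default) and 0.05 elsewhere.
* **Determinism**: one RNG stream per artifact, derived from the master
  seed by fixed labels; equal (config, seed) gives byte-identical files.

What passing tests therefore show: the filters, clustering, classification,
transfer and testing machinery are correct on inputs whose within-family
signal is clean and whose decoys are unambiguous. What they do not show:
robustness to real-data pathologies — fragmented transcripts, domain-level
chimeras, borderline homologs bridging families, uneven annotation coverage
across lineages (real charophyte annotation rates are far below the 100%
the generator produces).

## Problem sizes

The recovery experiment runs the full pipeline on 20 seeds at 300 families
(≈ 2,000 proteins, ≈ 17,000 hit rows each); the null calibration runs 200
replicates of the annotation+enrichment stages on ground-truth groups,
isolating the stage whose error rate is being measured. These sizes make
the whole suite and the reproduction script run in a few minutes on one
CPU while keeping every per-group count large enough for the statistics to
be non-trivial.
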