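# Methods

This note documents the models, rules and numerical choices behind
`metaboreg`, in the order the pipeline runs them.

## Study design and data model

The pipeline targets a three-group case/case/control design: two
parkinsonism cohorts (disease A ≈ idiopathic Parkinson's disease,
disease B ≈ vascular parkinsonism) of 9 patients each against 17
controls, profiled on a targeted HPLC-MS/MS panel of 44 metabolites —
14 amino acids (three-letter codes) and 30 acylcarnitines (named by acyl
chain, `C0` … `C18:1`, `C0` being free carnitine). Concentrations are in
µM; missing cells are missing, never zero, and are excluded pairwise per
metabolite per contrast, so effective sample sizes can differ across
metabolites. Group labels in input tables are canonicalised through an
alias map (`PD`→diseaseA, `VP`→diseaseB, `ctrl`→control, …), and
metabolite classes come from a sidecar mapping or, by default, from the
panel naming convention (`C`+digit ⇒ acylcarnitine).

## Differential screening

Per metabolite and per disease-vs-control contrast, two nonparametric
tests are run:

* **Mann–Whitney U**, two-sided. The exact null distribution of U is
  used when the smaller group has ≤ 12 observations and the pooled
  sample is tie-free; otherwise the normal approximation with midrank
  tie correction and continuity correction. With 9 vs 17 tie-free
  samples the exact branch applies.
* **Two-sample Kolmogorov–Smirnov**, D = sup|ECDF₁ − ECDF₂|. Exact when
  both groups have ≤ 12 tie-free observations (not the case at 9 vs 17,
  where the asymptotic branch is used); the exact branch is disabled
  under ties, where the exact null is biased.

Both are delegated to scipy; the test suite verifies the exact branches
against full permutation enumeration (all C(n₁+n₂, n₁) reassignments) to
1e-12. A comparison where all pooled values are identical is flagged
degenerate and returns p = 1.

**Multiplicity.** Benjamini–Hochberg is applied across the panel's
metabolites separately per test within each contrast (not pooled across
contrasts), because each disease-vs-control comparison is reported as its
own family. The alternative — pooling 2 tests × 44 metabolites into one
family — would couple the two contrasts' calls; with two tests combined
conjunctively (below) the per-test scope is also the more conservative
bookkeeping.

**Combination rule.** How the two tests combine into one significance
call is genuinely open; the default is `both` (a metabolite is
significant iff *both* BH-adjusted p-values < α = 0.05), with `either`,
`mw_only` and `ks_only` selectable and the effective rule recorded in the
run manifest. Metabolites are then classified as shared (significant in
both contrasts), A-/B-specific (exactly one), or none; these four labels
partition the panel by construction.

## Marker partition and enzyme mapping

Gene symbols are normalised (trimmed, upper-cased) and treated as sets;
duplicates collapse with a warning. The partition into A-only / B-only /
shared is an exact set operation, so |A-only| + |shared| = |set(A)|.
Significant metabolites map to conversion enzymes through a frozen
five-column table (metabolite, enzyme protein, enzyme gene, role ∈
{biosynthesis, degradation}, class ∈ {amino-acid, acylcarnitine
metabolism}). Live database queries are deliberately out of scope: a
frozen table keeps runs reproducible. The packaged
`data/enzyme_map_synthetic.tsv` is a synthetic stand-in whose enzyme
symbols are real (ALDH2, BCAT1/2, CPT1A/B/C, FAS, OCTC, FURIN, …) but
whose metabolite assignments are illustrative; analyses of real cohorts
should supply their own extraction.

## Knowledge graph

Nodes are proteins or genes. Directed edges carry one of eight kinds:
`ppi`, five protein-level regulation kinds (activity, degradation,
transport, proteolysis, catalysis), `expression_regulation`
(protein→gene), and `encodes` (gene→protein). Invariants — endpoint
typing per kind, no self-loops — are checked on every construction and
on file ingest, with line numbers in error messages. PPI is stored as two
directed edges so every template is a uniform directed pattern; a simple
path can never use both directions of one pair because it never revisits
a node. Three dialects are supported with deterministic lexicographic
writers: a six-column edge TSV (canonical; isolated nodes persist as
`#node` declaration lines), SIF with a `.nodes.tsv` sidecar carrying node
types (sign encoded as `edge_type.sign` in the relation), and GraphML.

## Pathway templates and enumeration

A template is data: an optional bounded run of intermediate-protein hops
followed by a terminal segment landing on the enzyme. The four defaults:

| id | pattern |
|----|---------|
| T1 | marker —(protein-level: ppi/activity/degradation/transport/proteolysis/catalysis)→ enzyme |
| T2 | marker —(expression)→ enzyme gene —(encodes)→ enzyme |
| T3 | marker —(ppi/any regulation)→ intermediate¹⁻ᴷ —(protein-level)→ enzyme |
| T4 | marker —(ppi/any regulation)→ intermediate¹⁻ᴷ —(expression)→ enzyme gene —(encodes)→ enzyme |

K (`max_intermediates`) defaults to 1; each additional intermediate
multiplies the search space by roughly the mean out-degree, so raising K
on dense graphs is exponential in cost. T3/T4 require ≥ 1 intermediate,
which makes the four templates pairwise disjoint by construction (no
path instance can match two of them); this is property-tested. Custom
templates load from YAML without code changes.

Enumeration is a depth-first search expanding one template step per hop,
with three rules: paths are simple (no node revisited — this also bounds
counts on cyclic graphs), two paths are distinct iff their (node
sequence, edge-type sequence) differ (parallel edges of different kinds
yield distinct paths; parallel duplicates of the same kind do not), and
all output is sorted lexicographically for reproducible diffs. Edge signs
(up/down) are carried through but not constrained by the default
templates. Missing source/target ids warn rather than fail, so marker
lists may be broader than the graph. Correctness is checked against an
independent brute-force oracle (exhaustive simple-path search plus a
literal template filter) on 100 random typed graphs.

Whether "number of regulatory connections" means path instances or
distinct marker–enzyme pairs is ambiguous in general; the default counts
path instances, with `dedupe="pairs"` as the alternative.

## Aggregation and specificity calls

Path counts form a marker × enzyme integer matrix whose row margin
(per marker, split by enzyme class) and column margin (per enzyme, split
by marker group) are the histogram contents; the total always equals the
number of enumerated paths. "Enzyme specific to a marker group" is not a
standard quantity, so this package defines it explicitly: the group with
the top count wins the call if top ≥ `min_count` (default 1) and
top / max(1, runner-up) ≥ `min_margin` (default 1.5); ties and
sub-threshold margins give `mixed`. Both thresholds are configuration and
are recorded in the manifest. Calls are invariant to input ordering.

## Synthetic data: what it emulates, what it does not

* **Panels** are log-normal per metabolite: a baseline log-location drawn
  once per metabolite (amino acids around 100 µM with log-sd 0.5,
  acylcarnitines around 1 µM with log-sd 1 — the concentration scales of
  targeted plasma panels), a shared log-scale standard deviation `cv`
  (default 0.3), and a planted shift of `log_fold_shift` (default 2.0)
  added to the log-location of effect metabolites in the corresponding
  disease group. Log-normality is the standard working model for LC-MS/MS
  concentration data. The study-condition configuration plants the
  published significance structure: 18 disease-A metabolites (alanine,
  proline, isoleucine, valine, methionine + 13 acylcarnitines) and 21
  disease-B metabolites (the same minus methionine, plus C0, C6, C10,
  C10:1), 17 shared.
* **Marker lists** contain exactly the requested overlap (defaults
  84/60/22).
* **Graphs** contain each planted (marker, enzyme, template) triple as
  one exact instance — T3/T4 get a dedicated mediator each, so planted
  counts are exact in noise-free graphs — plus Erdős–Rényi noise edges
  typed uniformly among kinds valid for their endpoints; noise never
  duplicates an existing (source, target, kind) triple, and gene nodes
  emit only their `encodes` edge.

What this does **not** emulate: metabolite–metabolite correlation,
heteroscedastic or batch-structured noise, missingness mechanisms, the
scale-free degree structure of literature-derived interaction networks,
or annotation errors. Passing tests therefore demonstrate correctness of
the statistical and combinatorial machinery under the stated generative
model, not robustness to real-data pathologies.

All generators take explicit integer seeds (no global random state);
identical configuration + seed is bit-identical, and the end-to-end
pipeline re-run with the same configuration reproduces every table and
the manifest byte for byte (manifests contain settings and content
hashes, never timestamps).

## Problem sizes and numerical choices

The test suite and the acceptance script use: 100 datasets for the
permutation-oracle comparison (n₁, n₂ ≤ 6, tolerance 1e-12), 500 null
panels for the type-I check (the mean significant fraction must stay
within three Monte-Carlo standard errors of α), 200 replicate panels for
planted-recovery power (threshold 0.9), and 100 random graphs of ≤ 12
nodes for the enumeration oracle. Text round-trips of concentration
tables are compared at 1e-9 relative tolerance (values are written with
12 significant digits).

## Known limitations

* The conjunctive default combination rule is conservative; with 9-vs-17
  exact tests its null false-call rate is far below the nominal α.
* The enzyme map ships as a synthetic stand-in (above).
* Path enumeration is exact, not sampled; on dense graphs with large K it
  is exponential. For the intended sparse curated networks with K = 1
  this is negligible.
* No statistical null model for path counts is provided (observed counts
  are not compared against randomised topologies); specificity calls are
  descriptive.
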