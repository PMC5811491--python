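# Methods

## Scope and model

The package implements a three-level comparison of two diseases'
candidate-gene catalogs:

1. **Gene level.** Evidence-source lists (core literature genes,
   computationally prioritized genes, association-study hits) are merged
   by set union into one catalog per disease, and the two catalogs are
   partitioned into A-only / shared / B-only.
2. **Function level.** Each catalog is tested for over-representation
   against an annotation collection (KEGG-style pathways, GO biological
   process) with the hypergeometric upper tail, BH-adjusted per
   collection, and the two diseases' significant terms are partitioned by
   name.
3. **Network level.** Each catalog is mapped onto a cleaned physical
   interactome; the seed-plus-first-neighbor subnetworks are intersected,
   and shared-subnetwork nodes outside both catalogs are ranked by their
   direct interactions with the diseases' common genes. Degree ≥ 5 to the
   common genes nominates a new candidate (guilt by association).

The statistical model behind step 2 is sampling without replacement:
conditioned on the margins (tested-set size *n*, term size *K*, universe
*N*), the overlap is hypergeometric under the null of no association, and
P(X ≥ k) is computed exactly via scipy's survival function. BH adjustment
uses statsmodels' step-up implementation; both are cross-checked in the
test suite against independent oracles (big-integer enumeration of the
tail; a literal implementation of the step-up definition).

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| universe *N* | annotation closure | union of all term members; the most common, fully reproducible background convention. An explicit universe may be supplied. |
| tested size *n* | mapped genes only | genes outside the universe are logged and excluded from the margins, so unmappable symbols never deflate p-values. |
| `min_overlap` | 2 | terms overlapping the tested set in fewer genes are not tested and do not enter the BH family. |
| `alpha` | 0.01 pathways, 0.05 GO-BP | conventional gates for the two collection types; one alpha per run. |
| `method` | `hypergeometric` | `ease` (overlap reduced by one, DAVID-compatible) is strictly more conservative and opt-in. |
| BH family | per collection, per gene set | matches per-run correction in the common desktop tools; never pooled across diseases or categories. |
| `edge_mode` | `seed-incident` | subnetwork edges must touch ≥ 1 seed; `induced` additionally keeps neighbor–neighbor edges among subnetwork nodes for sensitivity analysis. |
| `min_degree` | 5 | guilt-by-association threshold: direct interactions with the common genes required to call a candidate. |
| candidate target set | common genes in the network | the shared genes of both catalogs that mapped into the interactome; configurable. |
| candidate exclusion | full input catalogs | a gene on either disease list is never a "new" candidate, whether or not it mapped to the network. |

Symbol normalisation is trim-plus-uppercase only; alias/ID mapping is a
declared non-goal, keeping results a deterministic function of the input
lists. Result tables are sorted by (raw p, term name) or (degree
descending, symbol), with p-values serialized at six significant digits,
so reruns are byte-identical.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* the pipeline is
sensitive to, not the biology:

- **Annotations**: term sizes uniform in a range, members sampled without
  replacement, independently per term. Real annotations have correlated,
  nested terms; consequently real false-positive behaviour under BH can
  be worse than the independent-term benchmark measures.
- **Disease sets**: each set contains ⌈hit_fraction·|term|⌉ members of
  each of its planted terms plus uniform background genes; the two sets
  share *exactly* `shared_count` genes, drawn preferentially from terms
  planted in both diseases so the shared-pathway comparison has known
  truth. The overlap is made exact by filling the remainder of both sets
  from disjoint background pools.
- **Interactome**: independent-pair background (edge count binomial over
  allowed pairs, pairs uniform without replacement) plus candidate hubs
  wired to a prescribed number of shared genes. Pairs linking a planted
  candidate to a shared gene are excluded from the background so recorded
  and realized degrees agree exactly. Real interactomes are scale-free
  with study bias; degree structure is irrelevant to the threshold rule
  under test, and the independent-pair model admits closed-form checks. A
  degree-sequence background is noted as future work.
- One integer seed drives a hierarchical `SeedSequence`; each artifact
  has its own child stream, and emitted bundles are byte-identical under
  a fixed seed.

The study-scale preset fixes the conditions of the motivating analysis:
276- and 331-gene catalogs sharing 52 genes, 51 of which are present in
the interactome (one is deliberately isolated, exercising the
unmapped-seed path); 100 terms over a 3,000-gene universe with six
planted terms per disease (three shared, hit fraction 0.6); background
edge probability 5·10⁻⁴; 11 candidate hubs at degrees 5–9 and four decoys
at degrees 1–4. Benchmark problem sizes elsewhere (2,000-gene universes,
50 enrichment replicates, 20 interactome replicates) were chosen as the
smallest scales at which the binomial/hypergeometric expectations are
comfortably separated from their null fluctuations; all complete in
seconds.

Passing the recovery benchmarks therefore shows the *procedure* is
implemented correctly and is well-behaved under its own model; it does
not certify performance on real, correlated, biased annotation and
interaction data.

## Numerical and design choices

- The hypergeometric tail is computed in scipy's log-space survival
  function; stable for universes to ~10⁵ (interactome-scale margins yield
  p ≈ 10⁻³⁰ without underflow to zero). k = 0 returns exactly 1.
- `bh_adjust` validates p ∈ (0, 1]; adjusted values are returned in input
  order, never below raw values, capped at 1.
- Raw edge lists retain duplicates and self-interactions so cleaning can
  report exactly what it removed; cleaning is idempotent and drops nodes
  left without edges.
- An empty subnetwork intersection is a valid, flagged result, not an
  error; zero mapped seeds or zero universe-mapped genes are errors.
- The pipeline's JSON report is audited against the emitted tables
  (overlap categories, significant-term counts, candidate rows, shared
  edge counts) before it is written; the log records the background
  universe size, BH family size, and edge mode actually used.
- Where a published enrichment table is used as input (the bundled KEGG
  tables for the two disorders), its p-values are treated as descriptive
  attributes of curated rows; they are compared by term name only and are
  never recomputed or asserted numerically, since they depend on
  2017-era database snapshots.

## Known limitations

- No HGNC alias resolution or cross-species mapping: symbol mismatches
  between a gene list and an annotation/interactome release surface as
  unmapped genes rather than being rescued.
- GO term structure (parent–child propagation, topology-aware testing)
  and ClueGO-style term grouping are out of scope; terms are independent
  gene sets.
- Interactome-derived counts (subnetwork sizes, shared node/edge counts,
  specific candidate identities) depend entirely on the interaction
  snapshot supplied; the package reproduces the procedure, not any
  particular snapshot's numbers.
- The one-node discrepancy possible between role-count sums and neighbor
  counts in historical reports of this workflow is handled by computing
  all counts from the graph rather than asserting published totals.
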