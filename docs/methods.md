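# Methods

## Model and assumptions

`toxrank` treats chemical–disease evidence as three independent layers
over a shared chemical vocabulary and combines them without weighting:

1. **GWA layer.** The disease-gene panel is the union of common GWA
   variants (MAF strictly > 0.05; the boundary 0.05 is rejected, reading
   "above 5%" literally) and OMIM genes. SNPs collapse to unique gene
   symbols before any counting, and symbols are matched
   case-insensitively after trimming, since the source databases mix
   casings. Chemical–protein interactions contribute only when they are
   high-confidence, human, and free of negation ("does not affect") or
   co-treatment qualifiers. The layer score for chemical *c* is
   k/D with k = disease genes *c* interacts with and D = disease genes
   having at least one chemical interaction anywhere in the filtered
   table. D deliberately excludes chemically untouched genes: with the
   case-study panel this makes D = 54 rather than the raw 60-SNP count,
   the only reading under which the published three-decimal scores are
   integer fractions (0.574 = 31/54; 31/60 is not an integer numerator
   for any printed value).
2. **Disease-similarity layer.** The related-disease set is a curated
   subset of the target's diseasome neighbours and is supplied as
   input, not computed (eight diseases in the case study). Curated
   links (marker/mechanism, therapeutic) are always kept; inferred
   links need an inference score passing the cutoff. The published
   description is ambiguous between "above five" and "minimum of five";
   the default is the inclusive reading (≥ 5), with `strict_cutoff`
   selecting the exclusive one. The denominator is always |R| (8), not
   the number of related diseases with chemical data: the published
   scores are exact multiples of 0.125.
3. **Literature layer.** Binary membership in the review list; used as
   a retention filter, never as a summand.

**Integration.** The combined score is the mean of the two fractional
layers, computed from unrounded fractions and rounded only on output
(rounding pre-rounded layer scores gives 0.2595-style half-way
ambiguities). Ranking is combined-score-descending with a
name-ascending tie-break, which makes reruns on permuted inputs
byte-identical. Chemicals absent from a layer score 0 in it.

**Enrichment.** Over-representation only (upper tail); the exact tail
is summed in log space with `lgamma`-based binomial coefficients and a
max-shifted `fsum`, keeping tails far below 1e-300 finite. A tail whose
logarithm underflows even float64's subnormal range is clamped to
5e-324 rather than 0 so the (0, 1] contract and result ordering
survive. The Bonferroni family size is the number of categories in the
database being tested (`auto`), each database an independent family;
the published family size is not recoverable, so published corrected
values are treated as upper bounds on recomputed raw values rather than
as reproducible targets. When a database declares its universe
membership, the draw size is restricted to network ∩ universe (the
hypergeometric model samples from the universe); with only a declared
universe size N, the full network size is used against N. Both
conventions are exposed because the published counts do not determine
which was used.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `inference_cutoff` | 5.0 (inclusive) | minimum inference score for literature-inferred disease links |
| `exclude_classes` | {drug, natural} | chemical classes removed before ranking |
| `require_literature` | true | keep only review-documented candidates in the final table |
| `bonferroni_m` | auto | correction family = categories per database |
| `alpha_report` | 0.05 (inclusive) | significance label threshold in reports |
| `score_decimals` | 3 | output rounding of the ranked table |

## Synthetic knowledgebase generator

The generator emulates the statistical structure of the real inputs so
the whole pipeline is testable without the proprietary databases. Its
defaults mirror the case-study conditions: 60 SNP rows collapsing onto
54 disease genes (every gene guaranteed at least one chemical
interaction, pinning the GWA denominator), 8 related diseases among 22
diseasome neighbours, a 5515-gene enrichment universe with 206/228-gene
categories, 60 chemicals of which 10 are planted positives. Planted
positives interact with disease genes at probability 0.10 versus a 0.02
background (a 5× signal), link to related diseases at 0.50 versus 0.08,
and their networks draw category genes with probability inflated by an
enrichment factor ρ = 3 (ρ = 1 is the null). Inference scores are
gamma(2, 3)-distributed — right-skewed with mean 6, so a predictable
minority of inferred links falls below the cutoff of 5. The literature
list is the planted set plus 10% background noise. Identical seeds give
byte-identical files; ground truth is emitted as a JSON sidecar so
recovery tests never reverse-engineer the generator.

What the generator does **not** emulate: real chemical structure or
class correlations, cross-database identifier mismatches, the
heavy-tailed degree distributions of real interaction networks, or the
mechanics of the inference score itself (consumed as input). Passing
recovery tests therefore demonstrates the pipeline's correctness and
its ability to recover a planted multi-layer signal, not performance on
real knowledgebases.

Two deterministic fixtures reconstruct the published case-study inputs
from their printed summaries: the ranked-table fixture plants the
unique layer numerators reproducing every printed score (recovered by
enumerating k/54 and k/8 against the three-decimal values), and the
enrichment fixture builds the four networks (16/8/65/27 genes) around
the printed overlap gene lists, padded with synthetic filler symbols
(`SYN_*`, labelled as such) kept disjoint from the categories.

## Numerical and design choices

* Exact tail probabilities agree with brute-force draw enumeration to
  12 significant digits for every parameter combination with N ≤ 12
  (exhaustive test) and with an independent survival-function
  implementation at the published problem sizes.
* Significance labelling is inclusive at the threshold (p = α is
  significant); zero-overlap categories are labelled "n.d." rather than
  given the degenerate p = 1 label "n.s.".
* Filters are order-preserving and idempotent; every filter stage logs
  input/output row counts, and rejected rows are written to parse
  reports (row, field, reason) next to the outputs, so database-
  snapshot-dependent counts can be audited on any dataset even though
  the published ones (159/183/262 chemicals) depend on 2012 snapshots
  and are not reproducible from scratch.
* Problem sizes in the statistical test suites are chosen for the
  property being checked: null calibration uses a 400-gene universe
  with 40-gene categories and 15-gene networks over 240 seeds (the
  conservatism of a discrete test is size-independent); rank recovery
  runs the generator defaults over 50 seeds.

## Known limitations

* Cross-vocabulary chemical identifier mapping is the caller's
  responsibility; all inputs must share one `chemical_id` vocabulary.
* Corrected p-values depend on the (unstated) published family size and
  are validated only as upper bounds.
* The disease-similarity layer trusts the curated related-disease set;
  no diseasome-derived relevance ordering is computed.
* Heatmap and network rendering are out of scope: the package emits the
  plot-ready incidence matrix and Cytoscape-loadable network files.
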