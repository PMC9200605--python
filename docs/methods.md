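# Methods

## Model and procedure

The unit of analysis is the *sub-GO*: for every ontology term *R*, the
rooted subgraph consisting of *R* and its full descendant closure
(following `is_a` and `part_of` edges in reverse). Every term roots one
sub-GO, so the family of sub-GOs covers functional neighbourhoods of
every size, from single leaves to a whole namespace.

Each sample enters the analysis as a set of GO terms: the union of the
direct annotations of every gene whose interval overlaps one of the
sample's mosaic regions by at least one base pair (strand is ignored —
mosaic events are strand-agnostic; partial gene overlap counts). For one
sub-GO the pipeline is:

1. **Restriction.** Intersect each sample's term set with the sub-GO's
   nodes. Samples with empty restricted sets keep a zero row in the
   similarity matrix and a zero diagonal; samples with non-empty sets get
   a unit diagonal.
2. **Similarity.** Pairwise best-match average (BMA) of Lin term
   similarity: each term of one set is matched with its best partner in
   the other set, the directional means are averaged. Lin similarity is
   `2·IC(MICA)/(IC(t1)+IC(t2))`, zero when the denominator is zero or no
   common ancestor exists. The MICA search is restricted to the sub-GO's
   node set by default (`mica_scope="subgo"`), so two terms whose only
   shared ancestry lies outside the neighbourhood score zero there; a
   `global` scope is available for comparison.
3. **Clustering.** Ward linkage on the condensed `d = 1 − s` distance
   matrix (the squared-distance Lance–Williams update, i.e. the Ward.D2
   form), dendrogram cut at k = 2. k is fixed by design; the method asks
   a two-group question.
4. **Testing.** Two-sided exact Fisher test of the cluster × case/ctrl
   table, BH-FDR across all tested sub-GOs of the run. A sub-GO is tested
   only when at least `min_eligible` (default 2) samples *per phenotype
   class* have non-empty restricted sets; skipped sub-GOs are reported
   but excluded from the FDR family.

Results are ordered by (FDR, p, root id). "Genes under a root" are the
observed genes (present in at least one sample's region gene list) whose
annotations intersect the sub-GO — the permissive reading, used by the
detection-ratio validation.

## Information content

IC is corpus-based by default: annotations from the supplied gene→GO map
are propagated to all ancestors, `p(t)` is the fraction of annotated
genes carrying `t`, and `IC(t) = −ln p(t)` (natural log; the base cancels
in Lin's ratio). Terms absent from the corpus receive the add-one-smoothed
value `−ln(1/(N+1))`, which preserves monotonicity along parent edges. A
structure-based fallback (`p(t)` = descendant-closure share of the
namespace) is selectable for corpus-free use.

## Statistics

`fisher_exact_2x2` is exact integer arithmetic: hypergeometric point
probabilities are compared as integer numerators over the common binomial
denominator and summed exactly, so tables tied with the observed one are
resolved without floating-point fuzz; the float conversion happens once,
at the end. Zero-margin tables return p = 1 with a flag. BH adjustment
delegates to statsmodels' step-up implementation.

Under a label-exchangeable null the clustering is label-independent, so
the Fisher test is valid but — like every exact test on discrete 2×2
tables — conservative: null p-values are stochastically larger than
uniform (mean ≈ 0.6 on the default synthetic study), and p-values of
nested sub-GOs within one run are positively dependent. A
Kolmogorov–Smirnov comparison of the per-run p-value distribution against
U[0,1] therefore rejects even for a correct implementation; the
meaningful calibration statement is the one-sided one (no excess of small
p-values, no false sub-GO roots at FDR 0.05), which the test-suite and
the acceptance script both measure.

## Synthetic studies

The generators produce everything the pipeline reads. Defaults describe
one study design, chosen once:

- **Ontology**: 150 terms, single namespace; term *i* draws 1–3 parents
  uniformly from earlier terms (acyclic by construction, term 0 the
  root).
- **Annotation**: 300 genes tiled non-overlapping with jitter across 4
  chromosomes of 60 Mb; each gene draws 1–3 direct annotations with
  leaf-biased weights `1/(1+descendants)`, so low-frequency terms exist —
  the regime the method targets.
- **Cohort**: 100 cases (age 67.25 ± 9.5, 52.1% male, mirroring a
  lung-cancer-like case group) and 100 controls drawn from a 723-sample
  pool (age 65 ± 10, 50% male) by sex × age-decade matched sampling with
  largest-remainder quotas and nearest-bin fallback. Each sample carries
  1–5 uniform mosaic regions of 0.5–5 Mb; a fraction `effect` (default 1)
  of cases has one region centred on a random gene annotated under the
  planted sub-GO root. The planted root is chosen deterministically: the
  non-root term with at least two children whose branch annotates a
  number of genes closest to 20 (within 6–40).
- **Low-frequency preset** (`low_frequency_config`): a sparser 900-term
  ontology with 400 genes, 1–3 regions of 0.25–1.5 Mb, and a planted
  branch constrained to rare terms (each annotating ≤ 3 genes) with the
  signal spread at ~2 cases per planted gene
  (`cases_per_planted_gene`). Individually each planted term stays below
  10% sample frequency — too thin for a per-term Fisher test at any
  useful FDR — while the union of branch carriers still separates the
  cohort cleanly. This is the designed illustration of why sub-GO
  aggregation sees what per-term testing misses.

Every generator is a pure function of (config, seed); outputs are
byte-identical across runs. What the generators do **not** emulate:
chromosome-arm hotspot structure, mosaic cell-fraction dosage, realistic
GO term-count distributions (real annotations are far denser), or
gene-length/GC covariates. Passing tests therefore demonstrate the
statistical machinery and the low-frequency mechanism, not performance on
real cohorts.

## Numerical conventions and edge cases

- MICA ties break to the lexicographically smallest term id; runs are
  bit-reproducible for a fixed input order (clustering relies on scipy's
  deterministic merge order).
- Distance matrices with all-equal entries carry no structure: the
  cohort gets a deterministic first-vs-rest split and a `degenerate`
  flag rather than an error.
- Empty restricted sets score similarity 0 (not missing); the
  eligibility rule, not the similarity, decides testability.
- The similarity kernel precomputes a boolean ancestor matrix over the
  whole ontology (O(T²) bits) and reduces each sub-GO to dense numpy
  operations; fine up to a few thousand terms, a full-GO production run
  should batch per namespace.
- Duplicate gene symbols in the track: first occurrence wins, the rest
  are logged and dropped. GO ids in the gene→GO map that are missing
  from the ontology are dropped with a warning, not an error.

## Problem sizes

The test-suite and `scripts/acceptance.py` run the full pipeline on the
default 200-sample / 150-term study (~150 sub-GOs, about one second per
run) and the 900-term low-frequency study (~5 seconds per run), ten
seeds each where a rate is measured. These sizes were chosen as the
smallest at which clustering behaviour, FDR control and the
low-frequency contrast are all clearly expressed; the machinery itself
is size-agnostic.

## Known limitations

- The FDR family treats tested sub-GOs as exchangeable hypotheses even
  though nested sub-GOs are strongly dependent; BH remains valid under
  positive dependence but is conservative.
- Significant ancestors of a truly associated root are expected (they
  contain the signal), so gene selections at loose thresholds dilute
  toward the ontology root; the ranked output, not the flat significant
  set, is the primary result.
- Cross-namespace `part_of` edges are dropped with a warning.
- Gene-symbol matching in the detection-ratio validation is
  case-insensitive but performs no synonym resolution.
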