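"""Per-sub-GO cohort analysis: similarity, clustering, association testing.

For every sub-GO the cohort's term sets are restricted to the sub-GO's
nodes, a best-match-average Lin similarity matrix is built over all sample
pairs, samples are split into two groups by Ward clustering of the 1 - s
distances, and the cluster-by-phenotype 2x2 table is scored with the
two-sided Fisher exact test. Benjamini-Hochberg FDR is applied across all
sub-GOs actually tested in the run; sub-GO roots surviving the FDR
threshold are reported as candidate disease-associated functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .ontology import OntologyDAG, SubGO, enumerate_subgos
from .regions import SampleRecord
from .similarity import ICTable, LinKernel
from .stats import bh_fdr, fisher_exact_2x2

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise sample similarity in [0, 1].

    The diagonal is 1 for samples whose restricted term set is non-empty
    and 0 for samples with nothing under the sub-GO (those rows are all
    zero and such samples co-cluster).
    """

    sample_ids: list[str]
    values: np.ndarray


@dataclass
class SubGOResult:
    root: str
    root_name: str
    status: str  # "tested" | "skipped"
    n_eligible: int = 0
    n_eligible_case: int = 0
    n_eligible_ctrl: int = 0
    cluster_labels: dict[str, int] = field(default_factory=dict)
    table: tuple[tuple[int, int], tuple[int, int]] | None = None
    p_value: float = float("nan")
    fdr: float = float("nan")
    genes_under_root: frozenset[str] = frozenset()
    degenerate: bool = False
    zero_margin: bool = False


@dataclass
class AnalysisConfig:
    """Run-level knobs mirroring the command-line flags."""

    namespace: str | None = None
    min_subgo_nodes: int = 1
    min_eligible: int = 2  # per label class, samples with non-empty restricted sets
    fdr_threshold: float = 0.05
    mica_scope: str = "subgo"  # "subgo" | "global"
    ic_mode: str = "corpus"


def similarity_matrix(
    cohort: list[SampleRecord],
    subgo: SubGO,
    ic: ICTable,
    dag: OntologyDAG,
    mica_scope: str = "subgo",
    kernel: LinKernel | None = None,
) -> SimilarityMatrix:
    """Best-match-average Lin similarity between all sample pairs under one
    sub-GO."""
    if kernel is None:
        kernel = LinKernel(dag, ic)
    restricted = [sorted(frozenset(r.term_set) & subgo.nodes) for r in cohort]
    used = sorted({t for ts in restricted for t in ts})
    pos = {t: i for i, t in enumerate(used)}
    term_sim = kernel.term_matrix(used, restrict=subgo if mica_scope == "subgo" else None)
    idx_sets = [[pos[t] for t in ts] for ts in restricted]
    values = kernel.sample_matrix(idx_sets, term_sim)
    return SimilarityMatrix(sample_ids=[r.sample_id for r in cohort], values=values)


def ward_two_clusters(sim: SimilarityMatrix) -> tuple[np.ndarray, bool]:
    """Cut a Ward dendrogram of the 1 - s distances into two groups.

    Returns (labels in {1, 2}, degenerate flag). An all-equal distance
    matrix carries no structure; it gets a deterministic first-vs-rest
    split and the degenerate flag.
    """
    n = sim.values.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to cluster")
    dist = np.clip(1.0 - sim.values, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    degenerate = bool(np.all(condensed == condensed[0]))
    labels = fcluster(linkage(condensed, method="ward"), 2, criterion="maxclust")
    if len(np.unique(labels)) < 2:
        labels = np.full(n, 2, dtype=int)
        labels[0] = 1
        degenerate = True
    return labels.astype(int), degenerate


def contingency_from_clusters(
    cohort: list[SampleRecord],
    labels: np.ndarray,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """2x2 counts, rows = cluster 1/2, columns = case/ctrl."""
    a = sum(1 for r, l in zip(cohort, labels) if l == 1 and r.label == "case")
    b = sum(1 for r, l in zip(cohort, labels) if l == 1 and r.label == "ctrl")
    c = sum(1 for r, l in zip(cohort, labels) if l == 2 and r.label == "case")
    d = sum(1 for r, l in zip(cohort, labels) if l == 2 and r.label == "ctrl")
    return ((a, b), (c, d))


def run_subgofa(
    cohort: list[SampleRecord],
    dag: OntologyDAG,
    ic: ICTable,
    gene2go: dict[str, set[str]] | None = None,
    config: AnalysisConfig | None = None,
    subgos: list[SubGO] | None = None,
) -> list[SubGOResult]:
    """The full sub-GO scan.

    A sub-GO is eligible when at least ``config.min_eligible`` samples in
    EACH phenotype class have a non-empty restricted term set; ineligible
    sub-GOs are reported with status ``skipped`` and excluded from the FDR
    family. Tested results come back sorted by (fdr, p, root id), followed
    by the skipped ones sorted by root id.
    """
    config = config or AnalysisConfig()
    if len(cohort) < 4:
        raise ValueError("cohort must contain at least 4 annotated samples")
    if subgos is None:
        subgos = enumerate_subgos(dag, config.min_subgo_nodes, config.namespace)
    kernel = LinKernel(dag, ic)

    observed_genes: set[str] = set()
    for rec in cohort:
        observed_genes |= rec.genes
    gene_terms = {}
    if gene2go:
        gene_terms = {g: gene2go.get(g, set()) for g in observed_genes}

    tested: list[SubGOResult] = []
    skipped: list[SubGOResult] = []
    for subgo in subgos:
        restricted = [frozenset(r.term_set) & subgo.nodes for r in cohort]
        n_case = sum(1 for r, ts in zip(cohort, restricted) if ts and r.label == "case")
        n_ctrl = sum(1 for r, ts in zip(cohort, restricted) if ts and r.label == "ctrl")
        genes_under = frozenset(
            g for g, ts in gene_terms.items() if ts & subgo.nodes
        )
        result = SubGOResult(
            root=subgo.root,
            root_name=dag.names.get(subgo.root, subgo.root),
            status="tested",
            n_eligible=n_case + n_ctrl,
            n_eligible_case=n_case,
            n_eligible_ctrl=n_ctrl,
            genes_under_root=genes_under,
        )
        if n_case < config.min_eligible or n_ctrl < config.min_eligible:
            result.status = "skipped"
            skipped.append(result)
            continue
        sim = similarity_matrix(cohort, subgo, ic, dag, config.mica_scope, kernel)
        labels, degenerate = ward_two_clusters(sim)
        table = contingency_from_clusters(cohort, labels)
        fisher = fisher_exact_2x2(table)
        result.cluster_labels = {r.sample_id: int(l) for r, l in zip(cohort, labels)}
        result.table = table
        result.p_value = fisher.p_value
        result.degenerate = degenerate
        result.zero_margin = fisher.zero_margin
        tested.append(result)

    if not tested:
        logger.warning("no eligible sub-GO: every root failed the eligibility rule")
    else:
        fdrs = bh_fdr([r.p_value for r in tested])
        for r, q in zip(tested, fdrs):
            r.fdr = float(q)
    tested.sort(key=lambda r: (r.fdr, r.p_value, r.root))
    skipped.sort(key=lambda r: r.root)
    return tested + skipped


def significant_results(
    results: list[SubGOResult],
    threshold: float = 0.05,
    mode: str = "fdr",
) -> list[SubGOResult]:
    key = (lambda r: r.fdr) if mode == "fdr" else (lambda r: r.p_value)
    return [r for r in results if r.status == "tested" and key(r) <= threshold]
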