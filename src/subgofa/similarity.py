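"""Information content and Lin semantic similarity, restrictable to a sub-GO.

IC of a term is the negative natural log of its annotation probability in a
gene corpus, with annotations propagated upward (a gene annotated to a term
is implicitly annotated to every ancestor). The Lin similarity of two terms
is ``2*IC(MICA) / (IC(t1) + IC(t2))`` where the MICA is their most
informative common ancestor. Restricting the MICA search to a sub-GO's node
set is what lets a small functional neighbourhood express a similarity
signal that a whole-ontology comparison would average away.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ontology import OntologyDAG, SubGO


@dataclass
class ICTable:
    """Per-term information content (natural-log units) plus corpus size."""

    ic: dict[str, float]
    corpus_size: int

    def __getitem__(self, term: str) -> float:
        return self.ic[term]


def compute_ic(
    dag: OntologyDAG,
    gene2go: dict[str, set[str]],
    mode: str = "corpus",
) -> ICTable:
    """Information content of every term in ``dag``.

    ``mode="corpus"`` (default): propagate each gene's annotations to all
    ancestors; ``p(t)`` is the fraction of annotated genes carrying ``t``
    after propagation and ``IC(t) = -ln p(t)``. Terms never annotated get
    add-one smoothed IC ``-ln(1/(corpus_size+1))`` so they stay finite.

    ``mode="structure"`` ignores the corpus: ``p(t)`` is the fraction of the
    term's namespace covered by its descendant closure (self included).
    """
    if mode == "structure":
        ns_size = {ns: sum(1 for t in dag.terms if dag.namespace[t] == ns)
                   for ns in dag.namespaces_present()}
        ic = {
            t: -math.log(len(dag.descendants(t)) / ns_size[dag.namespace[t]]) + 0.0
            for t in dag.terms
        }
        return ICTable(ic=ic, corpus_size=len(dag.terms))
    if mode != "corpus":
        raise ValueError(f"unknown IC mode {mode!r}")

    counts: dict[str, int] = {t: 0 for t in dag.terms}
    n_genes = 0
    for gene in sorted(gene2go):
        terms = gene2go[gene]
        missing = terms - dag.terms
        if missing:
            raise KeyError(
                f"gene {gene} annotated to unknown terms {sorted(missing)}"
            )
        if not terms:
            continue
        n_genes += 1
        propagated: set[str] = set()
        for t in terms:
            propagated.update(dag.ancestors(t))
        for t in propagated:
            counts[t] += 1
    if n_genes == 0:
        raise ValueError("empty annotation corpus: no gene carries any term")

    smoothed = -math.log(1.0 / (n_genes + 1))
    ic = {
        t: (-math.log(c / n_genes) + 0.0 if c > 0 else smoothed)
        for t, c in counts.items()
    }
    return ICTable(ic=ic, corpus_size=n_genes)


def mica(
    t1: str,
    t2: str,
    dag: OntologyDAG,
    ic: ICTable,
    restrict: SubGO | None = None,
) -> str | None:
    """Most informative common ancestor (self-inclusive), or None.

    When ``restrict`` is given the ancestor search is intersected with the
    sub-GO's node set. Ties on IC break toward the lexicographically
    smallest term id so runs are bit-reproducible.
    """
    common = dag.ancestors(t1) & dag.ancestors(t2)
    if restrict is not None:
        common &= restrict.nodes
    if not common:
        return None
    return min(common, key=lambda t: (-ic[t], t))


def lin_similarity(
    t1: str,
    t2: str,
    dag: OntologyDAG,
    ic: ICTable,
    restrict: SubGO | None = None,
) -> float:
    """Lin similarity ``2*IC(MICA)/(IC(t1)+IC(t2))`` in [0, 1].

    Zero when the terms share no (restricted) ancestor or when both terms
    are uninformative (IC sum is zero).
    """
    m = mica(t1, t2, dag, ic, restrict)
    if m is None:
        return 0.0
    denom = ic[t1] + ic[t2]
    if denom <= 0.0:
        return 0.0
    return 2.0 * ic[m] / denom + 0.0


def set_similarity(
    set_a: set[str] | frozenset[str],
    set_b: set[str] | frozenset[str],
    dag: OntologyDAG,
    ic: ICTable,
    restrict: SubGO | None = None,
) -> float:
    """Best-match-average similarity between two term sets.

    Each term of A is matched to its most similar term of B and vice versa;
    the two directional means are averaged. Empty sets score 0 by
    convention — eligibility filtering happens downstream.
    """
    if not set_a or not set_b:
        return 0.0
    a_to_b = [max(lin_similarity(a, b, dag, ic, restrict) for b in set_b) for a in set_a]
    b_to_a = [max(lin_similarity(b, a, dag, ic, restrict) for a in set_a) for b in set_b]
    return 0.5 * (sum(a_to_b) / len(a_to_b) + sum(b_to_a) / len(b_to_a))


class LinKernel:
    """Vectorised Lin similarity over a fixed term universe.

    Precomputes the boolean ancestor matrix and IC vector once per ontology
    so that per-sub-GO pairwise term similarities and sample-level
    best-match-average matrices reduce to dense numpy operations. Memory is
    O(|terms|^2) bits, which is fine for ontologies up to a few thousand
    terms; production-scale runs over the full GO should batch by namespace.
    """

    def __init__(self, dag: OntologyDAG, ic: ICTable):
        self.dag = dag
        self.ic = ic
        self.terms = sorted(dag.terms)
        self.index = {t: i for i, t in enumerate(self.terms)}
        n = len(self.terms)
        self.anc = np.zeros((n, n), dtype=bool)
        for t in self.terms:
            i = self.index[t]
            cols = [self.index[a] for a in dag.ancestors(t)]
            self.anc[i, cols] = True
        self.ic_vec = np.array([ic[t] for t in self.terms])

    def term_matrix(
        self,
        used_terms: list[str],
        restrict: SubGO | None = None,
    ) -> np.ndarray:
        """Pairwise Lin similarity for ``used_terms`` (MICA search optionally
        restricted to a sub-GO)."""
        rows = [self.index[t] for t in used_terms]
        if restrict is not None:
            space = np.array(sorted(self.index[t] for t in restrict.nodes), dtype=int)
        else:
            space = np.arange(len(self.terms))
        anc = self.anc[np.ix_(rows, space)]
        ic_space = self.ic_vec[space]
        u = len(rows)
        ic_used = self.ic_vec[rows]
        sim = np.zeros((u, u))
        for i in range(u):
            common = anc & anc[i]
            masked = np.where(common, ic_space, -1.0)
            best = masked.max(axis=1)  # -1 marks "no common ancestor"
            denom = ic_used + ic_used[i]
            with np.errstate(divide="ignore", invalid="ignore"):
                row = np.where((best >= 0) & (denom > 0), 2.0 * best / denom, 0.0)
            sim[i] = row
        return sim

    def sample_matrix(
        self,
        term_sets: list[list[int]],
        term_sim: np.ndarray,
    ) -> np.ndarray:
        """Symmetric best-match-average matrix over samples.

        ``term_sets`` holds, per sample, indices into the rows of
        ``term_sim`` (its restricted term set). Empty sets give zero rows;
        the diagonal is 1 for non-empty sets and 0 for empty ones.
        """
        n = len(term_sets)
        u = term_sim.shape[0]
        if u == 0:
            out = np.zeros((n, n))
            return out
        best = np.zeros((u, n))
        weights = np.zeros((u, n))
        nonempty = np.array([len(s) > 0 for s in term_sets])
        for j, idx in enumerate(term_sets):
            if idx:
                best[:, j] = term_sim[:, idx].max(axis=1)
                weights[idx, j] = 1.0 / len(idx)
        directional = weights.T @ best  # (i,j): mean over i's terms of best match in j
        sim = 0.5 * (directional + directional.T)
        sim[~nonempty, :] = 0.0
        sim[:, ~nonempty] = 0.0
        np.fill_diagonal(sim, np.where(nonempty, 1.0, 0.0))
        return np.clip(sim, 0.0, 1.0)
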