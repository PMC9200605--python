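"""Similarity matrices, Ward clustering and the full sub-GO scan."""

import numpy as np
import pytest

from subgofa import (
    AnalysisConfig,
    SampleRecord,
    SimilarityMatrix,
    compute_ic,
    run_subgofa,
    set_similarity,
    similarity_matrix,
    ward_two_clusters,
)

from conftest import TOY_CORPUS, make_toy_dag


def sample(sid, label, terms):
    return SampleRecord(sample_id=sid, label=label, term_set=frozenset(terms))


@pytest.fixture
def toy():
    dag = make_toy_dag()
    return dag, compute_ic(dag, TOY_CORPUS)


class TestSimilarityMatrix:
    def test_identical_sets_score_one(self, toy):
        dag, ic = toy
        cohort = [sample("s1", "case", {"c", "d"}), sample("s2", "ctrl", {"c", "d"})]
        sim = similarity_matrix(cohort, dag.subgo("r"), ic, dag)
        assert sim.values[0, 1] == pytest.approx(1.0)
        assert sim.values[0, 0] == 1.0

    def test_empty_restricted_set_gives_zero_row(self, toy):
        dag, ic = toy
        cohort = [sample("s1", "case", {"e"}), sample("s2", "ctrl", {"c"})]
        sim = similarity_matrix(cohort, dag.subgo("a"), ic, dag)
        assert sim.values[0].sum() == 0.0  # e is outside sub-GO(a); diagonal 0
        assert sim.values[1, 1] == 1.0

    def test_two_block_structure(self, toy):
        dag, ic = toy
        cohort = [
            sample("s1", "case", {"c"}), sample("s2", "case", {"c"}),
            sample("s3", "ctrl", {"e"}), sample("s4", "ctrl", {"e"}),
        ]
        sim = similarity_matrix(cohort, dag.subgo("r"), ic, dag)
        assert sim.values[0, 1] == pytest.approx(1.0)
        assert sim.values[2, 3] == pytest.approx(1.0)
        assert sim.values[0, 2] == pytest.approx(0.0)  # c and e meet only at the root

    @pytest.mark.parametrize("scope", ["subgo", "global"])
    def test_matches_scalar_bma(self, toy, scope):
        dag, ic = toy
        cohort = [
            sample("s1", "case", {"c", "f"}), sample("s2", "case", {"d"}),
            sample("s3", "ctrl", {"c", "d", "f"}), sample("s4", "ctrl", {"a"}),
        ]
        subgo = dag.subgo("a")
        sim = similarity_matrix(cohort, subgo, ic, dag, mica_scope=scope)
        restrict = subgo if scope == "subgo" else None
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                expected = set_similarity(
                    cohort[i].term_set & subgo.nodes,
                    cohort[j].term_set & subgo.nodes,
                    dag, ic, restrict=restrict,
                )
                assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)


class TestWard:
    def test_perfect_blocks_recovered(self):
        values = np.zeros((6, 6))
        values[:3, :3] = 1.0
        values[3:, 3:] = 1.0
        sim = SimilarityMatrix([f"s{i}" for i in range(6)], values)
        labels, degenerate = ward_two_clusters(sim)
        assert not degenerate
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_two_samples_split(self):
        sim = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        labels, _ = ward_two_clusters(sim)
        assert sorted(labels) == [1, 2]

    def test_noisy_planted_blocks(self):
        rng = np.random.default_rng(42)
        n = 20
        planted = np.array([0] * 10 + [1] * 10)
        values = np.where(planted[:, None] == planted[None, :], 0.9, 0.1)
        noise = rng.normal(0, 0.03, (n, n))
        values = np.clip(values + (noise + noise.T) / 2, 0, 1)
        np.fill_diagonal(values, 1.0)
        labels, _ = ward_two_clusters(SimilarityMatrix([str(i) for i in range(n)], values))
        agree = max(np.sum((labels == 1) == (planted == 0)),
                    np.sum((labels == 2) == (planted == 0)))
        assert agree >= 18

    def test_all_identical_flagged_degenerate(self):
        sim = SimilarityMatrix(["a", "b", "c", "d"], np.ones((4, 4)))
        labels, degenerate = ward_two_clusters(sim)
        assert degenerate
        assert sorted(set(labels)) == [1, 2]  # deterministic fallback split


class TestRunSubgofa:
    def _cohort(self):
        # two cases carrying c-side terms, two plus controls on the e side
        cohort = []
        for i in range(4):
            cohort.append(sample(f"case{i}", "case", {"c", "f"}))
        for i in range(4):
            cohort.append(sample(f"ctrl{i}", "ctrl", {"e"}))
        return cohort

    def test_separating_subgo_found(self, toy):
        dag, ic = toy
        results = run_subgofa(self._cohort(), dag, ic)
        tested = {r.root: r for r in results if r.status == "tested"}
        assert "r" in tested
        best = min(tested.values(), key=lambda r: r.p_value)
        assert best.p_value == pytest.approx(2 / 70, rel=1e-9)  # 4v4 clean split

    def test_identical_term_sets_yield_no_signal(self, toy):
        dag, ic = toy
        cohort = [sample(f"s{i}", "case" if i < 4 else "ctrl", {"c", "e"})
                  for i in range(8)]
        results = run_subgofa(cohort, dag, ic)
        for r in results:
            if r.status == "tested":
                assert r.fdr == 1.0 or r.p_value == 1.0

    def test_sample_order_invariance_of_pvalues(self, toy):
        dag, ic = toy
        cohort = self._cohort()
        res_fwd = run_subgofa(cohort, dag, ic)
        res_rev = run_subgofa(cohort[::-1], dag, ic)
        p_fwd = {r.root: r.p_value for r in res_fwd if r.status == "tested"}
        p_rev = {r.root: r.p_value for r in res_rev if r.status == "tested"}
        assert p_fwd.keys() == p_rev.keys()
        for root in p_fwd:
            assert p_fwd[root] == pytest.approx(p_rev[root], rel=1e-12)

    def test_cluster_relabeling_leaves_fisher_invariant(self, toy):
        from subgofa.stats import fisher_exact_2x2
        dag, ic = toy
        results = run_subgofa(self._cohort(), dag, ic)
        for r in results:
            if r.status != "tested":
                continue
            (a, b), (c, d) = r.table
            assert fisher_exact_2x2(((c, d), (a, b))).p_value == pytest.approx(
                r.p_value, rel=1e-12
            )

    def test_eligibility_rule_skips_sparse_subgos(self, toy):
        dag, ic = toy
        cohort = self._cohort()
        results = run_subgofa(cohort, dag, ic)
        by_root = {r.root: r for r in results}
        # no control carries anything under sub-GO(a), so it cannot be tested
        assert by_root["a"].status == "skipped"
        assert by_root["a"].n_eligible_ctrl == 0

    def test_results_sorted_by_fdr_then_p_then_root(self, toy):
        dag, ic = toy
        results = [r for r in run_subgofa(self._cohort(), dag, ic) if r.status == "tested"]
        keys = [(r.fdr, r.p_value, r.root) for r in results]
        assert keys == sorted(keys)

    def test_fdr_family_excludes_skipped(self, toy):
        dag, ic = toy
        results = run_subgofa(self._cohort(), dag, ic)
        tested = [r for r in results if r.status == "tested"]
        for r in tested:
            assert r.fdr >= r.p_value - 1e-15
        for r in results:
            if r.status == "skipped":
                assert np.isnan(r.fdr)
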