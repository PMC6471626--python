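import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from grangernet import (
    GCResult,
    LagSpec,
    attach_qvalues,
    build_graph,
    candidate_mediators,
    make_motif,
    pairwise_scan,
    prune_graph,
    simulate_var,
    storey_qvalues,
)


class TestStoreyQvalues:
    def test_all_ones(self):
        q = storey_qvalues(np.ones(20))
        np.testing.assert_array_equal(q.q_values, np.ones(20))

    def test_bh_hand_example(self):
        # q_(i) = min_{j>=i} m p_(j)/j with pi0=1: all four collapse to 0.04
        q = storey_qvalues([0.01, 0.02, 0.03, 0.04], pi0_method="bh")
        np.testing.assert_allclose(q.q_values, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_bh_equals_statsmodels_bh(self):
        rng = np.random.default_rng(8)
        p = rng.random(500)
        q = storey_qvalues(p, pi0_method="bh")
        _, q_sm, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q.q_values, q_sm, atol=1e-12)

    def test_pi0_calibrated_under_null(self):
        """Median pi0 over null replicates is near 1; estimates never exceed 1."""
        estimates = [
            storey_qvalues(np.random.default_rng(s).random(1000)).pi0_estimate
            for s in range(20)
        ]
        assert all(e <= 1.0 for e in estimates)
        assert 0.85 <= float(np.median(estimates)) <= 1.0

    def test_pi0_shrinks_under_strong_alternative(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.random(300), rng.random(700) * 1e-4])
        q = storey_qvalues(p)
        assert q.pi0_estimate < 0.6

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            storey_qvalues([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p=st.lists(st.floats(0, 1), min_size=2, max_size=60),
        method=st.sampled_from(["smoother", "fixed_lambda", "bh"]),
    )
    def test_q_monotone_in_p(self, p, method):
        q = storey_qvalues(p, pi0_method=method).q_values
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0 + 1e-12)


def _res(src, tgt, p_value, status="ok"):
    return GCResult(src, tgt, 1, 0.1, 2.0, 1, 40, p_value, None, status)


class TestBuildGraph:
    def test_requires_qvalues(self):
        with pytest.raises(ValueError, match="q-values"):
            build_graph([_res("A", "B", 0.01)])

    def test_threshold_selects_edges(self):
        results = [_res("A", "B", 0.001), _res("B", "A", 0.9),
                   _res("A", "C", 0.8), _res("C", "A", 0.7),
                   _res("B", "C", 0.95), _res("C", "B", 0.99)]
        attach_qvalues(results, pi0_method="bh")
        g = build_graph(results, 0.05)
        assert g.edge_set() == {("A", "B")}
        assert g.isolated_vertices == ["C"]

    def test_all_nonsignificant_empty(self):
        results = [_res("A", "B", 0.9), _res("B", "A", 0.8)]
        attach_qvalues(results, pi0_method="bh")
        g = build_graph(results, 0.05)
        assert g.edge_set() == set()
        assert set(g.vertices) == {"A", "B"}

    def test_degenerate_excluded_from_family(self):
        results = [_res("A", "B", 0.001), _res("B", "A", np.nan, status="degenerate"),
                   _res("A", "C", 0.5), _res("C", "A", 0.6),
                   _res("B", "C", 0.7), _res("C", "B", 0.8)]
        qset = attach_qvalues(results, pi0_method="bh")
        assert len(qset.p_values) == 5  # family excludes the degenerate pair
        g = build_graph(results, 0.05)
        n = 3
        n_ok_nonsig = sum(1 for r in results if r.status == "ok" and r.q_value >= 0.05)
        n_degen = sum(1 for r in results if r.status == "degenerate")
        assert len(g.directed_edges) + n_ok_nonsig + n_degen == n * (n - 1)

    def test_cycle_warning(self):
        results = [_res("A", "B", 0.0001), _res("B", "A", 0.0001)]
        attach_qvalues(results, pi0_method="bh")
        with pytest.warns(UserWarning, match="cycles"):
            build_graph(results, 0.05)


class TestPruneGraph:
    def test_no_two_paths_returned_unchanged(self):
        results = [_res("A", "B", 0.001), _res("B", "A", 0.9),
                   _res("A", "C", 0.8), _res("C", "A", 0.7),
                   _res("B", "C", 0.95), _res("C", "B", 0.99)]
        attach_qvalues(results, pi0_method="bh")
        g = build_graph(results, 0.05)
        table, _ = simulate_var(make_motif("chain", T=100, seed=0))
        table.var_ids = ["A", "B", "C"]  # relabel to match the graph
        pruned = prune_graph(g, table)
        assert pruned.edge_set() == g.edge_set()
        assert pruned.pruned_edges == []

    def test_chain_spurious_edge_pruned_majority(self):
        import warnings

        n_sig = n_pruned = kept_true = det_true = 0
        for seed in range(100):
            table, _ = simulate_var(make_motif("chain", T=300, seed=seed))
            results = pairwise_scan(table, LagSpec(p=1, selection="fixed"))
            attach_qvalues(results, pi0_method="bh")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                graph = build_graph(results, 0.05, table.class_map())
                pruned = prune_graph(graph, table)
            if ("Y", "X") in graph.edge_set():
                n_sig += 1
                if ("Y", "X") not in pruned.edge_set():
                    n_pruned += 1
            for e in [("Y", "Z"), ("Z", "X")]:
                if e in graph.edge_set():
                    det_true += 1
                    if e in pruned.edge_set():
                        kept_true += 1
        assert n_sig >= 5  # the spurious edge does appear
        assert n_pruned / n_sig >= 0.8
        assert kept_true / det_true >= 0.95

    def test_idempotent(self):
        import warnings

        table, _ = simulate_var(make_motif("chain", T=300, seed=1))
        results = pairwise_scan(table, LagSpec(p=1, selection="fixed"))
        attach_qvalues(results, pi0_method="bh")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = build_graph(results, 0.05, table.class_map())
            once = prune_graph(graph, table)
            twice = prune_graph(once, table)
        assert twice.edge_set() == once.edge_set()
        assert {(e.source_id, e.target_id) for e in twice.pruned_edges} == {
            (e.source_id, e.target_id) for e in once.pruned_edges
        }

    def test_variable_mismatch_rejected(self):
        results = [_res("A", "B", 0.001), _res("B", "A", 0.9)]
        attach_qvalues(results, pi0_method="bh")
        g = build_graph(results, 0.05)
        table, _ = simulate_var(make_motif("chain", T=100, seed=0))
        with pytest.raises(ValueError, match="absent"):
            prune_graph(g, table)


class TestCandidateMediators:
    def test_two_path_policy(self):
        results = [_res("A", "B", 0.001), _res("B", "C", 0.001),
                   _res("A", "C", 0.001), _res("C", "A", 0.9),
                   _res("B", "A", 0.9), _res("C", "B", 0.9)]
        attach_qvalues(results, pi0_method="bh")
        g = build_graph(results, 0.05)
        assert candidate_mediators(g, "A", "C", "two_path") == ["B"]
        assert candidate_mediators(g, "A", "B", "two_path") == []

    def test_all_policy(self):
        results = [_res("A", "B", 0.001), _res("B", "A", 0.9),
                   _res("A", "C", 0.8), _res("C", "A", 0.7),
                   _res("B", "C", 0.95), _res("C", "B", 0.99)]
        attach_qvalues(results, pi0_method="bh")
        g = build_graph(results, 0.05)
        assert candidate_mediators(g, "A", "B", "all") == ["C"]
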