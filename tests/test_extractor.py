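import numpy as np
import pytest

from pkddi import extractor, synthetic
from pkddi.extractor import (CandidateInstance, DepGraph, DepToken,
                             EvalReport, all_paths_weights, build_graph,
                             collapse_labels, fallback_parse,
                             generate_candidates, kernel, kernel_matrix,
                             prepare_entities, read_conllu, write_conllu)
from pkddi.tagger import tag_all


def truncated_path_sum(graph, max_len=200):
    """Oracle: explicit truncated sum of adjacency powers A + A^2 + ..."""
    a = graph.adjacency()
    total = np.zeros_like(a)
    power = np.eye(graph.n)
    for _ in range(max_len):
        power = power @ a
        total += power
    return total


def enumerate_paths(graph, source, target, max_len):
    """Second oracle: direct DFS enumeration of all directed paths
    (revisits allowed) up to max_len edges, summing weight products."""
    adj = {}
    for u, v, w in graph.edges:
        adj.setdefault(u, []).append((v, w))
    total = 0.0
    stack = [(source, 1.0, 0)]
    while stack:
        node, weight, length = stack.pop()
        if length > 0 and node == target:
            total += weight
        if length < max_len:
            for nxt, w in adj.get(node, []):
                stack.append((nxt, weight * w, length + 1))
    return total


def random_graph(rng, max_vertices=6, edge_prob=0.3, max_weight=0.5):
    """Random sparse graph with spectral radius below 1."""
    while True:
        n = int(rng.integers(2, max_vertices + 1))
        edges = []
        for u in range(n):
            for v in range(n):
                if u != v and rng.random() < edge_prob:
                    edges.append((u, v,
                                  float(rng.uniform(0.05, max_weight))))
        labels = [frozenset({f"L{int(rng.integers(0, 4))}"})
                  for _ in range(n)]
        g = DepGraph(n, labels, edges)
        radius = float(np.max(np.abs(np.linalg.eigvals(g.adjacency()))))
        if radius < 0.9:
            return g


class TestEntitiesAndCandidates:
    def test_metabolites_removed(self, lex):
        terms = tag_all("verapamil norverapamil lovastatin", 0, lex)
        kept = prepare_entities(terms)
        assert [t.normal_form for t in kept] == ["verapamil", "lovastatin"]

    def test_enzymes_pairable(self, lex):
        terms = tag_all("ketoconazole and CYP3A4", 0, lex)
        kept = prepare_entities(terms)
        assert [t.normal_form for t in kept] == ["ketoconazole", "CYP3A4"]

    def test_synonym_mentions_collapse(self, lex):
        terms = tag_all("verapamil then verapamil again", 0, lex)
        assert len(prepare_entities(terms)) == 1

    def test_empty(self):
        assert prepare_entities([]) == []

    @pytest.mark.parametrize("n,expected", [(0, 0), (1, 0), (3, 3),
                                            (5, 10)])
    def test_candidate_counts(self, n, expected):
        assert len(generate_candidates(list(range(n)))) == expected

    def test_collapse_labels_total_and_idempotent(self):
        truth = {"DDI": True, "DEI": True, "ADDI": False, "NDDI": False,
                 "ADEI": False, "NDEI": False, "NONE": False}
        for label, expected in truth.items():
            assert collapse_labels(label) is expected


class TestParses:
    def test_conllu_round_trip(self, tmp_path):
        parses = [fallback_parse("A inhibits B"),
                  fallback_parse("The AUC of midazolam increased.")]
        path = tmp_path / "parses.conllu"
        write_conllu(parses, path)
        assert read_conllu(path) == parses

    def test_ten_column_conllu(self, tmp_path):
        path = tmp_path / "ud.conllu"
        path.write_text(
            "# sent_id = 1\n"
            "1\tA\ta\tNN\t_\t_\t0\troot\t_\t_\n"
            "2\tinhibits\tinhibit\tVB\t_\t_\t1\tdep\t_\t_\n\n")
        (parse,) = read_conllu(path)
        assert parse == [DepToken("A", "a", "NN", 0, "root"),
                         DepToken("inhibits", "inhibit", "VB", 1, "dep")]

    def test_fallback_parse_is_chain(self):
        parse = fallback_parse("A inhibits B")
        assert [t.head for t in parse] == [0, 1, 2]

    def test_bad_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.conllu"
        path.write_text("only\ttwo\n")
        with pytest.raises(ValueError, match=":1"):
            read_conllu(path)


class TestBuildGraph:
    def test_three_token_sentence_structure(self):
        parse = fallback_parse("A inhibits B")
        g = build_graph(parse, (0, 2))
        assert g.n == 6
        # chain edges 0->1->2 all lie on the shortest path
        dep_edges = {(u, v): w for u, v, w in g.edges if u < 3 and v < 3}
        assert dep_edges == {(0, 1): 0.9, (1, 2): 0.9}
        lin_edges = {(u, v): w for u, v, w in g.edges if u >= 3}
        assert lin_edges == {(3, 4): 0.9, (4, 5): 0.9}

    def test_pair_vertices_anonymized(self):
        parse = fallback_parse("verapamil inhibits lovastatin")
        g = build_graph(parse, (0, 2), other_entities=())
        assert "ENTITY1" in g.labels[0] and "verapamil" not in g.labels[0]
        assert "ENTITY2" in g.labels[2]

    def test_other_entities_anonymized(self):
        parse = fallback_parse("verapamil midazolam lovastatin")
        g = build_graph(parse, (0, 2), other_entities=(1,))
        assert "ENTITY" in g.labels[1]

    def test_off_path_edges_get_low_weight(self):
        # head structure: 1 -> 0, 1 -> 2, 1 -> 3; pair (0, 2) leaves the
        # edge to 3 off the shortest path
        parse = [DepToken("a", "a", "NN", 2), DepToken("b", "b", "VB", 0),
                 DepToken("c", "c", "NN", 2), DepToken("d", "d", "NN", 2)]
        g = build_graph(parse, (0, 2))
        weights = {(u, v): w for u, v, w in g.edges}
        assert weights[(1, 0)] == 0.9 and weights[(1, 2)] == 0.9
        assert weights[(1, 3)] == 0.3

    def test_misaligned_pair_errors(self):
        with pytest.raises(ValueError):
            build_graph(fallback_parse("one two"), (0, 5))


class TestAllPathsWeights:
    def test_single_edge(self):
        g = DepGraph(2, [frozenset({"a"}), frozenset({"b"})],
                     [(0, 1, 0.9)])
        w = all_paths_weights(g)
        assert w[0, 1] == pytest.approx(0.9)
        assert w[1, 0] == 0.0

    def test_chain(self):
        g = DepGraph(3, [frozenset({"x"})] * 3,
                     [(0, 1, 0.9), (1, 2, 0.9)])
        w = all_paths_weights(g)
        assert w[0, 2] == pytest.approx(0.81)

    def test_matches_truncated_power_sum(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            g = random_graph(rng)
            np.testing.assert_allclose(
                all_paths_weights(g), truncated_path_sum(g), atol=1e-9)

    def test_matches_path_enumeration_on_cycle(self):
        # 2-cycle with low weights: enumeration to length 40 converges
        g = DepGraph(2, [frozenset({"a"}), frozenset({"b"})],
                     [(0, 1, 0.3), (1, 0, 0.3)])
        w = all_paths_weights(g)
        assert w[0, 1] == pytest.approx(
            enumerate_paths(g, 0, 1, 40), abs=1e-9)
        assert w[0, 0] == pytest.approx(
            enumerate_paths(g, 0, 0, 40), abs=1e-9)

    def test_divergent_series_raises_and_rescales(self):
        g = DepGraph(2, [frozenset({"a"}), frozenset({"b"})],
                     [(0, 1, 1.0), (1, 0, 1.0)])
        with pytest.raises(ValueError, match="rescale"):
            all_paths_weights(g)
        w = all_paths_weights(g, rescale=True)
        assert np.isfinite(w).all()


class TestKernel:
    def test_identical_graphs_normalized_to_one(self):
        g = build_graph(fallback_parse("A inhibits B"), (0, 2))
        assert kernel(g, g) == pytest.approx(1.0)

    def test_disjoint_label_sets_zero(self):
        g1 = DepGraph(2, [frozenset({"a"}), frozenset({"b"})],
                      [(0, 1, 0.5)])
        g2 = DepGraph(2, [frozenset({"c"}), frozenset({"d"})],
                      [(0, 1, 0.5)])
        assert kernel(g1, g2) == 0.0

    def test_hand_computed_value(self):
        g1 = DepGraph(3, [frozenset({"a"}), frozenset({"b"}),
                          frozenset({"c"})],
                      [(0, 1, 0.5), (1, 2, 0.4)])
        g2 = DepGraph(3, [frozenset({"a"}), frozenset({"b"}),
                          frozenset({"c"})],
                      [(0, 1, 0.3), (1, 2, 0.2)])
        w1, w2 = truncated_path_sum(g1), truncated_path_sum(g2)
        expected = 0.0
        for i1 in range(3):
            for j1 in range(3):
                for i2 in range(3):
                    for j2 in range(3):
                        if g1.labels[i1] == g2.labels[i2] and \
                                g1.labels[j1] == g2.labels[j2]:
                            expected += w1[i1, j1] * w2[i2, j2]
        assert kernel(g1, g2, normalized=False) == pytest.approx(expected)

    def test_symmetry_and_psd(self):
        rng = np.random.default_rng(5)
        graphs = [random_graph(rng) for _ in range(12)]
        k = kernel_matrix(graphs)
        np.testing.assert_allclose(k, k.T, atol=1e-12)
        eigvals = np.linalg.eigvalsh(k)
        assert eigvals.min() >= -1e-8


class TestTrainAndEval:
    def test_separable_instances_perfect_on_train(self):
        docs, _ = synthetic.generate_corpus(
            synthetic.GenConfig(n_documents=16, seed=5))
        instances = extractor.instances_from_corpus(docs)
        result = extractor.train_and_eval(instances, test_fraction=0.2,
                                          seed=5)
        assert result.train_report.f_measure == pytest.approx(1.0)

    def test_degenerate_training_labels_error(self):
        docs, _ = synthetic.generate_corpus(
            synthetic.GenConfig(n_documents=10, seed=2, positive_rate=0.0))
        instances = extractor.instances_from_corpus(docs)
        with pytest.raises(ValueError, match="class"):
            extractor.train_and_eval(instances, seed=0)

    def test_document_level_split(self):
        docs, _ = synthetic.generate_corpus(
            synthetic.GenConfig(n_documents=16, seed=5))
        instances = extractor.instances_from_corpus(docs)
        train, test = extractor.split_instances(instances, 0.25, seed=1)
        assert not ({i.doc_id for i in train} & {i.doc_id for i in test})
        assert len(train) + len(test) == len(instances)

    def test_end_to_end_deterministic(self):
        docs, _ = synthetic.generate_corpus(
            synthetic.GenConfig(n_documents=16, seed=5))
        instances = extractor.instances_from_corpus(docs)
        r1 = extractor.train_and_eval(instances, seed=3)
        r2 = extractor.train_and_eval(instances, seed=3)
        assert r1.train_report == r2.train_report
        assert r1.test_report == r2.test_report

    def test_eval_report_f_measure_identity(self):
        report = EvalReport.from_predictions(
            [True, True, False, False], [True, False, True, False])
        p, r = report.precision, report.recall
        assert report.f_measure == pytest.approx(2 * p * r / (p + r))
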