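"""Graph-kernel relation extraction over dependency parses.

Pipeline: pairable entities are selected in each clear-DDI sentence
(metabolites removed, enzymes treated as drugs, synonym mentions
collapsed); all C(n,2) candidate pairs are generated with a default
negative label and flipped positive where the annotation says DDI or DEI;
each candidate sentence becomes a weighted directed graph combining the
dependency parse (shortest-path edges up-weighted, candidate entities
anonymized ENTITY1/ENTITY2) with a linear chain of part-of-speech vertices;
the all-paths graph kernel — path-weight sums from the convergent Neumann
series of the adjacency matrix, matched over shared vertex labels — feeds a
maximum-margin classifier with a precomputed kernel matrix, evaluated with
precision/recall/F on a document-level split.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from ._tokenize import tokenize
from .corpus_io import Document
from .relation_rules import RelationLabel
from .tagger import KeyTerm, select_entities

__all__ = [
    "DepToken", "DepGraph", "CandidateInstance", "EvalReport",
    "KernelConfig", "read_conllu", "write_conllu", "fallback_parse",
    "prepare_entities", "generate_candidates", "collapse_labels",
    "build_graph", "all_paths_weights", "kernel", "kernel_matrix",
    "instances_from_corpus", "split_instances", "train_and_eval",
    "TrainResult",
]


# ---------------------------------------------------------------------------
# Parses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepToken:
    form: str
    lemma: str
    pos: str
    head: int      # 1-based index of the head token; 0 = root
    deprel: str = "dep"


Parse = list[DepToken]


def read_conllu(path: str | Path) -> list[Parse]:
    """Read CoNLL-U-style parses: blank-line-separated token blocks.

    Accepts either the 5-column form (token, lemma, pos, head, relation)
    or full 10-column CoNLL-U rows (FORM, LEMMA, UPOS, HEAD, DEPREL are
    used). ``#`` comment lines are skipped.
    """
    parses: list[Parse] = []
    current: Parse = []
    for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            if current:
                parses.append(current)
                current = []
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        try:
            if len(cols) >= 10:
                current.append(DepToken(cols[1], cols[2], cols[3],
                                        int(cols[6]), cols[7]))
            elif len(cols) == 5:
                current.append(DepToken(cols[0], cols[1], cols[2],
                                        int(cols[3]), cols[4]))
            else:
                raise ValueError(f"{len(cols)} columns")
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: bad parse row: {exc}") \
                from exc
    if current:
        parses.append(current)
    return parses


def write_conllu(parses: list[Parse], path: str | Path) -> None:
    blocks = []
    for parse in parses:
        blocks.append("\n".join(
            f"{t.form}\t{t.lemma}\t{t.pos}\t{t.head}\t{t.deprel}"
            for t in parse))
    Path(path).write_text("\n\n".join(blocks) + "\n", encoding="utf-8")


_VERB_SUFFIXES = ("ed", "ing", "ate", "ates", "ize", "izes")
_FUNCTION_WORDS = {"of", "by", "with", "to", "in", "for", "on", "at",
                   "from", "versus", "vs"}
_CONJ = {"and", "or", "but", "while", "whereas"}
_DET = {"the", "a", "an", "its", "their", "this", "these"}


def fallback_parse(text: str) -> Parse:
    """Deterministic stand-in parser: a right-branching chain.

    Every token's head is the previous token (the first token is the
    root), with coarse part-of-speech tags from surface heuristics.  Used
    when no external dependency parser output is supplied; the graph
    machinery is agnostic to where parses come from.
    """
    tokens = tokenize(text)
    parse: Parse = []
    for i, tok in enumerate(tokens):
        low = tok.text.lower()
        if any(c.isdigit() for c in tok.text):
            pos = "CD"
        elif not tok.text[0].isalnum():
            pos = "PUNCT"
        elif low in _FUNCTION_WORDS:
            pos = "IN"
        elif low in _CONJ:
            pos = "CC"
        elif low in _DET:
            pos = "DT"
        elif low.endswith("ly"):
            pos = "RB"
        elif low.endswith(_VERB_SUFFIXES):
            pos = "VBD"
        else:
            pos = "NN"
        parse.append(DepToken(tok.text, low, pos, i, "dep"))
    return parse


# ---------------------------------------------------------------------------
# Candidates
# ---------------------------------------------------------------------------

def prepare_entities(key_terms: list[KeyTerm]) -> list[KeyTerm]:
    """Pairable entities of a tagged sentence: drop metabolites, keep
    enzymes as drugs, collapse synonym mentions to the first."""
    return select_entities(key_terms)


def generate_candidates(entities: list) -> list[tuple]:
    """All C(n,2) unordered entity pairs, in mention order."""
    return [(entities[i], entities[j])
            for i in range(len(entities))
            for j in range(i + 1, len(entities))]


def collapse_labels(relation: str) -> bool:
    """Collapse the six-way relation label to the binary extraction target:
    only DDI and DEI are true interactions."""
    return relation in (RelationLabel.DDI, RelationLabel.DEI)


# ---------------------------------------------------------------------------
# Graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelConfig:
    """Edge weights of the combined graph (published defaults): 0.9 on
    dependency edges along the shortest path between the candidate
    entities, 0.3 on other dependency edges, 0.9 on the linear
    part-of-speech chain."""
    w_shortest: float = 0.9
    w_other: float = 0.3
    w_linear: float = 0.9


DEFAULT_KERNEL_CONFIG = KernelConfig()


@dataclass
class DepGraph:
    """Labeled weighted directed graph: ``labels[i]`` is the label set of
    vertex i, ``edges`` are (from, to, weight) with weight in (0, 1]."""
    n: int
    labels: list[frozenset[str]]
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != self.n:
            raise ValueError("label list does not match vertex count")
        seen = set()
        for u, v, w in self.edges:
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u},{v}) out of range")
            if not (0.0 < w <= 1.0):
                raise ValueError(f"edge weight {w} outside (0,1]")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u},{v})")
            seen.add((u, v))

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n, self.n))
        for u, v, w in self.edges:
            a[u, v] = w
        return a


def _shortest_path_edges(n: int, edges: list[tuple[int, int]],
                         source: int, target: int) -> set[frozenset]:
    """Undirected BFS shortest path; returns its edge set (possibly empty
    when disconnected)."""
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    prev: dict[int, int] = {source: source}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        if node == target:
            break
        for nxt in adj[node]:
            if nxt not in prev:
                prev[nxt] = node
                queue.append(nxt)
    if target not in prev:
        return set()
    path_edges = set()
    node = target
    while node != source:
        path_edges.add(frozenset({node, prev[node]}))
        node = prev[node]
    return path_edges


def build_graph(parse: Parse, pair: tuple[int, int],
                other_entities: tuple[int, ...] = (),
                config: KernelConfig = DEFAULT_KERNEL_CONFIG) -> DepGraph:
    """Combined graph for one candidate pair.

    ``pair`` holds the token indices of the two candidate entities;
    ``other_entities`` the token indices of remaining entity mentions in
    the sentence.  Vertices 0..n-1 are the dependency graph (lemma +
    part-of-speech labels, candidate tokens anonymized ENTITY1/ENTITY2 and
    other entities ENTITY); vertices n..2n-1 are a disjoint linear chain of
    part-of-speech tags carrying positional markers relative to the pair.
    """
    n = len(parse)
    e1, e2 = pair
    if not (0 <= e1 < n and 0 <= e2 < n):
        raise ValueError("pair token indices out of range for parse")

    dep_edges = [(t.head - 1, i) for i, t in enumerate(parse) if t.head > 0]
    for u, v in dep_edges:
        if not 0 <= u < n:
            raise ValueError("parse head index out of range")
    sp = _shortest_path_edges(n, dep_edges, e1, e2)

    labels: list[frozenset[str]] = []
    for i, t in enumerate(parse):
        if i == e1:
            labels.append(frozenset({"ENTITY1", t.pos}))
        elif i == e2:
            labels.append(frozenset({"ENTITY2", t.pos}))
        elif i in other_entities:
            labels.append(frozenset({"ENTITY", t.pos}))
        else:
            labels.append(frozenset({t.lemma, t.pos}))

    lo, hi = min(e1, e2), max(e1, e2)
    for i, t in enumerate(parse):
        if i == e1:
            marker = "lin:ENTITY1"
        elif i == e2:
            marker = "lin:ENTITY2"
        elif i < lo:
            marker = "lin:BEFORE"
        elif i > hi:
            marker = "lin:AFTER"
        else:
            marker = "lin:MID"
        labels.append(frozenset({f"lin:{t.pos}", marker}))

    edges = [(u, v, config.w_shortest if frozenset({u, v}) in sp
              else config.w_other) for u, v in dep_edges]
    edges += [(n + i, n + i + 1, config.w_linear) for i in range(n - 1)]
    return DepGraph(2 * n, labels, edges)


# ---------------------------------------------------------------------------
# All-paths kernel
# ---------------------------------------------------------------------------

def all_paths_weights(graph: DepGraph, *, rescale: bool = False,
                      max_weight: float = 0.9) -> np.ndarray:
    """Path-weight sums between all vertex pairs.

    Entry (i, j) is the sum over all directed paths from i to j of the
    product of edge weights: the Neumann series A + A^2 + ... =
    A(I - A)^{-1}, which converges when the spectral radius of the
    weighted adjacency matrix A is below 1.  If it is not, either pass
    ``rescale=True`` to scale A down to radius ``max_weight``, or rescale
    the edge weights yourself.
    """
    a = graph.adjacency()
    if graph.n == 0:
        return a
    radius = float(np.max(np.abs(np.linalg.eigvals(a))))
    if radius >= 1.0:
        if not rescale:
            raise ValueError(
                f"path series does not converge (spectral radius "
                f"{radius:.3f} >= 1); rescale edge weights or pass "
                f"rescale=True")
        a = a * (max_weight / radius)
    identity = np.eye(graph.n)
    return a @ np.linalg.inv(identity - a)


def _label_matrix(graph: DepGraph, weights: np.ndarray):
    """Collapse the vertex-pair weight matrix onto label pairs.

    Returns (labels, M) where M[a, b] sums path weights from any vertex
    carrying label a to any vertex carrying label b — the explicit feature
    map of the kernel, indexed by the graph's own label vocabulary.
    """
    labels = sorted({lab for ls in graph.labels for lab in ls})
    index = {lab: i for i, lab in enumerate(labels)}
    incidence = np.zeros((len(labels), graph.n))
    for v, ls in enumerate(graph.labels):
        for lab in ls:
            incidence[index[lab], v] = 1.0
    return labels, incidence @ weights @ incidence.T


def kernel(g1: DepGraph, g2: DepGraph, *, normalized: bool = True) -> float:
    """All-paths graph kernel between two labeled graphs.

    Sums, over vertex pairs with shared labels at both path ends, the
    products of the two graphs' path weights; equivalently the inner
    product of the label-pair feature maps, hence symmetric and positive
    semidefinite.  The normalized variant is k(a,b)/sqrt(k(a,a) k(b,b)).
    """
    f1 = _Features(g1)
    f2 = _Features(g2)
    if not normalized:
        return f1.dot(f2)
    return _normalized_dot(f1, f2)


class _Features:
    """Cached label-pair feature map of one graph."""

    def __init__(self, graph: DepGraph, *, rescale: bool = False):
        self.labels, self.matrix = _label_matrix(
            graph, all_paths_weights(graph, rescale=rescale))
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        self._norm2: float | None = None

    def norm2(self) -> float:
        if self._norm2 is None:
            self._norm2 = float((self.matrix * self.matrix).sum())
        return self._norm2

    def dot(self, other: "_Features") -> float:
        shared = [lab for lab in self.labels if lab in other.index]
        if not shared:
            return 0.0
        ix1 = np.array([self.index[lab] for lab in shared])
        ix2 = np.array([other.index[lab] for lab in shared])
        m1 = self.matrix[np.ix_(ix1, ix1)]
        m2 = other.matrix[np.ix_(ix2, ix2)]
        return float((m1 * m2).sum())


def _normalized_dot(f1: _Features, f2: _Features) -> float:
    k12 = f1.dot(f2)
    k11 = f1.norm2()
    k22 = f2.norm2()
    if k11 <= 0.0 or k22 <= 0.0:
        return 0.0
    return k12 / np.sqrt(k11 * k22)


def kernel_matrix(graphs: list[DepGraph], *,
                  normalized: bool = True) -> np.ndarray:
    """Pairwise kernel matrix of an instance set (features cached)."""
    feats = [_Features(g) for g in graphs]
    n = len(feats)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            v = feats[i].dot(feats[j]) if not normalized \
                else _normalized_dot(feats[i], feats[j])
            mat[i, j] = mat[j, i] = v
    return mat


def cross_kernel_matrix(test: list[DepGraph], train: list[DepGraph],
                        *, normalized: bool = True) -> np.ndarray:
    feats_te = [_Features(g) for g in test]
    feats_tr = [_Features(g) for g in train]
    mat = np.zeros((len(feats_te), len(feats_tr)))
    for i, fe in enumerate(feats_te):
        for j, fr in enumerate(feats_tr):
            mat[i, j] = fe.dot(fr) if not normalized \
                else _normalized_dot(fe, fr)
    return mat


# ---------------------------------------------------------------------------
# Instances and evaluation
# ---------------------------------------------------------------------------

@dataclass
class CandidateInstance:
    doc_id: str
    sentence_index: int
    pair: tuple[str, str]        # canonical entity names
    graph: DepGraph
    gold: bool


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f_measure: float

    @classmethod
    def from_predictions(cls, gold, predicted) -> "EvalReport":
        gold = list(gold)
        predicted = list(predicted)
        tp = sum(1 for g, p in zip(gold, predicted) if g and p)
        fp = sum(1 for g, p in zip(gold, predicted) if not g and p)
        tn = sum(1 for g, p in zip(gold, predicted) if not g and not p)
        fn = sum(1 for g, p in zip(gold, predicted) if g and not p)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * precision * recall / (precision + recall) \
            if precision + recall else 0.0
        return cls(tp, fp, tn, fn, precision, recall, f)


def _anchor_token(parse: Parse, text: str, term: KeyTerm) -> int | None:
    """Index of the first parse token overlapping the term span (parses
    from :func:`fallback_parse` align with the shared tokenizer)."""
    for i, tok in enumerate(tokenize(text)):
        if tok.start < term.span.end and term.span.start < tok.end:
            if i < len(parse):
                return i
    return None


def instances_from_corpus(
        documents: list[Document],
        parses: dict[tuple[str, int], Parse] | None = None,
        config: KernelConfig = DEFAULT_KERNEL_CONFIG,
) -> list[CandidateInstance]:
    """Candidate instances from all clear-DDI (CDDIS) sentences.

    ``parses`` maps (pmid, sentence index) to an external dependency
    parse; sentences without one get the deterministic fallback chain.
    Gold labels come from the sentence pair annotations, collapsed to
    binary (DDI/DEI true), with un-annotated candidates negative.
    """
    instances: list[CandidateInstance] = []
    for doc in documents:
        for sent in doc.sentences:
            if sent.ddi_label != "CDDIS":
                continue
            entities = prepare_entities(sent.key_terms)
            if len(entities) < 2:
                continue
            parse = (parses or {}).get((doc.pmid, sent.index)) \
                or fallback_parse(sent.text)
            if len(parse) != len(tokenize(sent.text)):
                raise ValueError(
                    f"pmid {doc.pmid} sentence {sent.index}: parse does "
                    f"not align with sentence tokens")
            anchors = {}
            for t in entities:
                a = _anchor_token(parse, sent.text, t)
                if a is not None:
                    anchors[sent.term_id(t)] = a
            annotated = {}
            for p in sent.pairs:
                try:
                    key = frozenset({sent.term(p.entity_a).normal_form,
                                     sent.term(p.entity_b).normal_form})
                except (IndexError, ValueError):
                    continue
                annotated[key] = p.relation
            all_anchor_set = set(anchors.values())
            for t1, t2 in generate_candidates(entities):
                id1, id2 = sent.term_id(t1), sent.term_id(t2)
                if id1 not in anchors or id2 not in anchors:
                    continue
                others = tuple(all_anchor_set
                               - {anchors[id1], anchors[id2]})
                graph = build_graph(parse, (anchors[id1], anchors[id2]),
                                    others, config)
                rel = annotated.get(
                    frozenset({t1.normal_form, t2.normal_form}), "NONE")
                instances.append(CandidateInstance(
                    doc.pmid, sent.index,
                    (t1.normal_form, t2.normal_form), graph,
                    collapse_labels(rel)))
    return instances


def split_instances(instances: list[CandidateInstance],
                    test_fraction: float = 0.25, seed: int = 0
                    ) -> tuple[list[CandidateInstance],
                               list[CandidateInstance]]:
    """Document-level train/test split: all candidates of one abstract
    stay on the same side."""
    rng = np.random.default_rng(seed)
    doc_ids = sorted({inst.doc_id for inst in instances})
    rng.shuffle(doc_ids)
    n_test = max(1, int(round(test_fraction * len(doc_ids))))
    test_ids = set(doc_ids[:n_test])
    train = [i for i in instances if i.doc_id not in test_ids]
    test = [i for i in instances if i.doc_id in test_ids]
    return train, test


@dataclass
class TrainResult:
    model: SVC
    train_instances: list[CandidateInstance]
    train_report: EvalReport
    test_report: EvalReport | None


def train_and_eval(instances: list[CandidateInstance], *,
                   test_fraction: float = 0.25, c: float = 10.0,
                   seed: int = 0,
                   class_weight: str | dict | None = "balanced"
                   ) -> TrainResult:
    """Train the maximum-margin classifier on the precomputed normalized
    kernel matrix and evaluate on a held-out document-level split.

    Positive candidates are a small minority in DDI corpora, so the class
    weight defaults to "balanced"; the regularization default C=10 suits
    a normalized kernel, whose values are bounded by 1.
    """
    train, test = split_instances(instances, test_fraction, seed)
    y_train = [i.gold for i in train]
    if len(set(y_train)) < 2:
        raise ValueError("training split needs both classes; "
                         "got a degenerate class distribution")
    graphs_train = [i.graph for i in train]
    k_train = kernel_matrix(graphs_train)
    model = SVC(kernel="precomputed", C=c, class_weight=class_weight)
    model.fit(k_train, y_train)

    train_report = EvalReport.from_predictions(
        y_train, model.predict(k_train))
    test_report = None
    if test:
        k_test = cross_kernel_matrix([i.graph for i in test], graphs_train)
        test_report = EvalReport.from_predictions(
            [i.gold for i in test], model.predict(k_test))
    return TrainResult(model, train, train_report, test_report)
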