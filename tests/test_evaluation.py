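"""CAFA metrics against brute-force oracles and hand-enumerated toy corpora."""

import math

import networkx as nx
import numpy as np
import pytest

from gvpgo.evaluation import (EvaluationInput, aupr, default_thresholds,
                              evaluate_all, fmax, smin, term_auroc)
from gvpgo.go_graph import (AnnotationSet, GoDag, PredictionSet,
                            information_content, propagate_annotations,
                            propagate_predictions)

from .conftest import chain_dag


def sibling_dag():
    """Root R with independent children B and C (one namespace)."""
    g = nx.DiGraph()
    g.add_edge("GO:B", "GO:R", relation="is_a")
    g.add_edge("GO:C", "GO:R", relation="is_a")
    ns = {t: "MFO" for t in ("GO:R", "GO:B", "GO:C")}
    return GoDag(graph=g, namespace=ns, name={t: t for t in ns})


def make_input(dag, truth, preds, ic=None, thresholds=None):
    kwargs = {} if thresholds is None else {"thresholds": np.asarray(thresholds)}
    return EvaluationInput(
        predictions=PredictionSet(preds, propagated=True),
        truth=AnnotationSet(truth, propagated=True),
        ontology="MFO", dag=dag, ic=ic, **kwargs,
    )


# -- independent oracles ------------------------------------------------------


def oracle_pr_rc(truth, preds, terms, t):
    """Definition-level precision/recall at threshold t (loops, no matrices)."""
    prs, rcs = [], []
    for p in truth:
        T = truth[p] & terms
        if not T:
            continue
        P = {f for f, c in preds.get(p, {}).items() if c >= t and f in terms}
        tp = len(P & T)
        if P:
            prs.append(tp / len(P))
        rcs.append(tp / len(T))
    pr = sum(prs) / len(prs) if prs else None
    rc = sum(rcs) / len(rcs)
    return pr, rc


def oracle_fmax(truth, preds, terms):
    """Exhaustive sweep over every distinct confidence value."""
    distinct = sorted({c for tab in preds.values() for f, c in tab.items() if f in terms if c > 0})
    best = 0.0
    for t in distinct:
        pr, rc = oracle_pr_rc(truth, preds, terms, t)
        if pr is not None and pr + rc > 0:
            best = max(best, 2 * pr * rc / (pr + rc))
    return best


def oracle_aupr(truth, preds, terms, thresholds):
    pts = []
    for t in thresholds:
        pr, rc = oracle_pr_rc(truth, preds, terms, t)
        if pr is not None:
            pts.append((rc, pr))
    pts.sort()
    if not pts:
        return 0.0
    rc = [0.0] + [p[0] for p in pts]
    pr = [pts[0][1]] + [p[1] for p in pts]
    return float(np.trapezoid(pr, rc))


def oracle_auroc(scores, labels):
    """Mean over all (positive, negative) pairs with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return total / (len(pos) * len(neg))


def random_instance(rng, n_proteins=10, n_terms=12):
    """Random propagated-looking instance with on-grid scores."""
    g = nx.DiGraph()
    terms = [f"GO:T{j}" for j in range(n_terms)]
    for t in terms:
        g.add_edge(t, "GO:ROOT", relation="is_a")
    ns = {t: "MFO" for t in terms + ["GO:ROOT"]}
    dag = GoDag(graph=g, namespace=ns, name={t: t for t in ns})
    truth = {}
    preds = {}
    for i in range(n_proteins):
        k = int(rng.integers(1, n_terms))
        truth[f"p{i}"] = set(rng.choice(terms, k, replace=False)) | {"GO:ROOT"}
        scored = rng.choice(terms, int(rng.integers(1, n_terms)), replace=False)
        preds[f"p{i}"] = {t: float(np.round(rng.uniform(0.01, 1.0), 2)) for t in scored}
    return dag, truth, preds, set(terms)


class TestFmax:
    def test_perfect_predictor(self):
        dag = sibling_dag()
        truth = {"p1": {"GO:B", "GO:R"}, "p2": {"GO:C", "GO:R"}}
        preds = {"p1": {"GO:B": 1.0, "GO:R": 1.0}, "p2": {"GO:C": 1.0, "GO:R": 1.0}}
        f, t = fmax(make_input(dag, truth, preds))
        assert f == pytest.approx(1.0)

    def test_two_protein_toy_value(self):
        """Hand-checked sweep: best F = 2/3 at any t <= 0.2."""
        dag = sibling_dag()
        truth = {"p1": {"GO:B", "GO:R"}, "p2": {"GO:C", "GO:R"}}
        preds = {"p1": {"GO:B": 0.8, "GO:C": 0.3, "GO:R": 0.8},
                 "p2": {"GO:B": 0.9, "GO:C": 0.2, "GO:R": 0.9}}
        f, t = fmax(make_input(dag, truth, preds))
        assert f == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert t <= 0.2

    def test_empty_predictions_zero_with_warning(self):
        dag = sibling_dag()
        with pytest.warns(UserWarning, match="empty"):
            f, _ = fmax(make_input(dag, {"p1": {"GO:B"}}, {"p1": {}}))
        assert f == 0.0

    def test_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            dag, truth, preds, terms = random_instance(rng)
            f, _ = fmax(make_input(dag, truth, preds))
            assert f == pytest.approx(oracle_fmax(truth, preds, terms), abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        dag, truth, preds, terms = random_instance(rng)
        f0, _ = fmax(make_input(dag, truth, preds))
        warped = {p: {t: c**3 for t, c in tab.items()} for p, tab in preds.items()}
        distinct = sorted({c for tab in warped.values() for c in tab.values()})
        f1, _ = fmax(make_input(dag, truth, warped, thresholds=distinct))
        assert f1 == pytest.approx(f0, abs=1e-9)


class TestSmin:
    def test_perfect_predictions_zero(self):
        dag = chain_dag()
        truth = {"p1": {"GO:c", "GO:b", "GO:a"}}
        preds = {"p1": {"GO:c": 1.0, "GO:b": 1.0, "GO:a": 1.0}}
        ic = information_content(AnnotationSet(truth, propagated=True), dag)
        s, _, _ = smin(make_input(dag, truth, preds, ic=ic))
        assert s == pytest.approx(0.0)

    def test_empty_predictions_average_truth_ic(self):
        dag = chain_dag()
        truth = {"p1": {"GO:c", "GO:b", "GO:a"}, "p2": {"GO:b", "GO:a"}}
        ic = information_content(AnnotationSet(truth, propagated=True), dag)
        s, _, _ = smin(make_input(dag, truth, {"p1": {}, "p2": {}}, ic=ic))
        expected = (ic["GO:c"] + 2 * ic["GO:b"]) / 2  # root excluded, ic(a)=ic(b)
        assert s == pytest.approx(expected, abs=1e-12)

    def test_toy_corpus_hand_enumeration(self):
        """smin = IC(b)/2 = -log10(2/5)/2, reached for t in (0.4, 0.8]."""
        dag = chain_dag()
        truth = {"p1": {"GO:c", "GO:b", "GO:a"}, "p2": {"GO:b", "GO:a"}}
        preds = {"p1": {"GO:c": 0.8, "GO:b": 0.8, "GO:a": 0.8},
                 "p2": {"GO:c": 0.4, "GO:b": 0.4, "GO:a": 0.4}}
        ic = information_content(AnnotationSet(truth, propagated=True), dag)
        s, t, _ = smin(make_input(dag, truth, preds, ic=ic))
        assert s == pytest.approx(-math.log10(2 / 5) / 2, abs=1e-9)
        assert 0.4 < t <= 0.8

    def test_infinite_ic_rejected(self):
        dag = chain_dag()
        truth = {"p1": {"GO:b", "GO:a"}}
        preds = {"p1": {"GO:c": 0.9}}  # GO:c never annotated -> infinite IC
        ic = information_content(AnnotationSet(truth, propagated=True), dag)
        with pytest.raises(ValueError, match="outside the corpus"):
            smin(make_input(dag, truth, preds, ic=ic))


class TestAupr:
    def test_perfect_predictor_area_one(self):
        dag = sibling_dag()
        truth = {"p1": {"GO:B"}, "p2": {"GO:C"}}
        preds = {"p1": {"GO:B": 1.0}, "p2": {"GO:C": 1.0}}
        assert aupr(make_input(dag, truth, preds)) == pytest.approx(1.0)

    def test_constant_scores_degenerate_rectangle(self):
        dag = sibling_dag()
        truth = {"p1": {"GO:B"}, "p2": {"GO:C"}}
        preds = {"p1": {"GO:B": 0.5, "GO:C": 0.5}, "p2": {"GO:B": 0.5, "GO:C": 0.5}}
        with pytest.warns(UserWarning, match="degenerate"):
            a = aupr(make_input(dag, truth, preds))
        assert a == pytest.approx(0.5 * 1.0)  # pr = 0.5, rc = 1.0

    def test_matches_exhaustive_threshold_oracle(self):
        rng = np.random.default_rng(13)
        grid = default_thresholds()
        for _ in range(50):
            dag, truth, preds, terms = random_instance(rng)
            a = aupr(make_input(dag, truth, preds))
            assert a == pytest.approx(oracle_aupr(truth, preds, terms, grid), abs=1e-9)


class TestTermAuroc:
    def test_constant_scores_give_half(self):
        dag = sibling_dag()
        truth = {"p1": {"GO:B"}, "p2": {"GO:C"}}
        preds = {p: {"GO:B": 0.3, "GO:C": 0.3} for p in truth}
        per_term, macro = term_auroc(make_input(dag, truth, preds))
        assert all(v == 0.5 for v in per_term.values())
        assert macro == 0.5

    def test_scores_equal_labels_give_one(self):
        dag = sibling_dag()
        truth = {"p1": {"GO:B"}, "p2": {"GO:C"}}
        preds = {"p1": {"GO:B": 1.0, "GO:C": 0.0}, "p2": {"GO:B": 0.0, "GO:C": 1.0}}
        per_term, macro = term_auroc(make_input(dag, truth, preds))
        assert macro == pytest.approx(1.0)

    def test_matches_pairwise_comparison_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            dag, truth, preds, terms = random_instance(rng, n_proteins=20)
            inp = make_input(dag, truth, preds)
            per_term, macro = term_auroc(inp)
            proteins, tlist, scores, labels = inp.matrices()
            for term, value in per_term.items():
                j = tlist.index(term)
                assert value == pytest.approx(oracle_auroc(scores[:, j], labels[:, j]), abs=1e-9)

    def test_micro_pooling_flag(self):
        rng = np.random.default_rng(3)
        dag, truth, preds, terms = random_instance(rng)
        _, micro = term_auroc(make_input(dag, truth, preds), micro=True)
        assert 0.0 <= micro <= 1.0


class TestOntologySeparation:
    def test_namespaces_never_mix(self):
        g = nx.DiGraph()
        g.add_edge("GO:mB", "GO:mR", relation="is_a")
        g.add_edge("GO:bB", "GO:bR", relation="is_a")
        ns = {"GO:mR": "MFO", "GO:mB": "MFO", "GO:bR": "BPO", "GO:bB": "BPO"}
        dag = GoDag(graph=g, namespace=ns, name={t: t for t in ns})
        truth = {"p1": {"GO:mB", "GO:mR", "GO:bB", "GO:bR"}}
        preds = {"p1": {"GO:mB": 1.0, "GO:bB": 0.1}}
        inp = EvaluationInput(predictions=PredictionSet(preds, propagated=True),
                              truth=AnnotationSet(truth, propagated=True),
                              ontology="MFO", dag=dag)
        f, _ = fmax(inp)
        assert f == pytest.approx(1.0)  # the weak BPO prediction is invisible in MFO

    def test_unpropagated_inputs_rejected(self):
        dag = sibling_dag()
        with pytest.raises(ValueError, match="propagated"):
            EvaluationInput(predictions=PredictionSet({"p": {}}, propagated=False),
                            truth=AnnotationSet({"p": {"GO:B"}}, propagated=True),
                            ontology="MFO", dag=dag)


def test_evaluate_all_bundles_consistent_fields():
    rng = np.random.default_rng(21)
    dag, truth, preds, terms = random_instance(rng)
    ic = information_content(AnnotationSet(truth, propagated=True), dag)
    res = evaluate_all(make_input(dag, truth, preds, ic=ic))
    assert 0.0 <= res.fmax <= 1.0 and 0.0 <= res.aupr <= 1.0
    assert res.smin >= 0.0
    assert res.pr_curve.shape[0] == len(default_thresholds())
    f_direct, _ = fmax(make_input(dag, truth, preds))
    assert res.fmax == pytest.approx(f_direct)
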