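"""Protein-centric (Fmax, Smin, AUPR) and term-centric (AUROC) evaluation.

The conventions follow the CAFA community assessments. For a threshold t,
a protein's predicted set P_i(t) holds the terms scored >= t; precision
pr(t) averages |P_i & T_i| / |P_i| over the m(t) proteins with a nonempty
P_i(t), while recall rc(t) averages |P_i & T_i| / |T_i| over all n
evaluated proteins. Fmax maximizes the harmonic mean of the two over the
threshold grid. Smin minimizes sqrt(ru(t)^2 + mi(t)^2) where remaining
uncertainty ru and misinformation mi are information-content-weighted
false-negative and false-positive sums, both averaged over all n proteins.
Term-centric AUROC ranks proteins per term with half credit for ties.

Both predictions and ground truth must be ancestor/descendant propagated;
namespace roots are excluded, metrics never mix namespaces, and proteins
without truth terms in the evaluated ontology are excluded from n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .go_graph import AnnotationSet, GoDag, PredictionSet

__all__ = ["EvaluationInput", "MetricResult", "fmax", "smin", "aupr", "term_auroc", "evaluate_all", "default_thresholds"]


def default_thresholds() -> np.ndarray:
    """The CAFA grid t = 0.01, 0.02, ..., 1.00."""
    return np.round(np.arange(0.01, 1.001, 0.01), 2)


@dataclass
class EvaluationInput:
    """Propagated predictions + truth restricted to one ontology."""

    predictions: PredictionSet
    truth: AnnotationSet
    ontology: str
    dag: GoDag
    ic: dict[str, float] | None = None
    thresholds: np.ndarray = field(default_factory=default_thresholds)

    # matrix cache, built lazily
    _proteins: list[str] | None = None
    _terms: list[str] | None = None
    _scores: np.ndarray | None = None
    _labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.predictions.propagated or not self.truth.propagated:
            raise ValueError("both predictions and truth must be propagated before evaluation")
        t = np.asarray(self.thresholds, dtype=float)
        if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be a strictly increasing 1-D grid")
        self.thresholds = t

    def matrices(self) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
        """(proteins, terms, scores[n, T], labels[n, T]) for the ontology.

        Proteins: those with >= 1 truth term in the ontology (roots excluded).
        Terms: union of ontology truth and predicted terms, roots excluded.
        """
        if self._scores is not None:
            return self._proteins, self._terms, self._scores, self._labels
        ns_terms = self.dag.terms_in(self.ontology) - set(self.dag.roots.values())
        proteins = [
            p for p in sorted(self.truth.annotations)
            if self.truth.annotations[p] & ns_terms
        ]
        if not proteins:
            raise ValueError(f"no protein has truth terms in {self.ontology}")
        term_set: set[str] = set()
        for p in proteins:
            term_set |= self.truth.annotations[p] & ns_terms
            term_set |= set(self.predictions.scores.get(p, {})) & ns_terms
        terms = sorted(term_set)
        tindex = {t: j for j, t in enumerate(terms)}
        n, T = len(proteins), len(terms)
        scores = np.zeros((n, T))
        labels = np.zeros((n, T), dtype=bool)
        for i, p in enumerate(proteins):
            for t in self.truth.annotations[p]:
                j = tindex.get(t)
                if j is not None:
                    labels[i, j] = True
            for t, c in self.predictions.scores.get(p, {}).items():
                j = tindex.get(t)
                if j is not None:
                    scores[i, j] = c
        self._proteins, self._terms, self._scores, self._labels = proteins, terms, scores, labels
        return proteins, terms, scores, labels


@dataclass
class MetricResult:
    fmax: float
    fmax_threshold: float
    smin: float | None
    smin_threshold: float | None
    aupr: float
    auroc_per_term: dict[str, float]
    auroc_macro: float
    pr_curve: np.ndarray  # (n_thresholds, 2): recall, precision (NaN where m(t)=0)
    ru_mi_curve: np.ndarray | None  # (n_thresholds, 2)


def _pr_rc_sweep(inp: EvaluationInput) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per threshold: pr(t) (NaN if m(t)=0), rc(t), m(t)."""
    _, _, scores, labels = inp.matrices()
    n = scores.shape[0]
    truth_sizes = labels.sum(axis=1).astype(float)
    pr = np.full(len(inp.thresholds), np.nan)
    rc = np.zeros(len(inp.thresholds))
    m = np.zeros(len(inp.thresholds))
    for k, t in enumerate(inp.thresholds):
        P = scores >= t
        tp = (P & labels).sum(axis=1).astype(float)
        psize = P.sum(axis=1).astype(float)
        has_pred = psize > 0
        m[k] = has_pred.sum()
        if m[k] > 0:
            pr[k] = float(np.mean(tp[has_pred] / psize[has_pred]))
        rc[k] = float(np.mean(tp / truth_sizes))
    return pr, rc, m


def fmax(inp: EvaluationInput) -> tuple[float, float]:
    """Maximum protein-centric F-measure over the threshold grid."""
    _, _, scores, _ = inp.matrices()
    if not np.any(scores > 0):
        warnings.warn("empty prediction set: Fmax is 0 by convention", stacklevel=2)
        return 0.0, float(inp.thresholds[0])
    pr, rc, _ = _pr_rc_sweep(inp)
    best_f, best_t = 0.0, float(inp.thresholds[0])
    for k, t in enumerate(inp.thresholds):
        if np.isnan(pr[k]) or pr[k] + rc[k] <= 0:
            continue
        f = 2 * pr[k] * rc[k] / (pr[k] + rc[k])
        if f > best_f:
            best_f, best_t = float(f), float(t)
    return best_f, best_t


def smin(inp: EvaluationInput) -> tuple[float, float, np.ndarray]:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over the threshold grid.

    Returns (smin, argmin threshold, ru/mi curve). Requires finite IC for
    every term appearing in a truth set or a thresholded prediction.
    """
    if inp.ic is None:
        raise ValueError("smin requires information content")
    proteins, terms, scores, labels = inp.matrices()
    ic_vec = np.array([inp.ic.get(t, math.inf) for t in terms])
    n = len(proteins)
    used = labels.any(axis=0) | (scores > 0).any(axis=0)
    if np.any(np.isinf(ic_vec[used])):
        offenders = [t for t, u, v in zip(terms, used, ic_vec) if u and np.isinf(v)]
        raise ValueError(f"infinite IC for term(s) outside the corpus: {offenders[:5]}")
    curve = np.zeros((len(inp.thresholds), 2))
    best, best_t = math.inf, float(inp.thresholds[0])
    for k, t in enumerate(inp.thresholds):
        P = scores >= t
        fn = labels & ~P
        fp = P & ~labels
        ru = float(np.mean(fn @ ic_vec))
        mi = float(np.mean(fp @ ic_vec))
        curve[k] = (ru, mi)
        s = math.hypot(ru, mi)
        if s < best:
            best, best_t = s, float(t)
    return best, best_t, curve


def aupr(inp: EvaluationInput) -> float:
    """Area under the protein-centric precision-recall sweep (trapezoidal).

    The curve is extended horizontally from the highest-threshold point to
    recall 0; the lowest-threshold point is the other endpoint.
    """
    pr, rc, m = _pr_rc_sweep(inp)
    valid = ~np.isnan(pr)
    if not valid.any():
        warnings.warn("no threshold yields a prediction; AUPR = 0", stacklevel=2)
        return 0.0
    rc_v, pr_v = rc[valid], pr[valid]
    order = np.argsort(rc_v, kind="stable")
    rc_v, pr_v = rc_v[order], pr_v[order]
    if np.ptp(rc_v) == 0:
        warnings.warn("degenerate single-point PR curve; returning pr*rc rectangle", stacklevel=2)
        return float(pr_v[-1] * rc_v[-1])
    # extend to recall 0 at the precision of the most conservative threshold
    rc_full = np.concatenate([[0.0], rc_v])
    pr_full = np.concatenate([[pr_v[0]], pr_v])
    return float(np.trapezoid(pr_full, rc_full))


def _auroc_ranks(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUROC with half credit for ties."""
    pos = labels.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)  # average ranks on ties
    u = float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def term_auroc(inp: EvaluationInput, micro: bool = False) -> tuple[dict[str, float], float]:
    """Per-term AUROC across proteins and the macro (or micro) average.

    Terms lacking a positive or a negative protein are skipped with a warning.
    """
    proteins, terms, scores, labels = inp.matrices()
    per_term: dict[str, float] = {}
    skipped = 0
    for j, term in enumerate(terms):
        n_pos = int(labels[:, j].sum())
        if n_pos == 0 or n_pos == len(proteins):
            skipped += 1
            continue
        per_term[term] = _auroc_ranks(scores[:, j], labels[:, j])
    if skipped:
        warnings.warn(f"skipped {skipped} term(s) without both classes", stacklevel=2)
    if not per_term:
        raise ValueError("no term has both a positive and a negative protein")
    if micro:
        cols = [j for j, t in enumerate(terms) if t in per_term]
        macro = _auroc_ranks(scores[:, cols].ravel(), labels[:, cols].ravel())
    else:
        macro = float(np.mean(list(per_term.values())))
    return per_term, macro


def evaluate_all(inp: EvaluationInput) -> MetricResult:
    """Fmax, Smin (if IC given), AUPR and term-centric AUROC in one pass."""
    f, ft = fmax(inp)
    if inp.ic is not None:
        s, st, curve = smin(inp)
    else:
        s, st, curve = None, None, None
    a = aupr(inp)
    try:
        per_term, macro = term_auroc(inp)
    except ValueError:
        warnings.warn("term-centric AUROC undefined (no term with both classes)", stacklevel=2)
        per_term, macro = {}, float("nan")
    pr, rc, _ = _pr_rc_sweep(inp)
    return MetricResult(
        fmax=f,
        fmax_threshold=ft,
        smin=s,
        smin_threshold=st,
        aupr=a,
        auroc_per_term=per_term,
        auroc_macro=macro,
        pr_curve=np.stack([rc, pr], axis=1),
        ru_mi_curve=curve,
    )
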