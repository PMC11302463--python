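"""Naive frequency and BLAST-transfer baseline predictors.

The Naive baseline scores every term by its relative frequency among the
training proteins, identically for all query proteins — by construction
its tie-corrected term-centric AUROC is exactly 0.5. The BLAST baseline
transfers the annotations of aligned training proteins, scoring each term
by the maximum sequence identity among the hits that carry it. Identity
tables are consumed from TSV (any aligner); the pipeline never shells out
to PSI-BLAST.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from sklearn.base import BaseEstimator

from .go_graph import AnnotationSet, PredictionSet

__all__ = [
    "IdentityTable",
    "NaiveFrequencyClassifier",
    "BlastTransferClassifier",
    "naive_predict",
    "blast_transfer",
    "filter_by_identity",
    "read_identity_table",
]


@dataclass
class IdentityTable:
    """Sparse pairwise sequence identities in [0, 1]; absent pair = no alignment."""

    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, s in self.scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"identity {s} for {pair} outside [0, 1]")

    def get(self, query: str, subject: str) -> float | None:
        return self.scores.get((query, subject))

    def hits(self, query: str) -> dict[str, float]:
        return {s: v for (q, s), v in self.scores.items() if q == query}

    def max_identity(self, query: str) -> float:
        hits = self.hits(query)
        return max(hits.values()) if hits else 0.0


def read_identity_table(path: str | Path) -> IdentityTable:
    """Read ``query<TAB>subject<TAB>identity`` rows; 0-100 scales auto-detected."""
    rows: list[tuple[str, str, float]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        q, s, v = line.rstrip("\n").split("\t")[:3]
        rows.append((q, s, float(v)))
    if rows and max(v for _, _, v in rows) > 1.0:
        rows = [(q, s, v / 100.0) for q, s, v in rows]
    return IdentityTable({(q, s): v for q, s, v in rows})


class NaiveFrequencyClassifier(BaseEstimator):
    """Scores every GO term by its training relative frequency for every protein."""

    def fit(self, train_ann: AnnotationSet, y=None) -> "NaiveFrequencyClassifier":
        if not train_ann.annotations:
            raise ValueError("empty training annotations")
        if not train_ann.propagated:
            raise ValueError("train on propagated annotations")
        n = len(train_ann.annotations)
        counts: dict[str, int] = {}
        for terms in train_ann.annotations.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        self.term_frequency_ = {t: c / n for t, c in counts.items()}
        self.n_train_ = n
        return self

    def predict_proba(self, test_ids: list[str]) -> PredictionSet:
        freq = dict(self.term_frequency_)
        return PredictionSet({p: dict(freq) for p in test_ids}, propagated=True)


class BlastTransferClassifier(BaseEstimator):
    """Transfers training annotations by maximum sequence identity per term."""

    def fit(self, train_ann: AnnotationSet, y=None) -> "BlastTransferClassifier":
        if not train_ann.propagated:
            raise ValueError("train on propagated annotations")
        self.train_annotations_ = train_ann
        return self

    def predict_proba(self, test_ids: list[str], identities: IdentityTable) -> PredictionSet:
        ann = self.train_annotations_.annotations
        out: dict[str, dict[str, float]] = {}
        for q in test_ids:
            table: dict[str, float] = {}
            for subject, ident in identities.hits(q).items():
                for term in ann.get(subject, ()):
                    if table.get(term, -1.0) < ident:
                        table[term] = ident
            out[q] = table
        ps = PredictionSet(out, propagated=True)
        ps.validate()
        return ps


def naive_predict(train_ann: AnnotationSet, test_ids: list[str]) -> PredictionSet:
    return NaiveFrequencyClassifier().fit(train_ann).predict_proba(test_ids)


def blast_transfer(identities: IdentityTable, train_ann: AnnotationSet, test_ids: list[str]) -> PredictionSet:
    return BlastTransferClassifier().fit(train_ann).predict_proba(test_ids, identities)


def filter_by_identity(test_ids: list[str], identities: IdentityTable, cutoff: float) -> list[str]:
    """Drop test proteins whose maximum identity to training exceeds ``cutoff``.

    Strictly greater-than, so a protein at exactly the cutoff is retained;
    proteins absent from the table are retained (no evidence of similarity).
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    kept = [p for p in test_ids if identities.max_identity(p) <= cutoff]
    if not kept:
        import warnings

        warnings.warn("identity filter removed every test protein", stacklevel=2)
    return kept
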