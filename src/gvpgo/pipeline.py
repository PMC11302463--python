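"""End-to-end wiring: corpus -> features -> training -> CAFA evaluation.

Convenience layer shared by the command-line interface, the tests and the
reproduction script. Everything here is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import EvaluationInput, evaluate_all
from .geometry import FeatureBundle, featurize
from .go_graph import (
    AnnotationSet,
    GoDag,
    PredictionSet,
    information_content,
    propagate_annotations,
    select_candidate_terms,
)
from .model import GvpGoClassifier, ModelConfig
from .synthetic import SyntheticDataset

__all__ = ["PreparedData", "prepare_dataset", "label_matrix", "split_indices",
           "fit_on_prepared", "evaluate_predictions", "macro_fmax"]


@dataclass
class PreparedData:
    bundles: list[FeatureBundle]          # unmasked
    ids: list[str]
    truth: AnnotationSet                  # propagated, all proteins
    terms: list[str]                      # candidate terms (roots excluded)
    labels: np.ndarray                    # (n_proteins, n_terms) binary
    dag: GoDag
    ic: dict[str, float]
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray

    def subset(self, idx: np.ndarray) -> tuple[list[FeatureBundle], np.ndarray]:
        return [self.bundles[i] for i in idx], self.labels[idx]

    def truth_for(self, idx: np.ndarray) -> AnnotationSet:
        ids = {self.ids[i] for i in idx}
        return AnnotationSet(
            {p: t for p, t in self.truth.annotations.items() if p in ids}, propagated=True
        )


def split_indices(n: int, fractions: tuple[float, float, float], seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic shuffled split into train/validation/test index arrays."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return order[:n_train], order[n_train:n_train + n_val], order[n_train + n_val:]


def label_matrix(truth: AnnotationSet, ids: list[str], terms: list[str]) -> np.ndarray:
    index = {t: j for j, t in enumerate(terms)}
    y = np.zeros((len(ids), len(terms)))
    for i, p in enumerate(ids):
        for t in truth.annotations.get(p, ()):  # propagated
            j = index.get(t)
            if j is not None:
                y[i, j] = 1.0
    return y


def prepare_dataset(
    dataset: SyntheticDataset,
    k_neighbors: int = 8,
    min_proteins: int = 50,
    fractions: tuple[float, float, float] = (0.8, 0.2, 0.0),
    seed: int = 0,
) -> PreparedData:
    """Featurize a synthetic corpus and set up labels, splits and IC.

    Candidate terms are selected on the training partition only; the
    information content is computed on the full propagated corpus.
    """
    ids = dataset.protein_ids()
    bundles = [featurize(s, dataset.embeddings[s.protein_id], k=k_neighbors)
               for s in dataset.structures]
    truth = propagate_annotations(dataset.annotations, dataset.dag)
    train_idx, val_idx, test_idx = split_indices(len(ids), fractions, seed)
    train_truth = AnnotationSet(
        {ids[i]: truth.annotations[ids[i]] for i in train_idx}, propagated=True
    )
    terms = select_candidate_terms(train_truth, min_proteins=min_proteins, dag=dataset.dag)
    labels = label_matrix(truth, ids, terms)
    ic = information_content(truth, dataset.dag)
    return PreparedData(
        bundles=bundles, ids=ids, truth=truth, terms=terms, labels=labels,
        dag=dataset.dag, ic=ic,
        train_idx=train_idx, val_idx=val_idx, test_idx=test_idx,
    )


def evaluate_predictions(
    preds: PredictionSet,
    truth: AnnotationSet,
    dag: GoDag,
    ic: dict[str, float] | None = None,
    ontologies: tuple[str, ...] = ("MFO", "BPO", "CCO"),
) -> dict[str, object]:
    """Per-ontology CAFA metrics for already-propagated predictions."""
    out: dict[str, object] = {}
    for ont in ontologies:
        ns_terms = dag.terms_in(ont) - set(dag.roots.values())
        if not any(truth.annotations[p] & ns_terms for p in truth.annotations):
            continue
        out[ont] = evaluate_all(
            EvaluationInput(predictions=preds, truth=truth, ontology=ont, dag=dag, ic=ic)
        )
    return out


def macro_fmax(results: dict[str, object]) -> float:
    return float(np.mean([r.fmax for r in results.values()]))


def fit_on_prepared(
    data: PreparedData,
    config: ModelConfig,
    track_val_fmax: bool = True,
    stop_val_fmax: float | None = None,
) -> tuple[GvpGoClassifier, dict]:
    """Train on the prepared split; optionally track validation Fmax per epoch.

    ``stop_val_fmax`` halts training once the tracked validation Fmax
    reaches the given level (a compute cutoff; the reached value is reported
    as-is, never inflated).
    """
    Xtr, ytr = data.subset(data.train_idx)
    Xval, yval = data.subset(data.val_idx)
    val_truth = data.truth_for(data.val_idx)
    est = GvpGoClassifier.from_config(config)
    history: dict[str, list[float]] = {"val_fmax": []}

    def callback(model: GvpGoClassifier, epoch: int) -> bool:
        if not track_val_fmax:
            return False
        preds = model.prediction_set(Xval, dag=data.dag)
        res = evaluate_predictions(preds, val_truth, data.dag)
        f = macro_fmax(res)
        history["val_fmax"].append(f)
        return stop_val_fmax is not None and f >= stop_val_fmax

    est.fit(Xtr, ytr, terms=data.terms, validation=(Xval, yval), epoch_callback=callback)
    history["loss"] = est.loss_history_
    history["val_loss"] = est.val_loss_history_
    return est, history
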