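"""Loading a corpus directory (structures/, embeddings.npz, annotations.tsv, go.obo)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import featurize
from .go_graph import (AnnotationSet, information_content, parse_obo,
                       propagate_annotations, read_annotations, select_candidate_terms)
from .pipeline import PreparedData, label_matrix, split_indices
from .structure_io import read_structure


def load_corpus(
    directory: str | Path,
    k_neighbors: int,
    min_proteins: int = 50,
    fractions: tuple[float, float, float] = (0.8, 0.2, 0.0),
    seed: int = 0,
) -> PreparedData:
    directory = Path(directory)
    dag = parse_obo(directory / "go.obo")
    ann = read_annotations(directory / "annotations.tsv")
    truth = propagate_annotations(ann, dag)
    structures = sorted((directory / "structures").glob("*.pdb"))
    if not structures:
        raise FileNotFoundError(f"no structures under {directory / 'structures'}")
    with np.load(directory / "embeddings.npz") as arc:
        embeddings = {k: arc[k] for k in arc.files}
    bundles = []
    ids = []
    for p in structures:
        s = read_structure(p)
        if s.protein_id not in embeddings:
            raise KeyError(f"no embedding for {s.protein_id}")
        bundles.append(featurize(s, embeddings[s.protein_id], k=k_neighbors))
        ids.append(s.protein_id)
    train_idx, val_idx, test_idx = split_indices(len(ids), fractions, seed)
    train_truth = AnnotationSet(
        {ids[i]: truth.annotations.get(ids[i], set()) for i in train_idx}, propagated=True
    )
    terms = select_candidate_terms(train_truth, min_proteins=min_proteins, dag=dag)
    return PreparedData(
        bundles=bundles, ids=ids, truth=truth, terms=terms,
        labels=label_matrix(truth, ids, terms), dag=dag,
        ic=information_content(truth, dag),
        train_idx=train_idx, val_idx=val_idx, test_idx=test_idx,
    )
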