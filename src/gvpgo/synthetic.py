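"""Synthetic structures, ontologies and annotation corpora for testing.

Backbones are built by sequential internal-coordinate atom placement (NeRF)
from ideal bond lengths and angles, so the requested phi/psi/omega torsions
are exactly recoverable by measurement — geometry tests become analytic.
The planted structure->function rule maps each protein's backbone
conformation (helix vs extended) to one molecular-function leaf term, and
a three-residue tryptophan sequence motif to one biological-process leaf;
a shared cellular-component leaf is annotated to every protein. Stub
sequence embeddings stand in for protein-language-model features and are
residue-type-informative by construction. Pairwise sequence identities are
computed with edlib over the generated sequences (a fraction of proteins
are mutated copies of earlier ones, so the identity filter has signal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import networkx as nx
import numpy as np

from .baselines import IdentityTable
from .go_graph import AnnotationSet, GoDag
from .structure_io import ALPHABET, ProteinStructure, Residue

__all__ = [
    "IDEAL_GEOMETRY",
    "CONFORMATION_TORSIONS",
    "SyntheticSpec",
    "SyntheticDataset",
    "make_toy_structure",
    "make_toy_dag",
    "make_rule_dag",
    "make_synthetic_dataset",
    "make_stub_embedding",
    "make_plddt_profile",
    "write_dataset",
]

#: ideal backbone internal coordinates (lengths in Angstrom, angles in degrees)
IDEAL_GEOMETRY = {
    "bond_n_ca": 1.458,
    "bond_ca_c": 1.525,
    "bond_c_n": 1.329,
    "angle_n_ca_c": 111.2,
    "angle_ca_c_n": 116.2,
    "angle_c_n_ca": 121.7,
}

#: canonical (phi, psi) in degrees per conformation class; omega is trans (180)
CONFORMATION_TORSIONS = {
    "helix": (-57.0, -47.0),
    "extended": (-120.0, 120.0),
}

MOTIF = "WWW"

# -- planted ontology ---------------------------------------------------------

RULE_TERMS = {
    "mfo_root": "GO:9100000",
    "mfo_binding": "GO:9100001",
    "mfo_helix": "GO:9100002",     # leaf: helical proteins
    "mfo_catalytic": "GO:9100004",
    "mfo_extended": "GO:9100003",  # leaf: extended proteins
    "bpo_root": "GO:9200000",
    "bpo_process": "GO:9200001",
    "bpo_motif": "GO:9200002",     # leaf: proteins carrying the WWW motif
    "cco_root": "GO:9300000",
    "cco_cytoplasm": "GO:9300001",  # leaf: every protein
}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom D from A-B-C internal coordinates."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.stack([bc, np.cross(n, bc), n], axis=1)
    d_local = bond * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(chi), math.sin(theta) * math.sin(chi)]
    )
    return c + m @ d_local


def _build_backbone(torsions: np.ndarray) -> np.ndarray:
    """(L, 3, 3) N/CA/C coordinates from per-residue (phi, psi) degrees, trans omega."""
    L = len(torsions)
    g = IDEAL_GEOMETRY
    atoms = np.zeros((L, 3, 3))
    # first residue in the xy-plane
    atoms[0, 0] = (0.0, 0.0, 0.0)
    atoms[0, 1] = (g["bond_n_ca"], 0.0, 0.0)
    theta = math.radians(g["angle_n_ca_c"])
    atoms[0, 2] = atoms[0, 1] + g["bond_ca_c"] * np.array([-math.cos(theta), math.sin(theta), 0.0])
    for i in range(1, L):
        n_prev, ca_prev, c_prev = atoms[i - 1]
        psi_prev = torsions[i - 1, 1]
        atoms[i, 0] = _place_atom(n_prev, ca_prev, c_prev, g["bond_c_n"], g["angle_ca_c_n"], psi_prev)
        atoms[i, 1] = _place_atom(ca_prev, c_prev, atoms[i, 0], g["bond_n_ca"], g["angle_c_n_ca"], 180.0)
        atoms[i, 2] = _place_atom(c_prev, atoms[i, 0], atoms[i, 1], g["bond_ca_c"], g["angle_n_ca_c"], torsions[i, 0])
    return atoms


def make_plddt_profile(length: int, rng: np.random.Generator,
                       low_conf_prob: float = 0.2, segment_length: int = 6) -> np.ndarray:
    """Mostly-confident profile with an occasional low-confidence segment."""
    plddt = rng.uniform(0.92, 0.99, size=length)
    if rng.random() < low_conf_prob and length > segment_length:
        start = int(rng.integers(0, length - segment_length))
        plddt[start:start + segment_length] = rng.uniform(0.60, 0.85, size=segment_length)
    return np.round(plddt, 4)


def make_toy_structure(
    length: int,
    conformation: str = "helix",
    torsions: np.ndarray | None = None,
    seed: int = 0,
    sequence: str | None = None,
    plddt: np.ndarray | None = None,
    protein_id: str = "toy",
    low_conf_prob: float = 0.0,
) -> ProteinStructure:
    """Ideal-geometry backbone with exactly controllable torsions.

    ``conformation`` picks canonical (phi, psi): helix (-57, -47) or
    extended (-120, 120); ``mixed`` alternates helix and extended halves.
    An explicit (L, 2) ``torsions`` array (degrees) overrides it.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    if torsions is None:
        if conformation in CONFORMATION_TORSIONS:
            torsions = np.tile(CONFORMATION_TORSIONS[conformation], (length, 1))
        elif conformation == "mixed":
            half = length // 2
            torsions = np.vstack([
                np.tile(CONFORMATION_TORSIONS["helix"], (half, 1)),
                np.tile(CONFORMATION_TORSIONS["extended"], (length - half, 1)),
            ])
        else:
            raise ValueError(f"unknown conformation {conformation!r}")
    torsions = np.asarray(torsions, dtype=float)
    if torsions.shape != (length, 2):
        raise ValueError(f"torsions must have shape ({length}, 2)")
    atoms = _build_backbone(torsions)
    if sequence is None:
        sequence = "".join(rng.choice(list(ALPHABET), size=length))
    if plddt is None:
        plddt = make_plddt_profile(length, rng, low_conf_prob=low_conf_prob)
    residues = [
        Residue(i + 1, sequence[i], atoms[i, 0], atoms[i, 1], atoms[i, 2], float(plddt[i]))
        for i in range(length)
    ]
    return ProteinStructure(protein_id=protein_id, residues=residues)


def make_toy_dag(n_terms: int, branching: int = 2, seed: int = 0) -> GoDag:
    """Random rooted DAG with ``n_terms`` terms per namespace, acyclic by construction."""
    if n_terms < 1:
        raise ValueError("need at least one term per namespace")
    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    name: dict[str, str] = {}
    for k, ns in enumerate(("MFO", "BPO", "CCO")):
        terms = [f"GO:{8000000 + 10000 * k + i:07d}" for i in range(n_terms)]
        graph.add_node(terms[0])
        namespace[terms[0]] = ns
        name[terms[0]] = f"{ns} root"
        for i in range(1, n_terms):
            graph.add_node(terms[i])
            namespace[terms[i]] = ns
            name[terms[i]] = f"{ns} term {i}"
            n_parents = int(rng.integers(1, branching + 1))
            parents = rng.choice(i, size=min(n_parents, i), replace=False)
            for p in parents:
                rel = "is_a" if rng.random() < 0.8 else "part_of"
                graph.add_edge(terms[i], terms[int(p)], relation=rel)
    return GoDag(graph=graph, namespace=namespace, name=name)


def make_rule_dag() -> GoDag:
    """The fixed small ontology the planted annotation rule refers to."""
    T = RULE_TERMS
    graph = nx.DiGraph()
    edges = [
        (T["mfo_binding"], T["mfo_root"]),
        (T["mfo_catalytic"], T["mfo_root"]),
        (T["mfo_helix"], T["mfo_binding"]),
        (T["mfo_extended"], T["mfo_catalytic"]),
        (T["bpo_process"], T["bpo_root"]),
        (T["bpo_motif"], T["bpo_process"]),
        (T["cco_cytoplasm"], T["cco_root"]),
    ]
    names = {
        T["mfo_root"]: "molecular function root",
        T["mfo_binding"]: "binding-like activity",
        T["mfo_catalytic"]: "catalytic-like activity",
        T["mfo_helix"]: "helical-fold activity",
        T["mfo_extended"]: "extended-fold activity",
        T["bpo_root"]: "biological process root",
        T["bpo_process"]: "motif-driven process",
        T["bpo_motif"]: "tryptophan-motif process",
        T["cco_root"]: "cellular component root",
        T["cco_cytoplasm"]: "cytoplasm-like location",
    }
    ns = {t: ("MFO" if t.startswith("GO:91") else "BPO" if t.startswith("GO:92") else "CCO")
          for t in names}
    graph.add_nodes_from(names)
    for child, parent in edges:
        graph.add_edge(child, parent, relation="is_a")
    return GoDag(graph=graph, namespace=ns, name=names)


def make_stub_embedding(sequence: str, dim: int = 32, seed: int = 0) -> np.ndarray:
    """Deterministic per-residue embedding keyed by (residue identity, position, seed).

    Each row is a residue-type vector plus a smaller position-keyed
    perturbation, so the embedding carries sequence-identity signal the way
    a language-model embedding would.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    type_vecs = {}
    rows = np.zeros((len(sequence), dim))
    for i, aa in enumerate(sequence):
        tok = ALPHABET.index(aa) if aa in ALPHABET else len(ALPHABET)
        if tok not in type_vecs:
            type_vecs[tok] = np.random.default_rng([seed, 1000 + tok]).standard_normal(dim)
        pos = np.random.default_rng([seed, 2_000_000 + i]).standard_normal(dim)
        rows[i] = type_vecs[tok] + 0.1 * pos
    return rows


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic corpus. The seed is mandatory."""

    seed: int
    n_proteins: int = 200
    length_range: tuple[int, int] = (28, 36)
    helix_fraction: float = 0.5
    motif_prob: float = 0.5
    homolog_fraction: float = 0.1
    mutation_rate: float = 0.1
    label_noise: float = 0.0
    low_conf_prob: float = 0.2
    low_conf_segment: int = 6
    embedding_dim: int = 32
    identity_floor: float = 0.3

    def __post_init__(self) -> None:
        for p in (self.helix_fraction, self.motif_prob, self.homolog_fraction,
                  self.mutation_rate, self.label_noise, self.low_conf_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_proteins < 1 or self.length_range[0] < 8:
            raise ValueError("invalid corpus size")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    structures: list[ProteinStructure]
    embeddings: dict[str, np.ndarray]
    annotations: AnnotationSet          # unpropagated leaf labels
    dag: GoDag
    identities: IdentityTable
    conformations: dict[str, str] = field(default_factory=dict)
    has_motif: dict[str, bool] = field(default_factory=dict)

    def protein_ids(self) -> list[str]:
        return [s.protein_id for s in self.structures]


def _sequence_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def _rule_labels(conformation: str, motif: bool, rng: np.random.Generator, noise: float) -> set[str]:
    T = RULE_TERMS
    conf = conformation
    if noise > 0 and rng.random() < noise:
        conf = "extended" if conf == "helix" else "helix"
    m = motif
    if noise > 0 and rng.random() < noise:
        m = not m
    labels = {T["cco_cytoplasm"], T["mfo_helix"] if conf == "helix" else T["mfo_extended"]}
    if m:
        labels.add(T["bpo_motif"])
    return labels


def make_synthetic_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate structures, embeddings, leaf annotations and an identity table."""
    rng = np.random.default_rng(spec.seed)
    dag = make_rule_dag()
    structures: list[ProteinStructure] = []
    embeddings: dict[str, np.ndarray] = {}
    annotations: dict[str, set[str]] = {}
    conformations: dict[str, str] = {}
    has_motif: dict[str, bool] = {}
    sequences: dict[str, str] = {}

    for i in range(spec.n_proteins):
        pid = f"SYN{i:04d}"
        parent = None
        if i > 0 and rng.random() < spec.homolog_fraction:
            parent = structures[int(rng.integers(0, i))].protein_id
        if parent is None:
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            conformation = "helix" if rng.random() < spec.helix_fraction else "extended"
            seq = list(rng.choice(list(ALPHABET.replace("W", "")), size=length))
            motif = rng.random() < spec.motif_prob
            if motif:
                start = int(rng.integers(0, length - len(MOTIF)))
                seq[start:start + len(MOTIF)] = list(MOTIF)
            sequence = "".join(seq)
        else:
            # mutated copy: same conformation and motif status, substituted sequence
            conformation = conformations[parent]
            motif = has_motif[parent]
            src = list(sequences[parent])
            length = len(src)
            for j in range(length):
                if src[j] != "W" and rng.random() < spec.mutation_rate:
                    src[j] = str(rng.choice(list(ALPHABET.replace("W", ""))))
            sequence = "".join(src)
        plddt = make_plddt_profile(length, rng, spec.low_conf_prob, spec.low_conf_segment)
        structure = make_toy_structure(
            length,
            conformation=conformation,
            seed=int(rng.integers(0, 2**31 - 1)),
            sequence=sequence,
            plddt=plddt,
            protein_id=pid,
        )
        structures.append(structure)
        sequences[pid] = sequence
        conformations[pid] = conformation
        has_motif[pid] = motif
        embeddings[pid] = make_stub_embedding(sequence, spec.embedding_dim, seed=spec.seed)
        annotations[pid] = _rule_labels(conformation, motif, rng, spec.label_noise)

    ids = [s.protein_id for s in structures]
    table: dict[tuple[str, str], float] = {}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            ident = _sequence_identity(sequences[ids[a]], sequences[ids[b]])
            if ident >= spec.identity_floor:
                table[(ids[a], ids[b])] = ident
                table[(ids[b], ids[a])] = ident
    return SyntheticDataset(
        spec=spec,
        structures=structures,
        embeddings=embeddings,
        annotations=AnnotationSet(annotations, propagated=False),
        dag=dag,
        identities=IdentityTable(table),
        conformations=conformations,
        has_motif=has_motif,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write the corpus in the formats the production readers consume."""
    from .go_graph import write_annotations
    from .structure_io import write_structure

    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    for s in dataset.structures:
        write_structure(s, out / "structures" / f"{s.protein_id}.pdb", format="pdb")
    np.savez(out / "embeddings.npz", **dataset.embeddings)
    write_annotations(dataset.annotations, out / "annotations.tsv")
    dataset.dag.to_obo(out / "go.obo")
    rows = [f"{q}\t{s}\t{v:.4f}" for (q, s), v in sorted(dataset.identities.scores.items())]
    (out / "identity.tsv").write_text("\n".join(rows) + "\n")
    return out
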