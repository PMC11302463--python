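"""Gene Ontology handling: OBO parsing, closures, propagation, information content.

The ontology is a directed acyclic graph per namespace (molecular function,
biological process, cellular component) with child -> parent edges of type
is_a or part_of. Annotations are propagated up to the namespace root
(label union over ancestors); prediction scores are propagated so a term
receives the maximum confidence among itself and its descendants. The
information content of a term f in an annotation corpus is
IC(f) = -log10(Occur_f / Occur_all), with Occur_f the number of distinct
proteins annotated (after propagation) with f and Occur_all the total
number of propagated (protein, term) pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

__all__ = [
    "GoDag",
    "AnnotationSet",
    "PredictionSet",
    "parse_obo",
    "propagate_annotations",
    "propagate_predictions",
    "information_content",
    "select_candidate_terms",
    "read_annotations",
    "write_annotations",
    "read_predictions",
    "write_predictions",
]

NAMESPACES = {
    "molecular_function": "MFO",
    "biological_process": "BPO",
    "cellular_component": "CCO",
}
_NS_LONG = {v: k for k, v in NAMESPACES.items()}
RELATIONS = ("is_a", "part_of")


class GoGraphError(ValueError):
    pass


@dataclass
class GoDag:
    """Ontology graph. ``graph`` holds child -> parent edges (is_a, part_of)."""

    graph: nx.DiGraph
    namespace: dict[str, str]            # term -> MFO | BPO | CCO
    name: dict[str, str]                 # term -> human-readable name
    alt_ids: dict[str, str] = field(default_factory=dict)
    roots: dict[str, str] = field(default_factory=dict)  # namespace code -> root term

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise GoGraphError("ontology graph contains a cycle")
        bad_ns = set(self.namespace.values()) - set(NAMESPACES.values())
        if bad_ns:
            raise GoGraphError(f"unknown namespace(s): {sorted(bad_ns)}")
        if not self.roots:
            for ns in sorted(set(self.namespace.values())):
                terms = [t for t, n in self.namespace.items() if n == ns]
                candidates = [t for t in terms if self.graph.out_degree(t) == 0]
                if len(candidates) != 1:
                    raise GoGraphError(f"namespace {ns} has {len(candidates)} roots; expected 1")
                self.roots[ns] = candidates[0]
        for term in self.graph.nodes:
            ns = self.namespace[term]
            root = self.roots[ns]
            if term != root and not nx.has_path(self.graph, term, root):
                raise GoGraphError(f"term {term} cannot reach its namespace root {root}")

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary id (identity for primary ids)."""
        return self.alt_ids.get(term, term)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by is_a/part_of edges, excluding the term itself."""
        term = self.resolve(term)
        if term not in self.graph:
            raise GoGraphError(f"unknown term {term}")
        return set(nx.descendants(self.graph, term))  # child->parent edges point rootward

    def descendants(self, term: str) -> set[str]:
        term = self.resolve(term)
        if term not in self.graph:
            raise GoGraphError(f"unknown term {term}")
        return set(nx.ancestors(self.graph, term))

    def terms_in(self, ontology: str) -> set[str]:
        if ontology not in _NS_LONG:
            raise GoGraphError(f"unknown ontology code {ontology!r}; expected MFO, BPO or CCO")
        return {t for t, ns in self.namespace.items() if ns == ontology}

    def to_obo(self, path: str | Path) -> Path:
        """Serialize to a minimal OBO 1.2 document the parser round-trips."""
        path = Path(path)
        lines = ["format-version: 1.2", ""]
        for term in sorted(self.graph.nodes):
            lines += [
                "[Term]",
                f"id: {term}",
                f"name: {self.name.get(term, term)}",
                f"namespace: {_NS_LONG[self.namespace[term]]}",
            ]
            for alt, primary in sorted(self.alt_ids.items()):
                if primary == term:
                    lines.append(f"alt_id: {alt}")
            for _, parent, data in self.graph.out_edges(term, data=True):
                rel = data.get("relation", "is_a")
                if rel == "is_a":
                    lines.append(f"is_a: {parent} ! {self.name.get(parent, parent)}")
                else:
                    lines.append(f"relationship: {rel} {parent} ! {self.name.get(parent, parent)}")
            lines.append("")
        path.write_text("\n".join(lines))
        return path


def parse_obo(path: str | Path) -> GoDag:
    """Parse an OBO file: obsolete terms dropped, alt_ids mapped, is_a + part_of kept."""
    raw = obonet.read_obo(str(path), ignore_obsolete=True)
    graph = nx.DiGraph()
    namespace: dict[str, str] = {}
    name: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for term, data in raw.nodes(data=True):
        ns = data.get("namespace")
        if ns not in NAMESPACES:
            raise GoGraphError(f"term {term} has unknown namespace {ns!r}")
        graph.add_node(term)
        namespace[term] = NAMESPACES[ns]
        name[term] = data.get("name", term)
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    for child, parent, key in raw.edges(keys=True):
        if key in RELATIONS and parent in graph:
            graph.add_edge(child, parent, relation=key)
    return GoDag(graph=graph, namespace=namespace, name=name, alt_ids=alt_ids)


@dataclass
class AnnotationSet:
    """protein_id -> set of GO terms, with a propagation flag."""

    annotations: dict[str, set[str]]
    propagated: bool = False

    def __len__(self) -> int:
        return len(self.annotations)

    def __getitem__(self, protein: str) -> set[str]:
        return self.annotations[protein]

    def proteins(self) -> list[str]:
        return sorted(self.annotations)

    def restricted(self, terms: set[str]) -> "AnnotationSet":
        return AnnotationSet(
            {p: ts & terms for p, ts in self.annotations.items()}, propagated=self.propagated
        )


@dataclass
class PredictionSet:
    """protein_id -> {term -> confidence in [0, 1]}."""

    scores: dict[str, dict[str, float]]
    propagated: bool = False

    def __getitem__(self, protein: str) -> dict[str, float]:
        return self.scores[protein]

    def proteins(self) -> list[str]:
        return sorted(self.scores)

    def validate(self) -> None:
        for p, table in self.scores.items():
            for t, c in table.items():
                if not 0.0 <= c <= 1.0:
                    raise ValueError(f"confidence {c} for ({p}, {t}) outside [0, 1]")


def propagate_annotations(ann: AnnotationSet, dag: GoDag) -> AnnotationSet:
    """Union every protein's term set with all ancestors (idempotent)."""
    out: dict[str, set[str]] = {}
    unknown: set[str] = set()
    for protein, terms in ann.annotations.items():
        full: set[str] = set()
        for t in terms:
            rt = dag.resolve(t)
            if rt not in dag.graph:
                unknown.add(t)
                continue
            full.add(rt)
            full |= dag.ancestors(rt)
        out[protein] = full
    if unknown:
        raise GoGraphError(f"annotation terms not in DAG: {sorted(unknown)}")
    return AnnotationSet(out, propagated=True)


def propagate_predictions(preds: PredictionSet, dag: GoDag) -> PredictionSet:
    """score(f) := max over f and all its descendants of the input scores."""
    # single reverse-topological sweep: children processed before parents
    order = list(nx.topological_sort(dag.graph))  # children before parents (edges child->parent)
    out: dict[str, dict[str, float]] = {}
    for protein, table in preds.scores.items():
        resolved = {}
        for t, c in table.items():
            rt = dag.resolve(t)
            resolved[rt] = max(resolved.get(rt, 0.0), c)
        prop = dict(resolved)
        for term in order:
            if term not in prop:
                continue
            for _, parent in dag.graph.out_edges(term):
                if prop.get(parent, -1.0) < prop[term]:
                    prop[parent] = prop[term]
        out[protein] = prop
    return PredictionSet(out, propagated=True)


def information_content(ann: AnnotationSet, dag: GoDag) -> dict[str, float]:
    """IC(f) = -log10(Occur_f / Occur_all) on a propagated corpus.

    Occur_f counts distinct annotated proteins; terms never annotated get
    IC = +inf (excluded from semantic-distance sums by the caller).
    """
    if not ann.propagated:
        raise ValueError("information content requires propagated annotations")
    if not ann.annotations or all(len(t) == 0 for t in ann.annotations.values()):
        raise ValueError("empty annotation corpus")
    occur: dict[str, int] = {}
    total = 0
    for terms in ann.annotations.values():
        total += len(terms)
        for t in terms:
            occur[t] = occur.get(t, 0) + 1
    ic: dict[str, float] = {}
    for term in dag.graph.nodes:
        n = occur.get(term, 0)
        ic[term] = math.inf if n == 0 else -math.log10(n / total)
    return ic


def select_candidate_terms(ann: AnnotationSet, min_proteins: int = 50, dag: GoDag | None = None) -> list[str]:
    """Sorted terms annotated to at least ``min_proteins`` distinct proteins.

    Namespace roots are excluded. Expects propagated training annotations.
    """
    if not ann.propagated:
        raise ValueError("candidate selection requires propagated annotations")
    counts: dict[str, int] = {}
    for terms in ann.annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    roots = set(dag.roots.values()) if dag is not None else set()
    selected = sorted(t for t, n in counts.items() if n >= min_proteins and t not in roots)
    if not selected:
        raise ValueError("no terms meet the candidate threshold")
    return selected


# -- annotation / prediction table I/O ---------------------------------------

EXPERIMENTAL_EVIDENCE = ("EXP", "IDA", "IMP", "IGI", "IEP", "TAS", "IC")


def read_annotations(
    path: str | Path,
    evidence_filter: tuple[str, ...] | None = None,
) -> AnnotationSet:
    """Read a TSV of ``protein_id<TAB>term_id[<TAB>evidence_code]`` rows.

    With ``evidence_filter`` set (e.g. the experimental codes), rows with
    other codes are dropped. ``NOT``-qualified rows are dropped with a warning.
    """
    out: dict[str, set[str]] = {}
    dropped_not = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed annotation row: {line!r}")
        protein, term = parts[0], parts[1]
        qualifier = parts[3] if len(parts) > 3 else ""
        if "NOT" in qualifier.split("|"):
            dropped_not += 1
            continue
        if evidence_filter is not None and len(parts) > 2 and parts[2] not in evidence_filter:
            continue
        out.setdefault(protein, set()).add(term)
    if dropped_not:
        warnings.warn(f"dropped {dropped_not} NOT-qualified annotation rows", stacklevel=2)
    return AnnotationSet(out, propagated=False)


def write_annotations(ann: AnnotationSet, path: str | Path, evidence: str = "IDA") -> Path:
    path = Path(path)
    rows = [f"{p}\t{t}\t{evidence}" for p in ann.proteins() for t in sorted(ann.annotations[p])]
    path.write_text("\n".join(rows) + "\n")
    return path


def read_predictions(path: str | Path) -> PredictionSet:
    """Read a CAFA-style TSV: protein_id, term_id, confidence."""
    out: dict[str, dict[str, float]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        protein, term, conf = line.rstrip("\n").split("\t")[:3]
        out.setdefault(protein, {})[term] = float(conf)
    ps = PredictionSet(out)
    ps.validate()
    return ps


def write_predictions(preds: PredictionSet, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        f"{p}\t{t}\t{preds.scores[p][t]:.3f}"
        for p in preds.proteins()
        for t in sorted(preds.scores[p])
    ]
    path.write_text("\n".join(rows) + "\n")
    return path
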