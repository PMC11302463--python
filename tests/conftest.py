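"""Shared fixtures: hand-written structure files, toy ontologies, tiny corpora."""

from __future__ import annotations

import numpy as np
import pytest

from gvpgo.go_graph import GoDag
from gvpgo.structure_io import ProteinStructure, Residue

# A 3-residue hand-written PDB fixture; B-factors 95.0 / 85.0 / 91.0 so the
# parsed pLDDT must be 0.95 / 0.85 / 0.91.
THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 95.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 95.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 95.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00 85.00           N
ATOM      5  CA  GLY A   2       4.042   2.794   0.210  1.00 85.00           C
ATOM      6  C   GLY A   2       5.521   2.527   0.480  1.00 85.00           C
ATOM      7  N   TRP A   3       6.300   3.590   0.610  1.00 91.00           N
ATOM      8  CA  TRP A   3       7.740   3.480   0.850  1.00 91.00           C
ATOM      9  C   TRP A   3       8.480   4.790   0.620  1.00 91.00           C
TER
END
"""

TOY_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: mfo root
namespace: molecular_function

[Term]
id: GO:0000002
name: term b
namespace: molecular_function
alt_id: GO:0000099
is_a: GO:0000001 ! mfo root

[Term]
id: GO:0000003
name: term c
namespace: molecular_function
is_a: GO:0000002 ! term b

[Term]
id: GO:0000004
name: term d (diamond left)
namespace: molecular_function
is_a: GO:0000002 ! term b
relationship: part_of GO:0000001 ! mfo root

[Term]
id: GO:0000005
name: obsolete term
namespace: molecular_function
is_obsolete: true
is_a: GO:0000001 ! mfo root
"""


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def toy_obo(tmp_path):
    path = tmp_path / "toy.obo"
    path.write_text(TOY_OBO)
    return path


def make_structure(ca_coords, plddt=None, sequence=None, protein_id="test"):
    """Structure with given CA positions; N and C offset so frames are valid."""
    ca = np.asarray(ca_coords, dtype=float)
    L = len(ca)
    plddt = np.full(L, 0.95) if plddt is None else np.asarray(plddt, dtype=float)
    sequence = "A" * L if sequence is None else sequence
    residues = [
        Residue(i + 1, sequence[i],
                ca[i] + np.array([-1.0, 0.5, 0.0]),
                ca[i],
                ca[i] + np.array([1.0, 0.8, 0.3]),
                float(plddt[i]))
        for i in range(L)
    ]
    return ProteinStructure(protein_id, residues)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR with positive diagonal."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def chain_dag() -> GoDag:
    """c -> b -> a (root), single namespace."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_edge("GO:c", "GO:b", relation="is_a")
    g.add_edge("GO:b", "GO:a", relation="is_a")
    ns = {t: "MFO" for t in ("GO:a", "GO:b", "GO:c")}
    return GoDag(graph=g, namespace=ns, name={t: t for t in ns})
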