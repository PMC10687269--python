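"""Graph construction for proteins and drugs.

Proteins are residue contact graphs: one node per residue (located at its
C-alpha atom), an edge whenever two residues lie closer than 8 A in space.
Node features are per-residue embedding vectors supplied by the caller (e.g.
exported from a protein language model); this module never runs such a model
itself.

Drugs are heavy-atom molecular graphs parsed from SMILES with RDKit and
encoded with the OGB-style categorical vocabularies: a 9-tuple of integer
codes per atom and a 3-tuple per bond.  Unknown categories map to a reserved
``misc`` code at the end of each vocabulary.

Affinity measurements (Ki/Kd/IC50/EC50, in nM) are binarized with the
standard thresholds: below 1000 nM is binding, above 1e6 nM is nonbinding,
anything in between is excluded from the benchmark.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

BINDING = "binding"
NONBINDING = "nonbinding"
EXCLUDED = "excluded"

CONTACT_CUTOFF = 8.0  # Angstroms, strict '<'

AFFINITY_TYPES = ("Ki", "Kd", "IC50", "EC50")


class GraphError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ProteinGraph:
    """Residue contact graph.

    ``edges`` stores each undirected contact once as ``(i, j)`` with
    ``i < j``; ``edge_distance[k]`` is the Euclidean C-alpha distance of
    ``edges[k]``.  ``adjacency`` is the dense symmetric 0/1 matrix.
    """

    protein_id: str
    coords: np.ndarray           # (n, 3) float, Angstroms
    node_features: np.ndarray    # (n, D_p) float
    edges: np.ndarray            # (m, 2) int, i < j
    edge_distance: np.ndarray    # (m,) float

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        n = self.n_residues
        a = np.zeros((n, n))
        if len(self.edges):
            a[self.edges[:, 0], self.edges[:, 1]] = 1.0
            a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a

    def neighbors(self, i: int) -> set[int]:
        out = set()
        for a, b in self.edges:
            if a == i:
                out.add(int(b))
            elif b == i:
                out.add(int(a))
        return out


@dataclass
class MoleculeGraph:
    """Heavy-atom molecular graph with categorical OGB-style features.

    ``node_features`` is (n_atoms, 9) integer codes; ``edges`` stores each
    bond once as ``(i, j)`` with ``i < j`` and ``edge_features`` is the
    parallel (m, 3) integer code array.
    """

    molecule_id: str
    smiles: Optional[str]
    node_features: np.ndarray    # (n, 9) int codes
    edges: np.ndarray            # (m, 2) int, i < j
    edge_features: np.ndarray    # (m, 3) int codes

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        n = self.n_atoms
        a = np.zeros((n, n))
        if len(self.edges):
            a[self.edges[:, 0], self.edges[:, 1]] = 1.0
            a[self.edges[:, 1], self.edges[:, 0]] = 1.0
        return a


@dataclass(frozen=True)
class InteractionRecord:
    protein_id: str
    molecule_id: str
    label: str                           # binding / nonbinding
    provenance: str = "measured"         # measured / network_negative
    affinity_nM: Optional[float] = None
    affinity_type: Optional[str] = None

    def __post_init__(self):
        if self.label not in (BINDING, NONBINDING):
            raise GraphError(f"bad label {self.label!r}")
        if self.provenance not in ("measured", "network_negative"):
            raise GraphError(f"bad provenance {self.provenance!r}")
        if self.label == BINDING and self.provenance != "measured":
            raise GraphError("binding records must be measured")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_id, self.molecule_id)


# ---------------------------------------------------------------------------
# protein graphs
# ---------------------------------------------------------------------------

def build_protein_graph(coords, node_features, protein_id: str,
                        cutoff: float = CONTACT_CUTOFF) -> ProteinGraph:
    """Build the residue contact graph: edge iff distance < ``cutoff``."""
    coords = np.asarray(coords, dtype=float)
    node_features = np.asarray(node_features, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise GraphError(f"coords must be (n, 3), got {coords.shape}")
    if coords.shape[0] < 2:
        raise GraphError("need at least 2 residues")
    if node_features.shape[0] != coords.shape[0]:
        raise GraphError(
            f"{node_features.shape[0]} feature rows for {coords.shape[0]} residues")
    if not np.all(np.isfinite(coords)):
        raise GraphError("non-finite coordinates")

    from scipy.spatial.distance import pdist, squareform
    dmat = squareform(pdist(coords))
    iu, ju = np.triu_indices(coords.shape[0], k=1)
    mask = dmat[iu, ju] < cutoff
    edges = np.stack([iu[mask], ju[mask]], axis=1).astype(int)
    dists = dmat[iu, ju][mask]
    return ProteinGraph(protein_id=protein_id, coords=coords,
                        node_features=node_features, edges=edges,
                        edge_distance=dists)


def read_structure(pdb_text: str, chain: Optional[str] = None):
    """Extract per-residue C-alpha coordinates from PDB-format text.

    Returns ``(coords, residue_labels)`` where ``residue_labels[i]`` is
    ``(chain_id, residue_number, residue_name)`` in author order.  Only the
    first model is read; hetero residues and waters are skipped; for altloc
    duplicates a single C-alpha per residue is kept (the parser's selected
    conformer).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise GraphError("empty structure") from None

    chain_ids = [c.id for c in model]
    if chain is not None and chain not in chain_ids:
        raise KeyError(f"chain {chain!r} not in structure (has {chain_ids})")

    coords, labels = [], []
    for c in model:
        if chain is not None and c.id != chain:
            continue
        for res in c:
            if res.id[0] != " ":    # skip HETATM / waters
                continue
            if "CA" not in res:
                continue
            coords.append(np.asarray(res["CA"].get_coord(), dtype=float))
            labels.append((c.id, res.id[1], res.get_resname()))
    if not coords:
        raise GraphError("no C-alpha atoms found")
    return np.stack(coords), labels


# ---------------------------------------------------------------------------
# molecule graphs (OGB-style categorical vocabularies)
# ---------------------------------------------------------------------------

# Feature order: atomic number, chirality, formal charge, attached H count,
# radical electrons, hybridization, aromatic flag, degree, in-ring flag.
ATOM_VOCAB = {
    "atomic_num": list(range(1, 120)) + ["misc"],
    "chirality": ["CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW",
                  "CHI_TETRAHEDRAL_CCW", "CHI_OTHER", "misc"],
    "formal_charge": [-5, -4, -3, -2, -1, 0, 1, 2, 3, 4, 5, "misc"],
    "num_h": [0, 1, 2, 3, 4, 5, 6, 7, 8, "misc"],
    "radical_e": [0, 1, 2, 3, 4, "misc"],
    "hybridization": ["SP", "SP2", "SP3", "SP3D", "SP3D2", "misc"],
    "is_aromatic": [False, True],
    "degree": [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, "misc"],
    "is_in_ring": [False, True],
}
ATOM_FEATURE_NAMES = list(ATOM_VOCAB)

BOND_VOCAB = {
    "bond_type": ["SINGLE", "DOUBLE", "TRIPLE", "AROMATIC", "misc"],
    "stereo": ["STEREONONE", "STEREOZ", "STEREOE", "STEREOCIS",
               "STEREOTRANS", "STEREOANY"],
    "is_conjugated": [False, True],
}
BOND_FEATURE_NAMES = list(BOND_VOCAB)

ATOM_FEATURE_DIMS = [len(ATOM_VOCAB[k]) for k in ATOM_FEATURE_NAMES]
BOND_FEATURE_DIMS = [len(BOND_VOCAB[k]) for k in BOND_FEATURE_NAMES]


def _code(vocab: list, value) -> int:
    try:
        return vocab.index(value)
    except ValueError:
        return len(vocab) - 1      # reserved 'misc'


def atom_feature_codes(atom) -> list[int]:
    return [
        _code(ATOM_VOCAB["atomic_num"], atom.GetAtomicNum()),
        _code(ATOM_VOCAB["chirality"], str(atom.GetChiralTag())),
        _code(ATOM_VOCAB["formal_charge"], atom.GetFormalCharge()),
        _code(ATOM_VOCAB["num_h"], atom.GetTotalNumHs()),
        _code(ATOM_VOCAB["radical_e"], atom.GetNumRadicalElectrons()),
        _code(ATOM_VOCAB["hybridization"], str(atom.GetHybridization())),
        _code(ATOM_VOCAB["is_aromatic"], atom.GetIsAromatic()),
        _code(ATOM_VOCAB["degree"], atom.GetTotalDegree()),
        _code(ATOM_VOCAB["is_in_ring"], atom.IsInRing()),
    ]


def bond_feature_codes(bond) -> list[int]:
    return [
        _code(BOND_VOCAB["bond_type"], str(bond.GetBondType())),
        _code(BOND_VOCAB["stereo"], str(bond.GetStereo())),
        _code(BOND_VOCAB["is_conjugated"], bond.GetIsConjugated()),
    ]


def build_molecule_graph(smiles: str, molecule_id: str) -> MoleculeGraph:
    """Parse a SMILES string into the heavy-atom categorical graph."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GraphError(f"unparsable SMILES: {smiles!r}")
    node_features = np.array([atom_feature_codes(a) for a in mol.GetAtoms()],
                             dtype=int).reshape(mol.GetNumAtoms(), 9)
    edges, efeat = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
        efeat.append(bond_feature_codes(bond))
    edges = np.array(edges, dtype=int).reshape(-1, 2)
    efeat = np.array(efeat, dtype=int).reshape(-1, 3)
    order = np.lexsort((edges[:, 1], edges[:, 0])) if len(edges) else []
    return MoleculeGraph(molecule_id=molecule_id, smiles=smiles,
                         node_features=node_features,
                         edges=edges[order] if len(edges) else edges,
                         edge_features=efeat[order] if len(efeat) else efeat)


# ---------------------------------------------------------------------------
# affinity binarization
# ---------------------------------------------------------------------------

def label_from_affinity(affinity_nM: float, affinity_type: str = "Ki",
                        positive_below: float = 1000.0,
                        negative_above: float = 1e6) -> str:
    """Binarize an affinity: < 1000 nM binding, > 1e6 nM nonbinding."""
    if not np.isfinite(affinity_nM) or affinity_nM <= 0:
        raise GraphError(f"affinity must be positive, got {affinity_nM}")
    if affinity_type not in AFFINITY_TYPES:
        raise GraphError(f"unknown affinity type {affinity_type!r}")
    if affinity_nM < positive_below:
        return BINDING
    if affinity_nM > negative_above:
        return NONBINDING
    return EXCLUDED


def records_from_table(df) -> list[InteractionRecord]:
    """Convert an interaction table (pandas DataFrame) into records.

    Accepts either (protein_id, molecule_id, affinity_nM, affinity_type) —
    binarized via :func:`label_from_affinity`, records falling between the
    thresholds dropped — or (protein_id, molecule_id, label).
    """
    out = []
    if "affinity_nM" in df.columns:
        for row in df.itertuples(index=False):
            lab = label_from_affinity(float(row.affinity_nM), row.affinity_type)
            if lab == EXCLUDED:
                continue
            out.append(InteractionRecord(str(row.protein_id), str(row.molecule_id),
                                         lab, "measured",
                                         float(row.affinity_nM), row.affinity_type))
    else:
        for row in df.itertuples(index=False):
            out.append(InteractionRecord(str(row.protein_id), str(row.molecule_id),
                                         str(row.label)))
    return out


# ---------------------------------------------------------------------------
# JSON graph container
# ---------------------------------------------------------------------------

def protein_graph_to_dict(g: ProteinGraph) -> dict:
    return {
        "kind": "protein",
        "protein_id": g.protein_id,
        "coords": g.coords.tolist(),
        "node_features": g.node_features.tolist(),
        "edges": g.edges.tolist(),
        "edge_distance": g.edge_distance.tolist(),
    }


def molecule_graph_to_dict(g: MoleculeGraph) -> dict:
    return {
        "kind": "molecule",
        "molecule_id": g.molecule_id,
        "smiles": g.smiles,
        "node_features": g.node_features.tolist(),
        "edges": g.edges.tolist(),
        "edge_features": g.edge_features.tolist(),
    }


def graph_from_dict(d: dict):
    if d["kind"] == "protein":
        return ProteinGraph(
            protein_id=d["protein_id"],
            coords=np.asarray(d["coords"], dtype=float),
            node_features=np.asarray(d["node_features"], dtype=float),
            edges=np.asarray(d["edges"], dtype=int).reshape(-1, 2),
            edge_distance=np.asarray(d["edge_distance"], dtype=float),
        )
    if d["kind"] == "molecule":
        return MoleculeGraph(
            molecule_id=d["molecule_id"],
            smiles=d.get("smiles"),
            node_features=np.asarray(d["node_features"], dtype=int),
            edges=np.asarray(d["edges"], dtype=int).reshape(-1, 2),
            edge_features=np.asarray(d["edge_features"], dtype=int).reshape(-1, 3),
        )
    raise GraphError(f"unknown graph kind {d.get('kind')!r}")


def save_graphs(graphs: Sequence, path) -> None:
    """Serialize a mixed list of graphs to a JSON bundle (version-stamped)."""
    payload = {"format": "metabind-graphs", "version": 1, "graphs": []}
    for g in graphs:
        payload["graphs"].append(
            protein_graph_to_dict(g) if isinstance(g, ProteinGraph)
            else molecule_graph_to_dict(g))
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_graphs(path) -> list:
    with open(path) as fh:
        payload = json.load(fh)
    return [graph_from_dict(d) for d in payload["graphs"]]
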