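"""Molecular representations for the classifiers and the WL network.

Three channels:

* binary fingerprints — AtomPairs, MACCS, Morgan (radius 2), topological
  torsions and RDKit path fingerprints, folded to 512/1024/2048 bits
  (MACCS is fixed at 166 bits);
* a physicochemical 2D descriptor vector with training-fold-only
  standardization;
* node/edge one-hot featurized molecular graphs for the graph classifiers
  (scheme ``classifier``) and the WL network (scheme ``wln``).

Featurization is a pure function of the molecule: the same canonical
structure always yields identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, MACCSkeys
from rdkit.Chem import rdFingerprintGenerator as _rfg

VOCAB_VERSION = "1.0"

FP_KINDS = ("atompairs", "maccs", "morgan", "topotorsion", "rdkit_path")
FOLDED_NBITS = (512, 1024, 2048)
MACCS_NBITS = 166  # RDKit emits 167 bits with bit 0 always unset; dropped

MORGAN_RADIUS = 2


@dataclass(frozen=True)
class FingerprintVector:
    kind: str
    nbits: int
    bits: np.ndarray = field(compare=False)


@dataclass(frozen=True)
class DescriptorVector:
    names: Tuple[str, ...]
    values: np.ndarray = field(compare=False)


@dataclass
class MolGraph:
    """Heavy-atom molecular graph with one-hot node/edge feature blocks.

    ``src``/``dst`` list every bond in both directions, so the edge list is
    symmetric; ``edge_feats`` rows align with the directed edges.
    """

    n_atoms: int
    node_feats: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    edge_feats: np.ndarray
    scheme: str

    @property
    def n_bonds(self) -> int:
        return len(self.src) // 2


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

def _bitvect(mol: Chem.Mol, kind: str, nbits: Optional[int]):
    if kind == "maccs":
        return MACCSkeys.GenMACCSKeys(mol)
    if nbits not in FOLDED_NBITS:
        raise ValueError(
            f"nbits must be one of {FOLDED_NBITS} for kind {kind!r}, "
            f"got {nbits}")
    if kind == "morgan":
        gen = _rfg.GetMorganGenerator(radius=MORGAN_RADIUS, fpSize=nbits)
    elif kind == "atompairs":
        gen = _rfg.GetAtomPairGenerator(fpSize=nbits)
    elif kind == "topotorsion":
        gen = _rfg.GetTopologicalTorsionGenerator(fpSize=nbits)
    elif kind == "rdkit_path":
        gen = _rfg.GetRDKitFPGenerator(fpSize=nbits)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    return gen.GetFingerprint(mol)


def fingerprint(mol: Chem.Mol, kind: str,
                nbits: Optional[int] = None) -> FingerprintVector:
    """Deterministic binary fingerprint. ``nbits`` is ignored for MACCS."""
    bv = _bitvect(mol, kind, nbits)
    arr = np.zeros((bv.GetNumBits(),), dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(bv, arr)
    if kind == "maccs":
        arr = arr[1:]  # bit 0 is a placeholder, never set
        return FingerprintVector(kind, MACCS_NBITS, arr)
    return FingerprintVector(kind, nbits, arr)


def fingerprint_matrix(mols: Sequence[Chem.Mol], kind: str,
                       nbits: Optional[int] = None) -> np.ndarray:
    return np.vstack([fingerprint(m, kind, nbits).bits for m in mols])


# ---------------------------------------------------------------------------
# physicochemical descriptors
# ---------------------------------------------------------------------------

_DESCRIPTOR_NAMES: Optional[Tuple[str, ...]] = None


def descriptor_names() -> Tuple[str, ...]:
    """Stable, ordered manifest of 2D descriptor names."""
    global _DESCRIPTOR_NAMES
    if _DESCRIPTOR_NAMES is None:
        _DESCRIPTOR_NAMES = tuple(
            d[0] for d in Descriptors._descList)
    return _DESCRIPTOR_NAMES


def descriptors(mol: Chem.Mol) -> DescriptorVector:
    """Fixed-length real vector of 2D physicochemical descriptors.

    The molecule is canonicalized first: a few descriptors (BCUT
    eigenvalues, logP sums) are atom-order sensitive at machine epsilon,
    and canonical order makes the vector bitwise reproducible for any
    SMILES alias. Descriptor failures yield NaN entries; imputation
    happens in :class:`DescriptorScaler` with training-fold medians.
    """
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    values = Descriptors.CalcMolDescriptors(mol)
    names = descriptor_names()
    arr = np.array([float(values.get(n, np.nan)) for n in names])
    return DescriptorVector(names, arr)


def descriptor_matrix(mols: Sequence[Chem.Mol]) -> np.ndarray:
    return np.vstack([descriptors(m).values for m in mols])


class DescriptorScaler:
    """Median imputation + per-feature standardization.

    Fit on training folds only; apply to held-out data with the stored
    parameters so train/test never share statistics.
    """

    def __init__(self):
        self.medians_: Optional[np.ndarray] = None
        self.means_: Optional[np.ndarray] = None
        self.stds_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "DescriptorScaler":
        X = np.asarray(X, dtype=float)
        finite = np.where(np.isfinite(X), X, np.nan)
        with np.errstate(all="ignore"):
            self.medians_ = np.nan_to_num(np.nanmedian(finite, axis=0))
        Xi = self._impute(X)
        self.means_ = Xi.mean(axis=0)
        stds = Xi.std(axis=0)
        self.stds_ = np.where(stds > 0, stds, 1.0)
        return self

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float).copy()
        bad = ~np.isfinite(X)
        if bad.any():
            X[bad] = np.broadcast_to(self.medians_, X.shape)[bad]
        return X

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.medians_ is None:
            raise RuntimeError("scaler is not fitted")
        return (self._impute(X) - self.means_) / self.stds_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def to_json(self) -> str:
        return json.dumps({
            "vocab_version": VOCAB_VERSION,
            "medians": self.medians_.tolist(),
            "means": self.means_.tolist(),
            "stds": self.stds_.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "DescriptorScaler":
        payload = json.loads(text)
        obj = cls()
        obj.medians_ = np.array(payload["medians"])
        obj.means_ = np.array(payload["means"])
        obj.stds_ = np.array(payload["stds"])
        return obj


# ---------------------------------------------------------------------------
# molecular graphs
# ---------------------------------------------------------------------------

ATOM_TYPES = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
DEGREES = (0, 1, 2, 3, 4, 5)
EXPLICIT_VALENCES = (0, 1, 2, 3, 4, 5, 6)
IMPLICIT_VALENCES = (0, 1, 2, 3, 4, 5)
FORMAL_CHARGES = (-1, 0, 1)
BOND_TYPES = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE,
              Chem.BondType.TRIPLE, Chem.BondType.AROMATIC)


def node_blocks(scheme: str) -> List[Tuple[str, object]]:
    """Ordered node feature layout. Each categorical block carries an extra
    trailing "other" slot so every one-hot row sums to exactly 1."""
    blocks = [
        ("atom_type", ATOM_TYPES),
        ("degree", DEGREES),
        ("explicit_valence", EXPLICIT_VALENCES),
        ("implicit_valence", IMPLICIT_VALENCES),
        ("aromatic", "flag"),
    ]
    if scheme == "classifier":
        blocks.extend([("formal_charge", FORMAL_CHARGES), ("in_ring", "flag")])
    elif scheme != "wln":
        raise ValueError(f"unknown graph scheme {scheme!r}")
    return blocks


def edge_blocks(scheme: str) -> List[Tuple[str, object]]:
    return [
        ("bond_type", BOND_TYPES),
        ("conjugated", "flag"),
        ("in_ring", "flag"),
    ]


def _one_hot(value, categories) -> np.ndarray:
    vec = np.zeros(len(categories) + 1)
    try:
        vec[categories.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0  # explicit "other" slot
    return vec


def _node_values(atom: Chem.Atom) -> Dict[str, object]:
    return {
        "atom_type": atom.GetSymbol(),
        "degree": atom.GetDegree(),
        "explicit_valence": atom.GetExplicitValence(),
        "implicit_valence": atom.GetImplicitValence(),
        "aromatic": atom.GetIsAromatic(),
        "formal_charge": atom.GetFormalCharge(),
        "in_ring": atom.IsInRing(),
    }


def _featurize_blocks(values: Dict[str, object], blocks) -> np.ndarray:
    parts = []
    for name, cats in blocks:
        if cats == "flag":
            parts.append(np.array([1.0 if values[name] else 0.0]))
        else:
            parts.append(_one_hot(values[name], list(cats)))
    return np.concatenate(parts)


def node_feature_width(scheme: str) -> int:
    return sum(1 if c == "flag" else len(c) + 1
               for _, c in node_blocks(scheme))


def edge_feature_width(scheme: str) -> int:
    return sum(1 if c == "flag" else len(c) + 1
               for _, c in edge_blocks(scheme))


def mol_to_graph(mol: Chem.Mol, scheme: str = "wln") -> MolGraph:
    """Heavy-atom graph with concatenated one-hot/flag feature blocks."""
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError("molecule has no heavy atoms")
    nblocks = node_blocks(scheme)
    eblocks = edge_blocks(scheme)
    node_feats = np.vstack([
        _featurize_blocks(_node_values(a), nblocks) for a in mol.GetAtoms()])
    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        values = {
            "bond_type": bond.GetBondType(),
            "conjugated": bond.GetIsConjugated(),
            "in_ring": bond.IsInRing(),
        }
        vec = _featurize_blocks(values, eblocks)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src.extend([i, j])
        dst.extend([j, i])
        efeat.extend([vec, vec])
    edge_feats = (np.vstack(efeat) if efeat
                  else np.zeros((0, edge_feature_width(scheme))))
    return MolGraph(
        n_atoms=n, node_feats=node_feats.astype(np.float64),
        src=np.array(src, dtype=np.intp), dst=np.array(dst, dtype=np.intp),
        edge_feats=edge_feats.astype(np.float64), scheme=scheme)


def decode_node_features(graph: MolGraph) -> List[Dict[str, object]]:
    """Invert the one-hot encoding back to per-atom attribute values (the
    catch-all slot decodes to the string ``"other"``)."""
    decoded = []
    for row in graph.node_feats:
        out: Dict[str, object] = {}
        pos = 0
        for name, cats in node_blocks(graph.scheme):
            if cats == "flag":
                out[name] = bool(row[pos])
                pos += 1
            else:
                width = len(cats) + 1
                idx = int(np.argmax(row[pos:pos + width]))
                out[name] = list(cats)[idx] if idx < len(cats) else "other"
                pos += width
        decoded.append(out)
    return decoded


def combine_graphs(graphs: Sequence[MolGraph]):
    """Stack graphs into one block-diagonal graph.

    Returns ``(node_feats, src, dst, edge_feats, node_graph_ids, offsets)``
    where ``offsets[i]`` is the first node index of graph ``i``.
    """
    offsets = np.cumsum([0] + [g.n_atoms for g in graphs])
    node_feats = np.vstack([g.node_feats for g in graphs])
    src = np.concatenate([g.src + off for g, off in zip(graphs, offsets)]) \
        if graphs else np.zeros(0, dtype=np.intp)
    dst = np.concatenate([g.dst + off for g, off in zip(graphs, offsets)]) \
        if graphs else np.zeros(0, dtype=np.intp)
    edge_feats = np.vstack([g.edge_feats for g in graphs])
    gids = np.concatenate([
        np.full(g.n_atoms, i, dtype=np.intp) for i, g in enumerate(graphs)])
    return node_feats, src.astype(np.intp), dst.astype(np.intp), \
        edge_feats, gids, offsets


# ---------------------------------------------------------------------------
# similarity QC
# ---------------------------------------------------------------------------

def tanimoto_matrix(mols: Sequence[Chem.Mol], kind: str = "morgan",
                    nbits: int = 1024) -> np.ndarray:
    """Symmetric pairwise Tanimoto matrix (diagonal 1)."""
    if len(mols) == 0:
        raise ValueError("empty molecule set")
    fps = [_bitvect(m, kind, None if kind == "maccs" else nbits)
           for m in mols]
    n = len(fps)
    mat = np.eye(n)
    for i in range(n):
        if i + 1 < n:
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
            mat[i, i + 1:] = sims
            mat[i + 1:, i] = sims
    return mat


def mean_max_similarity(train: Sequence[Chem.Mol], test: Sequence[Chem.Mol],
                        kind: str = "morgan", nbits: int = 1024) -> float:
    """Mean over test molecules of the maximum Tanimoto similarity to any
    training molecule — the diversity QC used to judge train/test overlap."""
    if len(train) == 0 or len(test) == 0:
        raise ValueError("empty molecule set")
    train_fps = [_bitvect(m, kind, None if kind == "maccs" else nbits)
                 for m in train]
    vals = []
    for m in test:
        fp = _bitvect(m, kind, None if kind == "maccs" else nbits)
        vals.append(max(DataStructs.BulkTanimotoSimilarity(fp, train_fps)))
    return float(np.mean(vals))
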