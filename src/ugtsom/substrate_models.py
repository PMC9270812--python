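"""Substrate/nonsubstrate classifiers and soft-voting consensus.

Five traditional learners (RF, SVM, LR, NN, ET) over fingerprint or
descriptor vectors, plus two graph classifiers (GCN and an attention-based
AttentiveFP-style network) over molecular graphs. Models are ranked by
ten-fold cross-validated MCC; the top 10 are combined into the full family
of 2**10 - 1 = 1023 soft-voting committees (every non-empty member subset;
a single-member committee degenerates to the model itself). The consensus
probability is the arithmetic mean of member probabilities and a compound
is called a substrate when that mean is >= 0.5 (boundary inclusive).

GAT, Weave and MPNN are registered as pluggable names but deliberately
unimplemented; requesting them raises rather than silently aliasing GCN.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import os
import pickle
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import autodiff as ad
from . import featurize
from .evaluate import auc, classification_row
from .featurize import DescriptorScaler, MolGraph, combine_graphs

logger = logging.getLogger(__name__)

TRADITIONAL_METHODS = ("RF", "SVM", "LR", "NN", "ET")
GRAPH_METHODS = ("GCN", "AttentiveFP")
UNIMPLEMENTED_METHODS = ("GAT", "Weave", "MPNN")

SUBSTRATE_THRESHOLD = 0.5  # inclusive


class ModelError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """What a model consumes: a fingerprint family + width, the descriptor
    vector, or a graph featurization scheme."""

    kind: str  # fingerprint | descriptors | graph
    fp_kind: Optional[str] = None
    nbits: Optional[int] = None
    scheme: Optional[str] = None

    @property
    def name(self) -> str:
        if self.kind == "fingerprint":
            if self.fp_kind == "maccs":
                return "MACCS"
            pretty = {"morgan": "Morgan", "atompairs": "AtomPairs",
                      "topotorsion": "TopoTorsion",
                      "rdkit_path": "RDKitFP"}[self.fp_kind]
            return f"{pretty}_{self.nbits}"
        if self.kind == "descriptors":
            return "Descriptor"
        return f"Graph_{self.scheme}"


@dataclass(frozen=True)
class ClassifierSpec:
    method: str
    feature: FeatureSpec
    hyperparams: Tuple[Tuple[str, object], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.method in UNIMPLEMENTED_METHODS:
            return  # rejected at training time with a clear message
        if self.method in GRAPH_METHODS and self.feature.kind != "graph":
            raise ValueError(f"{self.method} requires a graph feature")
        if self.method in TRADITIONAL_METHODS and self.feature.kind == "graph":
            raise ValueError(f"{self.method} requires a vector feature")
        if self.method not in TRADITIONAL_METHODS + GRAPH_METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def name(self) -> str:
        return f"{self.feature.name}_{self.method}"

    @property
    def hp(self) -> Dict[str, object]:
        return dict(self.hyperparams)


@dataclass
class EarlyStopPolicy:
    """Stop training at the first satisfied criterion: the monitored metric
    has not improved for `patience_train` epochs on the training set, for
    `patience_valid` epochs on the validation set, or `max_epochs` is hit."""

    max_epochs: int = 500
    patience_train: int = 10
    patience_valid: int = 15
    monitor: str = "loss"

    def __post_init__(self):
        if self.max_epochs < 1 or self.patience_train < 1 \
                or self.patience_valid < 1:
            raise ValueError("invalid early-stopping policy")


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reproduce its inputs."""

    spec: ClassifierSpec
    impl: object = field(repr=False)
    scaler: Optional[DescriptorScaler] = None
    manifest: Dict = field(default_factory=dict)

    def predict_proba(self, X) -> np.ndarray:
        """Class-1 (substrate) probability for pre-featurized input."""
        if self.spec.method in TRADITIONAL_METHODS:
            return self.impl.predict_proba(X)[:, 1]
        return self.impl.predict_proba_graphs(X)

    def predict_proba_mols(self, mols) -> np.ndarray:
        return self.predict_proba(self.featurize_mols(mols))

    def featurize_mols(self, mols):
        return build_features(mols, self.spec.feature, scaler=self.scaler)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= SUBSTRATE_THRESHOLD).astype(int)


@dataclass(frozen=True)
class ConsensusSpec:
    members: Tuple[str, ...]  # member model names, distinct

    def __post_init__(self):
        if not (1 <= len(self.members) <= 10):
            raise ValueError("a consensus combines 1-10 member models "
                             "(a singleton degenerates to the model itself)")
        if len(set(self.members)) != len(self.members):
            raise ValueError("consensus members must be distinct")

    @property
    def name(self) -> str:
        return "+".join(self.members)


# ---------------------------------------------------------------------------
# featurization plumbing
# ---------------------------------------------------------------------------

def build_features(mols, feature: FeatureSpec,
                   scaler: Optional[DescriptorScaler] = None,
                   fit_scaler: bool = False):
    """Materialize the feature matrix (or graph list) for `mols`.

    For descriptors, standardization parameters must come from training
    folds: pass ``fit_scaler=True`` on training data and reuse the returned
    scaler on held-out data.
    """
    if feature.kind == "fingerprint":
        return featurize.fingerprint_matrix(mols, feature.fp_kind, feature.nbits)
    if feature.kind == "descriptors":
        X = featurize.descriptor_matrix(mols)
        if fit_scaler:
            if scaler is None:
                scaler = DescriptorScaler()
            return scaler.fit_transform(X), scaler
        if scaler is not None:
            return scaler.transform(X)
        return X
    if feature.kind == "graph":
        return [featurize.mol_to_graph(m, feature.scheme or "classifier")
                for m in mols]
    raise ValueError(f"unknown feature kind {feature.kind!r}")


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(records: Sequence, fractions: Sequence[float], seed: int,
                  group_key=None) -> List[List]:
    """Seeded random partition into len(fractions) sets.

    ``group_key(record)`` — e.g. reactant identity for reaction data — keeps
    whole groups inside one partition, so reactions sharing a substrate
    never straddle the train/test boundary.
    """
    fractions = list(fractions)
    if abs(sum(fractions) - 1.0) > 1e-6 or any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be positive and sum to 1: {fractions}")
    rng = np.random.default_rng(seed)
    n = len(records)
    targets = [f * n for f in fractions]

    if group_key is None:
        groups = [[r] for r in records]
    else:
        by_key: Dict[object, list] = {}
        for r in records:
            by_key.setdefault(group_key(r), []).append(r)
        groups = list(by_key.values())
        if max(len(g) for g in groups) > max(targets) + 1e-9:
            raise ValueError("a group is larger than the largest partition")

    order = rng.permutation(len(groups))
    parts: List[List] = [[] for _ in fractions]
    filled = [0.0] * len(fractions)
    for gi in order:
        deficits = [t - f for t, f in zip(targets, filled)]
        p = int(np.argmax(deficits))
        parts[p].extend(groups[gi])
        filled[p] += len(groups[gi])
    return parts


# ---------------------------------------------------------------------------
# traditional learners
# ---------------------------------------------------------------------------

def _make_estimator(method: str, hp: Dict, seed: int):
    if method == "RF":
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 200)),
            max_depth=hp.get("max_depth"), random_state=seed, n_jobs=1)
    if method == "ET":
        return ExtraTreesClassifier(
            n_estimators=int(hp.get("n_estimators", 200)),
            max_depth=hp.get("max_depth"), random_state=seed, n_jobs=1)
    if method == "SVM":
        # probability=True wraps the SVM in Platt probability calibration
        return SVC(C=float(hp.get("C", 1.0)), gamma=hp.get("gamma", "scale"),
                   kernel=hp.get("kernel", "rbf"), probability=True,
                   random_state=seed)
    if method == "LR":
        return LogisticRegression(
            C=float(hp.get("C", 1.0)), max_iter=int(hp.get("max_iter", 2000)),
            random_state=seed)
    if method == "NN":
        return MLPClassifier(
            hidden_layer_sizes=tuple(hp.get("hidden_layer_sizes", (128,))),
            alpha=float(hp.get("alpha", 1e-4)),
            max_iter=int(hp.get("max_iter", 500)), random_state=seed)
    raise ModelError(f"no estimator for method {method!r}")


def _data_hash(X, y) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.asarray(X, dtype=float)).tobytes()
             if not isinstance(X, list) else str(len(X)).encode())
    h.update(np.asarray(y).tobytes())
    return h.hexdigest()[:16]


def train_traditional(spec: ClassifierSpec, X, y) -> TrainedModel:
    """Fit one traditional learner; exposes calibrated class-1 probability."""
    if spec.method in UNIMPLEMENTED_METHODS:
        raise NotImplementedError(
            f"{spec.method} is a registered extension point, not implemented")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    if len(np.unique(y)) < 2:
        raise ModelError("training labels contain a single class")
    if not np.isfinite(X).all():
        raise ModelError("non-finite features after imputation")
    est = _make_estimator(spec.method, spec.hp, spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    manifest = {"data_hash": _data_hash(X, y), "n": int(len(y)),
                "vocab_version": featurize.VOCAB_VERSION}
    return TrainedModel(spec=spec, impl=est, manifest=manifest)


# ---------------------------------------------------------------------------
# graph classifiers (NumPy autodiff)
# ---------------------------------------------------------------------------

class _GraphNet:
    """Shared batching/prediction harness for the graph classifiers."""

    def __init__(self, scheme: str, hidden: int, n_layers: int, seed: int):
        self.scheme = scheme
        self.hidden = hidden
        self.n_layers = n_layers
        self.seed = seed
        self.params: Dict[str, ad.Tensor] = {}

    def _param(self, rng, name, fan_in, fan_out):
        t = ad.glorot(rng, fan_in, fan_out)
        self.params[name] = t
        return t

    def _bias(self, name, width):
        t = ad.Tensor(np.zeros((1, width)), requires_grad=True)
        self.params[name] = t
        return t

    def parameters(self):
        return list(self.params.values())

    def forward(self, graphs: Sequence[MolGraph]) -> ad.Tensor:
        raise NotImplementedError

    def predict_proba_graphs(self, graphs: Sequence[MolGraph]) -> np.ndarray:
        logits = self.forward(graphs)
        return 1.0 / (1.0 + np.exp(-logits.data[:, 0]))

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]):
        for k, v in state.items():
            self.params[k].data = v.copy()


class GCNClassifier(_GraphNet):
    """Graph convolutions with a concat(weighted-sum, max-pool) readout fed
    into a feed-forward head."""

    def __init__(self, scheme="classifier", hidden=64, n_layers=2, seed=0):
        super().__init__(scheme, hidden, n_layers, seed)
        rng = np.random.default_rng(seed)
        f = featurize.node_feature_width(scheme)
        self._param(rng, "W_embed", f, hidden)
        self._bias("b_embed", hidden)
        for layer in range(n_layers):
            self._param(rng, f"W_self{layer}", hidden, hidden)
            self._param(rng, f"W_nei{layer}", hidden, hidden)
            self._bias(f"b{layer}", hidden)
        self._param(rng, "W_gate", hidden, 1)
        self._bias("b_gate", 1)
        self._param(rng, "W_val", hidden, hidden)
        self._param(rng, "W_head", 2 * hidden, hidden)
        self._bias("b_head", hidden)
        self._param(rng, "w_out", hidden, 1)
        self._bias("b_out", 1)

    def forward(self, graphs):
        node_feats, src, dst, _ef, gids, _off = combine_graphs(graphs)
        G = len(graphs)
        n_atoms = node_feats.shape[0]
        p = self.params
        H = ad.relu(ad.Tensor(node_feats) @ p["W_embed"] + p["b_embed"])
        for layer in range(self.n_layers):
            if len(src):
                agg = ad.segment_sum(ad.gather(H, src), dst, n_atoms)
                msg = agg @ p[f"W_nei{layer}"]
            else:
                msg = ad.Tensor(np.zeros((n_atoms, self.hidden)))
            H = ad.relu(H @ p[f"W_self{layer}"] + msg + p[f"b{layer}"])
        gate = ad.sigmoid(H @ p["W_gate"] + p["b_gate"])
        wsum = ad.segment_sum(gate * (H @ p["W_val"]), gids, G)
        mpool = ad.segment_max(H, gids, G)
        hmol = ad.concat([wsum, mpool], axis=1)
        hidden = ad.relu(hmol @ p["W_head"] + p["b_head"])
        return hidden @ p["w_out"] + p["b_out"]


class AttentiveFPClassifier(_GraphNet):
    """Two-level attention graph classifier: edge-aware atom-level attention
    for message passing, then molecule-level attention readout."""

    def __init__(self, scheme="classifier", hidden=64, n_layers=2, seed=0,
                 readout_steps=2):
        super().__init__(scheme, hidden, n_layers, seed)
        self.readout_steps = readout_steps
        rng = np.random.default_rng(seed)
        f = featurize.node_feature_width(scheme)
        g = featurize.edge_feature_width(scheme)
        self._param(rng, "W_embed", f, hidden)
        self._bias("b_embed", hidden)
        for layer in range(n_layers):
            self._param(rng, f"W_msg{layer}", hidden + g, hidden)
            self._bias(f"b_msg{layer}", hidden)
            self._param(rng, f"W_att{layer}", 2 * hidden, hidden)
            self._bias(f"b_att{layer}", hidden)
            self._param(rng, f"u_att{layer}", hidden, 1)
            self._param(rng, f"W_self{layer}", hidden, hidden)
            self._param(rng, f"W_nei{layer}", hidden, hidden)
            self._bias(f"b_upd{layer}", hidden)
        self._param(rng, "W_ratt", 2 * hidden, hidden)
        self._bias("b_ratt", hidden)
        self._param(rng, "u_ratt", hidden, 1)
        self._param(rng, "W_rval", hidden, hidden)
        self._param(rng, "W_mself", hidden, hidden)
        self._param(rng, "W_mctx", hidden, hidden)
        self._bias("b_mupd", hidden)
        self._param(rng, "w_out", hidden, 1)
        self._bias("b_out", 1)

    def forward(self, graphs):
        node_feats, src, dst, efeat, gids, _off = combine_graphs(graphs)
        G = len(graphs)
        n_atoms = node_feats.shape[0]
        p = self.params
        H = ad.relu(ad.Tensor(node_feats) @ p["W_embed"] + p["b_embed"])
        E = ad.Tensor(efeat)
        for layer in range(self.n_layers):
            if len(src):
                msg = ad.relu(ad.concat([ad.gather(H, src), E], axis=1)
                              @ p[f"W_msg{layer}"] + p[f"b_msg{layer}"])
                att_in = ad.concat([ad.gather(H, dst), msg], axis=1)
                att = ad.tanh(att_in @ p[f"W_att{layer}"]
                              + p[f"b_att{layer}"]) @ p[f"u_att{layer}"]
                alpha = ad.segment_softmax(att, dst, n_atoms)
                agg = ad.segment_sum(alpha * msg, dst, n_atoms)
                nei = agg @ p[f"W_nei{layer}"]
            else:
                nei = ad.Tensor(np.zeros((n_atoms, self.hidden)))
            H = ad.relu(H @ p[f"W_self{layer}"] + nei + p[f"b_upd{layer}"])
        counts = np.bincount(gids, minlength=G).reshape(-1, 1).astype(float)
        m = ad.segment_sum(H, gids, G) * ad.Tensor(1.0 / counts)
        for _ in range(self.readout_steps):
            att_in = ad.concat([ad.gather(m, gids), H], axis=1)
            att = ad.tanh(att_in @ p["W_ratt"] + p["b_ratt"]) @ p["u_ratt"]
            alpha = ad.segment_softmax(att, gids, G)
            ctx = ad.segment_sum(alpha * (H @ p["W_rval"]), gids, G)
            m = ad.tanh(m @ p["W_mself"] + ctx @ p["W_mctx"] + p["b_mupd"])
        return m @ p["w_out"] + p["b_out"]


def train_graph_classifier(spec: ClassifierSpec, graphs: Sequence[MolGraph],
                           y, policy: Optional[EarlyStopPolicy] = None,
                           valid: Optional[Tuple[Sequence[MolGraph], Sequence[int]]] = None,
                           ) -> TrainedModel:
    """Train a graph classifier with BCE-with-logits loss, Adam updates,
    mini-batching and dual-patience early stopping.

    If no validation split is supplied, a seeded stratified 10% of the
    training data is carved out to drive early stopping.
    """
    if spec.method in UNIMPLEMENTED_METHODS:
        raise NotImplementedError(
            f"{spec.method} is a registered extension point, not implemented")
    if spec.method not in GRAPH_METHODS:
        raise ModelError(f"{spec.method} is not a graph method")
    if len(graphs) == 0:
        raise ModelError("empty training set")
    policy = policy or EarlyStopPolicy()
    hp = spec.hp
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ModelError("training labels contain a single class")

    rng = np.random.default_rng(spec.seed)
    if valid is None:
        idx = np.arange(len(graphs))
        pos, neg = idx[y == 1], idx[y == 0]
        rng.shuffle(pos)
        rng.shuffle(neg)
        nv_pos = max(1, len(pos) // 10)
        nv_neg = max(1, len(neg) // 10)
        val_idx = np.concatenate([pos[:nv_pos], neg[:nv_neg]])
        tr_idx = np.setdiff1d(idx, val_idx)
        valid = ([graphs[i] for i in val_idx], y[val_idx])
        graphs = [graphs[i] for i in tr_idx]
        y = y[tr_idx]
    vgraphs, vy = valid
    vy = np.asarray(vy).astype(int)

    cls = GCNClassifier if spec.method == "GCN" else AttentiveFPClassifier
    net = cls(scheme=spec.feature.scheme or "classifier",
              hidden=int(hp.get("hidden", 64)),
              n_layers=int(hp.get("n_layers", 2)), seed=spec.seed)
    opt = ad.Adam(net.parameters(), lr=float(hp.get("lr", 1e-3)))
    batch_size = int(hp.get("batch_size", 32))

    history: List[Dict] = []
    best_train = np.inf
    best_valid = np.inf
    best_state = net.state_dict()
    stall_train = stall_valid = 0
    for epoch in range(1, policy.max_epochs + 1):
        order = rng.permutation(len(graphs))
        losses = []
        for start in range(0, len(order), batch_size):
            sel = order[start:start + batch_size]
            logits = net.forward([graphs[i] for i in sel])
            loss = ad.bce_with_logits(logits, y[sel].reshape(-1, 1))
            if not np.isfinite(loss.data):
                raise ModelError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))
        vlogits = net.forward(list(vgraphs))
        vloss = float(ad.bce_with_logits(vlogits, vy.reshape(-1, 1)).data)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "valid_loss": vloss})
        if train_loss < best_train - 1e-6:
            best_train, stall_train = train_loss, 0
        else:
            stall_train += 1
        if vloss < best_valid - 1e-6:
            best_valid, stall_valid = vloss, 0
            best_state = net.state_dict()
        else:
            stall_valid += 1
        if stall_train >= policy.patience_train \
                or stall_valid >= policy.patience_valid:
            break
    net.load_state_dict(best_state)
    manifest = {"data_hash": _data_hash(graphs, y), "n": int(len(y)),
                "epochs": len(history), "history": history,
                "vocab_version": featurize.VOCAB_VERSION}
    return TrainedModel(spec=spec, impl=net, manifest=manifest)


def train_model(spec: ClassifierSpec, X, y,
                policy: Optional[EarlyStopPolicy] = None) -> TrainedModel:
    if spec.method in TRADITIONAL_METHODS:
        return train_traditional(spec, X, y)
    return train_graph_classifier(spec, X, y, policy=policy)


# ---------------------------------------------------------------------------
# cross-validation and model selection
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    spec: ClassifierSpec
    fold_metrics: List[Dict[str, float]]
    pooled: Dict[str, float]
    oof_probs: np.ndarray = field(repr=False)

    @property
    def name(self) -> str:
        return self.spec.name


def cross_validate(spec: ClassifierSpec, X, y, k: int = 10,
                   seed: Optional[int] = None,
                   policy: Optional[EarlyStopPolicy] = None) -> CVResult:
    """Stratified k-fold CV; metrics per fold and on the concatenated
    out-of-fold predictions."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y).astype(int)
    seed = spec.seed if seed is None else seed
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    fold_metrics = []
    is_graph = spec.method in GRAPH_METHODS
    Xarr = X if is_graph else np.asarray(X, dtype=float)
    for tr, va in skf.split(np.zeros(len(y)), y):
        if is_graph:
            model = train_graph_classifier(
                spec, [Xarr[i] for i in tr], y[tr], policy=policy)
            probs = model.predict_proba([Xarr[i] for i in va])
        else:
            model = train_traditional(spec, Xarr[tr], y[tr])
            probs = model.predict_proba(Xarr[va])
        oof[va] = probs
        fold_metrics.append(classification_row(y[va], probs))
    pooled = classification_row(y, oof)
    return CVResult(spec=spec, fold_metrics=fold_metrics, pooled=pooled,
                    oof_probs=oof)


def select_top_models(cv_results: Sequence[CVResult], n: int = 10
                      ) -> List[CVResult]:
    """Descending cross-validated MCC; ties broken by AUC then spec name."""
    if n > len(cv_results):
        raise ValueError(f"asked for top {n} of {len(cv_results)} models")
    ranked = sorted(cv_results,
                    key=lambda r: (-r.pooled["MCC"], -r.pooled["AUC"], r.name))
    return list(ranked[:n])


def enumerate_consensus(top_models: Sequence,
                        min_size: int = 1) -> List[ConsensusSpec]:
    """All member subsets of size `min_size`..m, in deterministic order.

    The default enumerates every non-empty subset, so 10 top models yield
    2**10 - 1 = 1023 committees (the reported family size; a single-member
    committee votes identically to the model itself). ``min_size=2``
    restricts to genuine multi-member combinations, 2**m - m - 1 of them.
    """
    names = [getattr(m, "name", str(m)) for m in top_models]
    if not (2 <= len(names) <= 10):
        raise ValueError("need between 2 and 10 top models")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    specs = []
    for size in range(min_size, len(names) + 1):
        for combo in itertools.combinations(names, size):
            specs.append(ConsensusSpec(members=combo))
    return specs


def soft_vote(member_probs) -> Tuple[np.ndarray, np.ndarray]:
    """Mean of member class-1 probabilities; substrate iff mean >= 0.5.

    ``member_probs`` has one row per member. A failed member prediction
    (NaN) fails the consensus rather than being silently dropped.
    """
    P = np.atleast_2d(np.asarray(member_probs, dtype=float))
    if P.shape[0] < 1:
        raise ValueError("no member probabilities")
    if not np.isfinite(P).all():
        raise ModelError("a consensus member failed to predict")
    mean = P.mean(axis=0)
    return mean, (mean >= SUBSTRATE_THRESHOLD).astype(int)


class ConsensusModel:
    """Soft-voting ensemble over trained members (each with its own
    featurization)."""

    def __init__(self, members: Sequence[TrainedModel]):
        if not (1 <= len(members) <= 10):
            raise ValueError("a consensus combines 1-10 member models")
        self.members = list(members)
        self.spec = ConsensusSpec(tuple(m.spec.name for m in members))

    def predict_proba_mols(self, mols) -> np.ndarray:
        probs = np.vstack([m.predict_proba_mols(mols) for m in self.members])
        return soft_vote(probs)[0]

    def predict_mols(self, mols) -> np.ndarray:
        return (self.predict_proba_mols(mols) >= SUBSTRATE_THRESHOLD).astype(int)


# ---------------------------------------------------------------------------
# y-randomization
# ---------------------------------------------------------------------------

def y_randomization(spec: ClassifierSpec, X, y, n_rounds: int = 20,
                    seed: int = 0, k: int = 10) -> Dict:
    """Label-shuffling control: CV MCC with true labels vs. the distribution
    of CV MCC over `n_rounds` shuffles, plus the empirical quantile of the
    true value within the shuffled distribution."""
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    y = np.asarray(y).astype(int)
    true_mcc = cross_validate(spec, X, y, k=k, seed=seed).pooled["MCC"]
    rng = np.random.default_rng(seed)
    shuffled = []
    for r in range(n_rounds):
        ys = rng.permutation(y)
        shuffled.append(
            cross_validate(replace(spec, seed=spec.seed + r + 1),
                           X, ys, k=k, seed=seed + r + 1).pooled["MCC"])
    shuffled_arr = np.array(shuffled)
    return {
        "true_mcc": float(true_mcc),
        "shuffled_mcc": [float(v) for v in shuffled],
        "shuffled_mean": float(shuffled_arr.mean()),
        "true_quantile": float(np.mean(shuffled_arr < true_mcc)),
    }


# ---------------------------------------------------------------------------
# small seeded grid search (replaces Bayesian optimization)
# ---------------------------------------------------------------------------

DEFAULT_GRIDS: Dict[str, List[Dict]] = {
    "RF": [{"n_estimators": n} for n in (100, 200, 500)],
    "ET": [{"n_estimators": n} for n in (100, 200, 500)],
    "SVM": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "LR": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "NN": [{"hidden_layer_sizes": h} for h in ((64,), (128,), (128, 64))],
}


def grid_search(method: str, feature: FeatureSpec, X, y, seed: int = 0,
                k: int = 5, grid: Optional[List[Dict]] = None) -> CVResult:
    """Pick the best hyperparameter cell by cross-validated MCC over a small
    deterministic grid."""
    grid = grid if grid is not None else DEFAULT_GRIDS[method]
    best: Optional[CVResult] = None
    for cell in grid:
        spec = ClassifierSpec(method=method, feature=feature,
                              hyperparams=tuple(sorted(cell.items())),
                              seed=seed)
        res = cross_validate(spec, X, y, k=k, seed=seed)
        if best is None or (res.pooled["MCC"], res.pooled["AUC"]) \
                > (best.pooled["MCC"], best.pooled["AUC"]):
            best = res
    return best


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_trained_model(model: TrainedModel, dirpath: str) -> None:
    os.makedirs(dirpath, exist_ok=True)
    spec = model.spec
    payload = {
        "method": spec.method,
        "feature": {"kind": spec.feature.kind, "fp_kind": spec.feature.fp_kind,
                    "nbits": spec.feature.nbits, "scheme": spec.feature.scheme},
        "hyperparams": list(spec.hyperparams),
        "seed": spec.seed,
    }
    with open(os.path.join(dirpath, "spec.json"), "w") as fh:
        json.dump(payload, fh, indent=2)
    with open(os.path.join(dirpath, "manifest.json"), "w") as fh:
        json.dump(model.manifest, fh, indent=2)
    if model.scaler is not None:
        with open(os.path.join(dirpath, "scaler.json"), "w") as fh:
            fh.write(model.scaler.to_json())
    if spec.method in TRADITIONAL_METHODS:
        with open(os.path.join(dirpath, "model.pkl"), "wb") as fh:
            pickle.dump(model.impl, fh)
    else:
        np.savez(os.path.join(dirpath, "params.npz"), **model.impl.state_dict())
        with open(os.path.join(dirpath, "arch.json"), "w") as fh:
            json.dump({"hidden": model.impl.hidden,
                       "n_layers": model.impl.n_layers,
                       "scheme": model.impl.scheme,
                       "seed": model.impl.seed}, fh)


def load_trained_model(dirpath: str) -> TrainedModel:
    with open(os.path.join(dirpath, "spec.json")) as fh:
        payload = json.load(fh)
    feature = FeatureSpec(**payload["feature"])
    spec = ClassifierSpec(
        method=payload["method"], feature=feature,
        hyperparams=tuple(tuple(p) for p in payload["hyperparams"]),
        seed=payload["seed"])
    with open(os.path.join(dirpath, "manifest.json")) as fh:
        manifest = json.load(fh)
    scaler = None
    scaler_path = os.path.join(dirpath, "scaler.json")
    if os.path.exists(scaler_path):
        with open(scaler_path) as fh:
            scaler = DescriptorScaler.from_json(fh.read())
    if spec.method in TRADITIONAL_METHODS:
        with open(os.path.join(dirpath, "model.pkl"), "rb") as fh:
            impl = pickle.load(fh)
    else:
        with open(os.path.join(dirpath, "arch.json")) as fh:
            arch = json.load(fh)
        cls = GCNClassifier if spec.method == "GCN" else AttentiveFPClassifier
        impl = cls(scheme=arch["scheme"], hidden=arch["hidden"],
                   n_layers=arch["n_layers"], seed=arch["seed"])
        state = dict(np.load(os.path.join(dirpath, "params.npz")))
        impl.load_state_dict(state)
    return TrainedModel(spec=spec, impl=impl, scaler=scaler, manifest=manifest)


def save_consensus(consensus: ConsensusModel, dirpath: str,
                   member_dirs: Sequence[str]) -> None:
    os.makedirs(dirpath, exist_ok=True)
    with open(os.path.join(dirpath, "consensus.json"), "w") as fh:
        json.dump({"members": list(member_dirs),
                   "threshold": SUBSTRATE_THRESHOLD}, fh, indent=2)


def load_consensus(dirpath: str) -> ConsensusModel:
    with open(os.path.join(dirpath, "consensus.json")) as fh:
        payload = json.load(fh)
    members = [load_trained_model(d) for d in payload["members"]]
    return ConsensusModel(members)
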