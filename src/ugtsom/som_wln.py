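"""Weisfeiler-Lehman network for site-of-glucuronidation ranking.

A glucuronidation reaction is treated as a single graph edit: a new bond
between a substrate nucleophile (O or N) and the anomeric carbon of the
glucuronosyl group. The network learns, from atom-mapped reaction examples,
to score the reactivity of every (candidate site, anomeric carbon) pair:

1. each atom's one-hot features are embedded and refined by iterated
   Weisfeiler-Lehman updates that merge the atom, its neighbors, and the
   incident bond features through a shared learned transformation
   (one iteration by default);
2. a global dot-product attention over ALL reactant atoms (substrate and
   glucuronosyl donor together) produces a context vector per atom, so the
   co-reactant can modulate the substrate representation;
3. a pair-scoring head maps the concatenated (local, context) features of
   the site atom and of the anomeric carbon to a reactivity logit.

Training minimizes binary cross-entropy with logits over the labeled pairs
of each reaction (the observed SOM is the positive; every other candidate
site of the same substrate is a negative), with Adam updates, mini-batches
of 20 reactions, and dual-patience early stopping (10 epochs on the
training loss, 15 on the validation top-1), capped at 500 epochs.

Ranked sites use canonical atom indices; equal scores break ties by
ascending atom index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from rdkit import Chem

from . import autodiff as ad
from . import chem_io, featurize
from .chem_io import (GLUCURONYL_DONOR_SMILES, ReactionRecord,
                      enumerate_candidate_sites, find_glucuronyl)
from .featurize import MolGraph, combine_graphs, mol_to_graph
from .substrate_models import EarlyStopPolicy, ModelError

logger = logging.getLogger(__name__)

TrueSom = Tuple[int, str]  # (atom_index, som_class)


@dataclass
class WLNConfig:
    n_wl_iterations: int = 1
    hidden_width: int = 300
    learning_rate: float = 0.001
    batch_size: int = 20
    early_stop: EarlyStopPolicy = field(
        default_factory=lambda: EarlyStopPolicy(monitor="top1"))
    seed: int = 0

    def __post_init__(self):
        if self.n_wl_iterations < 1:
            raise ValueError("n_wl_iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class SOMPrediction:
    """Candidate sites of one substrate ranked by reactivity score
    (descending; ties by ascending atom index)."""

    substrate_id: str
    ranked_sites: Tuple[Tuple[int, str, float], ...]

    @property
    def has_sites(self) -> bool:
        return len(self.ranked_sites) > 0


# ---------------------------------------------------------------------------
# sample preparation
# ---------------------------------------------------------------------------

def _normalize_mol(mol: Chem.Mol) -> Tuple[Chem.Mol, Dict[int, int]]:
    """Strip atom maps and re-parse through canonical SMILES so hydrogen
    bookkeeping and atom order are identical no matter how the molecule was
    written. Returns the normalized mol and the old->new index map."""
    m = Chem.Mol(mol)
    for a in m.GetAtoms():
        a.SetAtomMapNum(0)
    smi = Chem.MolToSmiles(m)
    order = list(map(int, m.GetProp("_smilesAtomOutputOrder")
                     .strip("[]").rstrip(",").split(",")))
    old_to_new = {old: new for new, old in enumerate(order)}
    return Chem.MolFromSmiles(smi), old_to_new


@dataclass
class _RxnSample:
    id: str
    substrate_smiles: str
    sub_graph: MolGraph
    donor_graph: MolGraph
    cand_idx: List[int]           # substrate-local, canonical order
    cand_classes: List[str]
    pos_idx: int                  # substrate-local canonical SOM index
    som_class: str
    anomeric_idx: int             # donor-local
    extra_negatives: List[int] = field(default_factory=list)


def _prepare_sample(record: ReactionRecord, idx: int) -> Optional[_RxnSample]:
    sub, o2n = _normalize_mol(record.substrate)
    pos = o2n[record.som_atom_index]
    donor_src = record.reactants[record.glucuronyl_index]
    donor, d_o2n = _normalize_mol(donor_src)
    anomeric_old = next(
        a.GetIdx() for a in donor_src.GetAtoms()
        if a.GetAtomMapNum() == record.anomeric_map) \
        if record.anomeric_map > 0 else find_glucuronyl(donor)[0]
    anomeric = d_o2n[anomeric_old] if record.anomeric_map > 0 \
        else anomeric_old
    sites = enumerate_candidate_sites(sub)
    cand = [s.atom_index for s in sites]
    if pos not in cand:
        logger.warning("reaction %s: observed SOM is not an enumerable "
                       "candidate site; sample skipped", record.id or idx)
        return None
    return _RxnSample(
        id=record.id or f"rxn{idx}",
        substrate_smiles=Chem.MolToSmiles(sub),
        sub_graph=mol_to_graph(sub, "wln"),
        donor_graph=mol_to_graph(donor, "wln"),
        cand_idx=cand,
        cand_classes=[s.site_class for s in sites],
        pos_idx=pos,
        som_class=record.som_class,
        anomeric_idx=anomeric)


def _batch_arrays(samples: Sequence[_RxnSample]):
    """Block-diagonal batch: stacked graphs, an attention mask restricting
    each atom to its own reaction's atoms, and global pair indices."""
    graphs: List[MolGraph] = []
    for s in samples:
        graphs.extend([s.sub_graph, s.donor_graph])
    node_feats, src, dst, efeat, gids, offsets = combine_graphs(graphs)
    rxn_of_atom = gids // 2
    mask = np.where(rxn_of_atom[:, None] == rxn_of_atom[None, :], 0.0, -1e9)
    site_idx, anom_idx, labels, owner = [], [], [], []
    for i, s in enumerate(samples):
        sub_off = offsets[2 * i]
        don_off = offsets[2 * i + 1]
        for c in s.cand_idx:
            site_idx.append(sub_off + c)
            anom_idx.append(don_off + s.anomeric_idx)
            labels.append(1.0 if c == s.pos_idx else 0.0)
            owner.append(i)
        for c in s.extra_negatives:
            site_idx.append(sub_off + c)
            anom_idx.append(don_off + s.anomeric_idx)
            labels.append(0.0)
            owner.append(i)
    return (node_feats, src, dst, efeat, mask,
            np.array(site_idx, dtype=np.intp),
            np.array(anom_idx, dtype=np.intp),
            np.array(labels), np.array(owner, dtype=np.intp))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class WLNModel:
    """Parameters and forward pass of the WL network."""

    def __init__(self, config: WLNConfig):
        self.config = config
        self.history: List[Dict] = []
        h = config.hidden_width
        f = featurize.node_feature_width("wln")
        g = featurize.edge_feature_width("wln")
        rng = np.random.default_rng(config.seed)
        self.params: Dict[str, ad.Tensor] = {}

        def P(name, fi, fo):
            self.params[name] = ad.glorot(rng, fi, fo)

        def B(name, w):
            self.params[name] = ad.Tensor(np.zeros((1, w)), requires_grad=True)

        P("W_embed", f, h); B("b_embed", h)
        P("W_msg", h + g, h); B("b_msg", h)
        P("W_self", h, h); P("W_nei", h, h); B("b_upd", h)
        P("W_q", h, h); P("W_k", h, h); P("W_v", h, h)
        P("W_pair", 4 * h, h); B("b_pair", h)
        P("u_out", h, 1); B("b_out", 1)

    def parameters(self):
        return list(self.params.values())

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state):
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    # -- forward pieces ----------------------------------------------------
    def local_features(self, node_feats, src, dst, efeat,
                       n_iter: Optional[int] = None) -> ad.Tensor:
        """Per-atom local features after `n_iter` WL update rounds.

        Each round merges the center atom, its adjacent atoms and the
        incident bond features through the shared learned transformation;
        isolated atoms pass through their self-features only.
        """
        n_iter = self.config.n_wl_iterations if n_iter is None else n_iter
        if n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        p = self.params
        n_atoms = node_feats.shape[0]
        H = ad.relu(ad.Tensor(node_feats) @ p["W_embed"] + p["b_embed"])
        E = ad.Tensor(efeat)
        for _ in range(n_iter):
            if len(src):
                nb = ad.relu(ad.concat([ad.gather(H, src), E], axis=1)
                             @ p["W_msg"] + p["b_msg"])
                agg = ad.segment_sum(nb, dst, n_atoms) @ p["W_nei"]
            else:
                agg = ad.Tensor(np.zeros((n_atoms, self.config.hidden_width)))
            H = ad.relu(H @ p["W_self"] + agg + p["b_upd"])
        return H

    def attention_context(self, local: ad.Tensor,
                          mask: np.ndarray) -> ad.Tensor:
        """Global attention over all reactant atoms (substrate and donor):
        per-atom weights normalized to sum 1 produce a context vector that
        is a convex combination of value projections."""
        p = self.params
        h = self.config.hidden_width
        q = local @ p["W_q"]
        k = local @ p["W_k"]
        v = local @ p["W_v"]
        scores = (q @ ad.transpose(k)) * (1.0 / np.sqrt(h))
        weights = ad.masked_row_softmax(scores, mask)
        return weights @ v

    def pair_logits(self, local, context, site_idx, anom_idx) -> ad.Tensor:
        p = self.params
        feats = ad.concat([
            ad.gather(local, site_idx), ad.gather(context, site_idx),
            ad.gather(local, anom_idx), ad.gather(context, anom_idx)],
            axis=1)
        return ad.relu(feats @ p["W_pair"] + p["b_pair"]) @ p["u_out"] \
            + p["b_out"]

    def forward(self, batch) -> Tuple[ad.Tensor, np.ndarray, np.ndarray]:
        node_feats, src, dst, efeat, mask, site_idx, anom_idx, labels, owner \
            = batch
        local = self.local_features(node_feats, src, dst, efeat)
        context = self.attention_context(local, mask)
        return self.pair_logits(local, context, site_idx, anom_idx), \
            labels, owner


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _valid_top1(model: WLNModel, samples: Sequence[_RxnSample]) -> float:
    hits = 0
    for s in samples:
        scores = _score_sample(model, s)
        order = sorted(range(len(s.cand_idx)),
                       key=lambda i: (-scores[i], s.cand_idx[i]))
        if s.cand_idx[order[0]] == s.pos_idx:
            hits += 1
    return hits / max(len(samples), 1)


def _score_sample(model: WLNModel, s: _RxnSample) -> np.ndarray:
    batch = _batch_arrays([s])
    logits, _labels, _owner = model.forward(batch)
    return logits.data[:len(s.cand_idx), 0]


def prepare_samples(reactions: Sequence[ReactionRecord]) -> List[_RxnSample]:
    samples = []
    for i, rec in enumerate(reactions):
        s = _prepare_sample(rec, i)
        if s is not None:
            samples.append(s)
    return samples


def train_wln(reactions: Sequence[ReactionRecord], config: WLNConfig,
              valid_reactions: Optional[Sequence[ReactionRecord]] = None
              ) -> WLNModel:
    """Train the WL network on atom-mapped glucuronidation reactions.

    Reactions sharing a substrate stay on one side of the train/validation
    split. The returned model carries the per-epoch training curve in
    ``model.history``. Same data + same config (seed included) reproduce
    the run exactly (single-threaded, float64).
    """
    samples = prepare_samples(reactions)
    if not samples:
        raise ModelError("empty training set")
    rng = np.random.default_rng(config.seed)

    if valid_reactions is not None:
        train_samples = samples
        valid_samples = prepare_samples(valid_reactions)
    elif len(samples) >= 10:
        from .substrate_models import split_dataset
        train_samples, valid_samples = split_dataset(
            samples, (0.9, 0.1), seed=config.seed,
            group_key=lambda s: s.substrate_smiles)
    else:
        train_samples = valid_samples = samples

    if all(len(s.cand_idx) == 1 for s in train_samples):
        warnings.warn("all training reactions have a single candidate site: "
                      "no contrastive negatives; sampling non-candidate "
                      "atoms as negatives", stacklevel=2)
        for s in train_samples:
            non_cand = [i for i in range(s.sub_graph.n_atoms)
                        if i not in s.cand_idx]
            if non_cand:
                take = min(2, len(non_cand))
                s.extra_negatives = list(
                    rng.choice(non_cand, size=take, replace=False))

    model = WLNModel(config)
    opt = ad.Adam(model.parameters(), lr=config.learning_rate)
    policy = config.early_stop

    best_train = np.inf
    best_valid = -np.inf
    best_state = model.state_dict()
    stall_train = stall_valid = 0
    for epoch in range(1, policy.max_epochs + 1):
        order = rng.permutation(len(train_samples))
        losses = []
        for start in range(0, len(order), config.batch_size):
            sel = [train_samples[i] for i in order[start:start + config.batch_size]]
            logits, labels, _owner = model.forward(_batch_arrays(sel))
            loss = ad.bce_with_logits(logits, labels.reshape(-1, 1))
            if not np.isfinite(loss.data):
                raise ModelError(f"training diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))
        vtop1 = _valid_top1(model, valid_samples)
        model.history.append({"epoch": epoch, "train_loss": train_loss,
                              "valid_top1": vtop1})
        if train_loss < best_train - 1e-6:
            best_train, stall_train = train_loss, 0
        else:
            stall_train += 1
        if vtop1 > best_valid + 1e-9:
            best_valid, stall_valid = vtop1, 0
            best_state = model.state_dict()
        else:
            stall_valid += 1
        if stall_train >= policy.patience_train \
                or stall_valid >= policy.patience_valid:
            break
    model.load_state_dict(best_state)
    return model


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def score_sites(model: WLNModel, substrate, co_reactant: Optional[str] = None,
                substrate_id: Optional[str] = None,
                canonicalize: bool = True,
                all_atoms: bool = False) -> SOMPrediction:
    """Rank the candidate glucuronidation sites of one substrate.

    The glucuronosyl donor is appended automatically when no co-reactant is
    given. With ``all_atoms=True`` every substrate heavy atom is scored
    (non-candidates labeled "other") for diagnostic heat-maps. A substrate
    with no candidate site yields an explicit empty prediction.
    """
    if isinstance(substrate, chem_io.MoleculeRecord):
        mol = substrate.mol
        substrate_id = substrate_id or substrate.id
    elif isinstance(substrate, Chem.Mol):
        mol = substrate
    else:
        rec = chem_io.parse_molecule(str(substrate))
        mol = rec.mol
        substrate_id = substrate_id or rec.smiles
    if canonicalize:
        mol, _ = _normalize_mol(mol)
    substrate_id = substrate_id or Chem.MolToSmiles(mol)

    donor = Chem.MolFromSmiles(co_reactant or GLUCURONYL_DONOR_SMILES)
    anomeric = find_glucuronyl(donor)[0]

    sites = enumerate_candidate_sites(mol)
    classes = {s.atom_index: s.site_class for s in sites}
    if all_atoms:
        cand = list(range(mol.GetNumAtoms()))
    else:
        cand = [s.atom_index for s in sites]
    if not cand:
        return SOMPrediction(substrate_id=substrate_id, ranked_sites=())

    sample = _RxnSample(
        id=substrate_id, substrate_smiles=Chem.MolToSmiles(mol),
        sub_graph=mol_to_graph(mol, "wln"),
        donor_graph=mol_to_graph(donor, "wln"),
        cand_idx=cand,
        cand_classes=[classes.get(i, "other") for i in cand],
        pos_idx=cand[0], som_class="", anomeric_idx=anomeric)
    scores = _score_sample(model, sample)
    order = sorted(range(len(cand)), key=lambda i: (-scores[i], cand[i]))
    ranked = tuple((cand[i], classes.get(cand[i], "other"), float(scores[i]))
                   for i in order)
    return SOMPrediction(substrate_id=substrate_id, ranked_sites=ranked)


def predictions_and_truths(model: WLNModel,
                           reactions: Sequence[ReactionRecord]
                           ) -> Tuple[List[SOMPrediction],
                                      Dict[str, Set[TrueSom]]]:
    """Score every distinct substrate in `reactions` and assemble the truth
    table (canonical atom indices). Reactions sharing a substrate merge
    into one prediction with the union of observed SOMs."""
    truths: Dict[str, Set[TrueSom]] = {}
    for i, rec in enumerate(reactions):
        sub, o2n = _normalize_mol(rec.substrate)
        key = Chem.MolToSmiles(sub)
        truths.setdefault(key, set()).add(
            (o2n[rec.som_atom_index], rec.som_class))
    preds = [score_sites(model, smiles, substrate_id=smiles)
             for smiles in truths]
    return preds, truths


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def topk_accuracy(predictions: Sequence[SOMPrediction],
                  truths: Mapping[str, Set[TrueSom]], k: int) -> float:
    """Fraction of substrates with ANY observed SOM in the top k ranked
    candidate sites. A true SOM absent from the candidate enumeration can
    never be ranked, so it counts as incorrect."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not predictions:
        raise ValueError("no predictions")
    hits = 0
    for pred in predictions:
        true_atoms = {a for a, _ in truths[pred.substrate_id]}
        top = [a for a, _, _ in pred.ranked_sites[:k]]
        if true_atoms & set(top):
            hits += 1
    return hits / len(predictions)


def per_class_topk(predictions: Sequence[SOMPrediction],
                   truths: Mapping[str, Set[TrueSom]],
                   ks: Sequence[int] = (1, 2, 3)) -> Dict[str, Dict[str, float]]:
    """Top-k accuracy restricted to substrates whose observed SOM carries
    each site class; a substrate counts in every class it has a true SOM
    for. Classes with no substrates are absent from the table (never 0)."""
    table: Dict[str, Dict[str, float]] = {}
    for cls in chem_io.SOM_CLASSES:
        subset = [p for p in predictions
                  if any(c == cls for _, c in truths[p.substrate_id])]
        if not subset:
            continue
        row = {f"Top-{k}": topk_accuracy(subset, truths, k) for k in ks}
        row["n"] = len(subset)
        table[cls] = row
    return table
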