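"""Synthetic benchmark generator with exact ground truth.

Molecules are built by rule-based scaffold decoration (benzene, naphthalene,
pyridine and cyclohexane cores crossed with a menu of substituents), which
guarantees chemical validity and an exactly known set of candidate sites —
no generative sampling, no ambiguity about the planted answer.

Two outputs:

* substrate/nonsubstrate sets where the label is a planted structural rule
  (default: "contains an aromatic hydroxyl or a carboxylic acid"), with
  optional label noise;
* balanced, fully atom-mapped glucuronidation SMIRKS whose SOM follows a
  planted preference rule (ArOH > COOH > AlOH > Nitrogen; within a class the
  lowest atom index with a transferable hydrogen). Single-site mode emits
  substrates with exactly one candidate site; multi-site mode adds a
  distractor site of strictly lower priority, so the planted site is always
  learnable from structure alone. Because Nitrogen is the lowest-priority
  class, nitrogen SOMs are always emitted as single-site reactions: any
  distractor would either outrank the site or create an unlearnable
  same-class tie.

Everything is driven by one integer seed; the same config yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .chem_io import (CandidateSite, MoleculeRecord, ReactionRecord,
                      UnsupportedReactionError, emit_smirks,
                      enumerate_candidate_sites, parse_molecule)

SOM_PRIORITY = ("ArOH", "COOH", "AlOH", "Nitrogen")

DEFAULT_CLASS_MIX = {"AlOH": 0.25, "ArOH": 0.25, "COOH": 0.25,
                     "Nitrogen": 0.25}


@dataclass
class GeneratorConfig:
    n_molecules: int = 100
    rule: str = "aroh_or_cooh"
    site_ambiguity: str = "single"  # single | multi
    label_noise: float = 0.0
    seed: int = 0
    class_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX))

    def __post_init__(self):
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must be in [0, 1)")
        if self.site_ambiguity not in ("single", "multi"):
            raise ValueError("site_ambiguity must be 'single' or 'multi'")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("class_mix proportions must sum to 1")


# ---------------------------------------------------------------------------
# scaffold decoration
# ---------------------------------------------------------------------------

# (core SMILES, aromatic?) — positions are the substitutable carbon atoms
CORES: Tuple[Tuple[str, bool], ...] = (
    ("c1ccccc1", True),
    ("c1ccc2ccccc2c1", True),
    ("C1CCCCC1", False),
)

# substituents that create a candidate site, by the class they produce when
# attached to an aromatic / aliphatic core carbon
SITE_SUBSTITUENTS: Dict[str, List[Tuple[str, str, str]]] = {
    # fragment SMILES, class on aromatic core, class on aliphatic core
    "hydroxyl": [("O", "ArOH", "AlOH")],
    "alkanol": [("CO", "AlOH", "AlOH"), ("CCO", "AlOH", "AlOH")],
    "carboxyl": [("C(=O)O", "COOH", "COOH"), ("CC(=O)O", "COOH", "COOH")],
    "amine": [("N", "Nitrogen", "Nitrogen"), ("CN", "Nitrogen", "Nitrogen")],
}

#: substituents that never add a candidate site
NEUTRAL_SUBSTITUENTS: Tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "Cl", "F", "Br", "OC", "OCC",
    "C(F)(F)F", "C#N", "C(=O)C", "[N+](=O)[O-]",
)


def _attach(core: Chem.Mol, position: int, fragment: str) -> Chem.Mol:
    frag = Chem.MolFromSmiles(fragment)
    n = core.GetNumAtoms()
    rw = Chem.RWMol(Chem.CombineMols(core, frag))
    rw.AddBond(position, n, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _decorate(rng: np.random.Generator, fragments: Sequence[str],
              aromatic_required: bool = False) -> Optional[Chem.Mol]:
    """Attach the given fragments at distinct random core positions."""
    choices = [c for c in CORES if c[1]] if aromatic_required else list(CORES)
    core_smiles, _arom = choices[rng.integers(len(choices))]
    core = Chem.MolFromSmiles(core_smiles)
    carbons = [a.GetIdx() for a in core.GetAtoms()
               if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1]
    if len(fragments) > len(carbons):
        return None
    positions = sorted(rng.choice(len(carbons), size=len(fragments),
                                  replace=False).tolist(), reverse=True)
    mol = core
    try:
        # attach right-to-left so earlier positions stay valid
        for pos_i, fragment in zip(positions, fragments):
            mol = _attach(mol, carbons[pos_i], fragment)
    except Exception:
        return None
    return mol


def _matches_rule(sites: Sequence[CandidateSite], rule: str) -> bool:
    if rule != "aroh_or_cooh":
        raise ValueError(f"unknown planted rule {rule!r}")
    return any(s.site_class in ("ArOH", "COOH") for s in sites)


# ---------------------------------------------------------------------------
# substrate / nonsubstrate sets
# ---------------------------------------------------------------------------

def gen_substrate_set(config: GeneratorConfig) -> List[MoleculeRecord]:
    """Unique decorated molecules with labels from the planted rule,
    balanced between classes, with `label_noise` random flips."""
    rng = np.random.default_rng(config.seed)
    # separate stream: noise flips never perturb the structural sequence,
    # so the same seed yields the same molecules at any noise level
    noise_rng = np.random.default_rng([config.seed, 1])
    records: List[MoleculeRecord] = []
    seen = set()
    site_menu = [f for group in SITE_SUBSTITUENTS.values()
                 for f, _, _ in group]
    misses = 0
    while len(records) < config.n_molecules:
        if misses > 5000:
            raise ValueError(
                "requested n exceeds the unique enumerable molecule space")
        want_positive = len(records) % 2 == 0
        n_subs = int(rng.integers(1, 4))
        menu = list(NEUTRAL_SUBSTITUENTS) + site_menu
        frags = [menu[rng.integers(len(menu))] for _ in range(n_subs)]
        mol = _decorate(rng, frags)
        if mol is None:
            misses += 1
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            misses += 1
            continue
        sites = enumerate_candidate_sites(Chem.MolFromSmiles(smiles))
        label = int(_matches_rule(sites, config.rule))
        if label != int(want_positive):
            misses += 1
            continue
        if config.label_noise > 0 and noise_rng.random() < config.label_noise:
            label = 1 - label
        seen.add(smiles)
        misses = 0
        records.append(MoleculeRecord(
            id=f"S{len(records):05d}", smiles=smiles, label=label,
            mol=Chem.MolFromSmiles(smiles)))
    return records


# ---------------------------------------------------------------------------
# reaction sets
# ---------------------------------------------------------------------------

def select_som_by_rule(mol: Chem.Mol) -> Tuple[int, str]:
    """The planted preference rule: highest-priority site class present;
    within a class, the lowest atom index with a transferable hydrogen."""
    sites = enumerate_candidate_sites(mol)
    for cls in SOM_PRIORITY:
        eligible = [s for s in sites if s.site_class == cls
                    and mol.GetAtomWithIdx(s.atom_index).GetTotalNumHs() >= 1]
        if eligible:
            return eligible[0].atom_index, cls
    raise UnsupportedReactionError("molecule has no attachable site")


def _site_fragment(rng, cls: str, aromatic: bool) -> str:
    if cls == "ArOH":
        return "O"
    if cls == "COOH":
        group = SITE_SUBSTITUENTS["carboxyl"]
    elif cls == "AlOH":
        group = SITE_SUBSTITUENTS["alkanol"] if aromatic \
            else SITE_SUBSTITUENTS["alkanol"] + [("O", "", "AlOH")]
        group = [g for g in group]
    else:
        group = SITE_SUBSTITUENTS["amine"]
    return group[rng.integers(len(group))][0]


def _build_reaction_molecule(rng: np.random.Generator, som_class: str,
                             multi: bool) -> Optional[Chem.Mol]:
    aromatic = som_class == "ArOH" or bool(rng.integers(2))
    frags = [_site_fragment(rng, som_class, aromatic)]
    if multi and som_class != "Nitrogen":
        lower = SOM_PRIORITY[SOM_PRIORITY.index(som_class) + 1:]
        dcls = lower[rng.integers(len(lower))]
        frags.append(_site_fragment(rng, dcls, aromatic))
    n_neutral = int(rng.integers(0, 2))
    frags.extend(NEUTRAL_SUBSTITUENTS[rng.integers(len(NEUTRAL_SUBSTITUENTS))]
                 for _ in range(n_neutral))
    mol = _decorate(rng, frags, aromatic_required=aromatic)
    if mol is None:
        return None
    smiles = Chem.MolToSmiles(mol)
    return Chem.MolFromSmiles(smiles)


def gen_reaction_set(config: GeneratorConfig,
                     smirks_path: Optional[str] = None
                     ) -> List[ReactionRecord]:
    """Atom-mapped glucuronidation reactions with planted SOMs.

    Single-site mode guarantees exactly one candidate site per substrate;
    multi-site mode guarantees >= 2 (except nitrogen SOMs; see module
    docstring). Chemically invalid attachments resample the scaffold.
    """
    rng = np.random.default_rng(config.seed)
    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    records: List[ReactionRecord] = []
    seen = set()
    multi = config.site_ambiguity == "multi"
    attempts = 0
    while len(records) < config.n_molecules:
        if attempts > 200 * config.n_molecules + 2000:
            raise ValueError("could not generate enough unique reactions")
        attempts += 1
        som_class = classes[rng.choice(len(classes), p=probs)]
        mol = _build_reaction_molecule(rng, som_class, multi)
        if mol is None:
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            continue
        sites = enumerate_candidate_sites(mol)
        n_sites = len(sites)
        want_multi = multi and som_class != "Nitrogen"
        if (not want_multi and n_sites != 1) or (want_multi and n_sites < 2):
            continue
        try:
            som_idx, got_class = select_som_by_rule(mol)
        except UnsupportedReactionError:
            continue
        if got_class != som_class:
            continue
        try:
            record = emit_smirks(mol, som_idx, id=f"R{len(records):05d}")
        except UnsupportedReactionError:
            continue
        seen.add(smiles)
        records.append(record)
    if smirks_path is not None:
        with open(smirks_path, "w") as fh:
            for rec in records:
                fh.write(rec.smirks + "\n")
    return records


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(config: GeneratorConfig, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
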