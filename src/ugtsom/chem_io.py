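"""Molecule and glucuronidation-reaction I/O.

Parses drug-like molecules (SMILES) and atom-mapped glucuronidation reactions
(SMIRKS, ``reactants >> products`` with reactants joined by ``.``), validates
atom-map balance, locates the bond formed between a substrate nucleophile and
the glucuronosyl anomeric carbon, and classifies the site of glucuronidation
(SOM) into the four functional-group classes used throughout the package:
aliphatic hydroxyl (AlOH), aromatic hydroxyl (ArOH), carboxylic acid (COOH)
and nitrogen sites.

Conventions
-----------
* Atom-map numbers are 1-based (SMIRKS convention); all atom indices exposed
  by this module are 0-based. The conversion never leaks out of this module.
* The glucuronic-acid co-reactant is written without its anomeric hydroxyl
  (the anomeric carbon appears as CH2), so the heavy-atom equation balances
  without modeling UDP. Glucuronosyl recognition uses a pyranose-uronic-acid
  substructure that ignores anomeric stereochemistry.
* Only O- and N-glucuronidation are supported; reactions forming a bond to
  any other element are rejected.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

SOM_CLASSES = ("AlOH", "ArOH", "COOH", "Nitrogen")

#: glucuronosyl donor written in the balanced dialect (anomeric carbon = CH2)
GLUCURONYL_DONOR_SMILES = "O=C(O)C1OCC(O)C(O)C1O"

#: pyranose-uronic-acid core; pattern atom 0 is the anomeric carbon
_GLUCURONYL_CORE_SMARTS = (
    "[CX4;R]1[OX2;R][CX4;R]([CX3](=[OX1])[OX2H1])"
    "[CX4;R]([OX2H1])[CX4;R]([OX2H1])[CX4;R]1[OX2H1]"
)
GLUCURONYL_CORE = Chem.MolFromSmarts(_GLUCURONYL_CORE_SMARTS)


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class ChemIOError(ValueError):
    """Base class for molecule/reaction input errors."""


class MoleculeParseError(ChemIOError):
    pass


class ReactionParseError(ChemIOError):
    pass


class MappingError(ChemIOError):
    """Missing, duplicate or otherwise unusable atom maps."""


class BalanceError(ChemIOError):
    """Reactant and product atom-map multisets differ."""


class UnsupportedReactionError(ChemIOError):
    """Chemically valid input outside the supported reaction scope."""


class UnclassifiableSiteError(ChemIOError):
    pass


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, canonical SMILES, optional substrate label."""

    id: str
    smiles: str
    label: Optional[int] = None
    mol: Chem.Mol = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class CandidateSite:
    """A potential site of glucuronidation within a substrate."""

    atom_index: int
    site_class: str


@dataclass
class ReactionRecord:
    """One atom-mapped glucuronidation event."""

    smirks: str
    reactants: List[Chem.Mol]
    products: List[Chem.Mol]
    formed_bonds: List[Tuple[int, int]]
    som_map: int
    som_class: str
    substrate_index: int
    som_atom_index: int
    glucuronyl_index: int
    anomeric_map: int
    id: Optional[str] = None

    @property
    def substrate(self) -> Chem.Mol:
        return self.reactants[self.substrate_index]


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------

def parse_molecule(smiles: str, id: Optional[str] = None,
                   label: Optional[int] = None) -> MoleculeRecord:
    """Parse a SMILES string into a record with canonical SMILES.

    Canonicalization is idempotent and preserves stereochemistry. Raises
    :class:`MoleculeParseError` on unparseable input.
    """
    if not smiles or not smiles.strip():
        raise MoleculeParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    return MoleculeRecord(id=id if id is not None else canonical,
                          smiles=canonical, label=label,
                          mol=Chem.MolFromSmiles(canonical))


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------

def _normalize_smirks(smirks: str) -> str:
    # tolerate the common depiction artifact for the anomeric methylene
    return smirks.strip().replace("[CH*:", "[CH2:")


def _map_numbers(mol: Chem.Mol) -> List[int]:
    return [a.GetAtomMapNum() for a in mol.GetAtoms()]


def _bond_map_pairs(mols: Sequence[Chem.Mol]) -> set:
    pairs = set()
    for mol in mols:
        for b in mol.GetBonds():
            pairs.add(frozenset((b.GetBeginAtom().GetAtomMapNum(),
                                 b.GetEndAtom().GetAtomMapNum())))
    return pairs


def find_glucuronyl(mol: Chem.Mol) -> Optional[Tuple[int, ...]]:
    """Return the atom indices of the glucuronosyl core, anomeric carbon
    first, or None if the molecule does not contain one."""
    matches = mol.GetSubstructMatches(GLUCURONYL_CORE)
    if not matches:
        return None
    if len(matches) > 1:
        raise UnsupportedReactionError(
            "multiple glucuronosyl moieties are unsupported")
    return matches[0]


def parse_reaction(smirks: str, id: Optional[str] = None) -> ReactionRecord:
    """Parse and validate an atom-mapped glucuronidation SMIRKS.

    Checks, in order: exactly one ``>>``; all sides parse; every heavy atom
    carries a unique positive map number; map multisets balance; exactly one
    reactant carries a glucuronosyl moiety; exactly one bond to the anomeric
    carbon is formed; the substrate-side atom of that bond is O or N.
    """
    text = _normalize_smirks(smirks)
    if text.count(">>") != 1:
        raise ReactionParseError(
            f"expected exactly one '>>' separator, got {text.count('>>')}")
    lhs, rhs = (side.strip() for side in text.split(">>"))
    if not lhs or not rhs:
        raise ReactionParseError("empty reactant or product side")

    def _parse_side(side: str, what: str) -> List[Chem.Mol]:
        mols = []
        for part in side.split("."):
            mol = Chem.MolFromSmiles(part.strip())
            if mol is None:
                raise ReactionParseError(f"unparseable {what}: {part.strip()!r}")
            mols.append(mol)
        return mols

    reactants = _parse_side(lhs, "reactant")
    products = _parse_side(rhs, "product")

    rmaps = [m for mol in reactants for m in _map_numbers(mol)]
    pmaps = [m for mol in products for m in _map_numbers(mol)]
    if any(m <= 0 for m in rmaps + pmaps):
        raise MappingError("every heavy atom must carry a positive atom map")
    if len(set(rmaps)) != len(rmaps):
        raise MappingError("duplicate atom-map numbers on the reactant side")
    if sorted(rmaps) != sorted(pmaps):
        raise BalanceError(
            "reactant and product atom-map multisets differ: the reaction "
            "equation is not balanced")

    glc_index = None
    anomeric_map = None
    for i, mol in enumerate(reactants):
        match = find_glucuronyl(mol)
        if match is not None:
            if glc_index is not None:
                raise UnsupportedReactionError(
                    "more than one glucuronosyl reactant")
            glc_index = i
            anomeric_map = mol.GetAtomWithIdx(match[0]).GetAtomMapNum()
    if glc_index is None:
        raise MappingError("no glucuronic acid found on the reactant side")

    record = ReactionRecord(
        smirks=text, reactants=reactants, products=products,
        formed_bonds=[], som_map=-1, som_class="",
        substrate_index=-1, som_atom_index=-1,
        glucuronyl_index=glc_index, anomeric_map=anomeric_map, id=id)
    record.formed_bonds = extract_formed_bonds(record)
    identify_som(record)
    return record


def extract_formed_bonds(record: ReactionRecord) -> List[Tuple[int, int]]:
    """Bonds present in the products but absent from the reactants, as
    sorted (map_i, map_j) pairs. Pure set arithmetic; validation of the
    single-glucuronidation contract happens in :func:`identify_som`."""
    formed = _bond_map_pairs(record.products) - _bond_map_pairs(record.reactants)
    return sorted(tuple(sorted(p)) for p in formed)


def identify_som(record: ReactionRecord) -> Tuple[int, int, str]:
    """Locate the glucuronidated substrate atom.

    Returns ``(substrate_index, atom_index, som_class)`` where atom_index is
    0-based within the substrate reactant, and stores the result on the
    record. The glucuronosyl reactant is never returned as the SOM host.
    """
    anomeric = record.anomeric_map
    touching = [b for b in record.formed_bonds if anomeric in b]
    if not record.formed_bonds:
        raise UnsupportedReactionError("no graph edit: no bond is formed")
    if len(touching) != 1:
        raise UnsupportedReactionError(
            f"expected exactly 1 formed bond at the anomeric carbon, "
            f"found {len(touching)}; flagged for manual review")
    pair = touching[0]
    som_map = pair[0] if pair[1] == anomeric else pair[1]

    glc_maps = set(_map_numbers(record.reactants[record.glucuronyl_index]))
    if som_map in glc_maps:
        raise UnsupportedReactionError(
            "formed bond lies entirely inside glucuronic acid")

    for i, mol in enumerate(record.reactants):
        if i == record.glucuronyl_index:
            continue
        for atom in mol.GetAtoms():
            if atom.GetAtomMapNum() == som_map:
                if atom.GetSymbol() not in ("O", "N"):
                    raise UnsupportedReactionError(
                        f"SOM atom is {atom.GetSymbol()}: only O- and "
                        "N-glucuronidation are supported")
                som_class = classify_som_type(mol, atom.GetIdx())
                record.substrate_index = i
                record.som_atom_index = atom.GetIdx()
                record.som_map = som_map
                record.som_class = som_class
                return i, atom.GetIdx(), som_class
    raise MappingError(f"SOM map number {som_map} not found in any substrate")


# ---------------------------------------------------------------------------
# site classification and enumeration
# ---------------------------------------------------------------------------

def classify_som_type(mol: Chem.Mol, atom_index: int) -> str:
    """Assign one of AlOH / ArOH / COOH / Nitrogen to an O or N atom.

    Oxygen precedence is COOH > ArOH > AlOH, so a carboxyl hydroxyl oxygen is
    never labeled AlOH. Any nitrogen is a Nitrogen site.
    """
    atom = mol.GetAtomWithIdx(atom_index)
    sym = atom.GetSymbol()
    if sym == "N":
        return "Nitrogen"
    if sym != "O":
        raise UnclassifiableSiteError(
            f"atom {atom_index} ({sym}) is not O or N")
    carbons = [n for n in atom.GetNeighbors() if n.GetSymbol() == "C"]
    for c in carbons:
        for b in c.GetBonds():
            other = b.GetOtherAtom(c)
            if (other.GetIdx() != atom_index and other.GetSymbol() == "O"
                    and b.GetBondType() == Chem.BondType.DOUBLE):
                return "COOH"
    if any(n.GetIsAromatic() for n in atom.GetNeighbors()):
        return "ArOH"
    if any(c.GetHybridization() == Chem.HybridizationType.SP3 for c in carbons):
        return "AlOH"
    raise UnclassifiableSiteError(
        f"oxygen atom {atom_index} matches no hydroxyl class")


def _is_nitro(atom: Chem.Atom) -> bool:
    dbl_o = sum(
        1 for b in atom.GetBonds()
        if b.GetBondType() == Chem.BondType.DOUBLE
        and b.GetOtherAtom(atom).GetSymbol() == "O")
    return dbl_o >= 1 and atom.GetDegree() >= 2


def _is_candidate_nitrogen(atom: Chem.Atom) -> bool:
    """Nucleophilic-nitrogen rule: neutral N with >=1 H, or an aromatic /
    sp2 N with a free lone pair; quaternary and nitro nitrogens excluded."""
    if atom.GetFormalCharge() != 0 or atom.GetTotalDegree() >= 4:
        return False
    if _is_nitro(atom):
        return False
    if atom.GetTotalNumHs() >= 1:
        return True
    if atom.GetIsAromatic() and atom.GetDegree() == 2:
        return True  # pyridine-type: lone pair in the ring plane
    if atom.GetHybridization() == Chem.HybridizationType.SP2:
        return True  # imine-type
    return False


def enumerate_candidate_sites(mol: Chem.Mol) -> List[CandidateSite]:
    """All potential glucuronidation sites, ordered by atom index.

    Includes every hydroxyl oxygen (COOH/ArOH/AlOH patterns) and every
    nitrogen passing the nucleophilic-nitrogen rule. An empty list is a
    valid result meaning "no potential SOM".
    """
    sites: List[CandidateSite] = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym == "O":
            if atom.GetTotalNumHs() < 1 or atom.GetDegree() != 1:
                continue
            try:
                cls = classify_som_type(mol, atom.GetIdx())
            except UnclassifiableSiteError:
                continue
            sites.append(CandidateSite(atom.GetIdx(), cls))
        elif sym == "N" and _is_candidate_nitrogen(atom):
            sites.append(CandidateSite(atom.GetIdx(), "Nitrogen"))
    return sites


# ---------------------------------------------------------------------------
# reaction construction (glucuronidation-specific atom mapping)
# ---------------------------------------------------------------------------

def emit_smirks(substrate: Chem.Mol, site_index: int,
                id: Optional[str] = None) -> ReactionRecord:
    """Build a balanced, fully atom-mapped glucuronidation SMIRKS that
    attaches the glucuronosyl group at ``site_index`` of ``substrate``.

    The attachment drops one hydrogen from the nucleophile and bonds it to
    the anomeric carbon. Raises :class:`UnsupportedReactionError` if the site
    atom has no hydrogen to give up or the result fails valence rules.
    """
    site = substrate.GetAtomWithIdx(site_index)
    if site.GetSymbol() not in ("O", "N"):
        raise UnsupportedReactionError("attachment atom must be O or N")
    if site.GetTotalNumHs() < 1:
        raise UnsupportedReactionError(
            "attachment atom has no hydrogen to substitute")

    donor = Chem.MolFromSmiles(GLUCURONYL_DONOR_SMILES)
    anomeric = find_glucuronyl(donor)[0]
    n = substrate.GetNumAtoms()

    rw = Chem.RWMol(Chem.CombineMols(substrate, donor))
    rw.AddBond(site_index, n + anomeric, Chem.BondType.SINGLE)
    product = rw.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:  # pragma: no cover - valence failures
        raise UnsupportedReactionError(f"attachment fails valence: {exc}")

    sub_mapped = Chem.Mol(substrate)
    for i, a in enumerate(sub_mapped.GetAtoms()):
        a.SetAtomMapNum(i + 1)
    don_mapped = Chem.Mol(donor)
    for i, a in enumerate(don_mapped.GetAtoms()):
        a.SetAtomMapNum(n + i + 1)
    for i, a in enumerate(product.GetAtoms()):
        a.SetAtomMapNum(i + 1)

    smirks = "{}.{}>>{}".format(
        Chem.MolToSmiles(sub_mapped), Chem.MolToSmiles(don_mapped),
        Chem.MolToSmiles(product))

    record = ReactionRecord(
        smirks=smirks,
        reactants=[sub_mapped, don_mapped],
        products=[product],
        formed_bonds=[tuple(sorted((site_index + 1, n + anomeric + 1)))],
        som_map=site_index + 1,
        som_class=classify_som_type(substrate, site_index),
        substrate_index=0,
        som_atom_index=site_index,
        glucuronyl_index=1,
        anomeric_map=n + anomeric + 1,
        id=id)
    return record


def map_glucuronidation(substrate_smiles: str,
                        product_smiles: str) -> ReactionRecord:
    """Derive a fully mapped reaction from an (unmapped) substrate/glucuronide
    pair by excising the glucuronosyl moiety from the product and matching
    the remaining aglycone back onto the substrate."""
    substrate = Chem.MolFromSmiles(substrate_smiles)
    product = Chem.MolFromSmiles(product_smiles)
    if substrate is None or product is None:
        raise MoleculeParseError("unparseable substrate or product SMILES")

    matches = product.GetSubstructMatches(GLUCURONYL_CORE)
    if not matches:
        raise UnsupportedReactionError("product contains no glucuronide")
    if len(matches) > 1:
        raise UnsupportedReactionError("diglucuronide products are unsupported")
    core = matches[0]
    anomeric = product.GetAtomWithIdx(core[0])
    attach = [a for a in anomeric.GetNeighbors() if a.GetIdx() not in core]
    if len(attach) != 1 or attach[0].GetSymbol() not in ("O", "N"):
        raise UnsupportedReactionError(
            "anomeric carbon is not linked to a single O/N aglycone atom")
    attach_idx = attach[0].GetIdx()

    marked = Chem.RWMol(product)
    marked.GetAtomWithIdx(attach_idx).SetProp("_attachment", "1")
    for idx in sorted(core, reverse=True):
        marked.RemoveAtom(idx)
    aglycone = marked.GetMol()
    Chem.SanitizeMol(aglycone)
    if Chem.MolToSmiles(aglycone) != Chem.MolToSmiles(substrate):
        raise UnsupportedReactionError(
            "aglycone does not match the supplied substrate")

    agly_attach = next(a.GetIdx() for a in aglycone.GetAtoms()
                       if a.HasProp("_attachment"))
    mapping = substrate.GetSubstructMatch(aglycone)
    if not mapping:
        raise UnsupportedReactionError(
            "could not align aglycone atoms onto the substrate")
    return emit_smirks(substrate, mapping[agly_attach])


# ---------------------------------------------------------------------------
# batch I/O
# ---------------------------------------------------------------------------

def load_molecules(path: str) -> List[MoleculeRecord]:
    """Load molecules from a CSV (columns id,smiles[,label]) or a SMILES file
    (one per line, optional tab-separated id). Invalid rows are logged and
    skipped."""
    records: List[MoleculeRecord] = []
    if str(path).lower().endswith(".csv"):
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                try:
                    label = row.get("label")
                    label = int(label) if label not in (None, "") else None
                    records.append(parse_molecule(
                        row["smiles"], id=row.get("id"), label=label))
                except (ChemIOError, KeyError) as exc:
                    logger.warning("skipping molecule row %r: %s", row, exc)
    else:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                smiles = parts[0]
                mid = parts[1] if len(parts) > 1 else f"line{ln}"
                try:
                    records.append(parse_molecule(smiles, id=mid))
                except ChemIOError as exc:
                    logger.warning("skipping line %d: %s", ln, exc)
    return records


def write_molecules_csv(records: Sequence[MoleculeRecord], path: str,
                        annotate_sites: bool = False) -> None:
    """Write a normalized CSV with canonical SMILES and, optionally, the
    candidate-site annotation as a JSON column of (atom_index, class)."""
    with open(path, "w", newline="") as fh:
        cols = ["id", "smiles", "label"] + (["sites"] if annotate_sites else [])
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for rec in records:
            row = {"id": rec.id, "smiles": rec.smiles,
                   "label": "" if rec.label is None else rec.label}
            if annotate_sites:
                sites = enumerate_candidate_sites(rec.mol)
                row["sites"] = json.dumps(
                    [[s.atom_index, s.site_class] for s in sites])
            writer.writerow(row)


def load_reactions(path: str) -> List[ReactionRecord]:
    """Load one SMIRKS per line (or a CSV with a ``smirks`` column). Rows
    that fail parsing or validation are logged and skipped."""
    records: List[ReactionRecord] = []
    if str(path).lower().endswith(".csv"):
        with open(path, newline="") as fh:
            rows = [(row.get("id"), row["smirks"])
                    for row in csv.DictReader(fh)]
    else:
        with open(path) as fh:
            rows = [(f"line{ln}", line.strip())
                    for ln, line in enumerate(fh, 1)
                    if line.strip() and not line.startswith("#")]
    for rid, smirks in rows:
        try:
            records.append(parse_reaction(smirks, id=rid))
        except ChemIOError as exc:
            logger.warning("skipping reaction %s: %s", rid, exc)
    return records


def write_reactions(records: Sequence[ReactionRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.smirks + "\n")
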