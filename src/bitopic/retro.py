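"""In-silico retrosynthesis and the two forward coupling reactions.

The library chemistry uses exactly two robust reactions:

* **amide coupling** — carboxylic acid + amine -> amide + water;
* **Buchwald-Hartwig amination** — aryl halide + amine -> secondary/tertiary
  aryl amine + HX.

Retrosynthesis inverts them: every *acyclic* amide C(=O)-N bond and every
acyclic aromatic-C to aliphatic-N bond (N non-amide, bonded to exactly one
aromatic carbon) is a candidate disconnection.  Ring bonds (lactams,
cyclic amines) are never cut.  Each cut caps the fragments back to
reagents: the acyl fragment regains its acid -OH; the aryl fragment is
capped as the aryl *bromide* (one canonical leaving group keeps
deduplication well defined, although the forward amination accepts Cl, Br
and I); the nitrogen regains one hydrogen.

Building blocks harvested from a ligand set are deduplicated on
(canonical structure, reactive class) and filtered to a heavy-atom window,
with provenance back to every parent ligand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem

from bitopic.chemio import Molecule, canonicalize, parse_smiles

logger = logging.getLogger(__name__)

AMIDE_COUPLING = "amide_coupling"
BUCHWALD_HARTWIG = "buchwald_hartwig"

# Amine reactant: any N-H amine that is not an amide/sulfonamide/amidine N.
# Aryl amines (e.g. 2-aminobenzothiazoles) are valid amide-coupling partners;
# the amination reaction additionally requires the amine N to be aliphatic
# so the product N carries exactly one aromatic carbon.
_AMIDE_FORWARD = AllChem.ReactionFromSmarts(
    "[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(N[#6,#16]=[O,S,N]):3]"
    ">>[C:1](=[O:2])[N:3]")
_BH_FORWARD = AllChem.ReactionFromSmarts(
    "[c:1][Cl,Br,I].[NX3;H2,H1;!$(N[#6,#16]=[O,S,N]);!$(N[a]):2]"
    ">>[c:1][N:2]")

# Junction signatures: the substructure each forward reaction creates.
JUNCTION_SMARTS = {
    AMIDE_COUPLING: Chem.MolFromSmarts("[CX3](=O)[NX3]"),
    BUCHWALD_HARTWIG: Chem.MolFromSmarts("[c][NX3;!$(N[#6,#16]=[O,S,N]);!$(N(c)c)]"),
}

# Reactive-group classifiers for building blocks.
_CLASS_SMARTS = {
    "amine": Chem.MolFromSmarts("[NX3;H2,H1;!$(N[#6,#16]=[O,S,N])]"),
    "aryl_halide": Chem.MolFromSmarts("[c][Cl,Br,I]"),
    "carboxylic_acid": Chem.MolFromSmarts("[CX3](=O)[OX2H1]"),
}

REACTIVE_CLASSES = tuple(_CLASS_SMARTS)


@dataclass(frozen=True)
class ReactionRule:
    """One of the two coupling reactions with its retro disconnection."""

    name: str
    left_class: str     # reactive class of the non-amine partner
    right_class: str    # always an amine


RULES: dict[str, ReactionRule] = {
    AMIDE_COUPLING: ReactionRule(AMIDE_COUPLING, "carboxylic_acid", "amine"),
    BUCHWALD_HARTWIG: ReactionRule(BUCHWALD_HARTWIG, "aryl_halide", "amine"),
}


@dataclass
class Disconnection:
    """A single retro cut: the bond, the rule, and the capped fragments."""

    rule: str
    bond_atoms: tuple[int, int]          # (carbon, nitrogen) indices in parent
    fragments: tuple[Molecule, Molecule]  # (left: acid|aryl_halide, right: amine)

    @property
    def fragment_classes(self) -> tuple[str, str]:
        return (RULES[self.rule].left_class, RULES[self.rule].right_class)


@dataclass
class BuildingBlock:
    """A molecule tagged with its reactive-group class and provenance."""

    molecule: Molecule
    reactive_class: str
    source: str = "catalog"              # retro | catalog
    parent_ids: list[str] = field(default_factory=list)
    polyfunctional: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.molecule.smiles_canonical, self.reactive_class)


@dataclass
class BlockLibrary:
    """Deduplicated building blocks keyed by (canonical SMILES, class)."""

    blocks: dict[tuple[str, str], BuildingBlock] = field(default_factory=dict)

    def add(self, block: BuildingBlock) -> None:
        existing = self.blocks.get(block.key)
        if existing is None:
            self.blocks[block.key] = block
        else:
            for pid in block.parent_ids:
                if pid not in existing.parent_ids:
                    existing.parent_ids.append(pid)

    def by_class(self, reactive_class: str) -> list[BuildingBlock]:
        return [b for b in self.blocks.values() if b.reactive_class == reactive_class]

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in REACTIVE_CLASSES}
        for b in self.blocks.values():
            out[b.reactive_class] += 1
        return out

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks.values())


def classify_block(m: Molecule | str, wanted: str | None = None) -> tuple[str | None, bool]:
    """Return (reactive_class, polyfunctional) for a candidate block.

    With ``wanted`` given, only that class is tested; otherwise classes are
    tried in the fixed order amine, aryl_halide, carboxylic_acid.
    """
    mol = m.to_rdkit() if isinstance(m, Molecule) else parse_smiles(m).to_rdkit()
    order = [wanted] if wanted else list(REACTIVE_CLASSES)
    for cls in order:
        matches = mol.GetSubstructMatches(_CLASS_SMARTS[cls])
        if matches:
            return cls, len(matches) > 1
    return None, False


# ---------------------------------------------------------------------------
# disconnection search
# ---------------------------------------------------------------------------

_AMIDE_BOND = Chem.MolFromSmarts("[CX3](=[OX1])[NX3]")
# Aromatic C - aliphatic N where N is a non-amide amine bonded to exactly
# one aromatic carbon (N-aryl amides belong to the amide rule only).
_ARYL_CN_BOND = Chem.MolFromSmarts("[c][NX3;!$(N[#6,#16]=[O,S,N]);!$(N(c)c)]")


def _candidate_bonds(mol: Chem.Mol) -> list[tuple[str, int, int]]:
    """All disconnectable (rule, carbon_idx, nitrogen_idx) bonds; acyclic only."""
    out: list[tuple[str, int, int]] = []
    for c_idx, _o, n_idx in mol.GetSubstructMatches(_AMIDE_BOND):
        bond = mol.GetBondBetweenAtoms(c_idx, n_idx)
        if bond is not None and not bond.IsInRing():
            out.append((AMIDE_COUPLING, c_idx, n_idx))
    for c_idx, n_idx in mol.GetSubstructMatches(_ARYL_CN_BOND):
        bond = mol.GetBondBetweenAtoms(c_idx, n_idx)
        if bond is not None and not bond.IsInRing():
            out.append((BUCHWALD_HARTWIG, c_idx, n_idx))
    return out


def _cut(mol: Chem.Mol, rule: str, c_idx: int, n_idx: int,
         parent_id: str) -> tuple[Molecule, Molecule] | None:
    """Break the bond and cap both fragments back to reagents."""
    rw = Chem.RWMol(mol)
    rw.RemoveBond(c_idx, n_idx)
    if rule == AMIDE_COUPLING:
        cap = rw.AddAtom(Chem.Atom(8))          # acid -OH
    else:
        cap = rw.AddAtom(Chem.Atom(35))         # aryl bromide
    rw.AddBond(c_idx, cap, Chem.BondType.SINGLE)
    n_atom = rw.GetAtomWithIdx(n_idx)
    n_atom.SetNumExplicitHs(n_atom.GetTotalNumHs() + 1)
    n_atom.SetNoImplicit(False)
    frag = rw.GetMol()
    try:
        Chem.SanitizeMol(frag)
    except Exception:                            # pragma: no cover - defensive
        logger.warning("sanitization failed cutting %s in %s", rule, parent_id)
        return None
    frag_indices = Chem.GetMolFrags(frag)
    pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True)
    if len(pieces) != 2:
        # an acyclic cut always splits the parent in two; anything else
        # means the bond was secretly ring-closing
        return None
    # the side carrying the freshly added cap atom is the acid/halide side
    left = right = None
    for piece, idxs in zip(pieces, frag_indices):
        mol_piece = parse_smiles(Chem.MolToSmiles(piece), id=f"{parent_id}|{rule}")
        if cap in idxs:
            left = mol_piece
        else:
            right = mol_piece
    if left is None or right is None:            # pragma: no cover
        return None
    return left, right


def find_disconnections(m: Molecule | str, rules: list[str] | None = None
                        ) -> list[tuple[str, tuple[int, int]]]:
    """List every disconnectable bond as (rule_name, (carbon, nitrogen)).

    Atom indices refer to the molecule's canonical atom order.  Ring bonds
    are never returned.
    """
    mol = m.to_rdkit() if isinstance(m, Molecule) else parse_smiles(m).to_rdkit()
    wanted = set(rules or RULES)
    return [(rule, (c, n)) for rule, c, n in _candidate_bonds(mol) if rule in wanted]


def deconstruct(m: Molecule | str, rules: list[str] | None = None) -> list[Disconnection]:
    """All single-cut deconstructions of a ligand into capped reagent pairs.

    Each result is one alternative cut (single-cut policy); a molecule with
    no disconnectable bond returns an empty list.
    """
    mol_obj = m if isinstance(m, Molecule) else parse_smiles(m)
    mol = mol_obj.to_rdkit()
    out: list[Disconnection] = []
    for rule, c_idx, n_idx in _candidate_bonds(mol):
        if rules is not None and rule not in rules:
            continue
        frags = _cut(mol, rule, c_idx, n_idx, mol_obj.id)
        if frags is not None:
            out.append(Disconnection(rule=rule, bond_atoms=(c_idx, n_idx),
                                     fragments=frags))
    return out


def harvest_blocks(ligands: list[Molecule],
                   size_window: tuple[int, int] = (5, 20),
                   classes_wanted: tuple[str, ...] = ("amine", "aryl_halide"),
                   rules: list[str] | None = None) -> BlockLibrary:
    """Deconstruct a ligand set and collect the fragments as building blocks.

    All single-cut fragments of all ligands are classified, filtered to
    ``classes_wanted`` and the heavy-atom ``size_window`` (inclusive), and
    deduplicated on (canonical structure, class) with provenance to every
    parent ligand.
    """
    if not ligands:
        raise ValueError("harvest_blocks requires at least one ligand")
    lo, hi = size_window
    library = BlockLibrary()
    for ligand in ligands:
        for disc in deconstruct(ligand, rules=rules):
            for frag, cls in zip(disc.fragments, disc.fragment_classes):
                if cls not in classes_wanted:
                    continue
                got_cls, poly = classify_block(frag, wanted=cls)
                if got_cls != cls:
                    continue
                if not (lo <= frag.n_heavy <= hi):
                    continue
                library.add(BuildingBlock(
                    molecule=frag, reactive_class=cls, source="retro",
                    parent_ids=[ligand.id], polyfunctional=poly))
    if not library:
        logger.warning("harvest produced no building blocks "
                       "(%d ligands, window %s)", len(ligands), size_window)
    return library


# ---------------------------------------------------------------------------
# forward reactions
# ---------------------------------------------------------------------------

def apply_forward(rule: str, left: Molecule | str, right: Molecule | str,
                  product_id: str = "") -> Molecule:
    """Run a forward coupling: ``left`` is the acid or aryl halide,
    ``right`` the amine.  Reacts exactly once, at the first matched site in
    canonical atom order.

    Raises
    ------
    ValueError
        If the pair has no matching reactive sites for the rule.
    """
    left_m = left if isinstance(left, Molecule) else parse_smiles(left)
    right_m = right if isinstance(right, Molecule) else parse_smiles(right)
    rxn = _AMIDE_FORWARD if rule == AMIDE_COUPLING else _BH_FORWARD
    if rule not in RULES:
        raise ValueError(f"unknown reaction rule {rule!r}")
    products = rxn.RunReactants((left_m.to_rdkit(), right_m.to_rdkit()))
    if not products:
        raise ValueError(
            f"{rule} has no matching sites for {left_m.smiles_canonical} + "
            f"{right_m.smiles_canonical}")
    prod = products[0][0]
    Chem.SanitizeMol(prod)
    out = parse_smiles(Chem.MolToSmiles(prod),
                       id=product_id or f"{left_m.id}+{right_m.id}")
    out.provenance.update({"rule": rule, "left": left_m.id, "right": right_m.id,
                           "ambiguous_site": len(products) > 1})
    if len(products) > 1:
        logger.debug("%s: %d alternative sites for %s + %s; using first",
                     rule, len(products), left_m.id, right_m.id)
    return out


def write_block_library(library: BlockLibrary, smi_path: str | Path,
                        manifest_path: str | Path) -> int:
    """Write a block library as .smi plus a CSV manifest
    (block id, class, parents, heavy atoms, polyfunctional)."""
    import csv

    blocks = sorted(library, key=lambda b: b.key)
    with Path(smi_path).open("w") as fh:
        for i, b in enumerate(blocks):
            fh.write(f"{b.molecule.smiles_canonical}\tBB{i:05d}\n")
    with Path(manifest_path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["block_id", "smiles", "reactive_class", "source",
                         "parents", "n_heavy", "polyfunctional"])
        for i, b in enumerate(blocks):
            writer.writerow([f"BB{i:05d}", b.molecule.smiles_canonical,
                             b.reactive_class, b.source,
                             ";".join(b.parent_ids), b.molecule.n_heavy,
                             int(b.polyfunctional)])
    return len(blocks)
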