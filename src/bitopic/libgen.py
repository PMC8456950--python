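"""Reaction-based enumeration of the dual-target virtual library.

The library is assembled as core + linker + building block:

* **core** — N-alkyl-2-aminoindane (the dopaminergic cation anchor);
  the N-alkyl group is methyl, ethyl or propyl;
* **linker** — a methylene chain grown from the core nitrogen ending in
  either a carboxylic acid (amide-coupling linkers: pentanamide /
  butanamide / propanamide with 4 / 3 / 2 methylenes before the carbonyl)
  or a primary amine (butylamine, 4 methylenes, for Buchwald-Hartwig
  amination);
* **building block** — an amine or aryl halide from retrosynthetic
  harvesting or a commercial catalog.

Core + linker gives a *synthon* with exactly one unreacted terminal group;
synthons are combined with compatible blocks by the forward reactions in
:mod:`bitopic.retro`.  A separate R-group grid enumerator reproduces the
optimization series: the benzothiazol-2-yl amide scaffold with R1 on the
core nitrogen, R2 at benzothiazole C4 and R3 at C7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem

from bitopic.chemio import Molecule, parse_smiles
from bitopic.retro import (
    AMIDE_COUPLING,
    BUCHWALD_HARTWIG,
    JUNCTION_SMARTS,
    BlockLibrary,
    apply_forward,
)

logger = logging.getLogger(__name__)

INDANE_CORE_SMILES = "C1Cc2ccccc2C1"  # indan-2-yl attachment at C2

_N_ALKYL = {"CH3": "C", "C2H5": "CC", "C3H7": "CCC"}


@dataclass(frozen=True)
class CoreScaffold:
    """N-alkyl-2-aminoindane core; the amine nitrogen is the attachment."""

    n_alkyl: str = "CH3"   # CH3 | C2H5 | C3H7

    def __post_init__(self):
        if self.n_alkyl not in _N_ALKYL:
            raise ValueError(f"n_alkyl must be one of {sorted(_N_ALKYL)}")

    @property
    def smiles(self) -> str:
        return f"{_N_ALKYL[self.n_alkyl]}NC1Cc2ccccc2C1"

    def molecule(self) -> Molecule:
        return parse_smiles(self.smiles, id=f"core_{self.n_alkyl}")


@dataclass(frozen=True)
class Linker:
    """Methylene chain attached to the core nitrogen with a terminal
    reactive group.

    ``chain`` counts the methylenes between the nitrogen and the terminal
    group carbon (the carbonyl carbon for acid linkers, the amine-bearing
    carbon is included in the chain for the amine linker).
    """

    name: str
    chain: int
    terminal: str  # carboxylic_acid | primary_amine

    @property
    def block_side_class(self) -> str:
        return "amine" if self.terminal == "carboxylic_acid" else "aryl_halide"

    @property
    def rule(self) -> str:
        return AMIDE_COUPLING if self.terminal == "carboxylic_acid" else BUCHWALD_HARTWIG


LINKERS: dict[str, Linker] = {
    "pentanamide": Linker("pentanamide", 4, "carboxylic_acid"),
    "butanamide": Linker("butanamide", 3, "carboxylic_acid"),
    "propanamide": Linker("propanamide", 2, "carboxylic_acid"),
    "butylamine": Linker("butylamine", 4, "primary_amine"),
}

_SECONDARY_AMINE = Chem.MolFromSmarts("[NX3;H1;!$(N[a]);!$(N[#6,#16]=[O,S,N])]")


@dataclass(frozen=True)
class Synthon:
    """Core fused to linker, carrying one unreacted terminal group."""

    molecule: Molecule
    core_id: str
    linker_id: str
    compatible_block_class: str  # amine | aryl_halide
    rule: str


def build_synthon(core: CoreScaffold, linker: Linker) -> Synthon:
    """Alkylate the core's secondary amine with the linker chain.

    The core amine becomes tertiary and the linker's terminal group is
    preserved as the synthon's single reactive handle.
    """
    core_mol = core.molecule()
    rd = core_mol.to_rdkit()
    matches = rd.GetSubstructMatches(_SECONDARY_AMINE)
    if not matches:
        raise ValueError(f"core {core_mol.id} lacks a free secondary aliphatic amine")
    n_idx = matches[0][0]

    chain = "C" * linker.chain
    terminus = "C(=O)O" if linker.terminal == "carboxylic_acid" else "N"
    linker_frag = Chem.MolFromSmiles(f"*{chain}{terminus}")

    combined = Chem.RWMol(Chem.CombineMols(rd, linker_frag))
    offset = rd.GetNumAtoms()
    dummy_idx = next(a.GetIdx() for a in combined.GetAtoms()
                     if a.GetIdx() >= offset and a.GetAtomicNum() == 0)
    attach_idx = combined.GetAtomWithIdx(dummy_idx).GetNeighbors()[0].GetIdx()
    combined.AddBond(n_idx, attach_idx, Chem.BondType.SINGLE)
    n_atom = combined.GetAtomWithIdx(n_idx)
    n_atom.SetNumExplicitHs(0)
    n_atom.SetNoImplicit(False)
    combined.RemoveAtom(dummy_idx)
    product = combined.GetMol()
    Chem.SanitizeMol(product)

    mol = parse_smiles(Chem.MolToSmiles(product),
                       id=f"synthon_{core.n_alkyl}_{linker.name}")
    return Synthon(molecule=mol, core_id=core_mol.id, linker_id=linker.name,
                   compatible_block_class=linker.block_side_class,
                   rule=linker.rule)


@dataclass
class LibraryProduct:
    """An enumerated compound with full provenance."""

    molecule: Molecule
    core_id: str
    linker_id: str
    block_id: str
    rule_name: str
    junction_ok: bool = True
    ambiguous_site: bool = False
    r_tuple: tuple[str, ...] | None = None
    provenance: list[tuple[str, str, str, str]] = field(default_factory=list)

    @property
    def smiles(self) -> str:
        return self.molecule.smiles_canonical


def _has_junction(mol: Chem.Mol, rule: str) -> bool:
    return mol.HasSubstructMatch(JUNCTION_SMARTS[rule])


def enumerate_library(synthons: list[Synthon], blocks: BlockLibrary
                      ) -> list[LibraryProduct]:
    """React every synthon with every compatible building block once.

    Each (synthon, block) pair with matching chemistry is reacted exactly
    once at the first matched site (polyfunctional blocks are flagged
    ambiguous rather than expanded into site isomers).  Products are
    deduplicated by canonical structure with merged provenance; failed
    transforms are logged, never silently dropped.
    """
    if not synthons:
        raise ValueError("enumerate_library requires at least one synthon")
    products: dict[str, LibraryProduct] = {}
    n_failed = 0
    for synthon in synthons:
        compatible = blocks.by_class(synthon.compatible_block_class)
        for block in sorted(compatible, key=lambda b: b.key):
            block_id = block.molecule.id
            if synthon.rule == AMIDE_COUPLING:
                left, right = synthon.molecule, block.molecule
            else:
                left, right = block.molecule, synthon.molecule
            try:
                prod = apply_forward(synthon.rule, left, right,
                                     product_id=f"{synthon.molecule.id}+{block_id}")
            except ValueError:
                n_failed += 1
                logger.warning("transform failed: %s + %s via %s",
                               synthon.molecule.id, block_id, synthon.rule)
                continue
            key = prod.smiles_canonical
            prov = (synthon.core_id, synthon.linker_id, block_id, synthon.rule)
            if key in products:
                products[key].provenance.append(prov)
                continue
            products[key] = LibraryProduct(
                molecule=prod,
                core_id=synthon.core_id,
                linker_id=synthon.linker_id,
                block_id=block_id,
                rule_name=synthon.rule,
                junction_ok=_has_junction(prod.to_rdkit(), synthon.rule),
                ambiguous_site=bool(prod.provenance.get("ambiguous_site")),
                provenance=[prov],
            )
    if not products:
        logger.warning("enumeration produced zero products")
    if n_failed:
        logger.warning("%d transforms failed during enumeration", n_failed)
    return list(products.values())


# ---------------------------------------------------------------------------
# R-group grid enumeration (optimization series)
# ---------------------------------------------------------------------------

# Monovalent substituent tokens accepted in grids, written as SMILES
# fragments from the attachment point.
R_TOKENS: dict[str, str] = {
    "H": "",
    "CH3": "C",
    "CH2CH3": "CC",
    "C2H5": "CC",
    "CH2CH2CH3": "CCC",
    "C3H7": "CCC",
    "OCH3": "OC",
    "OMe": "OC",
    "F": "F",
    "Cl": "Cl",
    "Br": "Br",
    "I": "I",
}


@dataclass(frozen=True)
class GridScaffold:
    """Markush scaffold for the optimization series.

    Default: indan-2-yl-N(R1)-(CH2)n-C(=O)NH-(benzothiazol-2-yl with R2 at
    C4 and R3 at C7); ``chain`` methylenes before the carbonyl (4 for the
    pentanamide series).
    """

    chain: int = 4

    def smiles(self, r1: str, r2: str, r3: str) -> str:
        r2_part = f"({r2})" if r2 else ""
        r3_part = f"({r3})" if r3 else ""
        chain = "C" * self.chain
        return (f"{r1}N(C1Cc2ccccc2C1){chain}C(=O)"
                f"Nc1nc2c{r2_part}ccc{r3_part}c2s1")


PENTANAMIDE_GRID_SCAFFOLD = GridScaffold(chain=4)


def _token_fragment(token: str, cell: str) -> str:
    if token in R_TOKENS:
        return R_TOKENS[token]
    # fall back to raw SMILES fragment; validate on a probe atom
    if Chem.MolFromSmiles(f"C{token}") is None:
        raise ValueError(f"invalid substituent {token!r} at grid cell {cell}")
    return token


def enumerate_rgroup_grid(grid: dict[str, list[str]],
                          scaffold: GridScaffold = PENTANAMIDE_GRID_SCAFFOLD
                          ) -> list[LibraryProduct]:
    """Enumerate the full R1 x R2 x R3 grid on the Markush scaffold.

    ``grid`` maps ``"R1"``/``"R2"``/``"R3"`` to non-empty lists of
    substituent tokens (named tokens like ``"OCH3"`` or raw SMILES
    fragments).  R1 is the core N-alkyl and must not be H.  Products are
    tagged with their R-tuple; duplicates (from synonymous tokens) are
    kept once.
    """
    for key in ("R1", "R2", "R3"):
        if not grid.get(key):
            raise ValueError(f"grid list {key} must be non-empty")
    products: dict[str, LibraryProduct] = {}
    for r1 in grid["R1"]:
        frag1 = _token_fragment(r1, f"R1={r1}")
        if not frag1:
            raise ValueError("R1 (core N-alkyl) cannot be H")
        for r2 in grid["R2"]:
            frag2 = _token_fragment(r2, f"R2={r2}")
            for r3 in grid["R3"]:
                frag3 = _token_fragment(r3, f"R3={r3}")
                smi = scaffold.smiles(frag1, frag2, frag3)
                mol = parse_smiles(smi, id=f"grid_{r1}_{r2}_{r3}")
                if mol.smiles_canonical in products:
                    continue
                products[mol.smiles_canonical] = LibraryProduct(
                    molecule=mol,
                    core_id=f"core_{r1}",
                    linker_id={4: "pentanamide", 3: "butanamide",
                               2: "propanamide"}.get(scaffold.chain,
                                                     f"chain{scaffold.chain}"),
                    block_id=f"benzothiazole_{r2}_{r3}",
                    rule_name=AMIDE_COUPLING,
                    junction_ok=_has_junction(mol.to_rdkit(), AMIDE_COUPLING),
                    r_tuple=(r1, r2, r3),
                    provenance=[(f"core_{r1}", "grid", f"{r2}|{r3}",
                                 AMIDE_COUPLING)],
                )
    return list(products.values())


def write_library(products: list[LibraryProduct], smi_path, manifest_path) -> int:
    """Write an enumerated library as .smi plus a CSV provenance manifest."""
    import csv
    from pathlib import Path

    ordered = sorted(products, key=lambda p: p.smiles)
    with Path(smi_path).open("w") as fh:
        for i, p in enumerate(ordered):
            fh.write(f"{p.smiles}\tLP{i:06d}\n")
    with Path(manifest_path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["product_id", "smiles", "core", "linker", "block",
                         "rule", "junction_ok", "ambiguous_site", "r_tuple"])
        for i, p in enumerate(ordered):
            writer.writerow([f"LP{i:06d}", p.smiles, p.core_id, p.linker_id,
                             p.block_id, p.rule_name, int(p.junction_ok),
                             int(p.ambiguous_site),
                             "|".join(p.r_tuple) if p.r_tuple else ""])
    return len(ordered)
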