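"""Physicochemical descriptors and CNS-permeability rule filtering.

Descriptors follow standard 2D conventions: average molecular weight from
standard atomic weights, Crippen atom-contribution logP, and the Ertl
topological polar surface area without S/P contributions (the classic
published table), so the <90 A^2 CNS comparison has a fixed meaning.

LogD at a given pH is derived from logP with a rule-based ionization
correction rather than a trained predictor.  Only aliphatic amines are
treated as basic; anilines and other aryl-conjugated amines, amide
nitrogens and azine/azole ring nitrogens are non-basic.  This encodes the
single ionization distinction that matters for the design series: the core
aliphatic amine is cationic at physiological pH, everything else is
neutral.  Assigned pKa values:

======================  ====
primary aliphatic amine 10.2
secondary               10.0
tertiary                 9.5
======================  ====

For a base, ``logD(pH) = logP - sum log10(1 + 10**(pKa - pH))`` over basic
centers; the correction vanishes in the basic limit and equals
``pKa - pH`` (plus ~0) when the center is fully protonated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from bitopic.chemio import Molecule

PKA_PRIMARY_AMINE = 10.2
PKA_SECONDARY_AMINE = 10.0
PKA_TERTIARY_AMINE = 9.5

# Aliphatic amine N: not an amide/sulfonamide/amidine N, not attached to
# any aromatic atom (excludes anilines and aryl-conjugated amines), not an
# aromatic ring N itself (uppercase N in SMARTS is aliphatic-only).
_BASIC_AMINE_PATTERNS = (
    (Chem.MolFromSmarts("[NX3;H2;!$(N[a]);!$(N[#6,#16]=[O,S,N]);!$(N#*)]"),
     "primary", PKA_PRIMARY_AMINE),
    (Chem.MolFromSmarts("[NX3;H1;!$(N[a]);!$(N[#6,#16]=[O,S,N]);!$(N#*)]"),
     "secondary", PKA_SECONDARY_AMINE),
    (Chem.MolFromSmarts("[NX3;H0;!$(N[a]);!$(N[#6,#16]=[O,S,N]);!$(N#*)]"),
     "tertiary", PKA_TERTIARY_AMINE),
)


@dataclass(frozen=True)
class BasicCenter:
    atom_idx: int
    kind: str           # primary | secondary | tertiary
    pka: float


@dataclass(frozen=True)
class PropertyProfile:
    """Computed physicochemical descriptors of one compound."""

    mw: float           # average molecular weight, Da
    clogp: float        # Crippen octanol/water partition estimate
    clogd74: float      # distribution coefficient estimate at pH 7.4
    tpsa: float         # topological polar surface area, A^2
    hbd: int            # H-bond donor count
    hba: int            # H-bond acceptor count
    rotb: int           # rotatable bonds
    charge74: int       # predicted formal charge at pH 7.4


@dataclass(frozen=True)
class CnsRuleSet:
    """CNS blood-brain-barrier permeability property bounds.

    Maxima are strict (a profile exactly at the bound fails); the logD
    window is inclusive.
    """

    mw_max: float = 500.0
    tpsa_max: float = 90.0
    hbd_max: int = 3
    clogd_range: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self):
        if self.mw_max <= 0:
            raise ValueError("mw_max must be positive")
        if self.clogd_range[0] > self.clogd_range[1]:
            raise ValueError("clogd_range low must not exceed high")


@dataclass(frozen=True)
class FilterResult:
    """Per-rule pass/fail flags; ``overall`` is their conjunction."""

    flags: dict = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(self.flags.values())

    def __bool__(self) -> bool:
        return self.overall


def _as_mol(m: Molecule | Chem.Mol | str) -> Chem.Mol:
    if isinstance(m, Molecule):
        return m.to_rdkit()
    if isinstance(m, str):
        from bitopic.chemio import mol_from_smiles
        return mol_from_smiles(m)
    return m


def find_basic_centers(m: Molecule | Chem.Mol | str) -> list[BasicCenter]:
    """Locate basic aliphatic amine nitrogens and assign rule-based pKa."""
    mol = _as_mol(m)
    centers: list[BasicCenter] = []
    seen: set[int] = set()
    for patt, kind, pka in _BASIC_AMINE_PATTERNS:
        for (idx,) in mol.GetSubstructMatches(patt):
            if idx not in seen:
                seen.add(idx)
                centers.append(BasicCenter(idx, kind, pka))
    return sorted(centers, key=lambda c: c.atom_idx)


def ionization_state(m: Molecule | Chem.Mol | str, pH: float = 7.4
                     ) -> tuple[int, list[tuple[BasicCenter, float]]]:
    """Predicted formal charge at ``pH`` plus fraction ionized per center.

    Fraction ionized for a base is ``1 / (1 + 10**(pH - pKa))``; a center
    counts toward the formal charge when it is majority-protonated.
    """
    centers = find_basic_centers(m)
    fractions = [(c, 1.0 / (1.0 + 10.0 ** (pH - c.pka))) for c in centers]
    charge = sum(1 for _, f in fractions if f > 0.5)
    return charge, fractions


def estimate_clogd(m: Molecule | Chem.Mol | str, pH: float = 7.4) -> float:
    """Rule-based logD(pH) from Crippen logP and assigned amine pKa values.

    Molecules with no ionizable center return clogp unchanged; ionization
    can only reduce apparent lipophilicity, so ``clogd <= clogp`` always.
    """
    mol = _as_mol(m)
    clogp = Crippen.MolLogP(mol)
    correction = sum(math.log10(1.0 + 10.0 ** (c.pka - pH))
                     for c in find_basic_centers(mol))
    return clogp - correction


def compute_profile(m: Molecule | Chem.Mol | str) -> PropertyProfile:
    """Compute the full descriptor profile of one molecule."""
    mol = _as_mol(m)
    charge, _ = ionization_state(mol, 7.4)
    return PropertyProfile(
        mw=Descriptors.MolWt(mol),
        clogp=Crippen.MolLogP(mol),
        clogd74=estimate_clogd(mol, 7.4),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(mol),
        charge74=charge,
    )


def cns_filter(p: PropertyProfile, rules: CnsRuleSet | None = None) -> FilterResult:
    """Apply CNS property bounds; strict maxima, inclusive logD window."""
    rules = rules or CnsRuleSet()
    low, high = rules.clogd_range
    return FilterResult(flags={
        "mw": p.mw < rules.mw_max,
        "tpsa": p.tpsa < rules.tpsa_max,
        "hbd": p.hbd < rules.hbd_max,
        "clogd": low <= p.clogd74 <= high,
    })
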