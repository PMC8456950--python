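"""Packaged reference compounds and seeded synthetic-data generators.

Two kinds of fixture data make every pipeline stage runnable and testable
without any external download:

* :func:`paper_compounds` — the registry of the published design series:
  the N-methyl-2-aminoindane core (compound 1), the first dual-target hit
  (compound 2), the optimization grid (compounds 18-30) and the two
  core+linker synthons, each with transcribed assay values.  Structures
  are reconstructed only where the published record fully determines them
  (named building block + named linker + the Markush grid); everything
  else is a data-only entry flagged ``underdetermined`` — no structure is
  ever guessed.

* seeded generators — :func:`generate_catalog` emulates a commercial
  building-block catalog (substituted benzenes, pyridines and
  benzothiazoles with amine / aryl-bromide / carboxylic-acid handles;
  the grammar deliberately includes benzothiazol-2-amines so
  retro/forward tests exercise the campaign's actual chemotype) and
  :func:`generate_mock_ligands` builds ligands by forward coupling of
  sampled catalog pairs, recording the true (block, block, rule) answer
  key for round-trip tests.  Both are pure functions of their seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from bitopic.chemio import Molecule, parse_smiles
from bitopic.libgen import (
    PENTANAMIDE_GRID_SCAFFOLD,
    CoreScaffold,
    LINKERS,
    build_synthon,
)
from bitopic.retro import (
    AMIDE_COUPLING,
    BUCHWALD_HARTWIG,
    BlockLibrary,
    BuildingBlock,
    apply_forward,
    classify_block,
)

CORE_SMILES = "CNC1Cc2ccccc2C1"  # compound 1, N-methyl-2-aminoindane

# Table-2 Markush tuples (R1 = core N-alkyl, R2 = benzothiazole C4,
# R3 = benzothiazole C7) for the pentanamide series.
GRID_TUPLES: dict[str, tuple[str, str, str]] = {
    "2": ("CH3", "CH3", "H"),
    "18": ("CH3", "OCH3", "H"),
    "19": ("CH3", "Cl", "H"),
    "20": ("CH3", "Br", "H"),
    "21": ("CH2CH3", "OCH3", "H"),
    "22": ("CH2CH3", "Br", "H"),
    "23": ("CH2CH2CH3", "F", "H"),
    "24": ("CH2CH2CH3", "CH2CH3", "H"),
    "25": ("CH2CH2CH3", "CH3", "H"),
    "26": ("CH2CH2CH3", "OCH3", "H"),
    "27": ("CH2CH2CH3", "Br", "H"),
    "28": ("CH2CH2CH3", "OCH3", "Cl"),
    "29": ("CH2CH2CH3", "OCH3", "CH3"),
    "30": ("CH2CH2CH3", "OCH3", "OCH3"),
}

# Shortened-linker analogs: R-tuples are published but whether each row
# carries the butanamide or propanamide linker is not, so these entries
# stay structure-underdetermined.
SHORT_LINKER_TUPLES: dict[str, tuple[str, str, str]] = {
    "31": ("CH3", "CH3", "H"),
    "32": ("CH3", "Br", "H"),
    "33": ("CH3", "Br", "H"),
    "37": ("CH3", "OCH3", "OCH3"),
    "39": ("CH2CH3", "OCH3", "CH3"),
    "40": ("CH2CH3", "OCH3", "OCH3"),
}

BENZOTHIAZOLE_BLOCK_SMILES = "Cc1cccc2sc(N)nc12"  # 2-amino-4-methylbenzothiazole


@dataclass
class PaperCompound:
    """One registry entry: structure (when determined) plus assay data."""

    id: str
    molecule: Molecule | None
    underdetermined: bool
    note: str
    r_tuple: tuple[str, str, str] | None = None
    linker: str | None = None
    assays: dict[str, dict[str, float]] = field(default_factory=dict)


class PaperCompoundRegistry(dict):
    """Mapping of compound id -> :class:`PaperCompound`."""

    def determined(self) -> list[PaperCompound]:
        return [c for c in self.values() if not c.underdetermined]


def load_assay_table() -> pd.DataFrame:
    """The transcribed binding/functional assay table as a DataFrame."""
    with resources.files("bitopic.data").joinpath("paper_assays.csv").open() as fh:
        return pd.read_csv(fh, dtype={"compound_id": str})


def assay_data_bytes() -> bytes:
    """Raw bytes of the packaged assay table (for integrity checks)."""
    return resources.files("bitopic.data").joinpath("paper_assays.csv").read_bytes()


def _grid_molecule(cid: str, r_tuple: tuple[str, str, str]) -> Molecule:
    r1, r2, r3 = r_tuple
    from bitopic.libgen import R_TOKENS
    smi = PENTANAMIDE_GRID_SCAFFOLD.smiles(
        R_TOKENS[r1], R_TOKENS[r2], R_TOKENS[r3])
    return parse_smiles(smi, id=cid)


def paper_compounds() -> PaperCompoundRegistry:
    """Build the reference-compound registry.

    Fully determined structures: compound 1 (the core amine), compounds 2
    and 18-30 (the pentanamide Markush grid), and the two N-methyl
    synthons.  Compounds 3, 4, 12, 13 and the short-linker analogs carry
    assay data with the structure flagged underdetermined.
    """
    registry = PaperCompoundRegistry()

    registry["1"] = PaperCompound(
        id="1", molecule=parse_smiles(CORE_SMILES, id="1"),
        underdetermined=False,
        note="N-methyl-2-aminoindane core scaffold")

    for cid, r_tuple in GRID_TUPLES.items():
        registry[cid] = PaperCompound(
            id=cid, molecule=_grid_molecule(cid, r_tuple),
            underdetermined=False,
            note="pentanamide-linked benzothiazol-2-yl amide series",
            r_tuple=r_tuple, linker="pentanamide")

    for cid, note in {
        "3": "dual-target hit; building block not published in full",
        "4": "dual-target hit from the commercial-block library; "
             "building block not published in full",
        "12": "benzothiazole-based orthosteric fragment; capping not drawn",
        "13": "aminoindane-based orthosteric fragment; capping not drawn",
    }.items():
        registry[cid] = PaperCompound(
            id=cid, molecule=None, underdetermined=True, note=note)

    for cid, r_tuple in SHORT_LINKER_TUPLES.items():
        registry[cid] = PaperCompound(
            id=cid, molecule=None, underdetermined=True,
            note="shortened-linker analog; butanamide vs propanamide "
                 "assignment not published",
            r_tuple=r_tuple, linker="unassigned")

    core = CoreScaffold("CH3")
    for linker_name in ("pentanamide", "butylamine"):
        synthon = build_synthon(core, LINKERS[linker_name])
        registry[synthon.molecule.id] = PaperCompound(
            id=synthon.molecule.id, molecule=synthon.molecule,
            underdetermined=False,
            note=f"N-methyl core + {linker_name} linker synthon")

    assays = load_assay_table()
    for _, row in assays.iterrows():
        cid = row["compound_id"]
        if cid not in registry:
            continue
        values = {k: row[k] for k in
                  ("ki_um", "ki_sem_um", "kb_um", "ec50_um", "emax_pct",
                   "displacement_pct")
                  if pd.notna(row[k])}
        registry[cid].assays[row["target"]] = values
    return registry


# ---------------------------------------------------------------------------
# seeded synthetic catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCatalogSpec:
    """Parameters of the synthetic building-block catalog."""

    n_amines: int = 50
    n_aryl_halides: int = 30
    n_acids: int = 20
    heavy_range: tuple[int, int] = (5, 20)
    seed: int = 0
    polyfunctional_fraction: float = 0.0

    def __post_init__(self):
        if min(self.n_amines, self.n_aryl_halides, self.n_acids) < 0:
            raise ValueError("block counts must be non-negative")
        if not 0.0 <= self.polyfunctional_fraction <= 1.0:
            raise ValueError("polyfunctional_fraction must be in [0, 1]")


_RING_TEMPLATES = [
    "c1ccccc1",
    "c1ccc({s})cc1",
    "c1cccc({s})c1",
    "c1ccc({s})c({s2})c1",
    "c1cccnc1",
    "c1ccc({s})cn1",
    "c1nc2ccccc2s1",
    "c1nc2c({s})cccc2s1",
    "c1nc2c({s})ccc({s2})c2s1",
]
_SUBS = ["C", "OC", "F", "CC"]


def _decorated_ring(rng: random.Random) -> str:
    template = rng.choice(_RING_TEMPLATES)
    return template.format(s=rng.choice(_SUBS), s2=rng.choice(_SUBS))


def _amine_smiles(rng: random.Random, polyfunctional: bool) -> str:
    if polyfunctional:
        # two amine handles by construction
        choice = rng.choice([
            "NCC({r})CN", "NCCN", "NCCCN", "NCc1ccc(CN)cc1", "NCCNCC",
        ])
        return choice.format(r=_decorated_ring(rng))
    kind = rng.randrange(5)
    ring = _decorated_ring(rng)
    if kind == 0:
        return f"N{ring}"          # aryl amine (2-aminoazole chemotype included)
    if kind == 1:
        return f"NC{ring}"         # benzylic
    if kind == 2:
        return f"NCC{ring}"        # phenethyl
    if kind == 3:
        return f"CNC{ring}"        # secondary N-methyl benzylic
    return "N" + "C" * rng.randint(4, 8)


def _halide_smiles(rng: random.Random) -> str:
    return f"Br{_decorated_ring(rng)}"


def _acid_smiles(rng: random.Random) -> str:
    kind = rng.randrange(3)
    if kind == 0:
        return f"OC(=O){_decorated_ring(rng)}"
    if kind == 1:
        return f"OC(=O)C{_decorated_ring(rng)}"
    return "OC(=O)" + "C" * rng.randint(3, 7)


def generate_catalog(spec: SyntheticCatalogSpec) -> BlockLibrary:
    """Generate a reproducible synthetic building-block catalog.

    Blocks are assembled from a fixed fragment grammar; the same seed
    yields a byte-identical catalog.  ``polyfunctional_fraction`` applies
    to the amine set: exactly ``round(fraction * n_amines)`` blocks carry
    two amine handles and are flagged polyfunctional.

    Raises
    ------
    ValueError
        If the constraints cannot be met (e.g. a heavy-atom range too
        narrow for the grammar).
    """
    rng = random.Random(spec.seed)
    lo, hi = spec.heavy_range
    library = BlockLibrary()

    def fill(n: int, cls: str, prefix: str, make, want_poly: bool) -> None:
        made = 0
        attempts = 0
        seen: set[str] = set()
        while made < n:
            attempts += 1
            if attempts > 300 * max(n, 1):
                raise ValueError(
                    f"cannot generate {n} {'polyfunctional ' if want_poly else ''}"
                    f"{cls} blocks within heavy-atom range {spec.heavy_range}")
            smi = make(rng)
            try:
                mol = parse_smiles(smi)
            except Exception:      # pragma: no cover - grammar emits valid SMILES
                continue
            if not (lo <= mol.n_heavy <= hi):
                continue
            got, poly = classify_block(mol, wanted=cls)
            if got != cls or poly != want_poly:
                continue
            if mol.smiles_canonical in seen:
                continue
            seen.add(mol.smiles_canonical)
            mol.id = f"{prefix}{made:04d}"
            library.add(BuildingBlock(molecule=mol, reactive_class=cls,
                                      source="catalog", polyfunctional=poly))
            made += 1

    n_poly = round(spec.polyfunctional_fraction * spec.n_amines)
    fill(n_poly, "amine", "AMP", _amine_smiles_poly, True)
    fill(spec.n_amines - n_poly, "amine", "AM", _amine_smiles_mono, False)
    fill(spec.n_aryl_halides, "aryl_halide", "AR", _halide_smiles, False)
    fill(spec.n_acids, "carboxylic_acid", "AC", _acid_smiles, False)
    return library


def _amine_smiles_poly(rng: random.Random) -> str:
    return _amine_smiles(rng, True)


def _amine_smiles_mono(rng: random.Random) -> str:
    return _amine_smiles(rng, False)


# ---------------------------------------------------------------------------
# seeded mock ligands with answer keys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MockLigandKey:
    """Ground truth for one generated ligand."""

    ligand_id: str
    rule: str
    left_smiles: str    # acid or aryl halide, canonical
    right_smiles: str   # amine, canonical


_ALIPHATIC_NH = None


def _is_aliphatic_amine(block: BuildingBlock) -> bool:
    from rdkit import Chem
    global _ALIPHATIC_NH
    if _ALIPHATIC_NH is None:
        _ALIPHATIC_NH = Chem.MolFromSmarts(
            "[NX3;H2,H1;!$(N[#6,#16]=[O,S,N]);!$(N[a])]")
    return block.molecule.to_rdkit().HasSubstructMatch(_ALIPHATIC_NH)


def generate_mock_ligands(catalog: BlockLibrary, n: int, seed: int = 0
                          ) -> tuple[list[Molecule], list[MockLigandKey]]:
    """Build ``n`` ligands by forward coupling of sampled catalog pairs.

    Each ligand is ``forward(rule, left, right)`` for a compatible pair;
    the true (left, right, rule) is returned as the answer key so
    deconstruction round trips can be checked exactly.  Polyfunctional
    blocks and aryl amines on the amination side are excluded so every
    ligand contains exactly one junction and the answer key is
    unambiguous.

    Raises
    ------
    ValueError
        If the catalog lacks a compatible (acid|halide, amine) pairing.
    """
    rng = random.Random(seed)
    amines = sorted((b for b in catalog.by_class("amine") if not b.polyfunctional),
                    key=lambda b: b.key)
    aliphatic_amines = [b for b in amines if _is_aliphatic_amine(b)]
    acids = sorted(catalog.by_class("carboxylic_acid"), key=lambda b: b.key)
    halides = sorted(catalog.by_class("aryl_halide"), key=lambda b: b.key)

    rules: list[str] = []
    if acids and amines:
        rules.append(AMIDE_COUPLING)
    if halides and aliphatic_amines:
        rules.append(BUCHWALD_HARTWIG)
    if not rules:
        raise ValueError("catalog has no compatible (acid|aryl halide, amine) pairs")

    ligands: list[Molecule] = []
    keys: list[MockLigandKey] = []
    for i in range(n):
        rule = rng.choice(rules)
        if rule == AMIDE_COUPLING:
            left, right = rng.choice(acids), rng.choice(amines)
        else:
            left, right = rng.choice(halides), rng.choice(aliphatic_amines)
        product = apply_forward(rule, left.molecule, right.molecule,
                                product_id=f"mock{i:04d}")
        ligands.append(product)
        keys.append(MockLigandKey(
            ligand_id=product.id, rule=rule,
            left_smiles=left.molecule.smiles_canonical,
            right_smiles=right.molecule.smiles_canonical))
    return ligands, keys
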