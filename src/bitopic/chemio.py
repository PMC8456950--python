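"""Molecule representation, canonicalization and file I/O.

Every structure entering the pipeline passes through :func:`parse_smiles`,
which applies a fixed normalization policy so that structural identity is
well defined across the retro/forward round trip:

* salt/counter-ion fragments are stripped (largest covalent fragment kept);
* stereochemistry is discarded (the design series has no stereocenters;
  the 2-aminoindane C2 is constitutionally symmetric);
* tautomers are canonicalized, which maps 2-aminoazole / 2-aminobenzothiazole
  systems onto the exocyclic-amine form;
* molecules are stored neutral — protonation is a property-layer
  computation, never a structural edit.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

# RDKit is chatty on malformed records; we report skips ourselves.
RDLogger.DisableLog("rdApp.error")

_TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()


class ParseError(ValueError):
    """Raised when a line notation or record cannot be parsed."""

    def __init__(self, message: str, *, source: str = "", line: int | None = None):
        loc = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{loc}: {source!r}")
        self.source = source
        self.line = line


class SchemaError(ValueError):
    """Raised when a tabular input lacks required columns."""


@dataclass
class Molecule:
    """A small organic structure with canonical line-notation identity.

    Attributes
    ----------
    id : str
        Free-text identifier (compound number, catalog id, ...).
    smiles_input : str
        Line notation exactly as read.
    smiles_canonical : str
        Canonical SMILES after salt stripping, stereo removal and
        tautomer normalization.  This is the identity key used for
        deduplication throughout the toolkit.
    formula : str
        Hill-order molecular formula.
    n_heavy : int
        Heavy-atom count.
    salt_stripped : bool
        True when the input contained more than one covalent fragment.
    """

    id: str
    smiles_input: str
    smiles_canonical: str
    formula: str
    n_heavy: int
    salt_stripped: bool = False
    provenance: dict = field(default_factory=dict)

    def to_rdkit(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles_canonical)
        if mol is None:  # pragma: no cover - canonical SMILES always parse
            raise ParseError("stored canonical SMILES failed to parse",
                             source=self.smiles_canonical)
        return mol

    def __hash__(self) -> int:
        return hash(self.smiles_canonical)


def _largest_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Keep the largest covalent fragment; ties broken lexicographically
    by canonical SMILES (smallest string wins)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return frags[0], False
    keyed = sorted(frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    return keyed[0], True


def normalize_mol(mol: Chem.Mol) -> Chem.Mol:
    """Apply the package-wide normalization policy to an RDKit mol."""
    mol, _ = _largest_fragment(mol)
    Chem.RemoveStereochemistry(mol)
    return _TAUTOMER_ENUMERATOR.Canonicalize(mol)


def parse_smiles(text: str, id: str = "", *, line: int | None = None) -> Molecule:
    """Parse a SMILES string into a normalized :class:`Molecule`.

    Multi-fragment inputs (salts) keep only the largest fragment and the
    stripping is recorded on ``salt_stripped``.

    Raises
    ------
    ParseError
        If ``text`` is empty or not valid line notation.
    """
    if not text or not text.strip():
        raise ParseError("empty SMILES input", source=text, line=line)
    raw = Chem.MolFromSmiles(text)
    if raw is None:
        raise ParseError("unparsable SMILES", source=text, line=line)
    frag, stripped = _largest_fragment(raw)
    Chem.RemoveStereochemistry(frag)
    norm = _TAUTOMER_ENUMERATOR.Canonicalize(frag)
    return Molecule(
        id=id or text,
        smiles_input=text,
        smiles_canonical=Chem.MolToSmiles(norm),
        formula=rdMolDescriptors.CalcMolFormula(norm),
        n_heavy=norm.GetNumHeavyAtoms(),
        salt_stripped=stripped,
    )


def canonicalize(smiles_or_mol: str | Chem.Mol | Molecule) -> str:
    """Return the canonical, normalized SMILES for any molecule input.

    Output is independent of input atom ordering and idempotent:
    ``canonicalize(canonicalize(x)) == canonicalize(x)``.
    """
    if isinstance(smiles_or_mol, Molecule):
        return smiles_or_mol.smiles_canonical
    if isinstance(smiles_or_mol, str):
        return parse_smiles(smiles_or_mol).smiles_canonical
    return Chem.MolToSmiles(normalize_mol(Chem.Mol(smiles_or_mol)))


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Normalized RDKit mol from SMILES (convenience for internal use)."""
    return parse_smiles(smiles).to_rdkit()


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FORMATS = ("smi", "sdf", "csv")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in _FORMATS:
            raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    raise ValueError(f"cannot infer molecule format from {path.name!r}")


def read_molecules(path: str | Path, format: str | None = None,
                   smiles_column: str = "smiles",
                   id_column: str = "id") -> list[Molecule]:
    """Read molecules from a ``.smi``, SDF (V2000) or CSV file.

    Malformed records are skipped with a logged warning and counted; if
    more than half of the records fail, the read aborts with
    :class:`ParseError`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list[tuple[str, str, int]] = []  # (smiles, id, line)

    if fmt == "smi":
        with path.open() as fh:
            for lineno, rawline in enumerate(fh, start=1):
                stripped = rawline.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                parts = stripped.split(None, 1)
                smi = parts[0]
                mol_id = parts[1].strip() if len(parts) > 1 else f"{path.stem}_{lineno}"
                records.append((smi, mol_id, lineno))
    elif fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            fields = [f.lower() for f in (reader.fieldnames or [])]
            if smiles_column.lower() not in fields:
                raise SchemaError(
                    f"CSV {path.name} lacks required column {smiles_column!r} "
                    f"(found {reader.fieldnames})")
            for lineno, row in enumerate(reader, start=2):
                row_l = {k.lower(): v for k, v in row.items()}
                smi = (row_l.get(smiles_column.lower()) or "").strip()
                mol_id = (row_l.get(id_column.lower()) or f"{path.stem}_{lineno}").strip()
                records.append((smi, mol_id, lineno))
    else:  # sdf
        return _read_sdf(path)

    mols: list[Molecule] = []
    n_failed = 0
    for smi, mol_id, lineno in records:
        try:
            mols.append(parse_smiles(smi, mol_id, line=lineno))
        except ParseError as exc:
            n_failed += 1
            logger.warning("skipping malformed record in %s: %s", path.name, exc)
    _check_failure_rate(path, n_failed, len(records))
    return mols


def _read_sdf(path: Path) -> list[Molecule]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    mols: list[Molecule] = []
    n_failed = 0
    n_total = 0
    for i, raw in enumerate(supplier):
        n_total += 1
        if raw is None:
            n_failed += 1
            logger.warning("skipping corrupt SDF record %d in %s", i + 1, path.name)
            continue
        mol_id = raw.GetProp("_Name") if raw.HasProp("_Name") and raw.GetProp("_Name") else f"{path.stem}_{i + 1}"
        provenance = {k: raw.GetProp(k) for k in raw.GetPropNames()}
        try:
            m = parse_smiles(Chem.MolToSmiles(raw), mol_id)
        except ParseError as exc:
            n_failed += 1
            logger.warning("skipping malformed record in %s: %s", path.name, exc)
            continue
        m.provenance.update(provenance)
        mols.append(m)
    _check_failure_rate(path, n_failed, n_total)
    return mols


def _check_failure_rate(path: Path, n_failed: int, n_total: int) -> None:
    if n_total and n_failed * 2 > n_total:
        raise ParseError(
            f"{n_failed}/{n_total} records in {path.name} failed to parse "
            "(>50 %); aborting", source=str(path))
    if n_failed:
        logger.warning("%s: %d of %d records skipped", path.name, n_failed, n_total)


def write_molecules(mols: Sequence[Molecule] | Iterable[Molecule],
                    path: str | Path, format: str | None = None) -> int:
    """Write molecules to ``.smi`` (``SMILES<TAB>id``) or SDF. Returns the
    number written.  SDF properties carry the molecule's provenance dict."""
    path = Path(path)
    fmt = _infer_format(path, format)
    mols = list(mols)
    if fmt == "smi":
        with path.open("w") as fh:
            for m in mols:
                fh.write(f"{m.smiles_canonical}\t{m.id}\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        for m in mols:
            rd = m.to_rdkit()
            rd.SetProp("_Name", m.id)
            rd.SetProp("smiles_canonical", m.smiles_canonical)
            for key, value in m.provenance.items():
                rd.SetProp(str(key), str(value))
            writer.write(rd)
        writer.close()
    else:
        raise ValueError("molecule output supports smi and sdf only")
    return len(mols)
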