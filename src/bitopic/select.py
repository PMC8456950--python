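"""Candidate triage and SAR analytics.

Docking is consumed, never computed: scores arrive as a CSV table from an
external docking engine (compound id, target, score; lower = better) and
this module only performs deterministic triage — design-constraint
substructure checks, top-N shortlisting and fold-change analytics over
assay tables.

The design constraints encode, as pure 2D substructure tests, the two
receptor interactions the campaign selects for: a basic aliphatic amine
(the cation that salt-bridges the orthosteric aspartate of the dopamine
receptor and the secondary-pocket glutamate of the adenosine receptor)
and a junction hydrogen-bond donor/acceptor pair (the amide or secondary
aryl-amine NH placed within hydrogen-bond distance of the adenosine
receptor's key asparagine).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem

from bitopic.chemio import Molecule, parse_smiles
from bitopic.libgen import LibraryProduct
from bitopic.properties import (
    CnsRuleSet,
    FilterResult,
    cns_filter,
    compute_profile,
    find_basic_centers,
)

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["compound_id", "target", "score"]
ASSAY_COLUMNS = ["compound_id", "target", "ki_um", "ki_sem_um", "kb_um",
                 "ec50_um", "emax_pct", "displacement_pct"]

# junction H-bond donor/acceptor pair: amide NH or secondary aryl amine NH
_JUNCTION_HBOND = (
    Chem.MolFromSmarts("[CX3](=O)[NX3;H1]"),
    Chem.MolFromSmarts("[c][NX3;H1;!$(N[#6,#16]=[O,S,N])][CX4]"),
)


@dataclass(frozen=True)
class ConstraintReport:
    """Design-constraint check for one candidate."""

    has_basic_amine: bool
    has_junction_hbond_pair: bool
    property_pass: FilterResult

    @property
    def overall(self) -> bool:
        return (self.has_basic_amine and self.has_junction_hbond_pair
                and self.property_pass.overall)

    def __bool__(self) -> bool:
        return self.overall


def _as_molecule(p: LibraryProduct | Molecule | str) -> Molecule:
    if isinstance(p, LibraryProduct):
        return p.molecule
    if isinstance(p, Molecule):
        return p
    return parse_smiles(p)


def check_design_constraints(p: LibraryProduct | Molecule | str,
                             rules: CnsRuleSet | None = None) -> ConstraintReport:
    """Substructure + property triage of one candidate."""
    mol = _as_molecule(p)
    rd = mol.to_rdkit()
    has_amine = bool(find_basic_centers(rd))
    has_junction = any(rd.HasSubstructMatch(patt) for patt in _JUNCTION_HBOND)
    profile = compute_profile(rd)
    return ConstraintReport(
        has_basic_amine=has_amine,
        has_junction_hbond_pair=has_junction,
        property_pass=cns_filter(profile, rules),
    )


def read_scores(path_or_df) -> pd.DataFrame:
    """Load and validate a docking-score table."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"score table lacks columns {missing}")
    df = df.copy()
    df["compound_id"] = df["compound_id"].astype(str)
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    if not df["score"].map(math.isfinite).all():
        raise ValueError("score table contains non-finite scores")
    if df.duplicated(["compound_id", "target"]).any():
        raise ValueError("duplicate (compound_id, target) rows in score table")
    return df


def rank_and_shortlist(products: list[LibraryProduct],
                       scores: pd.DataFrame,
                       top_n: int,
                       target: str = "A2AAR",
                       constraints: CnsRuleSet | None = None,
                       apply_constraints: bool = True
                       ) -> list[tuple[LibraryProduct, float, int]]:
    """Rank products by docking score and shortlist the top ``top_n``.

    Products are sorted ascending by score within ``target`` (ties broken
    lexicographically by compound id), truncated to ``top_n``, then run
    through the design-constraint filter.  Products without a score for
    the target are excluded with a logged count.  Returns
    ``(product, score, rank)`` triples in shortlist order; ranks refer to
    the pre-filter sort and start at 1.
    """
    scores = read_scores(scores)
    by_id = {p.molecule.id: p for p in products}
    target_scores = scores[scores["target"] == target]
    unknown = set(target_scores["compound_id"]) - set(by_id)
    if unknown:
        raise ValueError(f"{len(unknown)} scored ids do not resolve to products "
                         f"(e.g. {sorted(unknown)[:3]})")
    score_map = dict(zip(target_scores["compound_id"], target_scores["score"]))
    missing = [pid for pid in by_id if pid not in score_map]
    if missing:
        logger.warning("%d products lack a %s score and are excluded",
                       len(missing), target)
    ranked = sorted(((score_map[pid], pid) for pid in by_id if pid in score_map))
    shortlist: list[tuple[LibraryProduct, float, int]] = []
    for rank, (score, pid) in enumerate(ranked[:top_n], start=1):
        product = by_id[pid]
        if apply_constraints and not check_design_constraints(product, constraints):
            continue
        shortlist.append((product, score, rank))
    return shortlist


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fold_improvement(ki_fragment: float, ki_bitopic: float) -> float:
    """Affinity fold-change of the bitopic ligand over its fragment.

    Returns ``ki_fragment / ki_bitopic`` (>1 means the bitopic compound
    binds tighter).  Report rounded values with :func:`round_half_away`.
    """
    if ki_fragment <= 0 or ki_bitopic <= 0:
        raise ValueError("Ki values must be positive")
    return ki_fragment / ki_bitopic


def read_assays(path_or_df) -> pd.DataFrame:
    """Load and validate an assay table (Ki/Kb/EC50/Emax/displacement)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in ("compound_id", "target") if c not in df.columns]
    if missing:
        raise ValueError(f"assay table lacks columns {missing}")
    df = df.copy()
    df["compound_id"] = df["compound_id"].astype(str)
    for col in ASSAY_COLUMNS[2:]:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = float("nan")
    bad = df[(df["ki_um"] <= 0) | (df["kb_um"] <= 0) | (df["ec50_um"] <= 0)]
    if len(bad):
        raise ValueError(f"non-positive concentrations for {list(bad['compound_id'])}")
    return df


@dataclass
class SarSummary:
    """Per-compound SAR analytics relative to a reference compound."""

    reference_id: str
    dual_threshold_um: float
    table: pd.DataFrame = field(repr=False, default=None)


def sar_summary(assays, reference_id: str,
                targets: tuple[str, str] = ("A2AAR", "D2R"),
                dual_threshold_um: float = 1.0) -> SarSummary:
    """Summarize an assay table: per-target fold-change vs a reference
    compound, dual-target flags and selectivity ratios.

    A compound is dual-target when its Ki at *both* targets is below
    ``dual_threshold_um``.  Compounds missing one target's Ki are flagged
    incomplete, not dropped; displacement-only records (non-binders at
    10 uM) count as inactive.
    """
    df = read_assays(assays)
    reference_id = str(reference_id)
    ki = df.pivot_table(index="compound_id", columns="target", values="ki_um",
                        aggfunc="first")
    for t in targets:
        if t not in ki.columns:
            ki[t] = float("nan")
    ref_ki = {t: ki[t].get(reference_id, float("nan")) for t in targets}

    rows = []
    for cid in ki.index:
        k = {t: ki[t].get(cid, float("nan")) for t in targets}
        present = {t: pd.notna(k[t]) for t in targets}
        row = {"compound_id": cid}
        for t in targets:
            row[f"ki_{t}"] = k[t]
            row[f"fold_vs_{reference_id}_{t}"] = (
                ref_ki[t] / k[t]
                if present[t] and pd.notna(ref_ki[t]) else float("nan"))
        row["dual_target"] = bool(
            all(present.values())
            and all(k[t] < dual_threshold_um for t in targets))
        row["incomplete"] = not all(present.values())
        # selectivity: first-target Ki over second-target Ki
        row["selectivity"] = (k[targets[0]] / k[targets[1]]
                              if all(present.values()) else float("nan"))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("compound_id").sort_index()
    return SarSummary(reference_id=reference_id,
                      dual_threshold_um=dual_threshold_um, table=table)
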