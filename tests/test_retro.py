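"""Retrosynthetic disconnection, block harvesting and the forward round trip."""

import pytest
from rdkit import Chem

from bitopic import fixtures
from bitopic.chemio import parse_smiles
from bitopic.retro import (
    AMIDE_COUPLING,
    BUCHWALD_HARTWIG,
    apply_forward,
    classify_block,
    deconstruct,
    find_disconnections,
    harvest_blocks,
)


def brute_force_cut_bonds(smiles: str) -> list[tuple[str, int, int]]:
    """Independent disconnection oracle: inspect every bond directly
    (no SMARTS), applying the amide and aryl C-N rules by hand."""
    mol = Chem.MolFromSmiles(smiles)

    def is_amide_carbon(atom):
        return (atom.GetSymbol() == "C" and not atom.GetIsAromatic() and any(
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(atom).GetSymbol() == "O"
            for b in atom.GetBonds()))

    def n_has_carbonyl_neighbor(n):
        return any(is_amide_carbon(nb) or any(
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(nb).GetSymbol() in ("O", "S", "N")
            for b in nb.GetBonds())
            for nb in n.GetNeighbors() if nb.GetSymbol() in ("C", "S"))

    cuts = []
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        for x, y in ((a, b), (b, a)):
            if y.GetSymbol() != "N" or y.GetIsAromatic():
                continue
            if is_amide_carbon(x):
                cuts.append((AMIDE_COUPLING, x.GetIdx(), y.GetIdx()))
            elif (x.GetIsAromatic() and x.GetSymbol() == "C"
                  and not n_has_carbonyl_neighbor(y)
                  and sum(nb.GetIsAromatic() for nb in y.GetNeighbors()) == 1):
                cuts.append((BUCHWALD_HARTWIG, x.GetIdx(), y.GetIdx()))
    return cuts


class TestFindDisconnections:
    def test_n_phenylacetamide_single_amide_cut(self):
        discs = find_disconnections("CC(=O)Nc1ccccc1")
        assert [rule for rule, _ in discs] == [AMIDE_COUPLING]

    def test_lactam_ring_bond_never_cut(self):
        assert find_disconnections("O=C1CCCN1") == []

    def test_cyclic_amine_ring_bonds_never_cut(self):
        assert find_disconnections("C1CCNCC1") == []

    def test_bitopic_hit_has_one_amide_no_aryl_cut(self, compound2):
        discs = find_disconnections(compound2)
        rules = [rule for rule, _ in discs]
        assert rules == [AMIDE_COUPLING]

    def test_secondary_aryl_amine_cut(self):
        discs = find_disconnections("CN(C)CCNc1ccccn1")
        assert [r for r, _ in discs] == [BUCHWALD_HARTWIG]

    def test_diaryl_amine_not_cut(self):
        # N bonded to two aromatic carbons falls outside the amination rule
        assert find_disconnections("c1ccc(Nc2ccccn2)cc1") == []

    def test_matches_bond_inspection_oracle(self, mock_ligands):
        ligands, _ = mock_ligands
        for ligand in ligands:
            got = {(rule, frozenset(atoms))
                   for rule, atoms in find_disconnections(ligand)}
            expected = {(rule, frozenset((c, n)))
                        for rule, c, n in
                        brute_force_cut_bonds(ligand.smiles_canonical)}
            assert got == expected


class TestDeconstruct:
    def test_bitopic_hit_yields_named_block_and_acid_synthon(self, compound2):
        (disc,) = deconstruct(compound2)
        frags = {f.smiles_canonical for f in disc.fragments}
        assert frags == {
            parse_smiles("CN(CCCCC(=O)O)C1Cc2ccccc2C1").smiles_canonical,
            parse_smiles("Nc1nc2c(C)cccc2s1").smiles_canonical,
        }
        assert disc.fragment_classes == ("carboxylic_acid", "amine")

    def test_n_phenylacetamide_caps(self):
        (disc,) = deconstruct("CC(=O)Nc1ccccc1")
        assert {f.smiles_canonical for f in disc.fragments} == {"CC(=O)O",
                                                                "Nc1ccccc1"}

    def test_benzene_has_no_disconnections(self):
        assert deconstruct("c1ccccc1") == []

    def test_aryl_cut_emits_bromide_cap(self):
        (disc,) = deconstruct("CCNc1ccccn1")
        left, right = disc.fragments
        assert disc.rule == BUCHWALD_HARTWIG
        assert left.smiles_canonical == "Brc1ccccn1"
        assert right.smiles_canonical == "CCN"

    def test_fragment_heavy_atoms_sum_to_parent_plus_caps(self, mock_ligands):
        ligands, _ = mock_ligands
        for ligand in ligands:
            for disc in deconstruct(ligand):
                left, right = disc.fragments
                # each cut adds exactly one capping heavy atom (O or Br)
                assert left.n_heavy + right.n_heavy == ligand.n_heavy + 1


class TestRoundTrip:
    def test_forward_then_deconstruct_recovers_pair(self, mock_ligands):
        ligands, keys = mock_ligands
        for ligand, key in zip(ligands, keys):
            expected = {key.left_smiles, key.right_smiles}
            hits = [d for d in deconstruct(ligand)
                    if d.rule == key.rule
                    and {f.smiles_canonical for f in d.fragments} == expected]
            assert hits, f"{key.ligand_id}: generating pair not recovered"

    def test_recovered_fragments_regenerate_ligand(self, mock_ligands):
        ligands, keys = mock_ligands
        for ligand, key in zip(ligands, keys):
            rebuilt = apply_forward(key.rule, key.left_smiles, key.right_smiles)
            assert rebuilt.smiles_canonical == ligand.smiles_canonical


class TestHarvestBlocks:
    def test_construction_by_inverse_single_ligand(self):
        ligand = apply_forward(AMIDE_COUPLING, "OC(=O)Cc1ccccc1",
                               "NCCc1ccc(F)cc1", "lig")
        library = harvest_blocks([ligand], classes_wanted=("amine",))
        (block,) = list(library)
        assert block.molecule.smiles_canonical == parse_smiles(
            "NCCc1ccc(F)cc1").smiles_canonical
        assert block.reactive_class == "amine"
        assert block.parent_ids == ["lig"]

    def test_count_matches_bond_enumeration_oracle(self, mock_ligands):
        ligands, _ = mock_ligands
        library = harvest_blocks(ligands, size_window=(1, 100),
                                 classes_wanted=("amine", "aryl_halide",
                                                 "carboxylic_acid"))
        expected_keys = set()
        for ligand in ligands:
            for disc in deconstruct(ligand):
                assert len(brute_force_cut_bonds(ligand.smiles_canonical)) \
                    == len(deconstruct(ligand))
                for frag, cls in zip(disc.fragments, disc.fragment_classes):
                    got, _ = classify_block(frag, wanted=cls)
                    if got == cls:
                        expected_keys.add((frag.smiles_canonical, cls))
        assert {b.key for b in library} == expected_keys

    def test_size_window_excludes_large_fragments(self, compound2):
        # acid synthon has 19 heavy atoms; window (5, 12) keeps only the
        # 11-heavy-atom benzothiazole block
        library = harvest_blocks([compound2], size_window=(5, 12),
                                 classes_wanted=("amine", "carboxylic_acid"))
        assert [b.molecule.n_heavy for b in library] == [11]

    def test_harvest_is_deterministic_and_deduplicated(self, mock_ligands):
        ligands, _ = mock_ligands
        lib1 = harvest_blocks(ligands)
        lib2 = harvest_blocks(ligands + ligands)
        assert {b.key for b in lib1} == {b.key for b in lib2}

    def test_empty_ligand_list_rejected(self):
        with pytest.raises(ValueError):
            harvest_blocks([])

    def test_answer_key_blocks_recovered(self, mock_ligands):
        ligands, keys = mock_ligands
        library = harvest_blocks(ligands, size_window=(1, 100),
                                 classes_wanted=("amine", "aryl_halide",
                                                 "carboxylic_acid"))
        harvested = {b.molecule.smiles_canonical for b in library}
        for key in keys:
            assert key.left_smiles in harvested
            assert key.right_smiles in harvested
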