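import pytest

from bitopic import fixtures, libgen, retro


@pytest.fixture(scope="session")
def registry():
    return fixtures.paper_compounds()


@pytest.fixture(scope="session")
def small_catalog():
    """Seeded catalog with a mix of classes and some polyfunctional amines."""
    return fixtures.generate_catalog(fixtures.SyntheticCatalogSpec(
        n_amines=20, n_aryl_halides=10, n_acids=10, seed=7,
        polyfunctional_fraction=0.2))


@pytest.fixture(scope="session")
def clean_catalog():
    """Seeded catalog with no polyfunctional blocks."""
    return fixtures.generate_catalog(fixtures.SyntheticCatalogSpec(
        n_amines=15, n_aryl_halides=8, n_acids=8, seed=3))


@pytest.fixture(scope="session")
def mock_ligands(small_catalog):
    return fixtures.generate_mock_ligands(small_catalog, n=20, seed=11)


@pytest.fixture(scope="session")
def methyl_synthons():
    core = libgen.CoreScaffold("CH3")
    return [libgen.build_synthon(core, libgen.LINKERS["pentanamide"]),
            libgen.build_synthon(core, libgen.LINKERS["butylamine"])]


@pytest.fixture(scope="session")
def fixture_molecules(registry, small_catalog):
    """A diverse pool of valid molecules for property-based checks."""
    mols = [c.molecule for c in registry.determined()]
    mols += [b.molecule for b in small_catalog]
    return mols


@pytest.fixture(scope="session")
def compound2(registry):
    return registry["2"].molecule


@pytest.fixture(scope="session")
def benzothiazole_block():
    from bitopic.chemio import parse_smiles
    return parse_smiles(fixtures.BENZOTHIAZOLE_BLOCK_SMILES,
                        id="2-amino-4-methylbenzothiazole")
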