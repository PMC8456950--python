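# bitopic

A cheminformatics toolkit for structure-guided design of **dual-target
(bitopic) GPCR ligands** — compounds that engage both the orthosteric
binding pocket (OBP) of one receptor and a secondary binding pocket (SBP)
at the extracellular vestibule. The motivating application is
antiparkinson polypharmacology: a single compound that antagonizes the
A<sub>2A</sub> adenosine receptor and activates the D<sub>2</sub> dopamine
receptor.

The toolkit covers the desk-side stages of such a campaign:

1. **Retrosynthetic building-block harvesting** (`bitopic.retro`) — known
   single-target ligands are deconstructed at acyclic amide C(=O)–N bonds
   and acyclic aryl C–N amine bonds, the inverses of the two robust
   coupling reactions used for synthesis (amide coupling and
   Buchwald–Hartwig amination). Fragments are capped back to reagents
   (acid –OH restored; aryl bromide restored) and collected into a
   deduplicated, size-filtered block library.
2. **Reaction-based library enumeration** (`bitopic.libgen`) — an
   N-alkyl-2-aminoindane core (the cation that salt-bridges
   Asp114<sup>3.32</sup> in the D<sub>2</sub>R and Glu169<sup>EL2</sup> in
   the A<sub>2A</sub>AR vestibule) is fused to acid- or amine-terminated
   methylene linkers and coupled to building blocks; an R-group grid
   enumerator reproduces the benzothiazol-2-yl amide optimization series
   (R1 on the core nitrogen, R2/R3 at benzothiazole C4/C7).
3. **Physicochemical profiling and CNS filtering**
   (`bitopic.properties`) — average MW, Crippen clogP, Ertl TPSA (no S/P
   contributions), HBD/HBA, rotatable bonds, a rule-based clogD(7.4) and
   predicted charge at pH 7.4, filtered against the CNS permeability
   bounds MW < 500 Da, TPSA < 90 Å², HBD < 3, clogD 2–4.
4. **Triage and SAR analytics** (`bitopic.select`) — external docking
   scores (CSV) are ranked for top-N shortlisting; design constraints
   (basic amine, junction H-bond donor/acceptor pair near
   Asn253<sup>6.55</sup>) are pure substructure tests; assay tables
   (K<sub>i</sub>/K<sub>b</sub>/EC<sub>50</sub>/E<sub>max</sub>) feed
   fold-change and dual-target summaries. Docking itself is consumed,
   never computed.
5. **Fixtures** (`bitopic.fixtures`) — the published design series
   (structures where fully determined, assay values transcribed) plus
   seeded generators for synthetic block catalogs and mock ligands with
   round-trip answer keys.

## Worked example

```python
from bitopic import libgen, retro, fixtures, properties, select

# couple the N-methyl core + pentanamide synthon with the retro-derived
# 2-amino-4-methylbenzothiazole block
synthon = libgen.build_synthon(libgen.CoreScaffold("CH3"),
                               libgen.LINKERS["pentanamide"])
hit = retro.apply_forward(retro.AMIDE_COUPLING, synthon.molecule,
                          fixtures.BENZOTHIAZOLE_BLOCK_SMILES)
print(hit.smiles_canonical)   # Cc1cccc2sc(NC(=O)CCCCN(C)C3Cc4ccccc4C3)nc12
p = properties.compute_profile(hit)
print(f"MW {p.mw:.1f}  TPSA {p.tpsa:.1f}  HBD {p.hbd}  charge(7.4) {p.charge74}")
# MW 393.6  TPSA 45.2  HBD 1  charge(7.4) 1

# affinity gain of the bitopic hit over its orthosteric fragments
reg = fixtures.paper_compounds()
fold = select.fold_improvement(reg["12"].assays["A2AAR"]["ki_um"],
                               reg["2"].assays["A2AAR"]["ki_um"])
print(fold, select.round_half_away(fold))   # 6.75 7
```

The compound printed first is the campaign's first dual-target hit: a
393 Da ligand whose tertiary aliphatic amine is protonated at
physiological pH (the orthosteric cation) and whose amide NH provides the
junction hydrogen bond. The 6.75-fold ratio quantifies how much the
secondary-pocket extension improves binding over the bare benzothiazole
fragment.

The same stages are available from the shell:

```bash
bitopic fixtures make-ligands --n 20 --seed 5 --out-dir run/lig
bitopic retro --ligands run/lig/mock_ligands.smi --out-dir run/blocks
bitopic enumerate --blocks run/blocks/blocks.smi --out-dir run/lib
bitopic filter --molecules run/lib/library.smi --out run/props.csv
bitopic sar --assays <assays.csv> --reference 2 --out run/sar.csv
```

Every subcommand writes a JSON run manifest (seed, version, input hashes,
record counts).

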