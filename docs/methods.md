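# Methods

## Structural identity

All structures are normalized on entry and compared as canonical SMILES.
The normalization policy is fixed so that the retro ↔ forward round trip
is an exact set identity:

* **Salt stripping** keeps the largest covalent fragment by heavy-atom
  count; ties break lexicographically on the canonical string. Exactly
  one fragment remains.
* **Stereochemistry is discarded.** The design series has no
  stereocenters (the 2-aminoindane C2 is constitutionally symmetric), and
  keeping wedge information would create spurious duplicates during
  enumeration.
* **Tautomers are canonicalized** with RDKit's tautomer canonicalizer.
  The practically relevant effect is that 2-aminoazole /
  2-aminobenzothiazole systems map onto the exocyclic-amine aromatic
  form, so the amine form written by a retro cut and any imino form read
  from a file compare equal. Simple amides are left untouched.
* **Molecules are stored neutral.** Protonation is a property-layer
  computation (see clogD below), never a structural edit.

## Reaction model

Two coupling reactions define both the forward enumeration and the retro
disconnections:

| reaction | forward | junction created |
|---|---|---|
| amide coupling | acid + amine → amide + H₂O | acyclic C(=O)–N |
| Buchwald–Hartwig amination | aryl halide + aliphatic amine → aryl amine + HX | acyclic aryl C–N |

Retro rules return **every** acyclic amide C(=O)–N bond and every acyclic
aromatic-C–aliphatic-N bond where the nitrogen is a non-amide amine bonded
to exactly one aromatic carbon. Ring bonds (lactams, cyclic amines) are
never cut, so heavy-atom counts always satisfy
`left + right = parent + 1` (one capping heavy atom per cut: O or Br).
Design choices:

* **Single-cut policy.** Each building block arises from one
  disconnection of its parent; recursive multi-cut deconstruction is out
  of scope (the campaign's own retro example is single-cut).
* **Canonical bromide cap.** The reverse amination always emits the aryl
  *bromide*, keeping deduplication well defined; the forward amination
  accepts Cl, Br and I.
* **N-aryl amides belong to the amide rule only** (their nitrogen is
  excluded from the aryl C–N rule), so an acylated 2-aminobenzothiazole
  has exactly one disconnection.
* **Polyfunctional blocks** (two handles of the same class) are kept and
  flagged; enumeration reacts the first matched site in canonical atom
  order and flags the product ambiguous instead of expanding site
  isomers. This keeps enumeration counts equal to the pairing oracle.

## Property model

* **MW** uses average (not monoisotopic) atomic weights; printed values
  round to one decimal; the 393 Da hit is matched by integer floor.
* **clogP** is the Crippen atom-contribution estimate.
* **TPSA** is the Ertl topological scheme *without* S/P contributions
  (the classic table), fixing the meaning of the < 90 Å² CNS bound.
* **clogD(pH)** is rule-based, not a trained predictor:
  `clogd = clogp − Σ log₁₀(1 + 10^(pKa − pH))` over basic centers.
  Assigned pKa: primary aliphatic amine 10.2, secondary 10.0, tertiary
  9.5. Anilines and other aryl-conjugated amines, amide nitrogens and
  azine/azole ring nitrogens are non-basic. This encodes the single
  ionization distinction the design depends on — the core aliphatic
  amine is cationic at pH 7.4, everything else neutral — and guarantees
  clogd ≤ clogp. Published per-compound cLogD values computed with
  unnamed vendor software are method-dependent and are not reproduction
  targets; the 2–4 clogD window is therefore computed and reported as a
  flag but not asserted against published compound values.
* **Charge at pH 7.4** counts majority-protonated centers; fraction
  ionized per center is `1/(1 + 10^(pH − pKa))`.
* **CNS filter** bounds are strict for MW/TPSA/HBD maxima (a profile at
  exactly 500 Da fails) and inclusive for the clogD window; the overall
  flag is the conjunction.

## Triage and SAR conventions

* Docking scores are external input (lower = better). Shortlisting sorts
  ascending by score within the primary target, breaks ties
  lexicographically by compound id, truncates to top-N, then applies the
  design-constraint filter — a deterministic, testable replacement for
  the visual-inspection step of a real campaign.
* The design constraints are pure 2D substructure tests: ≥1 basic
  aliphatic amine, and ≥1 junction H-bond donor pair (amide NH or
  secondary aryl-amine NH).
* Fold improvement is `Ki(fragment)/Ki(bitopic)`; reported integers round
  half away from zero. Dual-target means Ki below the threshold
  (default 1.0 µM) at *both* targets; compounds missing one target's Ki
  are flagged incomplete, never dropped, and displacement-only records
  participate as "inactive at 10 µM".

## Reference compounds and synthetic data

The packaged registry reconstructs structures **only where the published
record fully determines them**: the N-methyl-2-aminoindane core, the
first hit and the 13 pentanamide-grid analogs (named building block +
named linker + Markush tuple), and the two N-methyl synthons. Fragments
whose capping was never drawn and shortened-linker analogs whose
butanamide/propanamide assignment is unpublished are data-only entries
flagged `underdetermined` — no structure is guessed. Assay values are
transcribed once into a packaged CSV whose SHA-256 digest is asserted in
the tests.

The synthetic catalog generator emulates a commercial building-block
collection with a fixed fragment grammar: substituted benzenes, pyridines
and benzothiazoles (the campaign's actual chemotype) carrying amine,
aryl-bromide or carboxylic-acid handles, 5–20 heavy atoms by default.
Mock ligands are built by forward coupling of sampled compatible pairs,
with the generating (left block, amine, rule) recorded as an answer key.
The generators are pure functions of their seed. What they do **not**
emulate: real vendor-catalog size and diversity, activity-annotated
ligand sets, reaction yields, or stereochemically rich chemotypes — so a
passing round-trip suite demonstrates correctness of the disconnection
and enumeration machinery, not recall against real databases. Library
scale-ups reported for real campaigns (tens of thousands of products)
and docking-rank distributions are likewise outside what synthetic
fixtures can certify. Mock-ligand sampling excludes polyfunctional
blocks and restricts amination partners to aliphatic amines so each
ligand carries exactly one junction and the answer key is unambiguous;
polyfunctional behaviour is exercised separately through the enumeration
oracle.

## Problem sizes and numerical choices

The test and acceptance workloads use 200 mock ligands for the
round-trip identity, a 200-block catalog (120 amines, 50 aryl bromides,
30 acids, 10 % polyfunctional) for the enumeration-vs-oracle equality,
and 1000 mock-scored products for the shortlist-vs-sort equality —
sizes at which the brute-force oracles are exact and fast while
exercising every rule branch. Tie-breaks are always lexicographic on
canonical SMILES or compound id, so every pipeline stage is
deterministic and order-independent; manifests hash all inputs to make
silent drift detectable.

## Known limitations

* The pKa table is a four-line rule set; unusual bases (amidines,
  guanidines) and acids (carboxylates are left neutral in logD) are out
  of scope by design.
* Retro rules cover the two campaign reactions only; other disconnection
  chemistries (sulfonamides, ureas, ethers) are not modelled.
* The R-group grid fixes the benzothiazole substitution pattern at C4/C7;
  other vectors require a custom scaffold template.
* No 3D: docking poses, conformers and binding-mode analysis are
  explicitly external to this toolkit.
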