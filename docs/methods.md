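# Methods

## Atom classification

The classifier assigns one of four classes to every heavy atom. The
core rule is purely topological: a carbon is *hydrophobic* exactly when
none of its covalent neighbours is nitrogen or oxygen. The charged
classes are fixed lists — the carboxylate oxygens of Asp/Glu
(*negative*) and the side-chain nitrogens of Lys/Arg (*positive*) —
reflecting the dominant protonation states at physiological pH. No pKa
calculation is performed; histidine, whose state is environment
dependent, is always treated as uncharged, and all amides, hydroxyls
and the backbone are *neutral*.

For the 20 standard residues the table is **generated**, not
hand-entered: each residue is represented as an idealized heavy-atom
bond graph (backbone `N-CA-C=O` plus canonical side-chain
connectivity) and the rule is applied to it. The backbone needs no
special-casing — `CA` is bonded to `N` and `C` to `O`, so both fall
out white from the carbon rule itself. The test-suite compares this
generated table atom-for-atom against an independently hand-derived
one frozen in the test source.

Decisions taken where the convention is genuinely open:

* **OXT / termini** — neutral by default; the zwitterionic state can be
  requested (`charged_termini`), which marks the C-terminal carboxylate
  oxygens negative and the N-terminal backbone nitrogen positive.
* **Sulfur/selenium** — never hydrophobic themselves (the rule colors
  only carbons), but they do not disqualify their carbon neighbours:
  Cys `CB`, Met `CG`/`CE` are hydrophobic because the rule excludes
  only N and O.
* **Non-standard residues** — polymer residues outside the table go
  through distance-based bond inference (bond iff separation ≤ sum of
  covalent radii + 0.45 Å, a common heuristic; tolerance configurable)
  and receive only the carbon rule — a non-standard residue can never
  acquire a charged class. Hetero compounds and waters are neutral by
  default: ligands sit outside an amino-acid-specific scheme. Both
  behaviours can be switched (`fallback` ∈ {bond-inference, neutral,
  skip}); provenance (table / bond-inference / policy-default) is
  recorded per atom.
* **Missing atoms** are classified as present; nothing is rebuilt.

## Structure preparation

Reading goes through gemmi (PDB and mmCIF, transparent `.gz`). The
model is reduced to the first coordinate model; alternate locations
resolve to the blank-altloc atom if present, otherwise the
highest-occupancy variant with ties broken by file order. Elements
missing from the file are inferred from PDB v3 atom names
(digit-prefixed names are hydrogens). Hydrogen removal is a separate,
idempotent step so that the raw parse remains inspectable. Insertion
codes are carried everywhere; residues are identified by
(chain, seq_id, icode) in every report. PDB output refuses chain ids
longer than the one-column field instead of truncating.

## Solvent-accessible surface area

Shrake–Rupley with a golden-angle spiral point set (default 960 points
per atom), probe 1.4 Å, and a named van der Waals radius table
(C 1.70, N 1.55, O 1.52, S 1.80 Å, …). The spiral is a fixed
deterministic construction — no RNG — so areas are bit-stable across
runs and platforms; doubling the point count changes fixture totals by
< 0.2 %. Per-class areas are obtained by summing per-atom areas under
the class map, so the partition over classes is exact by construction.
Atoms with no tabulated radius raise rather than defaulting silently;
an override table can be passed.

## Interface analysis

* **Salt bridges**: an inter-group pair of a Lys/Arg charged nitrogen
  and an Asp/Glu carboxylate oxygen within 4.0 Å (configurable). The
  value is a widely used literature convention for charged-pair
  identification; no claim of optimality is made and reports always
  carry the cutoff used. Pairs are counted at residue level: the
  minimal-distance atom pair per (cation residue, anion residue) is
  reported, so the symmetric NH1/NH2 and OD1/OD2 positions cannot
  double-count. Histidine never participates. Detection uses a k-d
  tree; the suite checks it against an all-pairs scan and for
  monotonicity in the cutoff.
* **Interface atoms / buried area**: the ΔSASA criterion — an atom is
  interfacial if its area in the isolated chain group exceeds its area
  in the complex — with the summed positive deltas as the buried area
  per side. A faster distance criterion (any opposite-group atom
  within 5.0 Å) selects atoms only; buried areas always come from
  ΔSASA so the per-class partition invariant holds for either method.
  Zero-contact interfaces report fractions as an explicit
  `"undefined"` marker instead of NaN.

## Synthetic fixtures

All tests run offline on generated structures:

* **Residue templates** — internal-coordinate (Z-matrix-style) recipes
  realized by natural-extension (NeRF) placement, with canonical bond
  lengths and angles; rings are closed to within the bond-inference
  tolerance. Realizing any template and re-inferring bonds from the
  coordinates reproduces the reference bond list exactly — that closure
  is itself a test.
* **Extended peptides** — trans peptide bonds (C–N 1.33 Å), φ/ψ ≈ 180°.
  Proline is the one exception: its ring excludes an extended φ, so
  proline residues use the canonical φ ≈ −65°. The all-residue 20-mer
  has no non-bonded contact under 2.0 Å.
* **Planted dimers** — chain B is rigid-body docked onto chain A by
  least squares over the requested atom-pair distances (with a soft
  repulsion keeping non-contact atoms apart), from 24 seeded starting
  orientations; among the poses satisfying every planted distance to
  within 0.05 Å the one with the largest minimum gap between
  non-contact atoms is kept, so only the planted contact touches.
  Unsatisfiable requests raise. The seed makes construction
  deterministic.

These fixtures exercise atom typing and distance geometry, not
conformational realism: no rotamer sampling, no energy minimization, no
crystallographic disorder, B-factors or solvent. Passing tests
therefore demonstrate the correctness of the classification rule,
the geometry kernels and the reporting machinery — not agreement with
experimental structures, which is checked separately against published
complexes when their coordinates are available locally (see
`tests/test_acceptance.py`).

## Rendering

Scripts define each palette color once (`set_color` / `color name`)
and then emit one color command per (residue, class) atom group in
(chain, residue, class) order, so output is byte-stable and every atom
is covered exactly once; the parsers in the same module invert the
mapping, and the suite asserts the round trip is exact. The published
origin of the scheme never printed its RGB constants, so the defaults
are pure primaries — yellow (1,1,0), red (1,0,0), blue (0,0,1),
white (1,1,1), mask gray50 — declared openly rather than guessed. The
CPK comparison palette follows the green-carbon convention
(C green, O red, N blue, P orange, S yellow, others gray). The
class-encoded PDB writes integer codes into the B-factor column
(neutral 0, hydrophobic 1, negative 2, positive 3, unclassified 9).

## Problem sizes and numerical choices

The suite and the acceptance script run on the 168-atom all-residue
peptide and planted dimers of ≤ 46 atoms, with 960-point SASA spheres
(240–480 where only relative comparisons matter) — sizes chosen so
every check is exact or tightly bounded while the whole pipeline stays
interactive. Bond-inference tolerance 0.45 Å, planted-distance
tolerance 0.05 Å, SASA probe 1.4 Å and the 4.0 Å salt-bridge cutoff are
the package-wide defaults discussed above.

## Known limitations

* Protonation is conventional, not computed; unusual active-site
  states (charged His, deprotonated Cys) are not represented.
* The classification of ligands as neutral is a display policy, not
  chemistry; a bond-graph treatment of hetero compounds would need
  element-complete connectivity templates.
* Shrake–Rupley areas depend slightly on molecular orientation
  (fixed point set); differences vanish as the point count grows.
* The planted-dimer builder poses rigid extended chains; it cannot
  satisfy contact sets that require backbone flexibility.
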