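# yrb — atom-level hydrophobicity/charge highlighting for protein structures

Protein–protein interfaces gain specificity from the matching of
hydrophobic patches and charged groups on the two sides of the contact.
Residue-level hydrophobicity scales blur this: the side chain of an
arginine contains both an aliphatic stem that can pack hydrophobically
and a charged guanidinium head, and a threonine's γ-methyl is apolar
while its β-carbon carries a hydroxyl. This package types **every heavy
atom** of a structure by its local chemistry and turns that typing into
viewer scripts and quantitative interface reports.

## The classification rule

Each heavy atom gets exactly one of four classes:

| class | color | rule |
|---|---|---|
| hydrophobic | yellow | carbon with **no covalently bonded N or O** |
| negative | red | Asp `OD1/OD2`, Glu `OE1/OE2` (carboxylate O, charged at physiological pH) |
| positive | blue | Lys `NZ`, Arg `NE/NH1/NH2` (amine/guanidinium N) |
| neutral | white | everything else, including the polar backbone `N, CA, C, O` |

Histidine is treated as uncharged. For the 20 standard residues the
classes come from a lookup table generated by applying the carbon rule
to idealized residue bond graphs; non-standard residues fall back to
distance-based bond inference (carbon rule only — never a charged
class), and hetero compounds/waters default to neutral.

On top of the classification the package provides:

* **structure I/O** — PDB/mmCIF reading (via gemmi) into a single-model,
  altloc-resolved, hydrogen-free model; PDB writing with optional
  B-factor overrides.
* **rendering** — PyMOL (`.pml`) and ChimeraX (`.cxc`) command scripts,
  a class-encoded PDB (class codes in the B-factor column), selection
  masks that gray out everything outside a region of interest, and an
  element-based CPK comparison palette (green carbons).
* **interface analysis** — Shrake–Rupley solvent-accessible surface
  area with a deterministic golden-spiral point set; inter-chain-group
  salt-bridge detection (charged N–O pairs within 4.0 Å, deduplicated
  per residue pair); buried-area computation (ΔSASA) partitioned over
  the four classes.
* **fixtures** — synthetic structures with known ground truth:
  idealized residues, extended peptides, and two-chain complexes with
  planted atom-pair distances.

## Worked example

Generate the synthetic fixtures and classify the 20-residue peptide
that contains each standard amino acid once:

```sh
$ yrb fixtures --outdir fx --seed 0
$ yrb classify fx/all_residues.pdb --out classes.json
hydrophobic: 51 atoms
negative: 4 atoms
positive: 4 atoms
neutral: 109 atoms
unclassified: 0 atoms
```

Of the peptide's 168 heavy atoms, 51 are carbons with no polar
substitution (e.g. all seven ring/side-chain carbons of Phe, but only
the γ-methyl of Thr), the 4 red atoms are the Asp/Glu carboxylate
oxygens, and the 4 blue atoms are Lys NZ plus the three Arg guanidinium
nitrogens; the polar backbone accounts for most of the 109 white atoms.

Analyse the planted Lys–Asp dimer interface:

```sh
$ yrb interface fx/salt_bridge_3.5.pdb --groups A:B
{
  ...
  "buried_area_a": 47.428,
  "buried_area_b": 38.922,
  "salt_bridges": [
    {"cation": "LYS A2 NZ", "anion": "ASP B2 OD1",
     "label": "K2(A)-D2(B)", "distance": 3.5}
  ]
}
```

The detector recovers exactly the planted charged pair at its planted
3.5 Å N–O distance, and the ΔSASA report shows each side burying
~40–47 Å² — on the Lys side 79 % of it positively charged surface.

A PyMOL script reproducing the coloring:

```sh
$ yrb render fx/all_residues.pdb --out color.pml
$ head -3 color.pml
# scheme=yrb object=all
set_color yrb_hydrophobic, [1.000, 1.000, 0.000]
set_color yrb_mask, [0.500, 0.500, 0.500]
```

`--mask "chain A and 10-50"` keeps only those residues in scheme colors
and grays the rest (gray50), the standard way to display just an
interaction interface. `--scheme cpk` switches to the element-based
comparison palette.

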