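# imotif

Analysis toolkit for pH-switchable DNA i-motifs — the four-stranded,
intercalated structures held together by hemiprotonated C:C⁺ base pairs.
The package targets the peculiar case of an oligonucleotide
(d(CCGTTCCGT)–T₄–d(CCGTTCCGT), "NN4") that folds into **two different**
i-motif structures depending on pH: a compact neutral-pH form with two
C:C⁺ pairs capped by two minor-groove G:C:G:C tetrads, and a more elongated
acidic form with four C:C⁺ pairs capped by two G:T:G:T tetrads.  Intended
users are structural-bioinformatics and molecular-modelling researchers who
want testable, self-contained implementations of the three computations
behind that story:

1. **Multisite protonation titration.**  Each titratable cytosine N3 site
   contributes to the microstate free energy

       G_X = Σᵢ xᵢ·ln10·kT·(pH − pK_int,i) + Σ_{i<j} g_ij·xᵢxⱼ ,

   with intrinsic pKa values pK_int (aqueous reference 4.4 corrected for
   desolvation and interaction with non-titratable charges) and pairwise
   couplings g_ij from a pluggable continuum-electrostatics model.  Mean
   protonations ⟨xᵢ⟩(pH) are exact Boltzmann averages over all 2^N
   microstates; macroscopic pKa values are the half-integer crossings of
   the total curve.  A residue-knockout scan decomposes the pKa into
   per-residue contributions.

2. **Geometry annotation.**  Hydrogen bonds, C:C⁺ / Watson–Crick /
   wobble-pair classification, slipped minor-groove tetrads, 3′E/5′E
   intercalation topology, sugar pseudorotation and glycosidic classes,
   principal-axis dimensions and ensemble RMSD.

3. **Ratchet-and-pawl transition surrogate.**  A coarse-grained
   double-basin model of the acidic→neutral switch, biased along the eRMSD
   reaction coordinate (one-sided harmonic pawl, 200 kcal/mol per squared
   eRMSD unit, exact analytic gradient).  Deprotonating the switching
   cytosines C1/C6/C14/C19 enables the transition; keeping them protonated
   blocks it.

A synthetic-structure builder generates idealized fragments (C:C⁺ stacks
with or without capping tetrads, known ground truth) so that everything is
testable offline with no downloads.

## Worked example

```python
from imotif import assign_charges, BuildSpec, build_imotif, TitrationModel

frag = build_imotif(BuildSpec(n_cc_pairs=2, capping="GCGC"))   # neutral-like
res = TitrationModel.from_structure(assign_charges(frag)).solve()
print(res.summary())
```

prints

```
Multisite titration (exact enumeration)
  sites: 4   T = 298.15 K
  site    pK_int
  C2        5.337
  C7        5.364
  C15       5.247
  C20       5.224
  max |g_ij| = 1.289 kcal/mol
  macroscopic pKa (level: pH):
     3.5:   2.289
     2.5:   3.539
     1.5:   4.711
     0.5:   5.966
```

The four sites are the cytosines of the two persistent C:C⁺ pairs; their
intrinsic pKa values sit ~1 unit above the aqueous reference 4.4 because
the surrounding structure stabilizes the bound proton, and the
anticooperative couplings g_ij spread the four macroscopic crossings apart.
Rebuilding the same stack **without** the capping tetrads
(`capping="none"`) drops the level-1.5 ("second protonation") pKa from
4.711 to 4.304: the minor-groove tetrads stabilize the adjacent positively
charged pairs, the electrostatic origin of the high pH stability of these
structures.  (The default uniform-screened dielectric makes this ordering
qualitative; the `two-dielectric` variant reproduces the multi-unit shifts
expected from Poisson–Boltzmann setups.)

The same comparison, plus knockout tables, geometry reports and the
transition simulation, is scriptable from the shell:

```
imotif synth --n-cc-pairs 4 --capping GTGT -o acidic.pdb
imotif geometry-report --structure acidic.pdb
imotif titrate --config run.cfg --print-pka
imotif transition-sim --scenario neutral --scenario acidic --seeds 20
```

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch with the given seed —
the bare-vs-capped titration comparison, the knockout decomposition, the
geometry annotation of both fragment types, and a seeded batch of biased
trajectories for the deprotonated and protonated scenarios — logging a
summary to stderr and writing the results file to `--out`.

## Layout

```
src/imotif/
  structure.py       PDB I/O, atoms/residues/ensembles, partial charges
  synth.py           idealized i-motif fragment builder
  electrostatics.py  EnergyModel, intrinsic pKa, coupling matrix
  titration.py       microstate enumeration, TitrationModel/Results, knockout
  geometry.py        H-bonds, pairs/tetrads, pucker, dimensions, RMSD
  ermsd.py           eRMSD metric
  dynamics.py        coarse-grained ratchet-and-pawl simulation
  reference.py       deposited-ensemble (8BV6/8BQY) analysis
  pipeline.py, cli.py
docs/methods.md      model assumptions, parameters, limitations
```
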