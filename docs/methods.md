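# Methods

`imotif` models the pH-driven switch of a DNA i-motif that folds into two
different minor-groove-tetrad (MGT)-capped structures: a neutral-pH form with
two hemiprotonated C:C+ base pairs capped by two G:C:G:C tetrads, and an
acidic form with four C:C+ pairs capped by two G:T:G:T tetrads.  The package
has three scientific cores — a multisite protonation model, a geometric
annotation layer, and a coarse-grained biased-dynamics surrogate of the
conformational transition — plus a synthetic-structure generator that makes
all of them testable without any external coordinates.

## Multisite titration

A system of N titratable cytosine N3 sites is described by a protonation
microstate vector X ∈ {0,1}^N with Gibbs free energy

    G_X = Σ_i x_i · ln10·kT · (pH − pK_int,i) + Σ_{i<j} g_ij · x_i · x_j .

Mean protonations ⟨x_i⟩(pH) are Boltzmann averages computed by exact
enumeration of all 2^N microstates (refused above N = 20; N ≤ 8 in all
shipped calculations).  The total curve Σ_i⟨x_i⟩ is strictly decreasing in
pH; macroscopic pKa values are defined as the pH at which it crosses the
half-integer levels n − 0.5, located by monotone bracketing on the grid and
bisection on the exact evaluator to better than 10⁻³ pH.  The "second
protonation" pKa is the crossing at level 1.5.  If the curve is flat at a
crossing level within 10⁻⁹ the midpoint of the flat bracket is reported.

Correctness is checked against three independent oracles: the
Henderson–Hasselbalch closed form for uncoupled systems (agreement to
10⁻¹⁰), a Metropolis Monte-Carlo sampler over microstates (3-standard-error
agreement at 10⁵ sweeps), and two-site closed-form crossing values
(4.4 ± log₁₀3 for two identical uncoupled sites with the aqueous cytosine
reference pKa of 4.4).

### Electrostatic inputs

The intrinsic pKa of site i is the aqueous cytosine reference (4.4) shifted
by the interaction of the proton charge-difference distribution Δq (the
per-atom difference between the protonated and neutral cytosine charge
entries, summing to +1 e) with all non-titratable charges, plus a
desolvation term:

    pK_int,i = 4.4 − (ΔΔG_background + ΔΔG_desolv) / (ln10·kT) .

Other titratable sites contribute to the background in their neutral form.
The coupling g_ij is the double difference of the four protonation
combinations of a site pair, E(C_iH⁺:C_jH⁺) − E(C_iH⁺:C_j) − E(C_i:C_jH⁺) +
E(C_i:C_j), which for a linear Coulomb model reduces to the Δq_i·Δq_j
interaction; the four-term form is implemented literally and the reduction
is exercised in the tests.

Two continuum variants are provided.  The default **uniform-screened**
variant screens every pair interaction with the solvent dielectric (80) and
has zero desolvation; it gets signs and orderings right but underestimates
magnitudes inside the folded core.  The **two-dielectric** variant screens
with the interior dielectric (6) and adds a Born-style burial penalty
(charging energy of Δq in a sphere of radius 2 Å, scaled by a crude
neighbour-count burial fraction).  Neither is a grid Poisson–Boltzmann
solver; the `EnergyModel` contract deliberately keeps a full solver
pluggable.  Temperature defaults to 298.15 K (kT = 0.5925 kcal/mol).

The charge table shipped in `data/charges.txt` is a simplified
AMBER-parm94-style set with separate neutral-C and N3-protonated-C+
entries.  Per-residue totals are made exact (−1 e per nucleotide with
phosphate, 0 for C+; C+ minus C base difference exactly +1 e) by absorbing
the rounding residual into C1'.  It is the package's own fixture set, not a
reproduction of any specific published library, and can be overridden from
a file of the same format.  Structures without an explicit N3 proton use a
united-proton fallback that folds the H3 charge onto N3.

By default the titratable sites are the four cytosines of the two
persistent C:C+ pairs (C2/C7/C15/C20 in the NN4 numbering of
d(CCGTTCCGTTTTTCCGTTCCGT)); tetrad cytosines are fixed neutral background.
The mobile axial-loop thymines T10–T13 are dropped before any energy
evaluation (configurable).  The residue-knockout scan silences one
non-titratable residue at a time (removal, all charges zeroed, or base
charges only) and reports the change of every macroscopic pKa; in the
uniform-screened variant removal and charge-zeroing are exactly equivalent,
which the tests assert.

## Geometry annotation

Hydrogen bonds use heavy donor–acceptor distance ≤ 3.5 Å and, when the
donor hydrogen is present, a D–H…A angle ≥ 120° (both configurable; the
angular filter is what keeps stacked, non-paired bases from generating
spurious bonds).  Base pairs are classified by bond-pattern templates:
C:C+ requires the shared N3…N3 contact plus N4–H…O2 in both directions;
Watson–Crick G:C requires N1…N3 plus at least one of O6…N4 / N2…O2; wobble
G:T requires both N1–H…O2 and N3–H…O6.  A minor-groove tetrad is two such
pairs linked by inter-guanine N2–H…N3 bonds, flagged *slipped* when both
reciprocal bonds are present.

Intercalation topology orders the C:C+ pairs along the principal axis of
their centroids and reports 3′E (5′E) when the outermost pairs engage the
3′-side (5′-side) cytosines of their sequence C-tracts.  When the tract
neighbours are absent from the structure (e.g. a bare stack fragment) the
annotation is honestly `none` — the fragment does not contain the
information.

Sugar pucker uses the standard pseudorotation relations
(P from atan2 of the torsion combinations, amplitude = ν2/cos P), inverted
exactly against the generating cosine series in the tests; south is the
experimentally constrained interval [144°, 180°].  Glycosidic classes use
fixed windows (anti (−120°,−60°], high-anti (−60°,0°], syn (0°,90°]).
Global dimensions are heavy-atom extents along the principal axes of the
coordinate covariance, sorted L1 ≥ L2 ≥ L3.  Ensemble RMSD is the mean
pairwise heavy-atom RMSD after least-squares superposition; the default
loop exclusion for the deposited ensembles is the disordered thymines
T4/T9/T10–T13/T17/T22 (the tetrad thymines T5/T18 are kept) — the exact
exclusion used for the published sub-1-Å figure is in supplementary
material we do not reproduce, so this default is documented rather than
asserted as identical.

## Synthetic structures

The builder produces idealized planar nucleobases (regular hexagon rings,
fused regular pentagon for purines, standard exocyclic bond lengths) and
assembles them into: C:C+ pairs (exact in-plane C2 rotation about the
N3…N3 midpoint → three H-bonds by construction), Watson–Crick and wobble
pairs (least-squares placement onto H-bond targets running parallel to the
pair axis), slipped tetrads (C2 rotation about a point outside the guanine
minor-groove edge → both reciprocal N2–H…N3 bonds at 2.9 Å), and
intercalated stacks (default rise 3.1 Å, twist 30° per step, alternating
duplex azimuth) with NN4 residue numbering.  Capping tetrads sit flat
against the outer pairs, one rise above/below.  Gaussian coordinate jitter
(`noise_sigma`, seeded) is applied last.

These fragments are geometric idealizations: no backbone beyond C1′, no
sugars, no refined stacking geometry, no sequence-dependent fine structure.
A green test on them establishes that the algorithms recover designed
ground truth and orderings — not that the package reproduces refined NMR
coordinates.  The acidic-like fragment is nonetheless ≈5 Å more elongated
than the neutral-like one, mirroring the real pair of structures.

## eRMSD

Each base gets a frame from the centroid and plane of C2/C4/C6 (present in
both purines and pyrimidines); the relative origin of every other base is
scaled anisotropically (5 Å in plane, 3 Å along the normal) and mapped to a
4-component G-vector that vanishes continuously at scaled distance 2.4;
beyond the cutoff the G-vector is zero in both structures, so absent
contacts never add distance.  We normalise by the number of bases,
eRMSD = √(Σ_{j≠k}|ΔG|²/N), the convention of the metric's literature, which
puts folded-vs-switched distances on the familiar O(1) scale (the two
fragment endpoints are 3.0 apart; σ = 0.5 Å jitter gives ≈1.1).  The
vectorized implementation is held to 10⁻⁸ agreement with an independent
plain-loop reimplementation and to premetric properties on random pairs.
Thymines are excluded by default except the tetrad thymines T5/T10/T13/T18
of the acidic structure.

## Transition surrogate

The all-atom, explicit-solvent rMD protocol is replaced by a deliberately
desk-scale surrogate; only orderings and gating are asserted, never rates
or the published 45/50 trajectory count.

*Model.*  Four beads per residue (C2, C4, C6, C1′) on the residues shared
by the two endpoint fragments (the 8 stack cytosines, 4 tetrad guanines and
4 tetrad cytosines; thymines drop out).  Every inter-residue bead pair
within 8 Å of either endpoint carries a smoothed two-well energy
softmin_T₀(½k(d−d_S)², ½k(d−d_T)² − δ) with k = 0.1 kcal/mol/Ų,
δ = 0.75 kcal/mol (the target/neutral basin is globally more stable, as the
free-energy landscape of the real system indicates) and softmin temperature
T₀ = 1.5 kcal/mol; intra-residue bead pairs are stiff single wells
(10 kcal/mol/Ų).  Protonation enters in two physically motivated ways:
(i) pairing restraints (20 kcal/mol/Ų on ring-centroid distances) exist
only for pairs protonated under the scenario — all four in the acidic
scenario, only C2:C20 and C7:C15 in the neutral one; (ii) contact gating —
in the neutral scenario the deprotonated pairs C1:C19 and C6:C14 lose the
start-state well of their pair-internal contacts (no shared proton, no
hemiprotonated H-bonds), while in the acidic scenario every contact of the
switching cytosines is pinned to the start geometry (a protonated stack
cannot disassemble).

*Dynamics.*  Overdamped Langevin steps x ← x − h∇E + √(2kT·h)·η with
mobility·Δt h = 0.02 Ų·mol/kcal at 298.15 K, 24 000 steps per trajectory
by default, batched over seeds and bit-reproducible per seed.  The reaction
coordinate ξ = eRMSD(current, target) is evaluated exactly every step; when
ξ > ξ_best the one-sided pawl adds the force −k_bias·(ξ−ξ_best)·∇ξ with
k_bias = 200 kcal/mol per squared eRMSD unit and the exact analytic eRMSD
gradient (differentiated through both the base origins and the base
frames; verified against finite differences to 10⁻¹⁰).  The pawl never
injects energy on descent.  Success is min ξ < 0.7 (the published figure
shows the threshold only as a dashed line; 0.7 sits between the target-
basin thermal floor ≈0.6 and the deepest intermediate ≈1.7, and is
configurable).

*What the surrogate establishes.*  With deprotonated C1/C6/C14/C19 a
majority of seeded trajectories reach the neutral target; with all
cytosines protonated none do (minimum ξ stays near the starting value);
without the ratchet none do.  Network stiffness, basin offset and step
counts were chosen so the transition is expressible within minutes of CPU —
they are surrogate design constants, not physical claims.  Observables for
the transition pathway are the distance between the two tetrad guanine
planes and the number of switching cytosines whose ring centroid lies
within 4 Å of the persistent-pair stack axis (4 at the start, 0 at the
target), aggregated into a 2-D occupancy histogram.

## Deposited-structure analysis

`imotif.reference` analyses the deposited NMR ensembles (PDB 8BV6 neutral,
8BQY acidic) when the files have been downloaded manually into
`data/reference/` — they are never fetched automatically and are not
bundled.  The analysis recomputes the macroscopic pKas of the neutral
structure with the two-dielectric variant, the elongation difference of the
mean structures, and both ensemble RMSDs with the documented loop
exclusion.  In an offline checkout the corresponding acceptance test fails
with the download instructions; that failure is expected and honest.

## Known limitations

* The continuum electrostatics is not a PB solver; uniform-screened
  magnitudes are qualitative, and the two-dielectric burial fraction is a
  neighbour-count heuristic.
* Synthetic fragments have no backbone/sugar degrees of freedom, so pucker
  and glycosidic annotations only engage on real coordinates.
* Hydrogen-free structures fall back to distance-only H-bond detection,
  which can over-detect stacked contacts.
* The transition surrogate's timescales, energetics and success counts are
  not comparable to the all-atom rMD results; only the protonation gating
  direction is meaningful.
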