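# Methods

## Titration model

Each ionizable group is treated as independent, with a fractional charge
from the Henderson–Hasselbalch relation: bases (N-terminal amine, Lys, Arg,
His side chains) contribute +1/(1+10^(pH−pKa)), acids (C-terminal carboxyl,
Asp, Glu, Cys, Tyr) −1/(1+10^(pKa−pH)).  Site–site coupling and
conformation-dependent pKa shifts are ignored; for a 7-residue peptide with
three well-separated pKa values this is the standard desk approximation.

The default pKa table is the Bjellqvist set of the ExPAsy Compute pI/Mw
tool: residue-specific N-terminal values (Ala 7.59, generic 7.50, …),
C-terminal carboxyl 3.55 (4.55/4.75 when the final residue is Asp/Glu),
side chains Asp 4.05, Glu 4.45, His 5.98, Cys 9.00, Tyr 10.00, Lys 10.00,
Arg 12.00.  Users can override any entry (`PKaSet`, or the CLI's
`--pka-set` file).  With this table, uncapped AAAAAAK gives rounded net
charges +2/+1/0/−1 at pH 2/7/8/11 and pI 8.8 — consistent with the
precipitation-onset behaviour expected of such a zwitterion between pH 8
and 9.

Both Henderson–Hasselbalch forms are strictly decreasing in pH, hence so is
the net charge; the isoelectric point is therefore a unique root on [0, 14]
and is found by bisection (default stop |Z| < 1e−4, report rounded to one
decimal).  If the charge does not change sign (e.g. no acid sites) a
"no isoelectric point" error is raised rather than a boundary value.

Verbal site labels are assigned from |q|: ≥ 0.9 *charged*, [0.7, 0.9)
*mostly_charged*, (0.3, 0.7) *mixed*, (0.1, 0.3] *mostly_neutral*, ≤ 0.1
*neutral*.  The 0.1/0.3/0.7/0.9 cuts are a documented convention chosen so
that everyday phrases ("substantially uncharged", "almost uncharged") map
onto defined numeric bands; they are configurable and nothing downstream
depends on them.  Integer net charges round half away from zero.

Molecular masses sum standard average (or monoisotopic) residue masses plus
one water when at least one terminus is free (572.66 → 573 g/mol for
uncapped AAAAAAK).  Capping-group masses themselves are not modelled.

## Chain construction

Backbones are built by sequential internal-to-Cartesian (NeRF) placement
with idealized geometry: bonds N–CA 1.458, CA–C 1.525, C–N 1.329,
C=O 1.231, N–H 1.01 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°,
CA–C–O 120.8°; ω trans (180°) throughout — cis peptide bonds are out of
scope.  The construction is exactly invertible: measuring φ/ψ/ω on a built
chain reproduces the inputs to better than 1e−6° (tested with a circular
angle metric, since ±180° name the same torsion).

Side chains are minimal by design: a Cβ on every non-Gly residue (NeRF
torsion N–C′–CA–CB = +122.6°, which yields L-chirality — the improper
torsion N–CA–C–CB comes out negative, matching an MMFF-optimized
L-alanine reference), and for Lys a single pseudo-atom NZ placed on the
Cα→Cβ direction at 4.9 Å from Cα, the average Cα–Nζ extent of an extended
Lys side chain.  This is sufficient to carry the side-chain charge and to
mark the hydrophilic end for radial analysis; it deliberately does not
model rotamers, so side-chain packing is not meaningful in these
ensembles.  The amide H is placed in the C′(prev)–N–CA plane bisecting the
two bonds; the N-terminal ammonium hydrogens are not modelled, so residue 1
is never a hydrogen-bond donor.  A free C-terminus gets a second
carboxylate oxygen (OXT) at a fixed torsion, making the terminal charge
position deterministic.

Motif templates: α-helix (−57, −47), extended β (−139, 135), polyproline II
(−75, 145), β-turn I (i+1: −60, −30; i+2: −90, 0), β-turn II (i+1: −60,
120; i+2: 80, 0), with extended flanks around planted turn windows.  The
random-coil sampler draws per-residue Ramachandran basins
(β: φ∈[−180,−60], ψ∈[60,180]; α_R: φ∈[−90,−40], ψ∈[−60,−10]; α_L:
φ∈[40,90], ψ∈[10,60]) with default weights 0.5/0.4/0.1 — a generic
disordered-ensemble composition, configurable — then uniform angles within
the basin.

## Multi-chain systems

The generator emulates what a short solution simulation of many copies of a
7-residue amphiphile provides: per-frame all-backbone coordinates of many
chains in a cubic box (default 8 nm, i.e. 512 nm³; the literature-standard
system for this peptide is 80 chains in that box).  *Dispersed* placement
is rejection-sampled rigid-body placement (uniform position and random
rotation) under a minimum inter-chain heavy-atom distance (default 4 Å),
with an attempt cap that raises a packing error suggesting a larger box.
*Micellar* placement arranges chains around the central z axis at a radius
set by chain extent, rotating each chain so its Lys NZ points outward and
its Ala body inward, with seeded angular/radial/axial jitter — the
idealized hydrophobic-core/hydrophilic-shell geometry.  All generators are
pure functions of (inputs, seed); multi-frame systems spawn per-frame
child seeds from one root seed.

What the generator does **not** emulate: solvent, energetics, realistic
packing correlations, conformational dynamics or any coupling between pH
and conformation.  Tests passing on these ensembles therefore validate the
measurement chain (building, counting, clustering, radial analysis) on
known ground truth; they do not validate claims about what real A6K does
at a given pH.

## Secondary structure and β-turns

φ/ψ/ω are measured with the standard four-atom torsion; termini and
residues missing backbone atoms give NaN and are labelled coil.  The
classifier assigns *helix* to runs of ≥ 4 consecutive residues in the α_R
region (φ∈[−100,−30], ψ∈[−80,−5]), *sheet* to runs of ≥ 2 in the β region
(φ∈[−180,−60], ψ∈[60,180] or ψ≤−150), then *turn* to the two central
residues (i+1, i+2) of any window i..i+3 whose Cα(i)–Cα(i+3) distance is
below the turn threshold and which are not already helix/sheet; the rest is
*coil*.  This is a deliberately simple Ramachandran-region stand-in for
hydrogen-bond-energy algorithms (STRIDE/DSSP): category-compatible, not
numerically identical, so ensemble turn percentages from different
assignment algorithms should be compared in trend, not digit by digit.

β-turn detection applies two classical window criteria: (A) a backbone
hydrogen bond from the C=O of residue i to the N–H of residue i+3, under a
geometric criterion of O···N ≤ 3.5 Å and N–H···O angle ≥ 120° (a common
choice; the amide H is reconstructed when absent from the file); (B) a
Cα(i)–Cα(i+3) distance strictly below 7.0 Å.  Because the field's usage
varies on whether the two classifications are alternatives or
requirements, the combination is configurable and defaults to *either*;
each record stores which criterion fired.  Windows whose central residues
are helical are excluded by default (a helix satisfies both geometries
trivially); this too is a switch.

Ensemble percentages: per frame, turn% = 100 × (residues labelled turn) /
(all residues); β-turn% = 100 × (residues inside qualifying windows) /
(all residues).  Since the criteria differ, neither percentage bounds the
other.  Because the residue-vs-window denominator convention is not
standardized, a window-fraction mode is provided
(`turn_content(..., denominator="windows")`).

## Aggregates

Chains are clustered per frame by single linkage on the contact graph:
adjacent iff minimum heavy-atom inter-chain distance ≤ cutoff (default
4.5 Å, a typical heavy-atom contact definition).  Aggregate shape is
summarized by the mass-weighted radius of gyration and the first principal
component of all Cα positions (sign fixed lexicographically for
reproducibility; degenerate clouds require an explicit axis).  The
amphiphilic order of an aggregate is the mean perpendicular distance of
Lys NZ atoms from the axis minus that of Ala CB atoms: positive for a
hydrophobic-core/hydrophilic-shell arrangement, near zero for random
organization.  For randomly dispersed systems the order has no preferred
sign; over 20 seeds its mean is statistically indistinguishable from zero
(one-sample t test), while micellar fixtures are constructed to make it
positive.

The pairwise electrostatic score places the titration model's fractional
charges on representative atoms — N-terminal N, Lys NZ, and the midpoint
of the two carboxylate oxygens (the carbonyl O if OXT is absent) — and
sums screened Coulomb terms q₁q₂·e²/(4πε₀ ε_r r) over cross-chain pairs,
with ε_r = 78.5 (bulk water) and a 1.4 nm cutoff (the conventional
short-range truncation radius in solution simulations of such systems).
Terms are summed in sorted order so the score is exactly symmetric in its
arguments.  This is a qualitative attraction/repulsion ranking across pH
— all-positive chains at pH 2 always score repulsive — not an energy.

## Pipeline

`run_pipeline` executes charge → (generate | load) → turns → aggregates
from one pydantic-validated YAML config (exactly one of `input_path` /
`generator`; generator seeds are mandatory).  The report echoes the config,
a SHA-256 config hash, and every threshold in use, so identical configs
reproduce identical numeric content.  Any stage failure removes partial
outputs and aborts with the stage named.  Bundled configs cover the four
standard pH conditions (2, 7, 8, 11); they use 12 chains × 3 frames so a
full run stays in the seconds range — the analysis code itself handles the
80-chain, 8 nm-box system in a few seconds per frame.

## Numerical and design notes

* Coordinates are Å internally; GRO nm fields are converted at the
  boundary.  PDB round-trips are exact to the format's 1e−3 Å, GRO to
  1e−2 Å.
* Torsions live in (−180, 180]; comparisons use a circular metric where
  wrap-around matters.
* The Cα-distance criterion is a strict `<`, and the contact criterion a
  `≤`; tests pin the strictness at the 7.0 Å threshold.
* Insertion codes and altlocs other than blank/'A' are rejected/ignored
  respectively; binary trajectory formats are out of scope (convert to
  multi-model PDB upstream).
* Known limitations: no side-chain rotamers; no coupling of protonation to
  conformation; the electrostatic score ignores solvent structure and
  counter-ions; the secondary-structure classifier is not STRIDE and the
  turn percentages of real trajectories assigned with STRIDE will differ
  numerically.
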