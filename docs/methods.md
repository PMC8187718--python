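# Methods

This note documents the models and procedures `allotrace` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Units and conventions

Coordinates are Ångström everywhere inside the library; PCA eigenvalues are
converted to nm² (÷100) and 2D-RMSD matrices to nm only at reporting
boundaries. Angles are degrees; torsions follow the IUPAC convention
(cis = 0°) on (−180°, 180°]. Residue numbering is taken verbatim from the
input file — the defaults (anchors I571/N574/I577, pivot W553, pair
E521–H1364/R1367) use human MRP1 numbering, and the synthetic toy protein
adopts the same ids so defaults apply unchanged. Selections use 1-based,
inclusive residue ranges; `backbone` means atom names N, CA, C, O and
`calpha` means CA. Alternate locations other than ''/'A' are dropped on
read.

## Superposition and RMSD

Least-squares rigid superposition is the Kabsch algorithm via SVD with
determinant-sign correction (always a proper rotation), uniform weights by
default. RMSD analyses superpose on the same atom selection they measure.
The 2D-RMSD matrix superposes every frame pair *independently* — entries
are mutual structural similarity, not distances to a common reference — so
the matrix of a trajectory against itself is exactly symmetric with a zero
diagonal.

## Conformational clustering

GROMOS (Daura) clustering: compute the all-pairs superposed RMSD on the
selection, repeatedly take the frame with the most neighbours within the
cutoff (default 3 Å) as a centroid, assign it and its neighbours to a
cluster, remove them, repeat. Ties in neighbour count break toward the
lowest frame index, making the result deterministic. Clusters are
renumbered 1, 2, … by descending size. Replicas are clustered separately;
occupancy vectors are averaged after size-rank alignment (cluster *k* of
one replica aligns with cluster *k* of another), SD over replicas with the
n−1 denominator.

## Essential dynamics

Frames are least-squares fitted to an iteratively refined mean (tolerance
1e-6 Å on the mean) before accumulating the mass-unweighted Cα covariance;
this removes rigid-body contamination, and fitting is skipped below 3
atoms where superposition is undefined. Eigendecomposition uses a
symmetric solver; the eigenvalue sum equals the covariance trace to 1e-8
relative (asserted in tests). The porcupine field maps mode *k* to one
3-vector per Cα, scaled by the span (max − min) of the trajectory's
projections on that mode — a definition robust to frame ordering, unlike
the literal first-to-last-frame difference; arrows shorter than the filter
cutoff (default 4 Å) are discarded.

## Helix geometry

The interhelical opening angle uses three anchor Cα positions: the angle
at the loop anchor between the vectors to the two helix anchors. For
single-residue anchors the Cα centre of mass reduces to the Cα position.

The kink (bend) angle at a pivot compares the axes of the two 6-residue
flanking segments. The helix-axis fit deserves a note: the raw principal
axis of Cα positions on a short helical window is tilted several degrees
by the unbalanced spiral phase (measured ≈ 3.6° phantom bend on an ideal
straight helix at window 6), which would swamp the kink contrasts of
interest. The implementation therefore first estimates the local twist
from consecutive bond-vector bisectors and smooths the Cα trace with a
4-tap symmetric filter whose weights null the spiral frequency exactly,
then takes the principal axis of the smoothed trace. On ideal geometry
this is exact (straight-helix bend < 1e-5°; a 6-residue window matches the
40-residue axis to 0.4°); traces without usable twist (straight lines,
strand zig-zags) fall back to the plain least-squares line. Axes are
oriented N→C so a straight helix reads 0°.

Noise floor: by simulation, the apparent bend of a straight ideal helix at
window 6 is ≈ 1.9° mean at σ = 0.1 Å coordinate noise and ≈ 5.5° at
σ = 0.3 Å — close to the information limit of six points spanning ~9 Å.
Kink *means* over a trajectory are much tighter (a planted 19° kink is
recovered within 0.2° at σ = 0.1 Å over 150 frames) because the per-frame
error is nearly unbiased at kinks far from 0°. Single-frame kink readings
near 0° should not be over-interpreted below the floor.

## Secondary structure

Per-frame assignment is a Kabsch–Sander hydrogen-bond scheme over a
4-state alphabet: the backbone H-bond energy
`E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol with a bond when
E < −0.5 kcal/mol; amide hydrogens are inferred (1.01 Å from N along the
bisector of the C(i−1) and CA directions) when absent. Two consecutive
i→i+4 turns make residues helical (H); parallel/antiparallel bridge
patterns make strands (E); i→i+3 / i→i+4 turns not inside a helix are T;
everything else is C. 3₁₀/π helices fold into T/C — a full 8-state
alphabet is out of scope. Against an established assignment tool (mdtraj's
DSSP, simplified alphabet) agreement on ideal-geometry fixtures is ~96%
pooled; the only disagreements are single-bridge strand termini, where
tool conventions genuinely differ.

"Unraveling" of a motif is operationalised as majority-class loss: the
motif's dominant class in the reference condition holds > 50% residue-time
occupancy there and ≤ 50% in the other condition; all-coil motifs are
never flagged (nothing to lose). Class deltas (mutant − WT residues per
class) are reported both frame-averaged and from per-residue dominant
labels, since either convention is defensible.

## Interactions

Contact scans rank residue pairs across two groups by trajectory-mean
minimum heavy-atom distance (default cutoff 3 Å). Salt bridges use the
conventional rule: charged-group heavy atoms (Arg Nε/Nη, Lys Nζ, His
Nδ/Nε vs Asp/Glu carboxylate O) at ≤ 4.0 Å, boundary inclusive; a pair is
reported as "no bond" when bridge occupancy falls below 0.1 — a threshold
chosen here since only the qualitative conclusion is standard.

Pair energies are screened Coulomb plus Lennard-Jones:
`E = Σ f·q_iq_j/(ε·r) + 4ε_ij((σ_ij/r)¹² − (σ_ij/r)⁶)` with
f = 138.935 kJ·mol⁻¹·nm·e⁻², Lorentz–Berthelot combining, and a constant
dielectric ε = 20 appropriate for charged surface residues. Solvation
terms are deliberately out of scope; the quantity reported is the plain
vdW + electrostatic interaction. The bundled parameter table covers
backbone atoms plus Arg/Lys/His⁺/Asp/Glu side chains with heavy-atom
united-group charges (side-chain sums exactly ±1e); because hydrogens are
implicit, ionizable-group N/O atoms carry reduced LJ radii so H-bonding
contact distances (2.4–3.2 Å) sit on the attractive branch. Missing
parameters raise, never default to zero. Distances below 0.5 Å abort as
clashes.

A caveat on magnitudes: with a constant dielectric and net ±1 charges, a
*broken* pair at ~6 Å still shows a monopole tail of ≈ −10 kJ/mol, larger
than a solvated estimate would give. Orderings (bridged more negative than
broken; WT more negative than mutant) are the meaningful output, and the
monotone screening property |E| decreasing in both ε and r is asserted in
tests.

## Statistics

Distribution comparisons default to Mann–Whitney U, exact by enumeration
when both sides have ≤ 8 untied observations and a tie-corrected normal
approximation otherwise (delegated to scipy behind the module surface);
Kolmogorov–Smirnov is available as an alternative. Replica aggregation is
the mean of replica means ± SD over replica means (n−1), with SD *absent*
— not zero — for a single replica. Frames within a trajectory are
autocorrelated; tests pool frames at stride 1 by default to match common
practice, so p-values overstate significance and should be read
comparatively. A stride parameter thins the series when calibrated
p-values matter. Dihedral distributions straddling ±180° can be recentred
(`circular_recenter`) before moment statistics.

## The synthetic generator

The toy protein is ~119 residues in MRP1-style numbering: helix 521–571
(kink pivot 553) → loop 572–576 → helix 577–600 form the TMD analogue;
a 13-residue helix 1328–1340 (Walker A analogue), a 14-residue helix
1358–1371 carrying His1364/Arg1367 (s5/h2 analogue), and an antiparallel
hairpin 1372–1377 / 1451–1456 (Q-loop and Walker B strand analogues) form
the NBD block. Glu521, His1364 and Arg1367 carry geometric side chains;
all other residues are backbone-only glycines. Chains are built by
internal-coordinate (NeRF) construction from φ/ψ torsions with standard
bond geometry; the sheet's strand placement is grid-searched once to
maximise inter-strand H-bond depth and cached.

Per frame the generator: samples a state from geometric-dwell blocks with
*exact* per-state frame quotas (so planted occupancies are recovered
exactly, not just in expectation); poses the interhelical anchors to the
state's angle by a closing rotation about the loop anchor (exact,
noise-free); kinks helix 10 by rotating the post-pivot segment about the
pivot Cα; offsets the NBD block rigidly by 22 Å per state index
(superposition absorbs ~70% of a block offset, so this leaves > 6 Å
backbone RMSD between adjacent states — twice the clustering cutoff);
displaces all atoms along a planted collective-mode field (unit Cα norm,
rigid-body components projected out so the fit-to-mean step cannot absorb
it) with Gaussian or linear-ramp amplitudes of chosen variance; rebuilds
scheduled segments with bridge-region coil torsions (φ ∈ −160…−100°,
ψ ∈ −20…60°, outside both the α and β basins) after their onset frame;
slides the basic side chains along their rod axes (scan + bisection) until
the min charged-group distance to the Glu tip equals the planted value
exactly; and finally adds isotropic Gaussian coordinate noise. Everything
derives from one seed, bit-for-bit reproducible.

The bundled scenarios plant the study-style contrasts: WT-like = states
(0.94, 0.06), angle 85.4 ± 2°, kink 19°, bridges at 2.4/3.2 Å; mutant-like
= four states (0.32/0.28/0.22/0.18), angle 82.2 ± 2°, kink 11°, His pair
at 5.9 Å (broken), Arg pair at 3.6 Å, and four motif windows unwinding at
30% of the run. Mode-1 variances are 0.116/0.161 nm² — the hundreds-of-nm²
collective variance of a 1,500-residue transporter is not reproducible in
a toy bundle, so the planted values preserve the mutant > WT ordering at
1000× smaller scale. The helix-motif unwinding windows extend a few
residues upstream of the motif itself because the i→i+4 H-bonds that label
a residue helical are anchored up to four residues before it.

What the generator does **not** emulate: force-field physics, solvent and
membrane, realistic side-chain rotamers and packing, sequence composition,
or correlated backbone dynamics beyond the single planted mode. Passing
the recovery suite therefore demonstrates that the *analysis* pipeline
measures what was planted — it does not validate conclusions about real
MRP1 dynamics.

## Problem sizes and runtime

Tests and the acceptance script use desk-scale sizes chosen for the
package's own CI: 50-frame ensembles for clustering oracles and occupancy
recovery, 150 frames for kink recovery, 1000 frames for mode-variance
recovery (recovered within 10%; ~30 s to generate), 3 replicas × 50 frames
per condition for the scenario contrasts. The full suite runs in a few
minutes on one CPU.

## Known limitations

- PDB fixed-column I/O only (no mmCIF); binary trajectory formats would
  enter as adapters behind the same `Trajectory` contract.
- The 4-state secondary-structure alphabet ignores 3₁₀/π helices,
  β-bulges, and polyproline II.
- Energies are pairwise vdW + screened electrostatics only — no
  Poisson–Boltzmann/GB solvation, no entropy.
- p-values ignore frame autocorrelation at the default stride.
- The helix-axis twist estimate assumes a locally uniform helix; strongly
  irregular segments fall back to a plain line fit.
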