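# Methods

## The system

The pyruvate dehydrogenase complex (PDC) core is a 60-mer of E2
C-terminal catalytic domains (CTD) arranged with icosahedral (532)
symmetry: 20 CTD trimers sit on the vertices of a dodecahedron. In
fungi, the E3-binding protein (E3BP) attaches to the *interior* of this
core through its core-binding domain (CBD), which trimerizes at the
interior face of a CTD trimer — i.e. at one of the 20 3-fold sites.
This package models four quantitative questions around that
architecture: how many CBD trimers occupy each core (occupancy
counting), how many could fit (steric capacity), whether the disordered
M3-containing loop of the CBD can reach nearby binding interfaces
(linker reach), and how E3BP is distinguished from E2 at the sequence
level (motif and triad discrimination).

## Symmetry expansion and the bins-of-three rule

A particle orientation is a ZYZ-intrinsic Euler triple (rot, tilt, psi)
in degrees; the matrix `A = Rz(psi)·Ry(tilt)·Rz(rot)` maps map-frame
coordinates into the particle image frame (the common single-particle
STAR convention). Symmetry expansion replaces each particle row by one
row per group operator G, with composed orientation `A·G` (the operator
acts on the map side, because symmetry relates identical positions of
the *map*). Under the icosahedral group this is a 60-fold multiplication
of the table. Re-centering on a map-frame site v uses
`shift = prior_shift − (A·G·v)_xy`: the image is translated so the site
projects at the center. Shifts are carried in Angstrom throughout;
pixel size belongs only at I/O boundaries.

A 3-fold site axis is fixed by a stabilizer subgroup of order 3, so each
physical trimer position appears in exactly 3 of the 60 expanded
sub-particles. A perfectly detected trimer therefore contributes 3
occupied regions, and per-core detection counts d are converted to
trimer estimates by bins of three: `t = floor((d+1)/3)`, i.e.
{3t−1, 3t, 3t+1} → t (8, 9 or 10 detections all read as 3 trimers). The
lowest bin {0, 1} is asymmetric: a single stray detection still reads as
zero trimers. The rule extends uniformly to d = 60; binned counts above
a plausibility ceiling (default 4, the steric maximum below) are
annotated as probable false positives but never dropped.

The icosahedral group is generated in the 222 setting (2-fold axes along
the coordinate axes) by closure from a 5-fold about (0, φ, 1) and a
3-fold about (1, 1, 1), with φ the golden ratio. The 5-fold generator's
chirality is the one whose 3-fold axes coincide with the dodecahedral
vertex family {(±1,±1,±1), (0,±1/φ,±φ), (±1/φ,±φ,0), (±φ,0,±1/φ)} used
by the geometry module; the mirror-image choice would place them on the
opposite vertex family. Operators are SVD-polished to SO(3) during
closure and listed in a fixed canonical order so site indices are
reproducible.

## Steric capacity

The core interior geometry is the 20 normalized dodecahedral vertex
directions plus the 30 nearest-neighbour vertex pairs (the dodecahedron
edges), which correspond to the dimeric CTD interfaces where a single
E3BP binding motif can dock. Pairwise vertex separations take only the
values 41.81°, 70.53°, 109.47°, 138.19° and 180°.

A bound CBD trimer is modelled as excluding any second trimer within an
angular threshold. The default threshold is 71°, the smallest round
value that excludes both nearest (41.81°) and next-nearest (70.53°)
pairs while admitting 109.47° pairs; it is exposed as a parameter
because the true steric footprint is not measured here. Maximum
placements are computed *exactly* by branch-and-bound maximum
independent set over the 20-site clash graph, returning every optimal
subset (at 71°: 4 trimers, and the 10 optimal subsets are the
tetrahedral vertex quadruples — two per each of the five cubes
inscribed in the dodecahedron). Note that under a pure angular model
antipodal sites (180° apart) never clash, so the maximum just below a
180° threshold is 2, not 1.

Capacities for E3BP monomers follow directly: `trimer_steric` = 4
trimers × 3 monomers = 12 (the fungal, CBD-trimerizing case);
`single_interface` = 30 (one motif per dimeric interface, no
coupling); `dual_interface` = floor(30/2) = 15 (each monomer engaging
two interfaces via M2- and M3-like motifs, the hypothesized
non-trimerizing case).

## M3 linker reach

The M3 motif lies in a 44-residue disordered loop anchored 45–50 Å from
the three nearest unoccupied dimeric interfaces, with 12 residues
upstream and 25 downstream of the motif. A fully extended chain gains
3.4 Å per residue, and the motif must remain connected through both
flanks, so the limiting reach is the shorter tether:
min(12, 25) × 3.4 = 40.8 Å. Since 40.8 < 45, the verdict is
`requires_unfolding` — the motif cannot span the gap unless the CBD
partially unfolds. No excluded-volume correction is applied; this is
deliberately the same back-of-envelope arithmetic, exposed with
configurable flank lengths, extension per residue and target range.

## Sequence discrimination

E3BP is a catalytically inactive E2 paralog. Two signals separate the
two at sequence level:

* **Triad state.** A transacetylase-homologous sequence is `active`
  only if it carries His at the canonical triad column; any substitution
  or internal gap is `inactive` (the E3BP signature); a triad column in
  a record's leading/trailing gap region is `indeterminate`.
* **PSBD motifs.** Position-specific rules over a fixed alignment-column
  frame: the polar 'EKG' motif ending PSBD helix 1 (E2-marking); an Arg
  on either side of a universally conserved Gly (universal, no vote); a
  conserved Asp followed by a hydrophobic motif with an exposed Leu
  ending helix 2 (E3BP-marking); the 'GxI' helix-2 termination motif
  (E3BP-marking; an alternate animal-frame span ships disabled); and an
  Ascomycota-specific extension of alternating hydrophobic residues
  (E3BP-marking, Asc records only). The hydrophobic class is fixed as
  {A,V,L,I,M,F,W,Y} so rules are bit-exact. A record's vote is the
  majority among matched polarity-carrying rules; ties are
  `unclassified`.

Candidate classification combines four criteria: (i) E2-homologous
domain topology, (ii) E3-specific PSBD, (iii) inactive catalytic
domain, (iv) M3-like motif. The default policy accepts E3BP when (i)
holds and at least one of (ii)–(iv) holds — different fungal groups
satisfy different subsets (Basidiomycota: i + iv only), hence the
or-combination; the minimum number of supporting criteria is
configurable. `E2-like` requires topology plus affirmatively false
(ii)–(iv); anything resting on unknowns is `inconclusive`, which makes
the classifier monotone in the criteria.

Column information content is `log2(|alphabet|) − H` bits with H the
Shannon entropy of the column's residue frequencies. The default gap
policy excludes gaps and renormalizes (residue-only logo convention;
columns >50% gap are flagged); the alternative treats the gap as a 21st
symbol. No small-sample entropy correction is applied by default, and
sequence redundancy is not filtered. Consensus characters use 'h' where
tied modal residues are all hydrophobic and 'x' below a 0.5 modal
frequency.

## Synthetic data

The generators produce every pipeline input with known ground truth.

**Cores.** Each simulated core draws its trimer count k from a
configurable distribution (default {0: 0.05, 1: 0.10, 2: 0.20, 3: 0.35,
4: 0.30}, concentrating mass at 3–4 trimers as observed), places the k
trimers on a uniformly chosen pairwise-compatible subset of the 20
sites (uniform over subsets, not sequential filling, to avoid order
artifacts), draws a uniform random orientation, and flags each of the
60 expanded regions occupied with probability 1−q if its central site
carries a trimer and p otherwise, independently. The defaults p = 0.01,
q = 0.05 are placeholders — the real classification's error rates are
unknown — and are labelled as such. Under this model E[d] =
3k(1−q) + (60−3k)p, which the tests verify by simulation. What the
generator does **not** emulate: image formation, correlated
misclassification (e.g. orientation-dependent detection), partial
trimer occupancy, or inter-core heterogeneity beyond the count
distribution; passing tests therefore certify the bookkeeping and
statistics of the pipeline, not classifier performance on real
micrographs.

**Sequences.** Records are built from a packaged *synthetic* 80-column
reference frame (a neutral background with the motif columns imprinted
and a designated triad column at 78) — not from any curated alignment —
with motifs planted or scrubbed per rule, the triad set by the record's
identity, and i.i.d. substitutions at a configurable per-site rate
(mutations always change the residue; gaps are never introduced). At
zero mutation the motif vote recovers every label; accuracy degrades
monotonically with the mutation rate toward the chance rate of fully
random sequences, which the tests check by simulation against a
random-sequence control.

Seeds are mandatory in every scenario; identical scenario + seed gives
identical output (counts and flags integer-exact; orientations subject
to ordinary floating-point determinism on one platform).

## Numerical choices

* Group-closure and operator-matching tolerance 1e-6 elementwise;
  operators SVD-projected to SO(3); orthonormality asserted at 1e-9.
* Stabilizer detection tolerance 1e-6 rad — far above float noise, far
  below any distinct-axis separation.
* Clash test `angle ≤ exclusion + 1e-9` (occupied pairs must strictly
  exceed the threshold).
* Euler decomposition at gimbal lock (tilt = 0 or 180) assigns the full
  in-plane angle to psi and zeroes rot; orientation comparisons in
  tests are made on matrices, never on Euler triples.
* Binning, capacities and reach are integer/closed-form arithmetic with
  no tolerance at all.

## Problem sizes

The test suite and the acceptance script run at desk scale: 1000
synthetic cores for noiseless recovery, 20 seeds × 150 cores for
noise-mean recovery, 120–240 records per mutation rate for the vote
recovery curve, and a 1°-step sweep of the exclusion angle for
placement monotonicity. The exact placement search visits a 20-vertex
graph and completes in milliseconds, so no heuristic mode exists.

## Known limitations

* The angular-exclusion clash model has a single scalar parameter; it
  does not use deposited atomic coordinates, and cannot decide whether
  a larger CBD footprint would also forbid 109.47° pairs (the threshold
  is exposed for exactly that exploration).
* Motif coordinates are meaningful only in the packaged reference
  frame; applying the rules to a real alignment requires mapping its
  columns to that frame first.
* The occupancy model treats detection errors as independent across
  regions; correlated failure modes of real classification are out of
  scope.
* Zygomyceta-specific rules ship disabled: the existence of a distinct
  M2 locus in that group is uncertain.
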