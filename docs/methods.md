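# Methods

## Model overview

pwmforge computes the binding preference of a DNA-binding protein from a
single co-complex structure.  Three model components are chained:

1. a distance-binned, residue-specific knowledge-based contact potential
   scores any protein–DNA complex;
2. fixed-backbone base-pair mutagenesis threads arbitrary sequences onto the
   complex's duplex geometry;
3. a linear energy model over one-hot sequence features is fit to the scores
   of 4N+X random sequences and converted to base probabilities with the
   Boltzmann factor.

The underlying assumptions are those of every PWM: positions contribute
independently and additively to binding, and the protein and DNA geometry is
rigid across substitutions.  Both are deliberate simplifications; their
consequences are noted under Limitations.

## The statistical potential

Heavy atoms only.  Atom types are (residue name, atom name) pairs from an
explicit registry (`data/atom_types.tsv`: 20 amino acids, 4 deoxynucleotides,
249 types; protein and DNA namespaces disjoint).  Editing the registry
changes the potential's resolution without touching code.

Contacts are interface pairs (one protein atom, one DNA atom) with Euclidean
distance d < 10 Å, binned with edges [0, 3, 4, 5, 6, 7, 8, 9, 10) Å — a wide
opening bin followed by seven 1 Å bins.  Bins are half-open; d = 10.0 Å is
not a contact.  A larger cutoff mostly adds noise-dominated long-range
pairs.

Training counts contacts N(b, t, u) over a corpus.  The contact energy is a
log-odds against the type-averaged marginal:

    P(b | t, u) = (N(b,t,u) + α) / (N(·,t,u) + 8α)
    P(b)        = (N(b,·,·) + αK) / (N(·,·,·) + 8αK)
    E(b, t, u)  = −ln [ P(b | t, u) / P(b) ]

with Laplace pseudocount α (default 0.5) and K the number of type pairs
observed at least once.  The Bayesian prior on complex correctness is fixed
at 1.  Type pairs never seen in training fall back to the uniform likelihood
1/8 over bins, i.e. E = −ln[(1/8)/P(b)].  With α = 0, bins never observed
for an otherwise-observed pair are capped at E = +10 with a warning.  The
complex score is the plain sum of contact energies: negative and decreasing
with more native-like interfaces (stronger predicted binding = lower score).
Training is invariant to corpus order, and — at α = 0 — to corpus
duplication.

Waters, ions, hydrogens and hetero ligands are excluded on parsing; only the
first alternate location and (by default) the first model are kept.  When
several crystal structures of the same complex exist, a purely repulsive
steric score Σ max(0, (r_min/d)¹² − 1) over interface pairs (r_min = sum of
element van der Waals radii from `data/vdw_radii.tsv`) ranks them; the
lowest-scoring structure has the fewest lattice-artifact clashes and is the
better scoring input.

## Base-pair mutagenesis

Bases are replaced as rigid idealized templates (`data/base_templates.pdb`):
planar regular-polygon ring geometries with exocyclic substituents, expressed
in the glycosidic anchor frame — origin at C1', x along the C1'→N9/N1 bond,
base plane normal as z (orientation fixed by purine C4 / pyrimidine C2).
Substituting a pair replaces the base atoms of both partners (Watson–Crick
complement on the partner strand) and never touches a backbone or sugar
atom: backbone coordinates are bit-identical by construction, substitutions
at distinct positions commute, and re-threading a sequence is a fixed point
up to float rounding (~1e-12 Å).

Pairs are detected geometrically: complementary residues whose C1'–C1'
distance lies within 10.4 ± 1.5 Å, ordered 5'→3' along the reference strand.
Unpaired interior residues (flipped-out bases) are excluded from the motif
with a warning.

Mutation fidelity is audited as the RMSD over the C4 atom subset between a
duplex and its fully mutated version, computed without superposition (the
frames are shared).  The sugar C4' is the reported default: it is the atom
common to all residues and held fixed by the protocol, so the published
sub-0.3 Å fidelity of torsion-library mutation tools is the right comparison
point; the base-ring C4 necessarily jumps by ~2 Å on purine↔pyrimidine swaps
and is available as an option.

## PWM construction

For motif length N, 4N+X i.i.d. uniform random sequences are drawn (default
X = 50, inside the 20–50 band where adding sequences stops changing the
result; hard cap 100 000).  Each is threaded and scored, giving

    A w = b,    A ∈ {0,1}^(4N+X × 4N),  A[s, 4(i−1)+u] = 1 iff seq s has base u at i.

Every row of A sums to N, so each position's four columns sum to the all-ones
vector and A has rank at most 3N+1: w is identifiable only up to per-position
additive constants.  We return the minimum-norm least-squares solution
(`lstsq`, relative singular-value tolerance 1e-10).  The gauge is harmless
because the Boltzmann conversion

    p(i, u) = exp(−β w(i,u)) / Σ_γ exp(−β w(i,γ))

(computed with per-position max subtraction) cancels per-position constants
exactly.  Consequently the PWM is a pure function of (structure, potential,
seed, X, β), and noiseless scores b = A·w_true reproduce Boltzmann(w_true)
to machine precision.

Dimensionless weights can be mapped to kJ/mol by ordinary least squares of
RT·Δln K_d (R = 8.314 J mol⁻¹ K⁻¹, T = 298.15 K default) against predicted
score differences to a declared reference sequence (the first calibration
entry); converting rescaled weights at β = 1/RT equals converting raw
weights at β = slope/RT.  Default β = 1 on dimensionless weights.

## Evaluation apparatus

*Relative entropy* (information content): Σ_ij p_ij log2(p_ij/0.25) bits,
after flooring cells at the pseudo-probability 1e-6 and renormalizing.
Additive over positions; zero only for the uniform matrix.

*Scanning*: the score of a word is Σ_i ln p(i, word_i), min-max normalized
between the per-column worst and best words so it lies in [0,1].  Windows
containing non-ACGT characters are skipped, not scored.  Hits on either
strand report 1-based inclusive coordinates on the forward strand (the
BED-style writer offers 0-based half-open output).

*Cutoff calibration*: smallest cutoff on a 0.001 grid whose empirical hit
rate on user-supplied background is ≤ the target (default 1e-4 per scanned
residue; the denominator counts residues × strands, making re-scanning at
the returned cutoff self-consistent).  At least 10/target_rate background
residues are required.

*Fragment ROC*: a fragment is recognized at threshold t iff its best window
score on either strand is ≥ t; TPR/FPR are evaluated on the descending 0.001
grid, AUC by trapezoid, averaged (mean ± sd) over the negative sets.

*Affinity regression*: ordinary least squares of ln K_d shifts on predicted
scores with a two-sided t-test on the slope.

## The synthetic fixtures

The generators provide ground truth without any external structure.

*Idealized duplex*: base pairs from the rigid templates, stacked at 3.4 Å
rise / 36° twist, C1' atoms of a pair diametrically opposite at 10.8 Å
(inside the pairing window).  Each pair is built exactly symmetric under a
local dyad (180° rotation about the in-pair y axis), which makes
reverse-complement duplexes exact rigid-motion images of each other — a
property real B-DNA has only approximately, used here as a strong
correctness oracle.  The backbone (P, O5', C5', C4', C3', O3') is a fixed
set of bond-length-plausible offsets, not a physical conformation; grooves,
pucker, and solvent are absent on purpose.

*Planted readers*: one protein residue per motif position with two probe
atoms placed in the open sector of the pair plane — one 2.8 Å off the
preferred base's edge atom (purine C8, cytosine C5, thymine C7), one off the
shared glycosidic edge.  The residue type encodes the preference (a 4×4
table of amino acids indexed by preferred base and position phase), so
discrimination rides on residue-specific typing exactly as in the real
potential: matched (probe, base) pairs are enriched at short range in the
corpus, and each matched contact is worth −ln 8 relative to an unseen pair
at the same bin, independent of the bin marginal.  Geometric separation
alone cannot distinguish bases sharing a scaffold position (adenine N6 vs
guanine O6), which is why typing, not distance, carries the signal.

*Training corpus*: random duplexes decorated with probes matched to the
bases actually present.  Default 100 duplexes of length 10 (~2×10⁵
contacts): each commonly occurring type pair then has on the order of a
hundred observations across 8 bins, enough that log-odds sampling noise
stays well below the planted signal.  A much smaller corpus makes the
neighbor-position contact energies noise-dominated and recovery unreliable —
the synthetic analogue of training a knowledge-based potential on too few
crystal structures.

What passing on these fixtures does *not* show: performance on real
complexes, where bases are non-planar and tilted, backbones deform, the
contact geometry is far richer, and crystal resolution limits the potential.
The fixtures validate the machinery (counting, solving, converting,
scanning), not the physics.

## Numerical choices and degenerate inputs

- Half-open bins; strict d < 10 Å; distances d ≤ 0 are rejected.
- Pseudocount α = 0.5 default; E cap +10 only in the α = 0 path.
- lstsq rcond 1e-10; solver warns (but solves, minimum-norm) when rows <
  columns.
- Softmax with per-position max subtraction; β = 0 yields the uniform PWM.
- Zero PWM cells floored at 1e-6 before any logarithm, then renormalized.
- A PWM whose best and worst words tie (fully uniform matrix) scores every
  word 1.0 in the normalized scanner.
- Degenerate affinity calibrations (all predicted scores equal) and
  zero-variance regressions are errors, not silent fits.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator and the end-to-end builder are deterministic given their seeds.

## Problem sizes

The shipped tests and the reproduction script run at desk scale: 10-position
motifs, 100-duplex corpora (~2×10⁵ contacts), 90-sequence design systems,
1.26 Mb calibration background, 20-fragment ROC sets with 5 negative
resamples.  These sizes give stable statistics for every quantity reported
while keeping a full run in seconds on one CPU; all of them scale up by
argument.

## Known limitations

- No hydrogens, no H-bond directionality, no solvation or electrostatics —
  the potential sees only typed heavy-atom distances.
- Position independence is baked into the linear model; coupled positions
  (e.g. palindromic half-site correlations) need a richer model, though the
  threading machinery can score arbitrary multi-base substitutions.
- Rigid backbone: strongly deformed or bent DNA is scored as found; no
  relaxation is attempted after substitution.
- The TRANSFAC/MEME readers accept the common minimal dialects, not every
  vendor extension.
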