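# pwmforge

Position weight matrices (PWMs) of transcription factors, computed from the
3D structure of a protein–DNA complex instead of from collections of known
binding sites.

Experimentally derived PWMs are biased toward strong binding sites and simply
do not exist for many annotated transcription factors.  When a co-crystal
structure (or a homology model placed on one) is available, the binding
preference of the factor can instead be computed: thread candidate sequences
onto the crystal DNA geometry, score each threaded complex with a
knowledge-based protein–DNA contact potential, and convert the per-position
energy contributions into base probabilities.

## Method

**Contact potential.**  Protein and DNA heavy atoms are typed
residue-specifically (ALA:CB and LEU:CB are different types).  Interface
contacts — protein/DNA atom pairs closer than 10 Å — are histogrammed into
eight distance bins (one 3 Å bin, then seven 1 Å bins).  The energy of a
contact between types *t, u* in bin *b* is the log-odds

    E(b, t, u) = −ln [ P(b | t, u) / P(b) ]

of the observed per-type-pair distance distribution against the type-averaged
marginal (Laplace pseudocount α = 0.5; the prior on complex correctness is
fixed at 1).  The binding score of a complex is the sum over interface
contacts; lower = stronger predicted binding.

**PWM construction.**  For a motif of length *N*, base pairs are substituted
on the fixed sugar-phosphate backbone (rigid idealized base templates
superposed on the glycosidic anchor frame, Watson–Crick complement maintained
on the partner strand).  4*N*+*X* random sequences (default *X* = 50) are
threaded and scored, giving a linear system **A w = b** with **A** the
one-hot design matrix (rows = sequences, columns = w(1,A), w(1,C), …,
w(N,T)) and **b** the score vector.  The minimum-norm least-squares solution
**w** is defined up to per-position constants — a gauge that the Boltzmann
conversion

    p(i, u) = exp(−β w(i, u)) / Σ_γ exp(−β w(i, γ))

cancels exactly.  Weights can be rescaled to kJ/mol against measured
ln K_d shifts before conversion with β = 1/RT.

**Evaluation.**  Relative entropy Σ_ij p_ij log2(p_ij / 0.25) in bits;
TRANSFAC and minimal-MEME motif I/O; a min-max normalized scanner
(consensus = 1, anti-consensus = 0) with cutoffs calibrated on background
sequence to a target hit rate (default 1 site per 10⁴ residues);
fragment-level ROC where a fragment counts as recognized when any window on
either strand beats the threshold.

A synthetic module generates everything needed to exercise the pipeline with
known ground truth: idealized B-DNA duplexes, "reader" probe atoms planted
with base-specific contact geometry, matching training corpora, and seeded
background sequence.

## Worked example

Train a potential on the synthetic corpus and rebuild the PWM of a planted
10-position reader complex:

```python
import pwmforge as pf

corpus = pf.make_training_corpus(seed=0)       # 100 duplexes with readers
model = pf.train_potential(corpus)             # 215013 contacts histogrammed
tc = pf.build_planted_complex("ACGTTACGGA")    # known ground truth
pwm = pf.build_pwm(tc, model, x_extra=50, seed=7)

print(pwm.consensus)                  # ACGTTACGGA  <- planted motif recovered
print(pf.relative_entropy(pwm))       # 20.00 bits (sharp, near-deterministic)
pref = pf.score_complex(model, pf.thread_sequence(tc, "ACGTTACGGA").structure)
anti = pf.score_complex(model, pf.thread_sequence(tc, "TGCAATGCCT").structure)
print(pref.value, anti.value)         # -1447.0 vs -214.3: preferred binds better
```

The recovered consensus equals the planted preference at every position; the
preferred sequence scores ~1200 energy units below the anti-consensus, the
sign convention being that of a binding free energy.

The same workflow runs from the shell on any PDB-format complex:

```sh
pwmforge inspect complex.pdb
pwmforge train-potential --pdb-list corpus.txt --out model.json
pwmforge build --pdb complex.pdb --model model.json --seed 17 --out motif.transfac
pwmforge entropy motif.transfac
pwmforge scan --pwm motif.transfac --fasta promoters.fa --cutoff auto --background bg.fa
```

## Limitations

The potential has no hydrogen atoms, no hydrogen-bond directionality and no
solvent; positions are modeled independently (a PWM cannot express
inter-position coupling); DNA deformation on binding is not modeled — the
backbone stays exactly as found in the input structure.  See
`docs/methods.md` for the full model description and numerical choices.
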