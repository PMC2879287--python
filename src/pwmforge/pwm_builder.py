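"""Core PWM construction: random sequences -> threaded scoring -> least
squares -> Boltzmann probabilities.

For a motif of length N, 4N+X random sequences are threaded onto the complex
geometry and scored with the statistical potential.  A one-hot design matrix
A ((4N+X) rows, 4N columns ordered w(1,A), w(1,C), w(1,G), w(1,T), w(2,A),
...) relates the scores b to per-position/per-base energy weights via
A w = b, solved as a minimum-norm least-squares problem.  The one-hot rows
make A rank-deficient (each position's four columns sum to the all-ones
vector), so w is defined only up to per-position additive constants -- a
gauge freedom that the Boltzmann conversion

    p(i, u) = exp(-beta w(i, u)) / sum_g exp(-beta w(i, g))

cancels exactly, which is why the particular least-squares representative is
irrelevant to the PWM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mutagenesis import ThreadedComplex, thread_sequence
from .potential import PotentialModel, score_complex

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: gas constant, kJ/(mol K)
R_GAS = 8.314e-3
DEFAULT_T = 298.15

#: hard cap on the number of extra random sequences
X_EXTRA_MAX = 100_000


@dataclass
class SequenceSample:
    sequences: list[str]
    seed: int
    x_extra: int

    @property
    def motif_length(self) -> int:
        return len(self.sequences[0])


@dataclass
class EnergyWeights:
    """Per-position/per-base binding-energy contributions w(i, u).

    ``matrix`` has shape (N, 4) with columns ordered A, C, G, T; the flat
    Eq.-style vector layout is ``vector``.  Defined only up to a per-position
    additive constant (see module docstring).  ``units`` is 'dimensionless'
    until rescaled against experimental affinities.
    """

    matrix: np.ndarray
    units: str = "dimensionless"
    metadata: dict = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[0]

    @property
    def vector(self) -> np.ndarray:
        return self.matrix.reshape(-1)

    @classmethod
    def from_vector(cls, v: np.ndarray, **kw) -> "EnergyWeights":
        v = np.asarray(v, float)
        return cls(matrix=v.reshape(-1, 4), **kw)

    def sequence_score(self, sequence: str) -> float:
        """Additive score of one sequence under these weights."""
        if len(sequence) != self.n_positions:
            raise ValueError("sequence length mismatch")
        return float(sum(self.matrix[i, BASE_INDEX[b]] for i, b in enumerate(sequence)))


@dataclass
class PWM:
    """Column-stochastic 4xN position weight matrix.

    ``probs`` has shape (N, 4), rows = motif positions, columns ordered
    A, C, G, T; every row sums to one.
    """

    probs: np.ndarray
    beta: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be (N, 4)")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("PWM rows must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


def generate_sequences(n_positions: int, x_extra: int = 50, seed: int = 0) -> SequenceSample:
    """4N + X i.i.d. uniform random sequences of length N, deterministic in
    the seed; duplicates permitted."""
    if n_positions < 1:
        raise ValueError("motif length must be >= 1")
    if x_extra < 0:
        raise ValueError("x_extra must be >= 0")
    if x_extra > X_EXTRA_MAX:
        raise ValueError(f"x_extra capped at {X_EXTRA_MAX}")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=(4 * n_positions + x_extra, n_positions))
    seqs = ["".join(BASES[c] for c in row) for row in codes]
    return SequenceSample(sequences=seqs, seed=seed, x_extra=x_extra)


def build_design_matrix(sample: SequenceSample) -> np.ndarray:
    """Binary (4N+X, 4N) matrix; entry [s, 4(i-1)+u] = 1 iff sequence s has
    base u at position i.  Every row sums to N."""
    n = sample.motif_length
    a = np.zeros((len(sample.sequences), 4 * n))
    for s, seq in enumerate(sample.sequences):
        for i, b in enumerate(seq):
            a[s, 4 * i + BASE_INDEX[b]] = 1.0
    return a


def score_sample(
    model: PotentialModel, complex_: ThreadedComplex, sample: SequenceSample
) -> np.ndarray:
    """Binding score of every sample sequence threaded onto the complex."""
    if sample.motif_length != complex_.n_pairs:
        raise ValueError(
            f"sample length {sample.motif_length} != motif length {complex_.n_pairs}"
        )
    return np.array([
        score_complex(model, thread_sequence(complex_, seq).structure).value
        for seq in sample.sequences
    ])


def solve_weights(a: np.ndarray, b: np.ndarray, rcond: float = 1e-10) -> EnergyWeights:
    """Minimum-norm least-squares solution of A w = b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape[0] < a.shape[1]:
        logger.warning(
            "underdetermined system (%d rows < %d columns); minimum-norm solution",
            a.shape[0], a.shape[1],
        )
    w, _, rank, _ = np.linalg.lstsq(a, b, rcond=rcond)
    residual = float(np.linalg.norm(a @ w - b))
    return EnergyWeights.from_vector(
        w, metadata={"residual_norm": residual, "rank": int(rank)}
    )


def rescale_weights(
    w: EnergyWeights,
    calibration: list[tuple[str, float]],
    temperature: float = DEFAULT_T,
) -> EnergyWeights:
    """Rescale dimensionless weights to kJ/mol against measured affinities.

    ``calibration`` pairs sequences with their ln K_d shifts relative to the
    first (reference) entry.  RT * dlnK_d is regressed by ordinary least
    squares on the predicted score difference to the reference sequence; the
    fitted slope maps scores onto kJ/mol.
    """
    if len(calibration) < 2:
        raise ValueError("need >= 2 calibration points")
    ref_seq, ref_shift = calibration[0]
    ref_score = w.sequence_score(ref_seq)
    x = np.array([w.sequence_score(s) - ref_score for s, _ in calibration])
    y = R_GAS * temperature * (np.array([k for _, k in calibration]) - ref_shift)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate calibration: all predicted scores equal")
    slope, intercept = np.polyfit(x, y, 1)
    return EnergyWeights(
        matrix=slope * w.matrix,
        units="kJ/mol",
        metadata={**w.metadata, "calibration_slope": float(slope),
                  "calibration_intercept": float(intercept),
                  "temperature_K": temperature},
    )


def energies_to_pwm(
    w: EnergyWeights,
    beta: float | None = 1.0,
    temperature: float = DEFAULT_T,
) -> PWM:
    """Boltzmann conversion of energy weights to base probabilities.

    ``beta`` is the inverse energy; pass ``None`` for 1/RT (appropriate when
    the weights are in kJ/mol).  Computed with per-position max subtraction
    for numerical stability; invariant to per-position constants in w.
    """
    if beta is None:
        beta = 1.0 / (R_GAS * temperature)
    if beta < 0:
        raise ValueError("beta must be non-negative")
    e = -beta * w.matrix
    e = e - e.max(axis=1, keepdims=True)
    p = np.exp(e)
    p /= p.sum(axis=1, keepdims=True)
    return PWM(probs=p, beta=beta, metadata=dict(w.metadata))


def build_pwm(
    complex_: ThreadedComplex,
    model: PotentialModel,
    x_extra: int = 50,
    seed: int = 0,
    beta: float | None = 1.0,
) -> PWM:
    """Full pipeline: generate sequences, thread and score, solve the linear
    system, convert to probabilities.  A pure function of (structure,
    potential, seed, x_extra, beta)."""
    n = complex_.n_pairs
    sample = generate_sequences(n, x_extra=x_extra, seed=seed)
    a = build_design_matrix(sample)
    b = score_sample(model, complex_, sample)
    w = solve_weights(a, b)
    logger.info(
        "build_pwm: N=%d x_extra=%d seed=%d residual=%.3g",
        n, x_extra, seed, w.metadata["residual_norm"],
    )
    pwm = energies_to_pwm(w, beta=beta)
    pwm.metadata.update({
        "n_positions": n, "x_extra": x_extra, "seed": seed,
        "potential_hash": model.hash,
    })
    return pwm
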