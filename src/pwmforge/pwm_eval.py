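"""PWM evaluation: information content, motif file formats, calibrated
scanning, fragment-level ROC and affinity regression.

Scanning uses a min-max normalized log-probability score: the additive
log-probability of a window is rescaled linearly between the worst- and
best-possible words of the matrix, so every score lies in [0, 1] with the
consensus word at 1.  Score cutoffs are calibrated empirically on background
sequence to a target hit frequency (default one site per 10^4 residues,
p ~ 1e-4), the way promoter scanners calibrate matrix precision thresholds.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs
from scipy import stats

from .pwm_builder import BASES, PWM

#: floor probability applied before any logarithm (zero-cell handling)
PSEUDO_PROB = 1e-6

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass
class ScanHit:
    """A motif occurrence; coordinates are 1-based inclusive on the forward
    strand regardless of the matched strand."""

    fragment_id: str
    start: int
    end: int
    strand: str
    score: float


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray          # mean over negative sets
    aucs: list[float] = field(default_factory=list)

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.aucs, ddof=1)) if len(self.aucs) > 1 else 0.0


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def _safe_probs(pwm: PWM) -> np.ndarray:
    """Zero cells floored at PSEUDO_PROB, rows renormalized."""
    q = np.maximum(pwm.probs, PSEUDO_PROB)
    return q / q.sum(axis=1, keepdims=True)


def relative_entropy(pwm: PWM) -> float:
    """Kullback-Leibler divergence (bits) of the PWM from the uniform base
    background, summed over positions; zero only for the uniform matrix."""
    q = _safe_probs(pwm)
    return float(np.sum(q * np.log2(q / 0.25)))


# ---------------------------------------------------------------------------
# motif file formats

def write_pwm(pwm: PWM, fmt: str = "transfac", name: str = "pwmforge") -> str:
    """Serialize to TRANSFAC or minimal MEME text.

    TRANSFAC stores count-style values; probabilities are scaled by 1e6 so
    the write/read round trip preserves them well below 1e-6.
    """
    if fmt == "transfac":
        counts = {
            b: [round(p * 1_000_000, 3) for p in pwm.probs[:, i]]
            for i, b in enumerate(BASES)
        }
        m = bio_motifs.Motif(alphabet="ACGT", counts=counts)
        m.name = name
        return bio_motifs.write([m], "transfac")
    if fmt == "meme":
        lines = [
            "MEME version 4", "",
            "ALPHABET= ACGT", "",
            "strands: + -", "",
            "Background letter frequencies",
            "A 0.25 C 0.25 G 0.25 T 0.25", "",
            f"MOTIF {name}",
            # large nsites so count-based parsers keep 1e-6 precision
            f"letter-probability matrix: alphabet= 4 w= {pwm.length} nsites= 100000000 E= 0",
        ]
        for row in pwm.probs:
            lines.append(" " + " ".join(f"{p:.10f}" for p in row))
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def read_pwm(text: str, fmt: str = "transfac") -> PWM:
    """Parse a TRANSFAC or minimal MEME motif; counts are normalized to
    column-stochastic probabilities."""
    parser = {"transfac": "TRANSFAC", "meme": "minimal"}.get(fmt)
    if parser is None:
        raise ValueError(f"unknown format {fmt!r}")
    try:
        parsed = bio_motifs.parse(io.StringIO(text), parser)
        records = list(parsed)
    except Exception as exc:
        raise ValueError(f"{fmt} parse error: {exc}") from exc
    if not records:
        raise ValueError(f"no motif found in {fmt} input")
    m = records[0]
    if set(m.counts.keys()) != set(BASES):
        raise ValueError(f"alphabet {sorted(m.counts.keys())} is not ACGT")
    counts = np.array([m.counts[b] for b in BASES], float).T  # (N, 4)
    sums = counts.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("motif has an empty column")
    return PWM(probs=counts / sums, metadata={"source_format": fmt})


# ---------------------------------------------------------------------------
# scanning

def _log_probs(pwm: PWM) -> np.ndarray:
    return np.log(_safe_probs(pwm))


def normalized_score(pwm: PWM, word: str) -> float:
    """Min-max normalized log-probability score of a single word in [0, 1]."""
    if len(word) != pwm.length:
        raise ValueError(f"word length {len(word)} != motif length {pwm.length}")
    codes = _CODE[np.frombuffer(word.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("word contains non-ACGT characters")
    lp = _log_probs(pwm)
    s = float(lp[np.arange(pwm.length), codes].sum())
    smin = float(lp.min(axis=1).sum())
    smax = float(lp.max(axis=1).sum())
    if smax == smin:
        return 1.0
    return (s - smin) / (smax - smin)


def window_scores(pwm: PWM, fragment: str) -> np.ndarray:
    """Normalized score of every window of the fragment (forward strand);
    windows containing non-ACGT characters are NaN."""
    n = pwm.length
    codes = _CODE[np.frombuffer(fragment.encode(), dtype=np.uint8)]
    m = len(codes) - n + 1
    if m <= 0:
        return np.empty(0)
    lp = _log_probs(pwm)
    smin = lp.min(axis=1).sum()
    smax = lp.max(axis=1).sum()
    s = np.zeros(m)
    bad = np.zeros(m, dtype=bool)
    for j in range(n):
        c = codes[j:j + m]
        bad |= c < 0
        s += lp[j][np.clip(c, 0, 3)]
    if smax == smin:
        out = np.ones(m)
    else:
        out = (s - smin) / (smax - smin)
    out[bad] = np.nan
    return out


def _revcomp(fragment: str) -> str:
    table = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return fragment.translate(table)[::-1]


def scan(
    pwm: PWM,
    fragment: str,
    cutoff: float,
    both_strands: bool = True,
    fragment_id: str = "fragment",
) -> list[ScanHit]:
    """All windows scoring at or above ``cutoff``; reverse-strand hits report
    their footprint on the forward strand, 1-based inclusive."""
    n = pwm.length
    length = len(fragment)
    hits: list[ScanHit] = []
    fwd = window_scores(pwm, fragment)
    for i in np.nonzero(fwd >= cutoff)[0]:
        hits.append(ScanHit(fragment_id, int(i) + 1, int(i) + n, "+", float(fwd[i])))
    if both_strands:
        rev = window_scores(pwm, _revcomp(fragment))
        for i in np.nonzero(rev >= cutoff)[0]:
            start = length - int(i) - n + 1
            hits.append(ScanHit(fragment_id, start, start + n - 1, "-", float(rev[i])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _all_scores(pwm: PWM, fragments: list[str], both_strands: bool) -> np.ndarray:
    parts = []
    for frag in fragments:
        parts.append(window_scores(pwm, frag))
        if both_strands:
            parts.append(window_scores(pwm, _revcomp(frag)))
    if not parts:
        return np.empty(0)
    s = np.concatenate(parts)
    return s[~np.isnan(s)]


GRID = np.round(np.arange(0.0, 1.0005, 0.001), 3)


def calibrate_cutoff(
    pwm: PWM,
    background_fragments: list[str],
    target_rate: float = 1e-4,
    both_strands: bool = True,
    seed: int | None = None,
) -> float:
    """Smallest cutoff on a 0.001 grid whose empirical hit rate on the
    background is at most ``target_rate`` hits per scanned residue.

    The rate denominator is residues scanned (fragment length times number of
    strands), so the calibration is self-consistent with re-scanning at the
    returned cutoff.  Deterministic given the background (``seed`` accepted
    for interface uniformity).
    """
    total = sum(len(f) for f in background_fragments)
    if total < 10 / target_rate:
        raise ValueError(
            f"insufficient background: {total} residues < {10 / target_rate:.0f};"
            " supply more sequence"
        )
    scores = np.sort(_all_scores(pwm, background_fragments, both_strands))
    denom = total * (2 if both_strands else 1)
    n_hits = len(scores) - np.searchsorted(scores, GRID, side="left")
    rates = n_hits / denom
    ok = np.nonzero(rates <= target_rate)[0]
    if len(ok) == 0:
        raise ValueError("no cutoff on the grid satisfies the target rate")
    return float(GRID[ok[0]])


def fragment_roc(
    pwm: PWM,
    positive_fragments: list[str],
    negative_sets: list[list[str]],
    both_strands: bool = True,
    seed: int | None = None,
) -> ROCResult:
    """Fragment-level ROC: a fragment is recognized at threshold t iff its
    best window score (either strand) is >= t.

    TPR/FPR are computed on a descending 0.001 threshold grid; AUC by the
    trapezoid rule, averaged over the negative sets.
    """
    if not positive_fragments or not negative_sets:
        raise ValueError("need non-empty positive fragments and negative sets")

    def best_scores(fragments: list[str]) -> np.ndarray:
        return np.array([
            np.nanmax(np.concatenate([
                window_scores(pwm, f),
                window_scores(pwm, _revcomp(f)) if both_strands else np.empty(0),
            ]))
            for f in fragments
        ])

    return roc_from_scores(
        best_scores(positive_fragments),
        [best_scores(neg_set) for neg_set in negative_sets],
    )


def roc_from_scores(positive_scores, negative_score_sets) -> ROCResult:
    """ROC over the descending 0.001 threshold grid from per-fragment best
    scores; AUC by the trapezoid rule, one value per negative set."""
    thresholds = GRID[::-1]  # descending 1.000 -> 0.000
    pos = np.sort(np.asarray(positive_scores, float))
    tpr = (len(pos) - np.searchsorted(pos, thresholds, side="left")) / len(pos)
    fprs = []
    aucs = []
    for neg_set in negative_score_sets:
        neg = np.sort(np.asarray(neg_set, float))
        fpr = (len(neg) - np.searchsorted(neg, thresholds, side="left")) / len(neg)
        fprs.append(fpr)
        aucs.append(float(np.trapezoid(np.r_[0.0, tpr], np.r_[0.0, fpr])))
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=np.mean(fprs, axis=0),
        aucs=aucs,
    )


def affinity_regression(scores, lnkd_shifts) -> RegressionResult:
    """Ordinary least squares of measured ln K_d shifts on predicted binding
    scores, with a two-sided t-test on the slope."""
    x = np.asarray(scores, float)
    y = np.asarray(lnkd_shifts, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in scores")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
        n=len(x),
    )
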