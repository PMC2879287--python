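"""Distance-binned knowledge-based statistical potential for protein-DNA scoring.

The potential is trained from contact histograms of protein-DNA complexes:
heavy-atom pairs across the interface, typed residue-specifically, are counted
into eight distance bins -- one 3 A bin followed by seven 1 A bins up to the
10 A cutoff (the "3/10/1" layout).  Per-bin energies are log-odds of the
observed per-type-pair distance distribution against the type-averaged
marginal, with a Laplace pseudocount; the Bayesian prior on complex
correctness is fixed at one.  The binding score of a complex is the sum of
contact energies over all interface pairs; lower means stronger predicted
binding, and zero-contact complexes score exactly zero.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_io import ComplexStructure, interface_contacts

logger = logging.getLogger(__name__)

#: energy cap for never-observed bins when training without pseudocounts
E_MAX = 10.0


@dataclass(frozen=True)
class BinScheme:
    """Half-open distance bins [lo, hi); default 3/10/1 layout."""

    edges: tuple[float, ...] = (0.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def max_distance(self) -> float:
        return self.edges[-1]


DEFAULT_BINS = BinScheme()


def bin_of(d: float, scheme: BinScheme = DEFAULT_BINS) -> int | None:
    """Bin index of distance ``d`` (A), or ``None`` at/beyond the cutoff."""
    if d <= 0:
        raise ValueError(f"invalid distance {d}")
    if d >= scheme.max_distance:
        return None
    return int(np.searchsorted(scheme.edges, d, side="right")) - 1


@dataclass
class ContactHistogram:
    """Raw contact counts indexed (bin, protein type, DNA type).

    Type ids are mapped to compact array indices through ``ptype_index`` /
    ``dtype_index``; only type pairs observed at least once in training occupy
    a column/row.
    """

    counts: np.ndarray
    ptype_index: dict[int, int]
    dtype_index: dict[int, int]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class BindingScore:
    value: float
    n_contacts: int


@dataclass
class PotentialModel:
    """Trained potential: histogram plus derived per-bin energies.

    ``energies[b, i, j]`` is the dimensionless contact energy for bin ``b``
    and the observed type pair with compact indices ``(i, j)``;
    ``unknown_energy[b]`` applies to type pairs never seen in training
    (pseudocount-only likelihood).
    """

    histogram: ContactHistogram
    pseudocount: float
    scheme: BinScheme = field(default_factory=BinScheme)
    prior_pc: float = 1.0
    energies: np.ndarray | None = None
    unknown_energy: np.ndarray | None = None

    def __post_init__(self):
        if self.energies is None:
            self._derive_energies()

    def _derive_energies(self) -> None:
        c = self.histogram.counts.astype(float)
        nb = self.scheme.n_bins
        alpha = self.pseudocount
        total = c.sum()
        pair_totals = c.sum(axis=0)                      # (P, D)
        observed = pair_totals > 0
        k_pairs = int(observed.sum())                    # K of the log-odds form
        bin_totals = c.sum(axis=(1, 2))                  # (nb,)
        marginal = (bin_totals + alpha * k_pairs) / (total + nb * alpha * k_pairs)
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = (c + alpha) / (pair_totals[None] + nb * alpha)
            e = -np.log(cond / marginal[:, None, None])
        if alpha == 0:
            empty = ~np.isfinite(e)
            if empty.any():
                logger.warning(
                    "capping %d never-observed bin energies at +%.1f", empty.sum(), E_MAX
                )
                e[empty] = E_MAX
        # never-observed type pair: likelihood collapses to the uniform 1/nb
        self.unknown_energy = -np.log((1.0 / nb) / marginal) if alpha > 0 else np.zeros(nb)
        self.energies = e

    @property
    def hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.histogram.counts.tobytes())
        h.update(str(self.pseudocount).encode())
        return h.hexdigest()[:16]

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        hist = self.histogram
        return json.dumps({
            "format": "pwmforge-potential-1",
            "edges": list(self.scheme.edges),
            "pseudocount": self.pseudocount,
            "ptype_ids": list(hist.ptype_index),
            "dtype_ids": list(hist.dtype_index),
            "counts": hist.counts.astype(int).tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "PotentialModel":
        d = json.loads(text)
        if d.get("format") != "pwmforge-potential-1":
            raise ValueError("unrecognized potential bundle")
        hist = ContactHistogram(
            counts=np.array(d["counts"], dtype=np.int64),
            ptype_index={t: i for i, t in enumerate(d["ptype_ids"])},
            dtype_index={t: i for i, t in enumerate(d["dtype_ids"])},
        )
        return cls(histogram=hist, pseudocount=d["pseudocount"],
                   scheme=BinScheme(tuple(d["edges"])))


def train_potential(
    complexes: list[ComplexStructure],
    scheme: BinScheme = DEFAULT_BINS,
    pseudocount: float = 0.5,
) -> PotentialModel:
    """Count interface contacts across a corpus and derive bin energies.

    Every atom must carry a ``type_id`` (see ``assign_atom_types``).  The
    result is invariant to the order of the corpus and to duplicating it.
    """
    if not complexes:
        raise ValueError("empty training corpus")
    raw: dict[tuple[int, int, int], int] = {}
    for cx in complexes:
        for c in interface_contacts(cx, scheme.max_distance):
            if c.protein_atom.type_id is None or c.dna_atom.type_id is None:
                raise ValueError("training structures must be typed first")
            b = bin_of(c.d, scheme)
            if b is None:
                continue
            key = (b, c.protein_atom.type_id, c.dna_atom.type_id)
            raw[key] = raw.get(key, 0) + 1
    if not raw:
        raise ValueError("no interface contacts in training corpus")
    ptypes = sorted({t for _, t, _ in raw})
    dtypes = sorted({u for _, _, u in raw})
    pidx = {t: i for i, t in enumerate(ptypes)}
    didx = {u: i for i, u in enumerate(dtypes)}
    counts = np.zeros((scheme.n_bins, len(ptypes), len(dtypes)), dtype=np.int64)
    for (b, t, u), n in raw.items():
        counts[b, pidx[t], didx[u]] = n
    hist = ContactHistogram(counts=counts, ptype_index=pidx, dtype_index=didx)
    return PotentialModel(histogram=hist, pseudocount=pseudocount, scheme=scheme)


def contact_energy(model: PotentialModel, t_i: int, t_j: int, d: float) -> float:
    """Energy of a single contact; 0 beyond the cutoff, pseudocount-only for
    type pairs never observed in training."""
    b = bin_of(d, model.scheme)
    if b is None:
        return 0.0
    hist = model.histogram
    if t_i in hist.ptype_index and t_j in hist.dtype_index:
        return float(model.energies[b, hist.ptype_index[t_i], hist.dtype_index[t_j]])
    return float(model.unknown_energy[b])


def score_complex(model: PotentialModel, structure: ComplexStructure) -> BindingScore:
    """Free-energy-like binding score: sum of contact energies over the
    interface.  Lower = stronger predicted binding."""
    value = 0.0
    n = 0
    for c in interface_contacts(structure, model.scheme.max_distance):
        value += contact_energy(model, c.protein_atom.type_id, c.dna_atom.type_id, c.d)
        n += 1
    return BindingScore(value=value, n_contacts=n)
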