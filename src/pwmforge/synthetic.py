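"""Synthetic fixtures with known ground truth.

Everything downstream of the potential is testable without any external
structure through three generators:

* :func:`build_bdna` -- an idealized double helix: base pairs built from the
  rigid base templates, stacked with a 3.4 A rise and 36 degree twist, each
  pair exactly symmetric under a dyad rotation so that reverse-complement
  duplexes are rigid-motion images of each other.  The backbone is a fixed
  set of plausible offsets per residue, not a physical sugar-phosphate
  conformation; grooves, sugar pucker and solvent are deliberately absent.
* :func:`build_planted_complex` -- a duplex plus one "reader" probe atom per
  motif position, placed 2.8 A off a distinguishing (handle) atom of the
  preferred base.  Probe residue types encode the preference, so any
  potential trained on a matching corpus rewards the planted base.
* :func:`make_training_corpus` -- random duplexes decorated with probes
  matched to the bases actually present, i.e. the corpus a potential needs
  to learn the planted geometry.

All randomness funnels through one seeded generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mutagenesis import COMPLEMENT, ThreadedComplex, load_templates
from .structure_io import Atom, ComplexStructure, assign_atom_types, default_registry


@dataclass(frozen=True)
class HelixParams:
    """Idealized helix geometry: constant rise/twist, C1' atoms of a pair
    diametrically opposite at 2 * c1_radius separation (10.8 A, inside the
    Watson-Crick 10.4 +/- 1.5 A window)."""

    rise: float = 3.4
    twist_deg: float = 36.0
    c1_radius: float = 5.4


DEFAULT_HELIX = HelixParams()

#: fictional but bond-length-plausible backbone offsets in the canonical
#: glycosidic frame (C1' at the origin, base toward +x)
BACKBONE_LOCAL = {
    "C4'": np.array([-1.3, -0.8, 0.5]),
    "C5'": np.array([-2.4, -1.3, 1.4]),
    "O5'": np.array([-3.3, -2.3, 1.6]),
    "P": np.array([-4.3, -3.4, 2.2]),
    "C3'": np.array([-1.7, -1.6, -0.7]),
    "O3'": np.array([-2.5, -2.6, -1.3]),
}

#: heavy atom of each base, on the open face of the pair plane, used to
#: anchor planted probes (purine C8; pyrimidine ring/methyl edge)
HANDLE_ATOM = {"A": "C8", "G": "C8", "C": "C5", "T": "C7"}
#: second probe site, shared by all bases: off the glycosidic nitrogen into
#: the same open sector (every base presents its ring edge there)
GLYCO_SITE = np.array([1.48, -3.5, 0.0])

#: probe residue type per (preferred base, position phase): encodes the
#: planted preference in the residue-specific type namespace
PROBE_TABLE = {
    "A": ["ARG", "LYS", "HIS", "GLN"],
    "C": ["GLU", "ASP", "ASN", "SER"],
    "G": ["LEU", "ILE", "VAL", "MET"],
    "T": ["PHE", "TYR", "TRP", "THR"],
}
PROBE_ATOM = "CB"
#: side-chain atom name used for the second probe site, per residue type
SECOND_PROBE_ATOM = {"SER": "OG", "THR": "CG2", "ILE": "CG1", "VAL": "CG1"}
PROBE_OFFSET = 2.8  # A from the handle atom


def _rz(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _residue_local_atoms(base: str) -> list[tuple[str, np.ndarray]]:
    """C1' + backbone + base atoms in the canonical glycosidic frame."""
    template = load_templates()["D" + base]
    atoms = [("C1'", np.zeros(3))]
    atoms += [(n, v.copy()) for n, v in BACKBONE_LOCAL.items()]
    atoms += [(n, v.copy()) for n, v in template.atoms]
    return atoms


def _ref_canonical(p: np.ndarray, r0: float) -> np.ndarray:
    """Reference-strand placement: base points inward (-x), C1' at +x = r0."""
    return np.array([r0 - p[0], -p[1], p[2]])


def _partner_canonical(p: np.ndarray, r0: float) -> np.ndarray:
    """Partner-strand placement: the dyad image (180 deg about y) of the
    reference placement, so every pair has an exact local two-fold axis."""
    return np.array([p[0] - r0, -p[1], -p[2]])


def _pair_transform(i: int, params: HelixParams):
    rot = _rz(params.twist_deg * (i - 1))
    shift = np.array([0.0, 0.0, params.rise * (i - 1)])
    return rot, shift


def build_bdna(
    sequence: str,
    params: HelixParams = DEFAULT_HELIX,
    chain_ref: str = "B",
    chain_partner: str = "C",
) -> ComplexStructure:
    """Idealized duplex for ``sequence`` on the reference strand.

    Both strands carry backbone (P, O5', C5', C4', C3', O3', C1') and full
    base heavy atoms; the pair map and reference strand are set; atoms are
    typed against the default registry.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    n = len(sequence)
    r0 = params.c1_radius
    dna: list[Atom] = []
    pair_map = []
    for i, base in enumerate(sequence, start=1):
        rot, shift = _pair_transform(i, params)
        comp = COMPLEMENT[base]
        for name, local in _residue_local_atoms(base):
            pos = rot @ _ref_canonical(local, r0) + shift
            dna.append(Atom(chain_ref, "D" + base, i, name, name[0], pos))
        for name, local in _residue_local_atoms(comp):
            pos = rot @ _partner_canonical(local, r0) + shift
            dna.append(Atom(chain_partner, "D" + comp, n + 1 - i, name, name[0], pos))
        pair_map.append(((chain_ref, i), (chain_partner, n + 1 - i)))
    structure = ComplexStructure(
        dna_atoms=dna, pair_map=pair_map, reference_strand=chain_ref
    )
    assign_atom_types(structure, default_registry())
    return structure


def _probe_local(base: str) -> np.ndarray:
    """Probe site in the canonical frame: 2.8 A off the base's edge atom into
    the open sector of the pair plane (no other atoms of either strand there,
    and the neighboring pair planes stay a full rise away)."""
    template = dict(load_templates()["D" + base].atoms)
    handle = template[HANDLE_ATOM[base]]
    return handle + np.array([0.0, -PROBE_OFFSET, 0.0])


def _probe_atoms(position: int, base: str, params: HelixParams) -> list[Atom]:
    """Two probe atoms of one reader residue: CB at the base-specific edge
    site, a second side-chain atom at the shared glycosidic-edge site (real
    DNA readers contact a base through several heavy atoms)."""
    rot, shift = _pair_transform(position, params)
    resname = PROBE_TABLE[base][(position - 1) % 4]
    second = SECOND_PROBE_ATOM.get(resname, "CG")
    out = []
    for name, local in ((PROBE_ATOM, _probe_local(base)), (second, GLYCO_SITE)):
        pos = rot @ _ref_canonical(local, params.c1_radius) + shift
        out.append(Atom("A", resname, position, name, name[0], pos))
    return out


@dataclass(frozen=True)
class PlantedPreference:
    """Ground truth for one motif position: the base the probe rewards."""

    position: int
    base: str


def build_planted_complex(
    preferences: str,
    seed: int = 0,
    params: HelixParams = DEFAULT_HELIX,
) -> ThreadedComplex:
    """Duplex threaded with the preferred sequence plus one typed probe atom
    per position; the probe's residue type encodes the preference.

    Deterministic for given preferences (the seed is accepted for interface
    uniformity with the other generators).
    """
    preferences = preferences.upper()
    if not preferences:
        raise ValueError("need at least one position")
    structure = build_bdna(preferences, params)
    structure.protein_atoms = [
        a for i, base in enumerate(preferences, start=1)
        for a in _probe_atoms(i, base, params)
    ]
    assign_atom_types(structure, default_registry())
    return ThreadedComplex.from_structure(structure)


def make_training_corpus(
    n_complexes: int = 100,
    seed: int = 0,
    length: int = 10,
    params: HelixParams = DEFAULT_HELIX,
) -> list[ComplexStructure]:
    """Random duplexes whose probes match the bases actually present, so a
    potential trained on them rewards the planted contact geometry.

    The default corpus size gives every commonly occurring (probe type, base
    atom type) pair on the order of a hundred observed contacts, enough to
    estimate an 8-bin distance distribution without the sampling noise of a
    small corpus overwhelming the planted likelihood-ratio signal -- the
    synthetic analogue of training a knowledge-based potential on a large
    crystallographic corpus rather than a handful of structures.
    """
    if n_complexes < 1:
        raise ValueError("need at least one complex")
    rng = np.random.default_rng(seed)
    corpus = []
    for _ in range(n_complexes):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        structure = build_bdna(seq, params)
        structure.protein_atoms = [
            a for i, base in enumerate(seq, start=1)
            for a in _probe_atoms(i, base, params)
        ]
        assign_atom_types(structure, default_registry())
        corpus.append(structure)
    return corpus


def random_background(length: int, seed: int = 0) -> str:
    """Uniform i.i.d. ACGT background sequence."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def reverse_complement(sequence: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(sequence.upper()))
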