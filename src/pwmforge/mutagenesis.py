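"""In-silico base-pair mutagenesis on a fixed sugar-phosphate backbone.

Any DNA sequence can be threaded onto the duplex geometry of a crystal (or
synthetic) protein-DNA complex by replacing base moieties while keeping every
backbone and sugar atom bit-identical.  Bases are placed as rigid idealized
templates superposed on the glycosidic anchor frame of the residue being
replaced: the frame origin is C1', its x axis points along the glycosidic
bond, and the base plane is taken from the outgoing base.  Watson-Crick
complementarity is maintained on the partner strand at every substitution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace as dc_replace
from importlib import resources

import gemmi
import numpy as np

from .structure_io import (
    Atom,
    AtomTypeRegistry,
    ComplexStructure,
    DNA_BACKBONE_ATOMS,
    default_registry,
)

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: glycosidic nitrogen per base (purine N9 / pyrimidine N1)
GLYCOSIDIC_N = {"DA": "N9", "DG": "N9", "DC": "N1", "DT": "N1"}
#: in-plane ring atom defining the frame orientation
ORIENTATION_ATOM = {"DA": "C4", "DG": "C4", "DC": "C2", "DT": "C2"}

#: expected C1'-C1' separation of a Watson-Crick pair, A, and tolerance
PAIR_C1_DISTANCE = 10.4
PAIR_C1_TOLERANCE = 1.5


@dataclass(frozen=True)
class BaseTemplate:
    """Rigid heavy-atom geometry of one base in the canonical glycosidic frame
    (C1' at the origin, glycosidic N on +x, base in the z=0 plane)."""

    base: str
    atoms: tuple[tuple[str, np.ndarray], ...]  # base moiety only, no C1'
    glycosidic: str
    orientation: str


_TEMPLATES: dict[str, BaseTemplate] | None = None


def load_templates() -> dict[str, BaseTemplate]:
    """Base template library from the shipped PDB fragment file."""
    global _TEMPLATES
    if _TEMPLATES is not None:
        return _TEMPLATES
    text = resources.files("pwmforge.data").joinpath("base_templates.pdb").read_text()
    st = gemmi.read_pdb_string(text)
    out = {}
    for chain in st[0]:
        for res in chain:
            atoms = tuple(
                (a.name, np.array([a.pos.x, a.pos.y, a.pos.z], float))
                for a in res
                if a.name != "C1'"
            )
            out[res.name] = BaseTemplate(
                base=res.name[-1],
                atoms=atoms,
                glycosidic=GLYCOSIDIC_N[res.name],
                orientation=ORIENTATION_ATOM[res.name],
            )
    assert set(out) == {"DA", "DC", "DG", "DT"}
    _TEMPLATES = out
    return out


def anchor_frame(residue_atoms: list[Atom]) -> tuple[np.ndarray, np.ndarray]:
    """(origin, rotation) of the glycosidic frame of a nucleotide residue."""
    byname = {a.atom_name: a.position for a in residue_atoms}
    resname = residue_atoms[0].residue_name
    try:
        c1 = byname["C1'"]
        g = byname[GLYCOSIDIC_N[resname]]
        o = byname[ORIENTATION_ATOM[resname]]
    except KeyError as exc:
        raise ValueError(f"residue {resname} lacks anchor atom {exc}") from exc
    x = g - c1
    x = x / np.linalg.norm(x)
    v = o - c1
    z = np.cross(x, v)
    nz = np.linalg.norm(z)
    if nz < 1e-6:
        raise ValueError("degenerate base plane (anchor atoms collinear)")
    z = z / nz
    y = np.cross(z, x)
    return c1, np.column_stack([x, y, z])


@dataclass
class ThreadedComplex:
    """A complex whose DNA carries an explicit, mutable motif sequence."""

    structure: ComplexStructure
    current_sequence: str

    @property
    def n_pairs(self) -> int:
        return self.structure.n_pairs

    @classmethod
    def from_structure(
        cls, structure: ComplexStructure, registry: AtomTypeRegistry | None = None
    ) -> "ThreadedComplex":
        if not structure.pair_map:
            build_pair_map(structure)
        seq = []
        for (chain, idx), _ in structure.pair_map:
            res = structure.dna_residue(chain, idx)
            seq.append(res[0].residue_name[-1])
        return cls(structure=structure, current_sequence="".join(seq))


def _c1_position(structure: ComplexStructure, chain: str, idx: int) -> np.ndarray | None:
    for a in structure.dna_atoms:
        if a.chain_id == chain and a.residue_index == idx and a.atom_name == "C1'":
            return a.position
    return None


def build_pair_map(structure: ComplexStructure) -> list:
    """Detect Watson-Crick pairs geometrically and order them 5'->3' along the
    reference strand.

    Residues pair when their bases are complementary and the C1'-C1' distance
    lies within 10.4 +/- 1.5 A.  Unpaired interior residues (e.g. flipped-out
    bases) are excluded from the motif with a warning.
    """
    strands = structure.dna_strands()
    if len(strands) < 2:
        raise ValueError("no duplex found (need two DNA strands)")
    if len(strands) > 2:
        raise ValueError(f"expected two DNA strands, found {len(strands)}")
    chains = list(strands)
    ref = structure.reference_strand or chains[0]
    other = chains[1] if ref == chains[0] else chains[0]

    used: set[int] = set()
    pair_map = []
    lo = PAIR_C1_DISTANCE - PAIR_C1_TOLERANCE
    hi = PAIR_C1_DISTANCE + PAIR_C1_TOLERANCE
    for idx, name in strands[ref]:
        c1 = _c1_position(structure, ref, idx)
        if c1 is None:
            continue
        best = None
        for jdx, jname in strands[other]:
            if jdx in used:
                continue
            if COMPLEMENT[name[-1]] != jname[-1]:
                continue
            c1j = _c1_position(structure, other, jdx)
            if c1j is None:
                continue
            d = float(np.linalg.norm(c1 - c1j))
            if lo <= d <= hi and (best is None or d < best[1]):
                best = (jdx, d)
        if best is None:
            logger.warning("residue %s:%d has no Watson-Crick partner; excluded", ref, idx)
            continue
        used.add(best[0])
        pair_map.append(((ref, idx), (other, best[0])))
    if not pair_map:
        raise ValueError("no duplex found (no Watson-Crick pairs detected)")
    structure.pair_map = pair_map
    structure.reference_strand = ref
    return pair_map


def _replace_base(
    structure: ComplexStructure,
    chain: str,
    idx: int,
    new_resname: str,
    registry: AtomTypeRegistry,
) -> dict[tuple[str, int], list[Atom]]:
    """New atom list for one residue with its base swapped; backbone position
    arrays are reused untouched."""
    old = structure.dna_residue(chain, idx)
    origin, rot = anchor_frame(old)
    template = load_templates()[new_resname]
    atoms: list[Atom] = []
    for a in old:
        if a.atom_name in DNA_BACKBONE_ATOMS:
            atoms.append(
                Atom(a.chain_id, new_resname, a.residue_index, a.atom_name,
                     a.element, a.position,
                     registry.type_of(new_resname, a.atom_name))
            )
    for name, local in template.atoms:
        pos = origin + rot @ local
        atoms.append(
            Atom(chain, new_resname, idx, name, name[0], pos,
                 registry.type_of(new_resname, name))
        )
    return atoms


def mutate_base_pair(
    complex_: ThreadedComplex,
    position: int,
    base: str,
    registry: AtomTypeRegistry | None = None,
) -> ThreadedComplex:
    """Substitute the base pair at motif ``position`` (1-based) for ``base`` on
    the reference strand and its complement on the partner strand.

    Backbone and sugar atoms keep bit-identical coordinates; base atoms of
    both partners are replaced by rigid templates superposed on the anchor
    frame of the outgoing bases.
    """
    base = base.upper()
    if base not in COMPLEMENT:
        raise ValueError(f"invalid base {base!r}")
    n = complex_.n_pairs
    if not 1 <= position <= n:
        raise IndexError(f"position {position} out of range 1..{n}")
    registry = registry or default_registry()
    structure = complex_.structure
    (rc, ri), (pc, pi) = structure.pair_map[position - 1]
    new_residues = {}
    new_residues[(rc, ri)] = _replace_base(structure, rc, ri, "D" + base, registry)
    new_residues[(pc, pi)] = _replace_base(structure, pc, pi, "D" + COMPLEMENT[base], registry)

    new_dna: list[Atom] = []
    emitted: set[tuple[str, int]] = set()
    for a in structure.dna_atoms:
        key = (a.chain_id, a.residue_index)
        if key in new_residues:
            if key not in emitted:
                new_dna.extend(new_residues[key])
                emitted.add(key)
            continue
        new_dna.append(a)
    new_structure = ComplexStructure(
        protein_atoms=structure.protein_atoms,
        dna_atoms=new_dna,
        pair_map=structure.pair_map,
        reference_strand=structure.reference_strand,
    )
    seq = complex_.current_sequence
    new_seq = seq[: position - 1] + base + seq[position:]
    return ThreadedComplex(structure=new_structure, current_sequence=new_seq)


def thread_sequence(
    complex_: ThreadedComplex,
    sequence: str,
    registry: AtomTypeRegistry | None = None,
) -> ThreadedComplex:
    """Thread a full sequence: compose base-pair substitutions over all motif
    positions (deterministic; order-independent across distinct positions)."""
    sequence = sequence.upper()
    if len(sequence) != complex_.n_pairs:
        raise ValueError(
            f"sequence length {len(sequence)} != motif length {complex_.n_pairs}"
        )
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    registry = registry or default_registry()
    out = complex_
    for pos, base in enumerate(sequence, start=1):
        out = mutate_base_pair(out, pos, base, registry)
    return out


def rmsd(atoms_a, atoms_b) -> float:
    """Root-mean-square deviation of two matched coordinate lists, without
    superposition (the structures are assumed to share a frame)."""
    a = np.asarray(atoms_a, float)
    b = np.asarray(atoms_b, float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate lists differ in shape: {a.shape} vs {b.shape}")
    return float(math.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def c4_rmsd(a: ThreadedComplex, b: ThreadedComplex, which: str = "sugar") -> float:
    """RMSD over the C4 atom subset of the DNA, between two threadings of the
    same duplex.

    ``which='sugar'`` uses the backbone C4' atom (shared by all residues and
    held fixed by the mutagenesis, so this measures mutation fidelity the way
    a fixed-backbone protocol is usually audited); ``which='base'`` uses the
    base-ring C4 atom, which necessarily jumps on purine<->pyrimidine swaps.
    """
    name = {"sugar": "C4'", "base": "C4"}[which]

    def collect(tc: ThreadedComplex) -> np.ndarray:
        pts = []
        for key in sorted({(x.chain_id, x.residue_index) for x in tc.structure.dna_atoms}):
            for atom in tc.structure.dna_residue(*key):
                if atom.atom_name == name:
                    pts.append(atom.position)
        return np.asarray(pts)

    return rmsd(collect(a), collect(b))
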