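"""Reading, typing and interface analysis of protein-DNA co-complex structures.

The scoring machinery downstream works on heavy atoms only, typed in a
residue-specific manner: the same atom name in two different residues (ALA:CB
vs LEU:CB) is a different chemical type.  The type registry is an explicit,
editable table shipped with the package (``data/atom_types.tsv``) covering the
20 standard amino acids and the four deoxynucleotides.

Hydrogens, waters and hetero ligands are excluded on parsing; only the first
alternate location of each atom is kept.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

#: three-letter codes accepted as protein residues
PROTEIN_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
#: accepted DNA residue spellings, normalized to the two-letter form
DNA_RESIDUE_ALIASES = {
    "DA": "DA", "DC": "DC", "DG": "DG", "DT": "DT",
    "A": "DA", "C": "DC", "G": "DG", "T": "DT",
}
WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: atom names that constitute the fixed sugar-phosphate backbone of a nucleotide
DNA_BACKBONE_ATOMS = frozenset("P OP1 OP2 O5' C5' C4' O4' C3' O3' C2' C1'".split())


@dataclass
class Atom:
    """A heavy atom with residue context and Cartesian coordinates in A."""

    chain_id: str
    residue_name: str
    residue_index: int
    atom_name: str
    element: str
    position: np.ndarray
    type_id: int | None = None

    def distance_to(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.position - other.position))


@dataclass
class Contact:
    """A protein-DNA heavy-atom pair closer than the interface cutoff."""

    protein_atom: Atom
    dna_atom: Atom
    d: float


@dataclass
class ComplexStructure:
    """Typed heavy atoms of one protein-DNA co-complex.

    ``pair_map`` lists Watson-Crick pairs as ``((chain, resindex),
    (chain, resindex))`` tuples ordered 5'->3' along ``reference_strand``;
    it is filled in by :func:`pwmforge.mutagenesis.build_pair_map`.
    """

    protein_atoms: list[Atom] = field(default_factory=list)
    dna_atoms: list[Atom] = field(default_factory=list)
    pair_map: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)
    reference_strand: str | None = None
    n_untyped_dropped: int = 0

    @property
    def n_protein(self) -> int:
        return len(self.protein_atoms)

    @property
    def n_dna(self) -> int:
        return len(self.dna_atoms)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_map)

    def dna_strands(self) -> dict[str, list[tuple[int, str]]]:
        """Ordered ``(residue_index, residue_name)`` per DNA chain (author order)."""
        strands: dict[str, dict[int, str]] = {}
        for a in self.dna_atoms:
            strands.setdefault(a.chain_id, {})[a.residue_index] = a.residue_name
        return {
            ch: sorted(residues.items())
            for ch, residues in sorted(strands.items())
        }

    def dna_residue(self, chain_id: str, residue_index: int) -> list[Atom]:
        return [
            a for a in self.dna_atoms
            if a.chain_id == chain_id and a.residue_index == residue_index
        ]

    def protein_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.protein_atoms], float).reshape(-1, 3)

    def dna_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.dna_atoms], float).reshape(-1, 3)


class AtomTypeRegistry:
    """Injective (residue_name, atom_name) -> type_id map, loaded from TSV.

    Protein and DNA types live in disjoint integer namespaces.
    """

    def __init__(self, rows: list[tuple[str, str, int, str]]):
        self._map: dict[tuple[str, str], int] = {}
        self.roles: dict[int, str] = {}
        for res, name, tid, role in rows:
            key = (res, name)
            if key in self._map:
                raise ValueError(f"duplicate registry entry {key}")
            self._map[key] = tid
            self.roles[tid] = role

    @classmethod
    def from_tsv(cls, text: str) -> "AtomTypeRegistry":
        rows = []
        for line in text.splitlines()[1:]:
            if not line.strip():
                continue
            res, name, tid, role = line.split("\t")
            rows.append((res, name, int(tid), role))
        return cls(rows)

    @classmethod
    def default(cls) -> "AtomTypeRegistry":
        text = resources.files("pwmforge.data").joinpath("atom_types.tsv").read_text()
        return cls.from_tsv(text)

    def type_of(self, residue_name: str, atom_name: str) -> int | None:
        return self._map.get((residue_name, atom_name))

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


_DEFAULT_REGISTRY: AtomTypeRegistry | None = None


def default_registry() -> AtomTypeRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = AtomTypeRegistry.default()
    return _DEFAULT_REGISTRY


def _vdw_radii() -> dict[str, float]:
    text = resources.files("pwmforge.data").joinpath("vdw_radii.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            el, r = line.split("\t")
            out[el] = float(r)
    return out


def read_complex(
    pdb_text: str,
    model_index: int = 0,
    chain_filter: set[str] | None = None,
    require_both: bool = True,
) -> ComplexStructure:
    """Parse a protein-DNA complex from PDB-format text.

    Keeps heavy atoms of standard amino acids and deoxynucleotides (``DA``/
    ``DC``/``DG``/``DT`` or single-letter spellings); waters, hetero ligands,
    hydrogens and non-first alternate locations are excluded.  Residues with
    unknown names are skipped with a logged warning.

    Raises
    ------
    ValueError
        If no protein chain or no DNA chain remains after filtering.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no ATOM records found")
    if model_index >= len(st):
        raise ValueError(f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    protein: list[Atom] = []
    dna: list[Atom] = []
    seen: set[tuple[str, int, str]] = set()
    skipped_residues: set[str] = set()
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            rname = res.name.strip()
            if rname in WATER_RESIDUES:
                continue
            if rname in PROTEIN_RESIDUES:
                target, norm_name = protein, rname
            elif rname in DNA_RESIDUE_ALIASES:
                target, norm_name = dna, DNA_RESIDUE_ALIASES[rname]
            else:
                skipped_residues.add(rname)
                continue
            for atom in res:
                if atom.element.name in ("H", "D"):
                    continue
                key = (chain.name, res.seqid.num, atom.name)
                if key in seen:  # keep first altloc only
                    continue
                seen.add(key)
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z], float)
                if not np.all(np.isfinite(pos)):
                    raise ValueError(f"non-finite coordinates for atom {key}")
                target.append(
                    Atom(chain.name, norm_name, res.seqid.num, atom.name,
                         atom.element.name, pos)
                )
    if skipped_residues:
        logger.warning("skipped unknown residues: %s", ", ".join(sorted(skipped_residues)))
    if require_both and (not protein or not dna):
        raise ValueError("not a protein-DNA complex (missing protein or DNA chain)")
    if not protein and not dna:
        raise ValueError("no recognizable protein or DNA atoms")
    return ComplexStructure(protein_atoms=protein, dna_atoms=dna)


def write_complex(structure: ComplexStructure) -> str:
    """Serialize a structure back to PDB-format text (fixed 1e-3 A precision)."""
    grouped: dict[str, dict[int, list[Atom]]] = {}
    for atom in structure.protein_atoms + structure.dna_atoms:
        grouped.setdefault(atom.chain_id, {}).setdefault(atom.residue_index, []).append(atom)
    st = gemmi.Structure()
    st.name = "pwmforge"
    model = gemmi.Model("1")
    for chain_id, residues in grouped.items():
        chain = gemmi.Chain(chain_id)
        for idx in sorted(residues):
            res = gemmi.Residue()
            res.name = residues[idx][0].residue_name
            res.seqid = gemmi.SeqId(idx, " ")
            for atom in residues[idx]:
                g = gemmi.Atom()
                g.name = atom.atom_name
                g.pos = gemmi.Position(*atom.position)
                g.element = gemmi.Element(atom.element)
                res.add_atom(g)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st.make_pdb_string()


def assign_atom_types(
    structure: ComplexStructure,
    table: AtomTypeRegistry | None = None,
) -> ComplexStructure:
    """Attach a ``type_id`` to every atom; atoms absent from the registry are
    dropped and counted in ``structure.n_untyped_dropped``."""
    table = table or default_registry()
    dropped = 0
    for attr in ("protein_atoms", "dna_atoms"):
        kept = []
        for atom in getattr(structure, attr):
            tid = table.type_of(atom.residue_name, atom.atom_name)
            if tid is None:
                dropped += 1
                continue
            atom.type_id = tid
            kept.append(atom)
        setattr(structure, attr, kept)
    structure.n_untyped_dropped = dropped
    if dropped:
        logger.warning("dropped %d atoms with no registry entry", dropped)
    return structure


def interface_contacts(structure: ComplexStructure, cutoff: float = 10.0) -> list[Contact]:
    """All protein-DNA atom pairs with Euclidean distance strictly below
    ``cutoff``, ordered by (protein atom index, DNA atom index)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not structure.protein_atoms or not structure.dna_atoms:
        return []
    dmat = cdist(structure.protein_coords(), structure.dna_coords())
    pi, di = np.nonzero(dmat < cutoff)
    return [
        Contact(structure.protein_atoms[p], structure.dna_atoms[d], float(dmat[p, d]))
        for p, d in zip(pi.tolist(), di.tolist())
    ]


def vdw_repulsion(structure: ComplexStructure, cutoff: float = 10.0) -> float:
    """Purely repulsive steric score over interface pairs.

    Per pair: ``max(0, (r_min/d)^12 - 1)`` with ``r_min`` the sum of the two
    element radii.  Zero for clash-free interfaces; higher is worse.  Used to
    rank alternative crystal structures of the same complex before scoring.
    """
    radii = _vdw_radii()
    total = 0.0
    for c in interface_contacts(structure, cutoff):
        rmin = radii.get(c.protein_atom.element, 1.7) + radii.get(c.dna_atom.element, 1.7)
        if c.d < rmin:
            total += (rmin / c.d) ** 12 - 1.0
    return total
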