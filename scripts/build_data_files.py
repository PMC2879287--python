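"""Regenerate the data files shipped with pwmforge.

Writes, under src/pwmforge/data/:

* ``base_templates.pdb`` -- idealized planar heavy-atom geometries of the four
  deoxynucleotide bases in the canonical glycosidic frame (C1' at the origin,
  glycosidic nitrogen on +x, base in the z=0 plane, orientation atom at y>0).
  Rings are regular polygons (hexagon side 1.39 A, pentagon side 1.38 A) with
  exocyclic substituents placed radially (1.35 A, methyl 1.50 A).
* ``atom_types.tsv`` -- the residue-specific heavy-atom type registry for the
  20 standard amino acids and the four deoxynucleotides.
* ``vdw_radii.tsv`` -- per-element van der Waals radii used by the steric
  pre-screen.

The geometry here is a deterministic idealization, not a crystallographic
library; distances that matter downstream (glycosidic bond 1.48 A, ring reach)
are in the right range for a contact potential with a 10 A cutoff.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

DATA = Path(__file__).resolve().parents[1] / "src" / "pwmforge" / "data"

GLYCO = 1.48   # C1'-N glycosidic bond length, A
HEX = 1.39     # aromatic six-ring side, A
PENT = 1.38    # five-ring side, A
SUB = 1.35     # exocyclic N/O bond, A
METHYL = 1.50  # C5-C7 methyl bond of thymine, A


def _rot(v, deg):
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _ring(center, first_vertex, n, step_deg):
    """Vertices of a regular ring starting at first_vertex, stepping by step_deg."""
    out = [np.asarray(first_vertex, float)]
    rel = np.asarray(first_vertex, float) - center
    for _ in range(n - 1):
        rel = _rot(rel, step_deg)
        out.append(center + rel)
    return out


def _sub(host, center, bond=SUB):
    u = (host - center) / np.linalg.norm(host - center)
    return host + bond * u


def pyrimidine():
    """Ring atoms N1 C2 N3 C4 C5 C6; glycosidic N1; orientation atom C2 (y>0)."""
    n1 = np.array([GLYCO, 0.0])
    center = np.array([GLYCO + HEX, 0.0])
    # N1 sits at 180 deg from the center; stepping -60 deg walks N1->C2->...->C6
    # with C2 at 120 deg (positive y).
    verts = _ring(center, n1, 6, -60.0)
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    return dict(zip(names, verts)), center


def purine():
    """Fused 5+6 ring; glycosidic N9; orientation atom C4 (y>0)."""
    n9 = np.array([GLYCO, 0.0])
    r5 = PENT / (2.0 * math.sin(math.pi / 5.0))
    c5ring = np.array([GLYCO + r5, 0.0])
    # N9 at 180 deg; stepping -72 deg walks N9->C4->C5->N7->C8, C4 at y>0.
    five = _ring(c5ring, n9, 5, -72.0)
    names5 = ["N9", "C4", "C5", "N7", "C8"]
    atoms = dict(zip(names5, five))
    c4, c5 = atoms["C4"], atoms["C5"]
    mid = 0.5 * (c4 + c5)
    apothem = np.linalg.norm(c5 - c4) * math.sqrt(3.0) / 2.0
    u = (mid - c5ring) / np.linalg.norm(mid - c5ring)
    c6ring = mid + apothem * u
    # Walk the six-ring from C4 away from C5: C4 -> N3 -> C2 -> N1 -> C6 -> C5.
    rel = c4 - c6ring
    step = -60.0 if np.allclose(_rot(rel, 60.0) + c6ring, c5, atol=1e-6) else 60.0
    six = _ring(c6ring, c4, 6, step)
    for name, v in zip(["C4", "N3", "C2", "N1", "C6", "C5x"], six):
        if name not in ("C4", "C5x"):
            atoms[name] = v
    assert np.allclose(six[5], c5, atol=1e-6)
    return atoms, c5ring, c6ring


def build_templates():
    py, py_center = pyrimidine()
    pu, _, pu6 = purine()
    t = {}
    t["DC"] = dict(py)
    t["DC"]["O2"] = _sub(py["C2"], py_center)
    t["DC"]["N4"] = _sub(py["C4"], py_center)
    t["DT"] = dict(py)
    t["DT"]["O2"] = _sub(py["C2"], py_center)
    t["DT"]["O4"] = _sub(py["C4"], py_center)
    t["DT"]["C7"] = _sub(py["C5"], py_center, METHYL)
    t["DA"] = dict(pu)
    t["DA"]["N6"] = _sub(pu["C6"], pu6)
    t["DG"] = dict(pu)
    t["DG"]["O6"] = _sub(pu["C6"], pu6)
    t["DG"]["N2"] = _sub(pu["C2"], pu6)
    return t


def write_templates(templates):
    lines = ["REMARK   idealized base templates, canonical glycosidic frame",
             "REMARK   C1' at origin, glycosidic N on +x, base plane z=0"]
    serial = 1
    for i, res in enumerate(["DA", "DC", "DG", "DT"], start=1):
        atoms = [("C1'", np.array([0.0, 0.0]))] + list(templates[res].items())
        for name, xy in atoms:
            el = name[0]
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{res:>3s} T{i:4d}    "
                f"{xy[0]:8.3f}{xy[1]:8.3f}{0.0:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {el:>2s}"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    (DATA / "base_templates.pdb").write_text("\n".join(lines) + "\n")


AA_ATOMS = {
    "ALA": "N CA C O CB",
    "ARG": "N CA C O CB CG CD NE CZ NH1 NH2",
    "ASN": "N CA C O CB CG OD1 ND2",
    "ASP": "N CA C O CB CG OD1 OD2",
    "CYS": "N CA C O CB SG",
    "GLN": "N CA C O CB CG CD OE1 NE2",
    "GLU": "N CA C O CB CG CD OE1 OE2",
    "GLY": "N CA C O",
    "HIS": "N CA C O CB CG ND1 CD2 CE1 NE2",
    "ILE": "N CA C O CB CG1 CG2 CD1",
    "LEU": "N CA C O CB CG CD1 CD2",
    "LYS": "N CA C O CB CG CD CE NZ",
    "MET": "N CA C O CB CG SD CE",
    "PHE": "N CA C O CB CG CD1 CD2 CE1 CE2 CZ",
    "PRO": "N CA C O CB CG CD",
    "SER": "N CA C O CB OG",
    "THR": "N CA C O CB OG1 CG2",
    "TRP": "N CA C O CB CG CD1 CD2 NE1 CE2 CE3 CZ2 CZ3 CH2",
    "TYR": "N CA C O CB CG CD1 CD2 CE1 CE2 CZ OH",
    "VAL": "N CA C O CB CG1 CG2",
}

DNA_BACKBONE = "P OP1 OP2 O5' C5' C4' O4' C3' O3' C2' C1'"
DNA_BASE = {
    "DA": "N9 C8 N7 C5 C4 N3 C2 N1 C6 N6",
    "DC": "N1 C2 N3 C4 C5 C6 O2 N4",
    "DG": "N9 C8 N7 C5 C4 N3 C2 N1 C6 O6 N2",
    "DT": "N1 C2 N3 C4 C5 C6 O2 O4 C7",
}


def write_registry():
    rows = []
    tid = 0
    for res in sorted(AA_ATOMS):
        for name in AA_ATOMS[res].split():
            rows.append((res, name, tid, "protein"))
            tid += 1
    tid = 1000  # disjoint namespace for nucleic-acid types
    for res in sorted(DNA_BASE):
        for name in (DNA_BACKBONE + " " + DNA_BASE[res]).split():
            rows.append((res, name, tid, "dna"))
            tid += 1
    with open(DATA / "atom_types.tsv", "w") as fh:
        fh.write("residue_name\tatom_name\ttype_id\trole\n")
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return rows


def write_vdw():
    radii = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80}
    with open(DATA / "vdw_radii.tsv", "w") as fh:
        fh.write("element\tradius\n")
        for el, r in radii.items():
            fh.write(f"{el}\t{r}\n")


def diagnostics(templates):
    comp = {"DA": "DT", "DT": "DA", "DC": "DG", "DG": "DC"}
    for r0 in (5.2, 5.4, 5.6):
        worst = 1e9
        for res, partner in comp.items():
            a = np.array([[r0 - x, -y] for x, y in templates[res].values()])
            b = np.array([[x - r0, -y] for x, y in templates[partner].values()])
            d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
            worst = min(worst, d.min())
        print(f"R0={r0}: C1'-C1'={2*r0:.1f}  min cross-pair atom distance={worst:.2f}")
    for res, atoms in templates.items():
        reach = max(np.linalg.norm(v) for v in atoms.values())
        print(f"{res}: {len(atoms)+1} atoms, max reach from C1' = {reach:.2f} A")


if __name__ == "__main__":
    DATA.mkdir(parents=True, exist_ok=True)
    templates = build_templates()
    write_templates(templates)
    rows = write_registry()
    write_vdw()
    print(f"registry entries: {len(rows)}")
    diagnostics(templates)
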