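"""Coordinate and trajectory I/O.

Extended XYZ (with a ``Lattice="..."`` comment entry for periodic
systems and a ``solute=...`` index list) is the package's native
coordinate format; multi-frame files serve as trajectories.  PDB files
are read/written through biotite when it is available.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .potentials import AlchemicalSystem

__all__ = ["write_xyz", "read_xyz", "read_pdb", "write_pdb"]


def _comment_line(system: AlchemicalSystem) -> str:
    parts = []
    if system.box is not None:
        flat = " ".join(f"{v:.10g}" for v in system.box.ravel())
        parts.append(f'Lattice="{flat}"')
    parts.append('Properties=species:S:1:pos:R:3')
    if system.solute:
        parts.append("solute=" + ",".join(str(i) for i in sorted(system.solute)))
    parts.append(f"lambda={system.lam:.10g}")
    return " ".join(parts)


def write_xyz(path: str | Path, systems: AlchemicalSystem | Sequence[AlchemicalSystem],
              append: bool = False) -> None:
    """Write one or more frames as extended XYZ."""
    if isinstance(systems, AlchemicalSystem):
        systems = [systems]
    lines = []
    for s in systems:
        lines.append(str(s.n_atoms))
        lines.append(_comment_line(s))
        for sp, (x, y, z) in zip(s.species, s.positions):
            lines.append(f"{sp} {x:.10f} {y:.10f} {z:.10f}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> list[AlchemicalSystem]:
    """Read all frames of an (extended) XYZ file."""
    text = Path(path).read_text().splitlines()
    frames: list[AlchemicalSystem] = []
    i = 0
    while i < len(text):
        line = text[i].strip()
        if not line:
            i += 1
            continue
        n = int(line)
        comment = text[i + 1]
        species, pos = [], []
        for row in text[i + 2 : i + 2 + n]:
            toks = row.split()
            species.append(toks[0])
            pos.append([float(v) for v in toks[1:4]])
        box = None
        m = re.search(r'Lattice="([^"]+)"', comment)
        if m:
            box = np.array([float(v) for v in m.group(1).split()]).reshape(3, 3)
        solute: frozenset[int] = frozenset()
        m = re.search(r"solute=([\d,]+)", comment)
        if m:
            solute = frozenset(int(v) for v in m.group(1).split(","))
        lam = 1.0
        m = re.search(r"lambda=([0-9.eE+-]+)", comment)
        if m:
            lam = float(m.group(1))
        frames.append(
            AlchemicalSystem(positions=np.array(pos), species=tuple(species),
                             solute=solute, lam=lam, box=box)
        )
        i += 2 + n
    return frames


def read_pdb(path: str | Path, solute_resname: str | None = None,
             solute_indices: Sequence[int] | None = None,
             lam: float = 1.0) -> AlchemicalSystem:
    """Read a single-model PDB; select the solute by residue name or indices."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1)
    species = tuple(str(e).capitalize() for e in atoms.element)
    pos = np.asarray(atoms.coord, dtype=float)
    box = None
    try:
        b = f.get_structure(model=1).box
        if b is not None:
            box = np.asarray(b, dtype=float)
    except Exception:
        box = None
    if solute_indices is not None:
        solute = frozenset(int(i) for i in solute_indices)
    elif solute_resname is not None:
        solute = frozenset(int(i) for i in np.where(atoms.res_name == solute_resname)[0])
    else:
        solute = frozenset()
    return AlchemicalSystem(positions=pos, species=species, solute=solute, lam=lam, box=box)


def write_pdb(path: str | Path, system: AlchemicalSystem, resname: str = "MOL") -> None:
    """Write a minimal single-model PDB."""
    lines = []
    if system.box is not None:
        a, b, c = np.diag(system.box)
        lines.append(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1")
    for i, (sp, (x, y, z)) in enumerate(zip(system.species, system.positions), start=1):
        rn = "SOL" if (i - 1) not in system.solute else resname
        lines.append(
            f"HETATM{i:5d} {sp:<4}{rn:<4}A{i:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00          {sp:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
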