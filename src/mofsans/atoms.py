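"""Atomic coordinate sets read from PDB files.

Only heavy atoms are kept; hydrogens are carried as per-heavy-atom implicit
counts assigned from residue templates, with the labile (N/O/S-bound)
hydrogens flagged separately so H/D exchange can be applied downstream.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

from .nsld_tables import B_COHERENT_FM, RESIDUE_H_TEMPLATES

__all__ = ["AtomSet", "read_atoms", "write_pdb"]


@dataclasses.dataclass
class AtomSet:
    """Heavy atoms with implicit-hydrogen bookkeeping.

    Attributes
    ----------
    positions : (N, 3) ndarray
        Cartesian coordinates, Angstrom.
    elements : (N,) ndarray of str
        Element symbols.
    h_counts : (N,) ndarray of int
        Implicit hydrogens bound to each heavy atom.
    exchangeable_counts : (N,) ndarray of int
        How many of those hydrogens are labile (bound to N, O or S).
    """

    positions: np.ndarray
    elements: np.ndarray
    h_counts: np.ndarray
    exchangeable_counts: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.elements = np.asarray(self.elements, dtype=object)
        self.h_counts = np.asarray(self.h_counts, dtype=int)
        self.exchangeable_counts = np.asarray(self.exchangeable_counts, dtype=int)
        n = len(self.positions)
        if not (len(self.elements) == len(self.h_counts)
                == len(self.exchangeable_counts) == n):
            raise ValueError("AtomSet arrays must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if np.any(self.exchangeable_counts > self.h_counts):
            raise ValueError("exchangeable H cannot exceed bound H")
        bad = [e for e in set(self.elements) if e.upper() not in B_COHERENT_FM]
        if bad:
            raise ValueError(f"unknown element symbols: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def rg(self) -> float:
        """Unweighted coordinate radius of gyration, Angstrom."""
        d2 = ((self.positions - self.centroid) ** 2).sum(axis=1)
        return float(np.sqrt(d2.mean()))

    def bounding_radius(self) -> float:
        """Maximum distance of any atom from the centroid, Angstrom."""
        d2 = ((self.positions - self.centroid) ** 2).sum(axis=1)
        return float(np.sqrt(d2.max()))

    def recentered(self) -> "AtomSet":
        return self.transformed(np.eye(3), -self.centroid)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomSet":
        """Rigid transform x -> R x + t, returning a new AtomSet."""
        pos = self.positions @ np.asarray(rotation).T + np.asarray(translation)
        return AtomSet(pos, self.elements.copy(), self.h_counts.copy(),
                       self.exchangeable_counts.copy())


def read_atoms(path: str | Path, add_hydrogens: bool = True,
               chain: str | None = None) -> AtomSet:
    """Read heavy atoms from a PDB file.

    Parameters
    ----------
    path : path to a PDB file with ATOM/HETATM records
    add_hydrogens : bool
        Assign implicit H counts from per-residue templates.  Unknown
        residues raise a warning and get zero implicit hydrogens.
    chain : str, optional
        Keep only this chain identifier.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    positions, elements, h_counts, x_counts = [], [], [], []
    warned: set[str] = set()
    for model in structure:
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for residue in ch:
                resname = residue.get_resname().strip()
                template = RESIDUE_H_TEMPLATES.get(resname)
                for atom in residue:
                    element = (atom.element or "").strip().upper() or atom.get_name()[0]
                    if element in ("H", "D"):
                        continue
                    positions.append(atom.get_coord())
                    elements.append(element)
                    if add_hydrogens:
                        if template is None:
                            if resname not in warned:
                                warnings.warn(
                                    f"unknown residue {resname!r}: assigning 0 implicit H",
                                    stacklevel=2,
                                )
                                warned.add(resname)
                            nh, nx = 0, 0
                        else:
                            nh, nx = template.get(atom.get_name().strip(), (0, 0))
                    else:
                        nh, nx = 0, 0
                    h_counts.append(nh)
                    x_counts.append(nx)
        break  # first model only
    if not positions:
        raise ValueError(f"{path}: no ATOM/HETATM records" +
                         (f" for chain {chain!r}" if chain else ""))
    return AtomSet(np.array(positions), np.array(elements, dtype=object),
                   np.array(h_counts), np.array(x_counts))


def write_pdb(atoms: AtomSet, path: str | Path, resname: str = "UNK") -> None:
    """Write an AtomSet as minimal fixed-column ATOM records.

    Implicit-H bookkeeping is not representable in PDB; files written here
    are for coordinate interchange and should be re-read with
    ``add_hydrogens=False``.
    """
    with Path(path).open("w") as fh:
        for i, (pos, el) in enumerate(zip(atoms.positions, atoms.elements), start=1):
            name = el.upper()[:2].rjust(2) + "  "
            fh.write(
                "ATOM  {serial:>5d} {name:<4s}{res:>4s} A{resseq:>4d}    "
                "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n".format(
                    serial=i % 100000, name=name, res=resname,
                    resseq=(i - 1) % 9999 + 1,
                    x=pos[0], y=pos[1], z=pos[2], occ=1.0, b=0.0,
                    el=el.upper()[:2],
                )
            )
        fh.write("END\n")
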