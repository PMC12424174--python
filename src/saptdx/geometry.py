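"""Dimer geometries and the XYZ reader.

Coordinates are stored in bohr throughout the package.  A :class:`DimerGeometry`
is a list of atoms, each carrying an element symbol, a position and a monomer
label (``"A"`` or ``"B"``).  Ghost centers (basis functions without nuclear
charge or electrons) are created on the fly by the dimer-centered-basis setup
and never appear here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ANGSTROM_TO_BOHR = 1.0 / 0.529177210903

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10,
}


@dataclass(frozen=True)
class Atom:
    symbol: str
    coord: tuple[float, float, float]

    @property
    def charge(self) -> int:
        try:
            return ATOMIC_NUMBERS[self.symbol]
        except KeyError:
            raise ValueError(f"unknown element symbol {self.symbol!r}") from None


@dataclass
class DimerGeometry:
    """A weakly bound dimer: atoms plus a per-atom monomer assignment.

    Parameters
    ----------
    atoms:
        Sequence of :class:`Atom` with coordinates in bohr.
    monomer_assignment:
        One label, ``"A"`` or ``"B"``, per atom.
    """

    atoms: list[Atom]
    monomer_assignment: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.atoms) != len(self.monomer_assignment):
            raise ValueError("one monomer label per atom is required")
        bad = set(self.monomer_assignment) - {"A", "B"}
        if bad:
            raise ValueError(f"monomer labels must be 'A' or 'B', got {bad}")
        for lab in ("A", "B"):
            if lab not in self.monomer_assignment:
                raise ValueError(f"monomer {lab} has no atoms")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        n = len(self.atoms)
        for i in range(n):
            for j in range(i + 1, n):
                if np.linalg.norm(coords[i] - coords[j]) < 1e-8:
                    raise ValueError(
                        f"atoms {i} and {j} coincide at {coords[i]}"
                    )
        # charges are implicit from the elements; validate eagerly
        for at in self.atoms:
            at.charge

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def symbols(self) -> list[str]:
        return [a.symbol for a in self.atoms]

    def monomer_indices(self, label: str) -> list[int]:
        return [i for i, lab in enumerate(self.monomer_assignment) if lab == label]

    def swapped(self) -> "DimerGeometry":
        """Return the same dimer with the A and B roles interchanged."""
        flip = {"A": "B", "B": "A"}
        return DimerGeometry(list(self.atoms), [flip[x] for x in self.monomer_assignment])

    def translated(self, shift) -> "DimerGeometry":
        shift = np.asarray(shift, dtype=float)
        atoms = [Atom(a.symbol, tuple(np.asarray(a.coord) + shift)) for a in self.atoms]
        return DimerGeometry(atoms, list(self.monomer_assignment))

    def nuclear_repulsion_between(self) -> float:
        """V_AB: Coulomb repulsion between the nuclei of A and those of B (hartree)."""
        coords = self.coords
        vab = 0.0
        for i in self.monomer_indices("A"):
            for j in self.monomer_indices("B"):
                vab += (
                    self.atoms[i].charge
                    * self.atoms[j].charge
                    / np.linalg.norm(coords[i] - coords[j])
                )
        return vab


def make_dimer(symbols, coords, labels) -> DimerGeometry:
    atoms = [Atom(s, tuple(np.asarray(c, dtype=float))) for s, c in zip(symbols, coords)]
    return DimerGeometry(atoms, list(labels))


def read_xyz(path) -> DimerGeometry:
    """Read a standard XYZ file.

    The comment line may carry ``unit=bohr`` or ``unit=angstrom`` (default
    angstrom, the common XYZ convention) and ``monomer_split=k``, meaning the
    first *k* atoms belong to monomer A.  Without a split annotation the file
    must contain exactly two atoms (one per monomer).
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    natom = int(lines[0].split()[0])
    comment = lines[1] if len(lines) > 1 else ""
    unit = "angstrom"
    split = None
    for tok in comment.split():
        if tok.startswith("unit="):
            unit = tok.split("=", 1)[1].lower()
        elif tok.startswith("monomer_split="):
            split = int(tok.split("=", 1)[1])
    if unit not in ("bohr", "angstrom"):
        raise ValueError(f"unknown unit {unit!r} in XYZ comment")
    if split is None:
        if natom == 2:
            split = 1
        else:
            raise ValueError("XYZ comment must declare monomer_split=k for >2 atoms")
    fac = 1.0 if unit == "bohr" else ANGSTROM_TO_BOHR
    symbols, coords = [], []
    for ln in lines[2 : 2 + natom]:
        parts = ln.split()
        symbols.append(parts[0])
        coords.append([float(x) * fac for x in parts[1:4]])
    labels = ["A"] * split + ["B"] * (natom - split)
    return make_dimer(symbols, coords, labels)
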