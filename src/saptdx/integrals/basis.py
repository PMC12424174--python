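"""Gaussian basis sets: parsing, normalization and spherical AO bookkeeping.

Shells are segmented contractions of primitive Cartesian Gaussians; real
spherical harmonics are formed by a fixed linear combination of Cartesian
components followed by self-normalization against the computed overlap, so
every AO has unit norm by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np

ANGMOM = {"S": 0, "P": 1, "D": 2, "F": 3}
MAX_L = 2  # all supported basis sets stop at d functions


class BasisError(ValueError):
    pass


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Monomial exponents (i, j, k), i+j+k = l, in lexicographic order."""
    return [(i, j, l - i - j) for i in range(l, -1, -1) for j in range(l - i, -1, -1)]


def n_cart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def n_sph(l: int) -> int:
    return 2 * l + 1


def cart_to_sph(l: int) -> np.ndarray:
    """Rows: real solid harmonics m = -l..l as combinations of Cartesian monomials.

    Row scale is arbitrary; contracted AOs are renormalized against the overlap
    matrix afterwards.
    """
    if l == 0:
        return np.array([[1.0]])
    if l == 1:  # cartesian order x, y, z
        return np.eye(3)
    if l == 2:  # cartesian order xx, xy, xz, yy, yz, zz
        return np.array(
            [
                [0.0, 1.0, 0.0, 0.0, 0.0, 0.0],   # xy
                [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],   # yz
                [-0.5, 0.0, 0.0, -0.5, 0.0, 1.0], # (2zz - xx - yy)/2
                [0.0, 0.0, 1.0, 0.0, 0.0, 0.0],   # xz
                [1.0, 0.0, 0.0, -1.0, 0.0, 0.0],  # xx - yy
            ]
        )
    raise BasisError(f"angular momentum l={l} not supported (max d)")


@dataclass
class Shell:
    l: int
    exps: np.ndarray
    coefs: np.ndarray  # contraction coefficients, primitive norms folded in
    center: np.ndarray
    atom_index: int

    @property
    def nprim(self) -> int:
        return len(self.exps)


def _fold_primitive_norms(l: int, exps: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    # (l,0,0)-type primitive norm up to an exponent-independent constant;
    # the constant cancels in the final AO self-normalization.
    return coefs * exps ** ((2 * l + 3) / 4.0)


def parse_basis_text(text: str) -> dict[str, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Parse the bundled basis format into {element: [(l, exps, coefs), ...]}."""
    out: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    element = None
    shell: tuple[int, list[float], list[float]] | None = None

    def flush():
        nonlocal shell
        if shell is not None:
            l, e, c = shell
            out[element].append((l, np.array(e), np.array(c)))
            shell = None

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("element"):
            flush()
            element = line.split()[1]
            out.setdefault(element, [])
        elif re.fullmatch(r"[A-Za-z]", line):
            flush()
            if element is None:
                raise BasisError("shell block before any 'element' line")
            ltok = line.upper()
            if ltok not in ANGMOM:
                raise BasisError(f"unknown shell type {ltok!r}")
            if ANGMOM[ltok] > MAX_L:
                raise BasisError(f"{ltok} shells not supported (max d)")
            shell = (ANGMOM[ltok], [], [])
        else:
            parts = line.split()
            if shell is None or len(parts) != 2:
                raise BasisError(f"malformed basis line: {raw!r}")
            shell[1].append(float(parts[0]))
            shell[2].append(float(parts[1]))
    flush()
    return out


_KNOWN_BASES = {"aug-cc-pvtz", "aug-cc-pvdz", "cc-pvdz"}


def load_basis(name_or_dict) -> dict[str, list[tuple[int, np.ndarray, np.ndarray]]]:
    """Resolve a basis by bundled name (e.g. ``aug-cc-pVTZ``) or pass a dict through."""
    if isinstance(name_or_dict, dict):
        return name_or_dict
    key = str(name_or_dict).lower()
    if key not in _KNOWN_BASES:
        raise BasisError(
            f"unknown basis {name_or_dict!r}; bundled sets: {sorted(_KNOWN_BASES)}"
        )
    text = (resources.files("saptdx.data") / f"{key}.bas").read_text()
    return parse_basis_text(text)


class BasisSet:
    """All shells for a list of centers, with spherical-AO offsets.

    ``symbols``/``coords`` include ghost centers; ghosts carry basis functions
    but no charge (charges are handled by the caller).
    """

    def __init__(self, symbols, coords, basis) -> None:
        table = load_basis(basis)
        self.shells: list[Shell] = []
        for iat, (sym, xyz) in enumerate(zip(symbols, coords)):
            if sym not in table:
                raise BasisError(f"element {sym!r} missing from basis set")
            for l, exps, coefs in table[sym]:
                self.shells.append(
                    Shell(
                        l=l,
                        exps=np.asarray(exps, dtype=float),
                        coefs=_fold_primitive_norms(l, np.asarray(exps), np.asarray(coefs)),
                        center=np.asarray(xyz, dtype=float),
                        atom_index=iat,
                    )
                )
        self.sph_offsets = np.zeros(len(self.shells) + 1, dtype=np.int64)
        for i, sh in enumerate(self.shells):
            self.sph_offsets[i + 1] = self.sph_offsets[i] + n_sph(sh.l)
        self.nao = int(self.sph_offsets[-1])

    def packed_arrays(self):
        """Flat numpy views of the shell data for the numba kernels."""
        ns = len(self.shells)
        maxprim = max(sh.nprim for sh in self.shells)
        ls = np.array([sh.l for sh in self.shells], dtype=np.int64)
        nprim = np.array([sh.nprim for sh in self.shells], dtype=np.int64)
        exps = np.zeros((ns, maxprim))
        coefs = np.zeros((ns, maxprim))
        centers = np.zeros((ns, 3))
        for i, sh in enumerate(self.shells):
            exps[i, : sh.nprim] = sh.exps
            coefs[i, : sh.nprim] = sh.coefs
            centers[i] = sh.center
        return ls, nprim, exps, coefs, centers
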