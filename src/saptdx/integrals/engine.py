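"""AO integral engine for a dimer in the dimer-centered basis (DCBS).

`DimerSystem` owns the AO-level objects every downstream step consumes: the
overlap and kinetic matrices, one nuclear-attraction matrix per monomer (so
that monomer Hamiltonians and the interaction blocks v^A/v^B can be formed
independently), and the full two-electron tensor in chemists' notation
(pq|rs).  Every atom of the dimer contributes basis functions; which nuclei
carry charge is decided by the monomer partition, which is what makes the
ghost-atom DCBS convention automatic.
"""

from __future__ import annotations

import logging

import numpy as np

from ..geometry import DimerGeometry
from .basis import BasisSet, cart_to_sph, n_cart, n_sph
from . import md

log = logging.getLogger(__name__)

LINDEP_THRESHOLD = 1e-8


def _c2s_packed():
    c2s_flat = np.zeros((3, 5, 6))
    nsph = np.zeros(3, dtype=np.int64)
    ncart = np.zeros(3, dtype=np.int64)
    for l in range(3):
        m = cart_to_sph(l)
        c2s_flat[l, : m.shape[0], : m.shape[1]] = m
        nsph[l] = n_sph(l)
        ncart[l] = n_cart(l)
    return c2s_flat, nsph, ncart


class DimerSystem:
    """AO integrals over the dimer basis plus monomer bookkeeping.

    Parameters
    ----------
    geometry:
        The dimer, coordinates in bohr.
    basis:
        Bundled basis-set name or an explicit ``{element: shells}`` table.
    """

    def __init__(self, geometry: DimerGeometry, basis) -> None:
        self.geometry = geometry
        self.basis_name = basis if isinstance(basis, str) else "custom"
        self.basis = BasisSet(geometry.symbols, geometry.coords, basis)
        self.nao = self.basis.nao
        self._eri = None
        self._build_one_electron()
        self._check_linear_dependence()

    # -- construction -------------------------------------------------------

    def _build_one_electron(self) -> None:
        shells = self.basis.shells
        nao = self.nao
        S = np.zeros((nao, nao))
        T = np.zeros((nao, nao))
        coords = self.geometry.coords
        charges = np.array([a.charge for a in self.geometry.atoms], dtype=float)
        idxA = self.geometry.monomer_indices("A")
        idxB = self.geometry.monomer_indices("B")
        VA = np.zeros((nao, nao))
        VB = np.zeros((nao, nao))
        chargesA = np.where([i in idxA for i in range(len(charges))], charges, 0.0)
        chargesB = np.where([i in idxB for i in range(len(charges))], charges, 0.0)

        # raw cartesian blocks per shell pair, then spherical + normalization
        sph_rows = []
        for sh in shells:
            sph_rows.append(cart_to_sph(sh.l))
        raw_S = [[None] * len(shells) for _ in shells]
        cart_idx = {l: np.array(md_cart(l), dtype=np.int64) for l in range(3)}
        for i, shi in enumerate(shells):
            for j, shj in enumerate(shells):
                if j > i:
                    continue
                nci, ncj = n_cart(shi.l), n_cart(shj.l)
                Sb = np.zeros((nci, ncj))
                Tb = np.zeros((nci, ncj))
                md._pair_overlap_kinetic(
                    shi.l, shj.l, shi.exps, shi.coefs, shj.exps, shj.coefs,
                    shi.center - shj.center, cart_idx[shi.l], cart_idx[shj.l], Sb, Tb,
                )
                Vb_A = np.zeros((nci, ncj))
                Vb_B = np.zeros((nci, ncj))
                md._pair_nuclear(
                    shi.l, shj.l, shi.exps, shi.coefs, shj.exps, shj.coefs,
                    shi.center, shj.center, cart_idx[shi.l], cart_idx[shj.l],
                    chargesA, coords, Vb_A,
                )
                md._pair_nuclear(
                    shi.l, shj.l, shi.exps, shi.coefs, shj.exps, shj.coefs,
                    shi.center, shj.center, cart_idx[shi.l], cart_idx[shj.l],
                    chargesB, coords, Vb_B,
                )
                oi = self.basis.sph_offsets[i]
                oj = self.basis.sph_offsets[j]
                for M, Mb in ((S, Sb), (T, Tb), (VA, Vb_A), (VB, Vb_B)):
                    blk = sph_rows[i] @ Mb @ sph_rows[j].T
                    M[oi : oi + n_sph(shi.l), oj : oj + n_sph(shj.l)] = blk
                    if i != j:
                        M[oj : oj + n_sph(shj.l), oi : oi + n_sph(shi.l)] = blk.T
        # self-normalize spherical AOs
        norms = 1.0 / np.sqrt(np.diag(S))
        self.ao_norms = norms
        for M in (S, T, VA, VB):
            M *= norms[:, None] * norms[None, :]
        self.S = S
        self.T = T
        self.Vnuc_A = VA
        self.Vnuc_B = VB

    def _check_linear_dependence(self) -> None:
        evals = np.linalg.eigvalsh(self.S)
        self.smallest_overlap_eigenvalue = float(evals[0])
        self.n_pruned = int(np.sum(evals < LINDEP_THRESHOLD))
        log.info(
            "smallest AO-overlap eigenvalue %.3e (%d vector(s) below %.0e)",
            evals[0], self.n_pruned, LINDEP_THRESHOLD,
        )
        if self.n_pruned:
            log.warning(
                "AO basis nearly linearly dependent; canonical orthogonalization "
                "will drop %d vector(s)", self.n_pruned,
            )

    @property
    def eri(self) -> np.ndarray:
        """Two-electron integrals (pq|rs), chemists' notation, full dimer basis."""
        if self._eri is None:
            ls, nprim, exps, coefs, centers = self.basis.packed_arrays()
            c2s_flat, nsph, ncart = _c2s_packed()
            raw = md.compute_eri(
                ls, nprim, exps, coefs, centers, self.basis.sph_offsets,
                c2s_flat, nsph, ncart, self.nao, 1e-13,
            )
            n = self.ao_norms
            raw *= n[:, None, None, None] * n[None, :, None, None]
            raw *= n[None, None, :, None] * n[None, None, None, :]
            self._eri = raw
        return self._eri

    # -- monomer bookkeeping ------------------------------------------------

    def n_electrons(self, label: str) -> int:
        return sum(self.geometry.atoms[i].charge
                   for i in self.geometry.monomer_indices(label))

    def core_hamiltonian(self, label: str) -> np.ndarray:
        """h = T + V_nuc(own monomer): partner atoms are ghosts for monomer SCF."""
        return self.T + (self.Vnuc_A if label == "A" else self.Vnuc_B)

    def nuclear_repulsion(self, label: str) -> float:
        idx = self.geometry.monomer_indices(label)
        coords = self.geometry.coords
        e = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                e += (self.geometry.atoms[i].charge * self.geometry.atoms[j].charge
                      / np.linalg.norm(coords[i] - coords[j]))
        return e

    def orthogonalizer(self) -> np.ndarray:
        """Canonical orthogonalization X (drops near-dependent vectors)."""
        w, V = np.linalg.eigh(self.S)
        keep = w > LINDEP_THRESHOLD
        return V[:, keep] / np.sqrt(w[keep])


def md_cart(l: int):
    return [(i, j, l - i - j) for i in range(l, -1, -1) for j in range(l - i, -1, -1)]


def build_dimer_system(geometry: DimerGeometry, basis_name) -> DimerSystem:
    """Build the dimer in the dimer-centered basis and expose its AO integrals."""
    return DimerSystem(geometry, basis_name)
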