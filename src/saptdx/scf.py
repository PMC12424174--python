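"""Restricted Hartree-Fock for a monomer in the dimer-centered basis.

The Fock operator contains only the monomer's own nuclei; partner atoms act
as ghosts (basis functions without charge), which is exactly the DCBS
convention used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SCFError(RuntimeError):
    pass


@dataclass
class RHFResult:
    energy: float          # electronic + own-monomer nuclear repulsion
    mo_coeff: np.ndarray   # (nao, nmo) in the dimer AO basis
    mo_energy: np.ndarray
    n_occ: int             # doubly occupied orbitals

    @property
    def occ_coeff(self) -> np.ndarray:
        return self.mo_coeff[:, : self.n_occ]


def rhf(h, eri, S_ao, n_elec, e_nuc=0.0, X=None, max_cycle=100, conv=1e-10):
    """Solve closed-shell RHF.

    Parameters
    ----------
    h : core Hamiltonian (kinetic + nuclear attraction of the monomer's nuclei).
    eri : AO two-electron integrals, chemists' (pq|rs).
    S_ao : AO overlap.
    n_elec : number of electrons (even).
    X : orthogonalizer; computed by canonical orthogonalization if omitted.
    """
    if n_elec % 2 or n_elec <= 0:
        raise SCFError(f"closed-shell RHF needs a positive even electron count, got {n_elec}")
    nocc = n_elec // 2
    if X is None:
        w, V = np.linalg.eigh(S_ao)
        keep = w > 1e-8
        X = V[:, keep] / np.sqrt(w[keep])

    def fock(D):
        J = np.einsum("pqrs,rs->pq", eri, D, optimize=True)
        K = np.einsum("prqs,rs->pq", eri, D, optimize=True)
        return h + 2.0 * J - K

    def density(F):
        Fo = X.T @ F @ X
        e, C = np.linalg.eigh(Fo)
        C = X @ C
        occ = C[:, :nocc]
        return occ @ occ.T, C, e

    D, C, mo_e = density(h)
    e_old = 0.0
    diis_F, diis_err = [], []
    for cycle in range(max_cycle):
        F = fock(D)
        err = F @ D @ S_ao - S_ao @ D @ F
        diis_F.append(F)
        diis_err.append(err.ravel())
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            n = len(diis_F)
            B = -np.ones((n + 1, n + 1))
            B[n, n] = 0.0
            for i in range(n):
                for j in range(n):
                    B[i, j] = diis_err[i] @ diis_err[j]
            rhs = np.zeros(n + 1)
            rhs[n] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:n]
                F = sum(ci * Fi for ci, Fi in zip(c, diis_F))
            except np.linalg.LinAlgError:
                pass
        D, C, mo_e = density(F)
        e_elec = float(np.einsum("pq,qp->", h + fock(D), D))
        if abs(e_elec - e_old) < conv and cycle > 1:
            return RHFResult(e_elec + e_nuc, C, mo_e, nocc)
        e_old = e_elec
    raise SCFError(f"RHF did not converge in {max_cycle} cycles (dE={e_elec - e_old:.2e})")
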