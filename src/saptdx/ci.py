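"""Two-electron singlet CI and variational CAS(2,n)/geminal orbital optimization.

A two-electron singlet wave function in an orthonormal orbital basis {phi_p}
is Psi = sum_pq C_pq |p_alpha q_beta> with C symmetric and ||C||_F = 1.  Its
natural expansion C = U diag(c) U^T is exactly a single APSG geminal, which is
why every monomer state in this package (FCI, GVB-PP, CAS(2,n), with or
without a frozen core) reduces to core orbitals plus one geminal.

CAS(2,n)SCF is implemented as exact variational optimization of the selected
CI root over the n-dimensional orbital span, using the Hellmann-Feynman
orbital gradient dE/dK = 4 V^T (H C) U Chat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, qr
from scipy.sparse.linalg import eigsh


class CIError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# pair-space Hamiltonian
# ---------------------------------------------------------------------------


def _pair_indices(m: int):
    iu = np.triu_indices(m)
    return iu[0], iu[1]


def pair_hamiltonian(h: np.ndarray, eri: np.ndarray) -> np.ndarray:
    """Dense singlet two-electron Hamiltonian over symmetrized pairs p<=q.

    Basis: |pp> and (|pq>+|qp>)/sqrt(2); eri is (pq|rs) over the same orbitals.
    """
    m = h.shape[0]
    pi, qi = _pair_indices(m)
    # G[p,q,r,s] = <pq|H|rs> = h_pr d_qs + d_pr h_qs + (pr|qs); the two-electron
    # part is gathered from a transposed view to avoid an m^4 copy
    eT = eri.transpose(0, 2, 1, 3)
    ri, si = pi[None, :], qi[None, :]
    li, mi = pi[:, None], qi[:, None]
    Hp = eT[li, mi, ri, si] + eT[li, mi, si, ri]
    Hp += h[li, ri] * (mi == si) + h[mi, si] * (li == ri)
    Hp += h[li, si] * (mi == ri) + h[mi, ri] * (li == si)
    # basis B_pp = |pp>, B_pq = (|pq>+|qp>)/sqrt(2) for p<q:
    # <B_pq|H|B_rs> = 2 (G_pqrs + G_pqsr) / (s_pq s_rs), s = 2 (diag), sqrt(2)
    s = np.where(pi == qi, 2.0, np.sqrt(2.0))
    Hp *= 2.0 / (s[:, None] * s[None, :])
    return Hp


def pack_C(C: np.ndarray) -> np.ndarray:
    m = C.shape[0]
    pi, qi = _pair_indices(m)
    s = np.where(pi == qi, 1.0, np.sqrt(2.0))
    return C[pi, qi] * s


def unpack_C(x: np.ndarray, m: int) -> np.ndarray:
    pi, qi = _pair_indices(m)
    s = np.where(pi == qi, 1.0, np.sqrt(2.0))
    C = np.zeros((m, m))
    C[pi, qi] = x / s
    C[qi, pi] = x / s
    return C


def sigma(C: np.ndarray, h: np.ndarray, eri: np.ndarray) -> np.ndarray:
    """(H C)_pq = sum_r h_pr C_rq + C_pr h_rq + sum_rs (pr|qs) C_rs."""
    out = h @ C + C @ h.T
    out += np.einsum("prqs,rs->pq", eri, C, optimize=True)
    return out


@dataclass
class TwoElectronState:
    """One root of a two-electron singlet CI.

    ``orbitals`` maps the CI orbital space to the dimer AO basis; ``C`` is the
    symmetric CI matrix over those orbitals.
    """

    energy: float            # electronic energy (no nuclear repulsion)
    C: np.ndarray
    orbitals: np.ndarray     # (nao, m)

    def natural_geminal(self, threshold: float = 0.0):
        """Natural expansion C = sum_i c_i |phi_i phibar_i>: (coefs, orbitals_ao)."""
        w, V = np.linalg.eigh(self.C)
        order = np.argsort(-np.abs(w))
        w, V = w[order], V[:, order]
        if threshold > 0.0:
            keep = np.abs(w) >= threshold
            w, V = w[keep], V[:, keep]
        # fix global sign: leading coefficient positive
        if w[0] < 0:
            w = -w
        return w, self.orbitals @ V


def solve_two_electron_ci(h, eri, orbitals, nroots=1, dense_cutoff=400):
    """All-orbital two-electron singlet CI; returns the lowest ``nroots`` states."""
    m = h.shape[0]
    Hp = pair_hamiltonian(h, eri)
    if Hp.shape[0] <= dense_cutoff:
        w, V = eigh(Hp)
    else:
        k = min(nroots + 4, Hp.shape[0] - 2)
        v0 = np.full(Hp.shape[0], 1.0 / np.sqrt(Hp.shape[0]))  # deterministic start
        w, V = eigsh(Hp, k=k, which="SA", v0=v0)
        order = np.argsort(w)
        w, V = w[order], V[:, order]
    states = []
    for i in range(min(nroots, len(w))):
        C = unpack_C(V[:, i], m)
        nrm = np.linalg.norm(C)
        states.append(TwoElectronState(float(w[i]), C / nrm, orbitals))
    return states


def state_parity(state: TwoElectronState, R_mo: np.ndarray) -> float:
    """<Psi| R x R |Psi> for a one-electron symmetry operation R (MO basis)."""
    C = state.C
    return float(np.sum((R_mo @ C @ R_mo.T) * C))


# ---------------------------------------------------------------------------
# CAS(2,n) / geminal subspace optimization
# ---------------------------------------------------------------------------


@dataclass
class SubspaceCIResult:
    energy: float
    C_act: np.ndarray        # (n, n) symmetric over active orbitals
    U: np.ndarray            # (m, n) active span in the working orthonormal basis
    gradient_norm: float
    n_iter: int


def _active_eri(eri, U):
    m, n = U.shape
    t = np.tensordot(eri, U, axes=([0], [0]))        # q r s a
    t = np.tensordot(t, U, axes=([0], [0]))          # r s a b
    t = np.tensordot(t, U, axes=([0], [0]))          # s a b c
    t = np.tensordot(t, U, axes=([0], [0]))          # a b c d
    return t.transpose(0, 1, 2, 3)                   # (ab|cd) index order a,b,c,d


def _solve_active(h_act, eri_act, nroots):
    Hp = pair_hamiltonian(h_act, eri_act)
    w, V = eigh(Hp)
    n = h_act.shape[0]
    roots = []
    for i in range(min(len(w), max(nroots, 1))):
        C = unpack_C(V[:, i], n)
        C /= np.linalg.norm(C)
        roots.append((float(w[i]), C))
    return roots


def optimize_subspace_ci(
    h,
    eri,
    U0,
    root_select=None,
    frozen=None,
    max_iter=300,
    gtol=1e-8,
    nroots=4,
):
    """Variationally optimize the orbital span of a two-electron CI root.

    Parameters
    ----------
    h, eri:
        One- and two-electron integrals in an orthonormal working basis of
        dimension m (for a frozen-core system, ``h`` must already contain the
        core Coulomb/exchange embedding).
    U0:
        (m, n) initial active span.
    root_select:
        ``None`` for the lowest root, an ``int`` root index, or a callable
        ``f(list[(energy, C_act)], U) -> int`` for symmetry-aware selection.
    frozen:
        Orbitals (columns in the working basis, (m, nf)) excluded from the
        active span and from its variational complement.
    """
    m, n = U0.shape
    U, _ = qr(U0, mode="economic")
    proj_frozen = None
    if frozen is not None and frozen.shape[1] > 0:
        proj_frozen = frozen @ frozen.T
        U = U - proj_frozen @ U
        U, _ = qr(U, mode="economic")

    def pick_root(roots, U):
        if root_select is None:
            return 0
        if isinstance(root_select, int):
            return root_select
        return root_select(roots, U)

    def energy_of(U):
        h_act = U.T @ h @ U
        eri_act = _active_eri(eri, U)
        roots = _solve_active(h_act, eri_act, nroots)
        k = pick_root(roots, U)
        return roots[k][0], roots[k][1]

    def gradient(U, C_act):
        Cfull = U @ C_act @ U.T
        HC = sigma(Cfull, h, eri)
        G_full = 4.0 * (HC @ (U @ C_act))         # (m, n)
        G_ext = G_full - U @ (U.T @ G_full)
        if proj_frozen is not None:
            G_ext = G_ext - proj_frozen @ G_ext
        return G_ext

    def retract(U, dU):
        U_new, _ = qr(U + dU, mode="economic")
        if proj_frozen is not None:
            U_new = U_new - proj_frozen @ U_new
            U_new, _ = qr(U_new, mode="economic")
        return U_new

    # Polak-Ribiere conjugate gradient with Armijo backtracking
    e, C_act = energy_of(U)
    g = gradient(U, C_act)
    d = -g
    step = 0.2
    gnorm = np.linalg.norm(g)
    for it in range(max_iter):
        if gnorm < gtol:
            return SubspaceCIResult(e, C_act, U, gnorm, it)
        slope = float(np.sum(g * d))
        if slope >= 0.0:          # not a descent direction: restart on -g
            d = -g
            slope = -gnorm**2
        accepted = False
        t = step
        for _ in range(40):
            U_new = retract(U, t * d)
            e_new, C_new = energy_of(U_new)
            if e_new <= e + 1e-4 * t * slope:
                accepted = True
                break
            t *= 0.5
        if not accepted or e_new > e - 1e-15:
            return SubspaceCIResult(e, C_act, U, gnorm, it)
        g_new = gradient(U_new, C_new)
        beta = max(0.0, float(np.sum(g_new * (g_new - g)) / max(np.sum(g * g), 1e-300)))
        # transport the direction naively and re-project on the external space
        d = -g_new + beta * d
        d = d - U_new @ (U_new.T @ d)
        if proj_frozen is not None:
            d = d - proj_frozen @ d
        step = min(max(2.0 * t, 1e-3), 5.0)
        U, e, C_act, g = U_new, e_new, C_new, g_new
        gnorm = np.linalg.norm(g)
        if it >= 20 and gnorm < 1e-3:
            break  # switch to the quasi-Newton polish
    # re-centered L-BFGS polish: exact gradient at K = 0, pullback elsewhere
    from scipy.optimize import minimize as _minimize

    for _macro in range(6):
        if gnorm < gtol:
            break
        Qfull, _ = qr(U)              # full m x m orthogonal factor
        Vc = Qfull[:, n:]             # orthonormal complement of span(U)
        if proj_frozen is not None:
            Vc = Vc - proj_frozen @ Vc
            Vc, _ = qr(Vc, mode="economic")

        def fun(kflat):
            K = kflat.reshape(Vc.shape[1], n)
            U_k = retract(U, Vc @ K)
            e_k, C_k = energy_of(U_k)
            G = gradient(U_k, C_k)
            return e_k, (Vc.T @ G).ravel()

        res = _minimize(fun, np.zeros(Vc.shape[1] * n), jac=True,
                        method="L-BFGS-B",
                        options={"maxiter": 60, "ftol": 1e-16, "gtol": 0.1 * gtol})
        U = retract(U, Vc @ res.x.reshape(Vc.shape[1], n))
        e, C_act = energy_of(U)
        g = gradient(U, C_act)
        gnorm = np.linalg.norm(g)
    return SubspaceCIResult(e, C_act, U, gnorm, max_iter)


def core_embedded_h(h, eri, core_coeff):
    """Effective one-electron Hamiltonian with doubly occupied core orbitals.

    Returns (h_eff, E_core): h_eff = h + 2 J_core - K_core over the working
    basis; E_core is the core electronic energy.
    """
    Dc = core_coeff @ core_coeff.T
    J = np.einsum("pqrs,rs->pq", eri, Dc, optimize=True)
    K = np.einsum("prqs,rs->pq", eri, Dc, optimize=True)
    h_eff = h + 2.0 * J - K
    e_core = float(np.einsum("pq,qp->", h + h_eff, Dc))
    return h_eff, e_core
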