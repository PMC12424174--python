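"""Two-electron CI and the subspace (CAS(2,n)) orbital optimizer."""

import numpy as np
import pytest

from saptdx import ci, fock, make_dimer, build_dimer_system
from saptdx.scf import rhf


def random_integrals(m, seed):
    rng = np.random.default_rng(seed)
    h = rng.normal(size=(m, m))
    h = (h + h.T) / 2
    L = rng.normal(size=(m * m, m * (m + 1)))
    eri4 = (L @ L.T).reshape(m, m, m, m) / m**2
    # impose full 8-fold real-orbital permutational symmetry
    eri4 = (eri4 + eri4.transpose(1, 0, 2, 3) + eri4.transpose(0, 1, 3, 2)
            + eri4.transpose(1, 0, 3, 2) + eri4.transpose(2, 3, 0, 1)
            + eri4.transpose(3, 2, 0, 1) + eri4.transpose(2, 3, 1, 0)
            + eri4.transpose(3, 2, 1, 0)) / 8
    return h, eri4


def brute_pair_hamiltonian(h, eri):
    """Independent determinant-space construction of the singlet pair Hamiltonian."""
    m = h.shape[0]
    pairs = [(p, q) for p in range(m) for q in range(p, m)]
    dim = len(pairs)
    H = np.zeros((dim, dim))
    # basis vectors as CI vectors over 2m spinorbitals
    vecs = []
    for p, q in pairs:
        C = np.zeros((m, m))
        if p == q:
            C[p, p] = 1.0
        else:
            C[p, q] = C[q, p] = 1.0 / np.sqrt(2.0)
        vecs.append(fock.two_electron_ci_vector(C))
    for j, (r, s) in enumerate(pairs):
        # H |rs>: apply one- and two-electron operators determinant-wise
        ket = vecs[j]
        out: dict[int, float] = {}
        for det, c0 in ket.coeffs.items():
            occ = fock.occ_list(det)
            for o in occ:
                sp, spin = divmod(o, 2)
                for t in range(m):
                    new = fock.apply_excitation(
                        fock.CIVector({det: c0}, 2 * m), [2 * t + spin], [o]
                    )
                    for d2, c2 in new.coeffs.items():
                        out[d2] = out.get(d2, 0.0) + h[t, sp] * c2
            for i1 in range(len(occ)):
                for i2 in range(len(occ)):
                    if i1 == i2:
                        continue
                    o1, o2 = occ[i1], occ[i2]
                    s1, sp1 = o1 % 2, o1 // 2
                    s2, sp2 = o2 % 2, o2 // 2
                    for t1 in range(m):
                        for t2 in range(m):
                            new = fock.apply_excitation(
                                fock.CIVector({det: c0}, 2 * m),
                                [2 * t1 + s1, 2 * t2 + s2], [o2, o1]
                            )
                            for d2, c2 in new.coeffs.items():
                                out[d2] = out.get(d2, 0.0) + 0.5 * eri[t1, sp1, t2, sp2] * c2
        Hket = fock.CIVector(out, 2 * m)
        for i in range(dim):
            H[i, j] = vecs[i].dot(Hket)
    return H


def test_pair_hamiltonian_matches_determinant_algebra():
    """The packed singlet Hamiltonian equals an independent determinant build."""
    m = 3
    h, eri = random_integrals(m, 7)
    Hp = ci.pair_hamiltonian(h, eri)
    Hb = brute_pair_hamiltonian(h, eri)
    assert np.allclose(Hp, Hb, atol=1e-10)


def test_h2_fci_literature_anchor():
    """H2 FCI/cc-pVDZ at r = 1.4 a0 reproduces the published value."""
    geo = make_dimer(["H"] * 4,
                     [[0, 0, 0], [0, 0, 1.4], [0, 0, 500], [0, 0, 501.4]], "AABB")
    system = build_dimer_system(geo, "cc-pvdz")
    r = rhf(system.core_hamiltonian("A"), system.eri, system.S, 2, e_nuc=1.0 / 1.4)
    C = r.mo_coeff
    h = C.T @ system.core_hamiltonian("A") @ C
    t = np.tensordot(system.eri, C, axes=([0], [0]))
    t = np.tensordot(t, C, axes=([0], [0]))
    t = np.tensordot(t, C, axes=([0], [0]))
    eri = np.tensordot(t, C, axes=([0], [0]))
    st = ci.solve_two_electron_ci(h, eri, C)[0]
    assert r.energy == pytest.approx(-1.128709, abs=2e-5)
    assert st.energy + 1.0 / 1.4 == pytest.approx(-1.163399, abs=2e-5)


def test_natural_geminal_roundtrip():
    rng = np.random.default_rng(3)
    A = rng.normal(size=(5, 5))
    C = (A + A.T) / 2
    C /= np.linalg.norm(C)
    st = ci.TwoElectronState(0.0, C, np.eye(5))
    c, orb = st.natural_geminal()
    assert np.sum(c**2) == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(orb @ np.diag(c) @ orb.T, C, atol=1e-10) or np.allclose(
        orb @ np.diag(c) @ orb.T, -C, atol=1e-10
    )
    assert c[0] > 0


def test_subspace_gradient_matches_finite_differences():
    """The Hellmann-Feynman orbital gradient agrees with numerical derivatives."""
    m, n = 6, 2
    h, eri = random_integrals(m, 11)

    def energy(U):
        h_act = U.T @ h @ U
        t = np.tensordot(eri, U, axes=([0], [0]))
        t = np.tensordot(t, U, axes=([0], [0]))
        t = np.tensordot(t, U, axes=([0], [0]))
        eri_act = np.tensordot(t, U, axes=([0], [0]))
        Hp = ci.pair_hamiltonian(h_act, eri_act)
        w, V = np.linalg.eigh(Hp)
        C = ci.unpack_C(V[:, 0], n)
        return w[0], C / np.linalg.norm(C)

    rng = np.random.default_rng(5)
    U, _ = np.linalg.qr(rng.normal(size=(m, n)))
    e0, C_act = energy(U)
    Cfull = U @ C_act @ U.T
    HC = ci.sigma(Cfull, h, eri)
    G = 4.0 * (HC @ (U @ C_act))
    G_ext = G - U @ (U.T @ G)
    # finite-difference along a random external direction
    V_ext = np.linalg.qr(np.eye(m) - U @ U.T)[0][:, : m - n]
    K = rng.normal(size=(m - n, n))
    d = V_ext @ K
    eps = 1e-6
    Up, _ = np.linalg.qr(U + eps * d)
    Um, _ = np.linalg.qr(U - eps * d)
    de_num = (energy(Up)[0] - energy(Um)[0]) / (2 * eps)
    de_ana = float(np.sum(G_ext * d))
    assert de_ana == pytest.approx(de_num, rel=1e-4, abs=1e-8)


def test_subspace_optimizer_full_span_equals_fci():
    """CAS(2,m) over the whole orbital space reproduces the untruncated CI."""
    m = 4
    h, eri = random_integrals(m, 13)
    states = ci.solve_two_electron_ci(h, eri, np.eye(m))
    res = ci.optimize_subspace_ci(h, eri, np.eye(m))
    assert res.energy == pytest.approx(states[0].energy, abs=1e-9)


def test_subspace_optimizer_improves_on_truncated_nos():
    m, n = 6, 2
    h, eri = random_integrals(m, 17)
    st = ci.solve_two_electron_ci(h, eri, np.eye(m))[0]
    w, V = np.linalg.eigh(st.C)
    order = np.argsort(-np.abs(w))
    U0 = V[:, order[:n]]

    def e_of(U):
        h_act = U.T @ h @ U
        t = np.tensordot(eri, U, axes=([0], [0]))
        t = np.tensordot(t, U, axes=([0], [0]))
        t = np.tensordot(t, U, axes=([0], [0]))
        eri_act = np.tensordot(t, U, axes=([0], [0]))
        return np.linalg.eigvalsh(ci.pair_hamiltonian(h_act, eri_act))[0]

    res = ci.optimize_subspace_ci(h, eri, U0)
    assert res.energy <= e_of(U0) + 1e-12
    assert res.energy >= st.energy - 1e-12
    assert res.gradient_norm < 1e-6
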