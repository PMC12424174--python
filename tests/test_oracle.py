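"""Determinant-space oracle: closed forms and first-quantized cross-checks."""

import numpy as np
import pytest

from saptdx import fock, oracle, make_dimer, build_dimer_system
from saptdx.exchange import SpinTensors
from saptdx.tensors import transform_interaction_tensors

from conftest import MINIMAL_H, solve_fci_monomer


def one_electron_product_state(s_overlap):
    """Two one-electron 'monomers' with a single spatial orbital each."""
    psi = fock.CIVector({0b01: 1.0}, 2)  # alpha electron in the only orbital
    state = oracle.ProductState(psi, psi, 2, 2, 1, 1)
    S_so = np.kron(np.array([[s_overlap]]), np.eye(2))
    return state, S_so


@pytest.mark.parametrize("s", [0.0, 0.2, 0.7])
def test_single_pair_exchange_closed_form(s):
    """<P_2> = -s^2 for one-electron monomers with orbital overlap s."""
    state, S_so = one_electron_product_state(s)
    joint = oracle.apply_P2k(state, S_so, 1)
    # <Psi|P_2|Psi>: project on the original product determinant
    val = joint.get((0b01, 0b01), 0.0)
    assert val == pytest.approx(-s * s, abs=1e-14)


def test_P4_vanishes_beyond_electron_count():
    state, S_so = one_electron_product_state(0.5)
    assert oracle.apply_P2k(state, S_so, 2) == {}


def test_spinorbital_cap_enforced():
    psi = fock.CIVector({0b01: 1.0}, 30)
    with pytest.raises(ValueError, match="cap"):
        oracle.ProductState(psi, psi, 30, 30, 1, 1)


def test_first_quantized_permutation_cross_check(minimal_dimer, minimal_monomers):
    """All five expectation values equal an explicit transposition-sum evaluation.

    The reference applies P_2 = -sum T_ij and P_4 = T13 T24 + T14 T23 to the
    4-electron product wave function with nonorthogonal A/B orbitals - an
    evaluation that shares no code with the second-quantized oracle.
    """
    system = minimal_dimer
    (rA, stA), (rB, stB) = minimal_monomers
    CA, CB = rA.mo_coeff, rB.mo_coeff
    mA = CA.shape[1]

    J = np.concatenate([CA, CB], axis=1)
    Sj = J.T @ system.S @ J
    VAj = J.T @ system.Vnuc_A @ J
    VBj = J.T @ system.Vnuc_B @ J
    t = np.tensordot(system.eri, J, axes=([0], [0]))
    t = np.tensordot(t, J, axes=([0], [0]))
    t = np.tensordot(t, J, axes=([0], [0]))
    ERIj = np.tensordot(t, J, axes=([0], [0]))
    VAB = system.geometry.nuclear_repulsion_between()

    spins = ["a", "b", "a", "b"]
    termsA = [(p, q, stA.C[p, q]) for p in range(mA) for q in range(mA)
              if abs(stA.C[p, q]) > 1e-14]
    termsB = [(r, s, stB.C[r, s]) for r in range(mA) for s in range(mA)
              if abs(stB.C[r, s]) > 1e-14]

    def melem(bra, ket_orbs, perm, with_V):
        ket = [ket_orbs[perm[e]] for e in range(4)]
        for e in range(4):
            if spins[e] != spins[perm[e]]:
                return 0.0
        ov = [Sj[bra[e], ket[e]] for e in range(4)]
        if not with_V:
            return float(np.prod(ov))
        tot = 0.0
        for e, vmat in ((0, VBj), (1, VBj), (2, VAj), (3, VAj)):
            rest = np.prod([ov[f] for f in range(4) if f != e])
            tot += vmat[bra[e], ket[e]] * rest
        for e in (0, 1):
            for f in (2, 3):
                rest = np.prod([ov[g] for g in range(4) if g not in (e, f)])
                tot += ERIj[bra[e], ket[e], bra[f], ket[f]] * rest
        return tot + VAB * np.prod(ov)

    identity = [0, 1, 2, 3]
    P2_perms = [([2, 1, 0, 3], -1), ([3, 1, 2, 0], -1),
                ([0, 2, 1, 3], -1), ([0, 3, 2, 1], -1)]
    P4_perms = [([2, 3, 0, 1], 1), ([3, 2, 1, 0], 1)]

    def expval(perms, with_V):
        tot = 0.0
        for (p, q, ca) in termsA:
            for (r, s, cb) in termsB:
                ket = [p, q, mA + r, mA + s]
                for (p2, q2, ca2) in termsA:
                    for (r2, s2, cb2) in termsB:
                        bra = [p2, q2, mA + r2, mA + s2]
                        w = ca * cb * ca2 * cb2
                        for perm, sgn in perms:
                            tot += w * sgn * melem(bra, ket, perm, with_V)
        return tot

    tensors = transform_interaction_tensors(system, CA, CB)
    st = SpinTensors.from_tensors(tensors)
    psiA = fock.two_electron_ci_vector(stA.C).normalized()
    psiB = fock.two_electron_ci_vector(stB.C).normalized()
    ps = oracle.ProductState(psiA, psiB, 2 * mA, 2 * mA, 2, 2)
    res = oracle.brute_expectations(ps, st, 2)

    assert res["V"] == pytest.approx(expval([(identity, 1)], True), abs=1e-12)
    assert res["P"][1] == pytest.approx(expval(P2_perms, False), abs=1e-12)
    assert res["P"][2] == pytest.approx(expval(P4_perms, False), abs=1e-12)
    assert res["VP"][1] == pytest.approx(expval(P2_perms, True), abs=1e-12)
    assert res["VP"][2] == pytest.approx(expval(P4_perms, True), abs=1e-12)


def test_orthogonalized_monomers_have_zero_exchange(minimal_dimer, minimal_monomers):
    """With the intermolecular overlap zeroed, every exchange expectation dies."""
    system = minimal_dimer
    (rA, stA), (rB, stB) = minimal_monomers
    tensors = transform_interaction_tensors(system, rA.mo_coeff, rB.mo_coeff)
    st = SpinTensors.from_tensors(tensors)
    st.S = np.zeros_like(st.S)
    psiA = fock.two_electron_ci_vector(stA.C).normalized()
    psiB = fock.two_electron_ci_vector(stB.C).normalized()
    ps = oracle.ProductState(psiA, psiB, 8, 8, 2, 2)
    res = oracle.brute_expectations(ps, st, 2)
    for k in (1, 2):
        assert res["P"][k] == pytest.approx(0.0, abs=1e-14)
        assert res["VP"][k] == pytest.approx(0.0, abs=1e-14)
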