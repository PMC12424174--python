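"""Overlap-expansion engine: oracle equivalence, compositions, invariances."""

import numpy as np
import pytest

from saptdx import ci, fock, oracle, rdms
from saptdx.exchange import (CompositionTerm, SpinTensors, assemble_first_order,
                             electrostatic_energy, exchange_order_general,
                             expectation_P2k, expectation_VP2k,
                             frozen_core_correction, generate_compositions,
                             intermediate_C, intermediate_D, intermediate_F,
                             intermediate_G)
from saptdx.tensors import transform_interaction_tensors

from conftest import solve_fci_monomer


@pytest.fixture(scope="module")
def fci_setup(minimal_dimer, minimal_monomers):
    system = minimal_dimer
    (rA, stA), (rB, stB) = minimal_monomers
    t = transform_interaction_tensors(system, rA.mo_coeff, rB.mo_coeff)
    st = SpinTensors.from_tensors(t)
    dmA = rdms.two_electron_rdms(stA.C, rA.mo_coeff, k_max=3)
    dmB = rdms.two_electron_rdms(stB.C, rB.mo_coeff, k_max=3)
    psiA = fock.two_electron_ci_vector(stA.C).normalized()
    psiB = fock.two_electron_ci_vector(stB.C).normalized()
    ps = oracle.ProductState(psiA, psiB, 8, 8, 2, 2)
    return st, dmA, dmB, oracle.brute_expectations(ps, st, 2)


def dm_values(st, dmA, dmB):
    return {
        "V": electrostatic_energy(st.vt_qs, dmA.gamma(1), dmB.gamma(1)),
        "P": {k: expectation_P2k(k, st.S, dmA.gamma(k), dmB.gamma(k))
              for k in (1, 2)},
        "VP": {k: expectation_VP2k(k, st, dmA.gammas, dmB.gammas) for k in (1, 2)},
    }


def test_dense_path_matches_oracle(fci_setup):
    st, dmA, dmB, ref = fci_setup
    vals = dm_values(st, dmA, dmB)
    assert vals["V"] == pytest.approx(ref["V"], abs=1e-12)
    for k in (1, 2):
        assert vals["P"][k] == pytest.approx(ref["P"][k], abs=1e-12)
        assert vals["VP"][k] == pytest.approx(ref["VP"][k], abs=1e-12)


def test_expectation_vp2k_equals_intermediate_contraction(fci_setup):
    """<V P_2> literally equals -(G.vt + F.vt_ss + D.vt_qq + C.vt_sq)."""
    st, dmA, dmB, _ = fci_setup
    G = intermediate_G(1, st.S, dmA.gamma(2), dmB.gamma(2))
    F = intermediate_F(1, st.S, dmA.gamma(1), dmB.gamma(2))
    D = intermediate_D(1, st.S, dmA.gamma(2), dmB.gamma(1))
    C = intermediate_C(1, st.S, dmA.gamma(1), dmB.gamma(1))
    total = -(np.sum(G * st.vt_qs) + np.sum(F * st.vt_ss)
              + np.sum(D * st.vt_qq) + np.sum(C * st.vt_sq))
    assert total == pytest.approx(
        expectation_VP2k(1, st, dmA.gammas, dmB.gammas), abs=1e-13
    )


def test_intermediates_vanish_for_zero_overlap(fci_setup):
    st, dmA, dmB, _ = fci_setup
    Z = np.zeros_like(st.S)
    assert np.count_nonzero(intermediate_G(1, Z, dmA.gamma(2), dmB.gamma(2))) == 0
    assert expectation_P2k(1, Z, dmA.gamma(1), dmB.gamma(1)) == 0.0


def test_missing_rank_raises(fci_setup):
    st, dmA, dmB, _ = fci_setup
    with pytest.raises(ValueError, match="required"):
        intermediate_G(1, st.S, None, dmB.gamma(2))


def test_lambda_scaling_of_overlap(fci_setup):
    """<P_2> scales as lambda^2 and <P_4> as lambda^4 under S -> lambda S."""
    st, dmA, dmB, _ = fci_setup
    p1 = expectation_P2k(1, st.S, dmA.gamma(1), dmB.gamma(1))
    p2 = expectation_P2k(2, st.S, dmA.gamma(2), dmB.gamma(2))
    for lam in (0.5, 0.25):
        assert expectation_P2k(1, lam * st.S, dmA.gamma(1), dmB.gamma(1)) \
            == pytest.approx(lam**2 * p1, rel=1e-12)
        assert expectation_P2k(2, lam * st.S, dmA.gamma(2), dmB.gamma(2)) \
            == pytest.approx(lam**4 * p2, rel=1e-12)


def test_electrostatics_neutral_far_limit():
    """Neutral monomers at huge separation: E_elst below 1e-10 hartree."""
    from conftest import MINIMAL_H, t_shaped_h2h2

    system = t_shaped_h2h2(R=1000.0, basis=MINIMAL_H)
    rA, stA = solve_fci_monomer(system, "A")
    rB, stB = solve_fci_monomer(system, "B")
    t = transform_interaction_tensors(system, rA.mo_coeff, rB.mo_coeff)
    st = SpinTensors.from_tensors(t)
    dmA = rdms.two_electron_rdms(stA[0].C, rA.mo_coeff, k_max=1)
    dmB = rdms.two_electron_rdms(stB[0].C, rB.mo_coeff, k_max=1)
    e = electrostatic_energy(st.vt_qs, dmA.gamma(1), dmB.gamma(1))
    assert abs(e) < 1e-10


def test_electrostatics_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        electrostatic_energy(np.zeros((2, 2, 2, 2)), np.zeros((4, 4)),
                             np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# composition generator
# ---------------------------------------------------------------------------


def test_compositions_order_one_is_single_exchange():
    terms = generate_compositions(1)
    assert terms == [CompositionTerm((), 1), CompositionTerm((1,), 0)]
    # evaluates to <V P_2> - <V><P_2>
    val = sum(t.evaluate(2.0, {1: 3.0}, {1: 5.0}) for t in terms)
    assert val == 5.0 - 2.0 * 3.0


def test_compositions_order_two_reproduce_double_exchange():
    terms = generate_compositions(2)
    expected = {
        CompositionTerm((), 2): 1,        # +<V P_4>
        CompositionTerm((1,), 1): -1,     # -<V P_2><P_2>
        CompositionTerm((2,), 0): -1,     # -<V><P_4>
        CompositionTerm((1, 1), 0): 1,    # +<V><P_2>^2
    }
    assert {t: t.sign for t in terms} == expected


def test_compositions_match_symbolic_series():
    """Order n coefficients agree with the sympy expansion of the SRS ratio."""
    sympy = pytest.importorskip("sympy")
    x = sympy.symbols("x")
    V = sympy.Symbol("V")
    P = {k: sympy.Symbol(f"P{k}") for k in (1, 2, 3)}
    VP = {k: sympy.Symbol(f"VP{k}") for k in (1, 2, 3)}
    num = V + sum(VP[k] * x**k for k in (1, 2, 3))
    den = 1 + sum(P[k] * x**k for k in (1, 2, 3))
    series = sympy.series(num / den, x, 0, 4).removeO().expand()
    for n in (1, 2, 3):
        coef = series.coeff(x, n)
        built = sum(
            t.sign
            * (V if t.residual == 0 else VP[t.residual])
            * sympy.prod([P[k] for k in t.k_list])
            for t in generate_compositions(n)
        )
        assert sympy.simplify(coef - built) == 0


def test_general_order_matches_dedicated_s4(fci_setup):
    st, dmA, dmB, _ = fci_setup
    vals = dm_values(st, dmA, dmB)
    dec = assemble_first_order(
        {"V": vals["V"], "P2": vals["P"][1], "VP2": vals["VP"][1],
         "P4": vals["P"][2], "VP4": vals["VP"][2]}
    )
    gen = exchange_order_general(2, vals["V"], vals["P"], vals["VP"])
    assert gen == pytest.approx(dec.exch_s4_increment, abs=1e-16)


def test_general_order_three_vanishes_for_two_electron_monomers(fci_setup):
    """n = 3 requires triple exchanges, impossible with two electrons each."""
    st, dmA, dmB, _ = fci_setup
    P = {k: expectation_P2k(k, st.S, dmA.gamma(k) if k <= 2 else None,
                            dmB.gamma(k) if k <= 2 else None) if k <= 2 else 0.0
         for k in (1, 2, 3)}
    VP = {k: expectation_VP2k(k, st, dmA.gammas, dmB.gammas) if k <= 2 else 0.0
          for k in (1, 2, 3)}
    # P6/VP6 vanish identically (min(N_A, N_B) = 2); remaining terms assemble
    val = exchange_order_general(3, electrostatic_energy(st.vt_qs, dmA.gamma(1),
                                                         dmB.gamma(1)), P, VP)
    # the surviving products reproduce the x^3 series coefficient with P3 = VP3 = 0
    ref = (-VP[2] * P[1] - VP[1] * P[2]
           + VP[1] * P[1] ** 2
           + electrostatic_energy(st.vt_qs, dmA.gamma(1), dmB.gamma(1))
           * (2 * P[1] * P[2] - P[1] ** 3))
    assert val == pytest.approx(ref, abs=1e-15)


def test_general_order_missing_expectations():
    with pytest.raises(ValueError, match="missing"):
        exchange_order_general(2, 1.0, {1: 0.1}, {1: 0.2})


def test_assemble_requires_all_expectations():
    with pytest.raises(ValueError, match="missing"):
        assemble_first_order({"V": 1.0, "P2": 0.1})


# ---------------------------------------------------------------------------
# frozen-core correction
# ---------------------------------------------------------------------------


def test_frozen_core_correction_identities():
    assert frozen_core_correction(1.5, 2.0, 2.0) == 1.5      # no core effect
    # applying the correction with swapped HF arguments undoes it
    e = frozen_core_correction(1.5, 2.3, 2.0)
    assert frozen_core_correction(e, 2.0, 2.3) == pytest.approx(1.5, abs=1e-15)
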