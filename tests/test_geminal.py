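"""Factorized geminal fast path against the dense density-matrix path."""

import numpy as np
import pytest

from saptdx import rdms
from saptdx.exchange import (SpinTensors, electrostatic_energy, expectation_P2k,
                             expectation_VP2k)
from saptdx.geminal import (GeminalState, cost_model, exchange_S4_geminal,
                            geminal_expectations)
from saptdx.tensors import transform_interaction_tensors

from conftest import solve_fci_monomer, t_shaped_h2h2


def dense_reference(system, dmA, dmB, orbA, orbB):
    t = transform_interaction_tensors(system, orbA, orbB)
    st = SpinTensors.from_tensors(t)
    return t, {
        "V": electrostatic_energy(st.vt_qs, dmA.gamma(1), dmB.gamma(1)),
        "P": {k: expectation_P2k(k, st.S, dmA.gamma(k), dmB.gamma(k))
              for k in (1, 2)},
        "VP": {k: expectation_VP2k(k, st, dmA.gammas, dmB.gammas) for k in (1, 2)},
    }


def assert_close(ev, ref, tol=1e-12):
    assert ev["V"] == pytest.approx(ref["V"], abs=tol)
    for k in (1, 2):
        assert ev["P"][k] == pytest.approx(ref["P"][k], abs=tol)
        assert ev["VP"][k] == pytest.approx(ref["VP"][k], abs=tol)


def test_fastpath_equals_dense_for_fci_monomers(minimal_dimer, minimal_monomers):
    """A two-electron CI state is exactly its natural geminal."""
    system = minimal_dimer
    (rA, stA), (rB, stB) = minimal_monomers
    dmA = rdms.two_electron_rdms(stA.C, rA.mo_coeff, k_max=3)
    dmB = rdms.two_electron_rdms(stB.C, rB.mo_coeff, k_max=3)
    t, ref = dense_reference(system, dmA, dmB, rA.mo_coeff, rB.mo_coeff)
    cA, oA = stA.natural_geminal()
    cB, oB = stB.natural_geminal()
    gsA = GeminalState.from_natural_geminal(cA, oA, label="A")
    gsB = GeminalState.from_natural_geminal(cB, oB, label="B")
    tg = transform_interaction_tensors(system, gsA.orbitals, gsB.orbitals)
    assert_close(geminal_expectations(tg, gsA, gsB, 2), ref)


def test_fastpath_hf_limit(minimal_dimer, minimal_monomers):
    """All-core geminal states reproduce the Hartree-Fock dense path."""
    system = minimal_dimer
    (rA, _), (rB, _) = minimal_monomers
    dmA = rdms.hf_rdms(rA.mo_coeff, 1, k_max=3)
    dmB = rdms.hf_rdms(rB.mo_coeff, 1, k_max=3)
    t, ref = dense_reference(system, dmA, dmB, rA.occ_coeff, rB.occ_coeff)
    gsA = GeminalState.from_rhf(rA.occ_coeff, "A")
    gsB = GeminalState.from_rhf(rB.occ_coeff, "B")
    assert_close(geminal_expectations(t, gsA, gsB, 2), ref)


def test_fastpath_multi_geminal_with_gamma3(small_dimer):
    """4-electron APSG monomer (nonzero 3-RDM): fast path == dense wedge path."""
    system = small_dimer
    rA, _ = solve_fci_monomer(system, "A")
    rB, stB = solve_fci_monomer(system, "B")
    CA = rA.mo_coeff[:, :4]
    gmA = rdms.GeminalModel(
        [[0, 1], [2, 3]],
        [np.array([0.92, -np.sqrt(1 - 0.92**2)]), np.array([0.85, np.sqrt(1 - 0.85**2)])],
    )
    dmA = rdms.apsg_rdms(gmA, CA, k_max=3)
    cB, oB = stB[0].natural_geminal()
    gsB = GeminalState.from_natural_geminal(cB, oB, label="B")
    dmB = rdms.two_electron_rdms(stB[0].C, rB.mo_coeff, k_max=3)
    t, ref = dense_reference(system, dmA, dmB, CA, rB.mo_coeff)
    gsA = GeminalState.from_geminal_model(gmA, CA, "A")
    tg = transform_interaction_tensors(system, CA, gsB.orbitals)
    ev = geminal_expectations(tg, gsA, gsB, 2)
    # tensors differ only through the B support ordering; compare values
    assert ev["V"] == pytest.approx(ref["V"], abs=1e-11)
    for k in (1, 2):
        assert ev["P"][k] == pytest.approx(ref["P"][k], abs=1e-11)
        assert ev["VP"][k] == pytest.approx(ref["VP"][k], abs=1e-11)


def test_fastpath_core_plus_geminal(small_dimer):
    """Frozen-core-embedded dense RDMs equal the core-as-geminal fast path."""
    system = small_dimer
    rA, _ = solve_fci_monomer(system, "A")
    rB, stB = solve_fci_monomer(system, "B")
    CA = rA.mo_coeff[:, :3]
    gm_act = rdms.GeminalModel([[1, 2]], [np.array([0.9, -np.sqrt(0.19)])])
    act = rdms.apsg_rdms(gm_act, CA, k_max=3)
    dmA = rdms.frozen_core_embed_rdms(act, [0], k_max=3)
    dmB = rdms.two_electron_rdms(stB[0].C, rB.mo_coeff, k_max=3)
    t, ref = dense_reference(system, dmA, dmB, CA, rB.mo_coeff)
    gsA = GeminalState(CA, [(np.array([0]), np.array([1.0])),
                            (np.array([1, 2]), np.array([0.9, -np.sqrt(0.19)]))], "A")
    cB, oB = stB[0].natural_geminal()
    gsB = GeminalState.from_natural_geminal(cB, oB, label="B")
    tg = transform_interaction_tensors(system, CA, gsB.orbitals)
    ev = geminal_expectations(tg, gsA, gsB, 2)
    assert ev["V"] == pytest.approx(ref["V"], abs=1e-11)
    for k in (1, 2):
        assert ev["P"][k] == pytest.approx(ref["P"][k], abs=1e-11)
        assert ev["VP"][k] == pytest.approx(ref["VP"][k], abs=1e-11)


def test_decomposition_identities(minimal_dimer, minimal_monomers):
    """Stored fields satisfy the S^2/S^4 composition identities bit-exactly."""
    system = minimal_dimer
    (rA, stA), (rB, stB) = minimal_monomers
    cA, oA = stA.natural_geminal()
    cB, oB = stB.natural_geminal()
    gsA = GeminalState.from_natural_geminal(cA, oA, label="A")
    gsB = GeminalState.from_natural_geminal(cB, oB, label="B")
    t = transform_interaction_tensors(system, gsA.orbitals, gsB.orbitals)
    dec = exchange_S4_geminal(gsA, gsB, t)
    assert dec.exch_s2 == dec.vp2 - dec.e_elst * dec.p2
    assert dec.exch_s4_increment == (dec.vp4 - dec.vp2 * dec.p2
                                     - dec.e_elst * dec.p4
                                     + dec.e_elst * dec.p2**2)
    assert dec.exch_s4 == dec.exch_s2 + dec.exch_s4_increment


def test_geminal_state_validation():
    with pytest.raises(ValueError, match="overlap"):
        GeminalState(np.eye(3), [(np.array([0, 1]), np.array([0.8, 0.6])),
                                 (np.array([1, 2]), np.array([1.0, 0.0]))])
    with pytest.raises(ValueError, match="normalized"):
        GeminalState(np.eye(2), [(np.array([0, 1]), np.array([0.9, 0.9]))])


def test_cost_model_scaling():
    """Predicted cost grows no faster than the sixth power of geminal size."""
    def state(n_orb):
        c = np.zeros(n_orb)
        c[0] = 1.0
        return GeminalState(np.eye(n_orb), [(np.arange(n_orb), c)])

    c2 = cost_model(state(2), state(2))
    c4 = cost_model(state(4), state(4))
    c8 = cost_model(state(8), state(8))
    assert c4 / c2 <= 2**6 + 1e-9
    assert c8 / c4 <= 2**6 + 1e-9

    # HF-only monomers collapse to the occupied-orbital polynomial
    hf = GeminalState.from_rhf(np.eye(3), "A")
    assert cost_model(hf, hf) <= cost_model(state(6), state(6))
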