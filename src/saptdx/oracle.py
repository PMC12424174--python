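"""Exact determinant-space evaluation of the first-order SAPT expectation values.

The zeroth-order state is the product Psi_A Psi_B of monomer CI expansions
living in commuting Fock spaces (operators of different monomers commute; the
intermolecular non-orthogonality enters exclusively through the overlap
factors carried by the exchange operators).  The exchange operator

    P_2k = (-1)^k (1/k!)^2 sum_{q in A, s in B}
           [atil_{s1}^+ .. atil_{sk}^+ a_{qk} .. a_{q1}]
           [btil_{q1}^+ .. btil_{qk}^+ b_{sk} .. b_{s1}]

is applied literally, with the dressed creators atil_s^+ = sum_p S_ps a_p^+
and btil_q^+ = sum_r S_rq b_r^+.  This is a brute-force, sign-exact reference
for every density-matrix contraction in the package; it is limited to about
20 spinorbitals.

Determinant enumeration and phases follow :mod:`saptdx.fock` (occupation
bitstrings, interleaved spin, ascending orbital order), so oracle numbers are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from itertools import product

import numpy as np

from .fock import CIVector, apply_excitation
from .exchange import SpinTensors

HARD_CAP_SPINORBITALS = 20


@dataclass
class ProductState:
    """Monomer CI vectors over disjoint orbital sets plus their overlap."""

    psiA: CIVector
    psiB: CIVector
    nA_so: int
    nB_so: int
    n_elec_A: int
    n_elec_B: int

    def __post_init__(self):
        if self.nA_so + self.nB_so > HARD_CAP_SPINORBITALS:
            raise ValueError(
                f"{self.nA_so + self.nB_so} spinorbitals exceed the oracle cap "
                f"({HARD_CAP_SPINORBITALS}); use the density-matrix path"
            )
        for name, psi in (("A", self.psiA), ("B", self.psiB)):
            if abs(psi.norm() - 1.0) > 1e-12:
                raise ValueError(f"CI vector of monomer {name} is not normalized")


def _dressed_create(vec: CIVector, weights: np.ndarray) -> CIVector:
    """sum_p weights[p] a_p^dag |vec>."""
    out: dict[int, float] = {}
    for p, w in enumerate(weights):
        if w == 0.0:
            continue
        new = apply_excitation(vec, [p], [])
        for d, c in new.coeffs.items():
            out[d] = out.get(d, 0.0) + w * c
    return CIVector(out, vec.n_spinorb)


def _transition_1rdm(bra: CIVector, ket: CIVector, n_so: int) -> np.ndarray:
    """T[q, p] = <bra| a_p^dag a_q |ket>."""
    T = np.zeros((n_so, n_so))
    for p in range(n_so):
        for q in range(n_so):
            T[q, p] = bra.dot(apply_excitation(ket, [p], [q]))
    return T


def _exchange_term_vectors(state: ProductState, S_so: np.ndarray, k: int):
    """Yield (vecA, vecB) for every (q-tuple, s-tuple) of the P_2k sum."""
    nA, nB = state.nA_so, state.nB_so
    # annihilator parts first (operators act right to left)
    ann_B = {}
    for ss in product(range(nB), repeat=k):
        if len(set(ss)) < k:
            continue
        vB = apply_excitation(state.psiB, [], list(ss)[::-1])   # b_{sk}..b_{s1}
        if vB.coeffs:
            ann_B[ss] = vB
    for qs in product(range(nA), repeat=k):
        if len(set(qs)) < k:
            continue
        vA0 = apply_excitation(state.psiA, [], list(qs)[::-1])  # a_{qk}..a_{q1}
        if not vA0.coeffs:
            continue
        for ss, vB0 in ann_B.items():
            vA = vA0
            for s in reversed(ss):
                vA = _dressed_create(vA, S_so[:, s])            # atil_s^+
            if not vA.coeffs:
                continue
            vB = vB0
            for q in reversed(qs):
                vB = _dressed_create(vB, S_so[q, :])            # btil_q^+
            if not vB.coeffs:
                continue
            yield vA, vB


def apply_P2k(state: ProductState, S_so: np.ndarray, k: int) -> dict:
    """P_2k |Psi_A Psi_B> as a joint {(detA, detB): coeff} dictionary."""
    if k > min(state.n_elec_A, state.n_elec_B):
        return {}
    pref = (-1) ** k / factorial(k) ** 2
    out: dict[tuple[int, int], float] = {}
    for vA, vB in _exchange_term_vectors(state, S_so, k):
        for dA, cA in vA.coeffs.items():
            for dB, cB in vB.coeffs.items():
                key = (dA, dB)
                out[key] = out.get(key, 0.0) + pref * cA * cB
    return out


def _expectation_V_between(state: ProductState, vt_so: np.ndarray,
                           vecA: CIVector, vecB: CIVector) -> float:
    """<Psi_A Psi_B | V | vecA vecB> via transition 1-RDMs."""
    TA = _transition_1rdm(state.psiA, vecA, state.nA_so)
    TB = _transition_1rdm(state.psiB, vecB, state.nB_so)
    return float(np.einsum("pqrs,qp,sr->", vt_so, TA, TB, optimize=True))


def brute_expectations(state: ProductState, st: SpinTensors, k_max: int) -> dict:
    """Exact <V>, <P_2k>, <V P_2k> for k <= k_max, plus assembled energies.

    Returns a dict with keys ``V``, ``P`` (dict k -> value), ``VP``,
    ``exch_s2``, ``exch_s4_increment`` and the unexpanded SRS first-order
    ratio ``ratio_full`` (computed with every k up to min(N_A, N_B)).
    """
    S_so = st.S
    vt_so = st.vt_qs
    kmax_full = min(state.n_elec_A, state.n_elec_B)
    V = _expectation_V_between(state, vt_so, state.psiA, state.psiB)
    P: dict[int, float] = {}
    VP: dict[int, float] = {}
    for k in range(1, max(k_max, kmax_full) + 1):
        if k > kmax_full:
            P[k] = 0.0
            VP[k] = 0.0
            continue
        pref = (-1) ** k / factorial(k) ** 2
        pk = 0.0
        vpk = 0.0
        for vA, vB in _exchange_term_vectors(state, S_so, k):
            pk += pref * state.psiA.dot(vA) * state.psiB.dot(vB)
            vpk += pref * _expectation_V_between(state, vt_so, vA, vB)
        P[k] = pk
        VP[k] = vpk
    sumP = sum(P[k] for k in range(1, kmax_full + 1))
    sumVP = sum(VP[k] for k in range(1, kmax_full + 1))
    ratio_full = (V + sumVP) / (1.0 + sumP)
    exch_s2 = VP.get(1, 0.0) - V * P.get(1, 0.0)
    exch_s4_inc = (VP.get(2, 0.0) - VP.get(1, 0.0) * P.get(1, 0.0)
                   - V * P.get(2, 0.0) + V * P.get(1, 0.0) ** 2)
    return {
        "V": V,
        "P": P,
        "VP": VP,
        "exch_s2": exch_s2,
        "exch_s4_increment": exch_s4_inc,
        "ratio_full": ratio_full,
        "exch_full": ratio_full - V,
    }
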