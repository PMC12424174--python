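"""First-order overlap expansion: expectation values, intermediates, assembly.

The exchange operator P_2k swaps k electron pairs between the monomers and is
of order S^{2k} in the intermolecular overlap.  The first-order interaction
energy (<V> + <V P>)/(1 + <P>), expanded through a given order 2n, yields

    E_exch(prop S^2)  = <V P_2> - <V><P_2>
    E_exch(prop S^4)  = <V P_4> - <V P_2><P_2> - <V><P_4> + <V><P_2>^2

and, in general, signed products generated by `generate_compositions`.

This module implements the density-matrix route: the expectation values are
contractions of monomer k-RDMs (k <= n+1) with the intermolecular overlap S
and the modified potential vtilde.  The dense implementation below works on
spinorbital tensors and is meant for small or truncated supports; Moszynski-
type intermediates G_k, F_k, D_k, C_k are exposed individually.  Production
calculations on geminal-structured states use :mod:`saptdx.geminal`, which
evaluates identical formulas without materializing 3-RDMs.

Sign bookkeeping: the (-1)^k prefactors live in the expectation functions;
intermediates are sign-free.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from math import factorial

import numpy as np

from .tensors import InteractionTensors


# ---------------------------------------------------------------------------
# spin lifting of the interaction tensors
# ---------------------------------------------------------------------------


def spin_lift_matrix(M: np.ndarray) -> np.ndarray:
    """Spatial matrix -> spinorbital matrix with interleaved spin."""
    return np.kron(M, np.eye(2))


def spin_lift_v(v: np.ndarray) -> np.ndarray:
    """v[p,x,r,y] -> spinorbital with spin-diagonal electron slots."""
    eye = np.eye(2)
    out = np.einsum("pxry,ac,bd->paxcrbyd", v, eye, eye, optimize=True)
    s = v.shape
    return out.reshape(2 * s[0], 2 * s[1], 2 * s[2], 2 * s[3])


@dataclass
class SpinTensors:
    """Spinorbital interaction tensors for the dense contraction path."""

    S: np.ndarray
    vt_qs: np.ndarray
    vt_ss: np.ndarray
    vt_qq: np.ndarray
    vt_sq: np.ndarray

    @classmethod
    def from_tensors(cls, t: InteractionTensors) -> "SpinTensors":
        return cls(
            S=spin_lift_matrix(t.S),
            vt_qs=spin_lift_v(t.vt_qs),
            vt_ss=spin_lift_v(t.vt_ss),
            vt_qq=spin_lift_v(t.vt_qq),
            vt_sq=spin_lift_v(t.vt_sq),
        )


# ---------------------------------------------------------------------------
# dense expectation values and intermediates
# ---------------------------------------------------------------------------

_LET = string.ascii_letters


def _lab(n: int, start: int = 0) -> list[str]:
    return [_LET[start + i] for i in range(n)]


def electrostatic_energy(vt_qs, g1A, g1B) -> float:
    """<V> = sum vtilde[p,q,r,s] Gamma1_A[q,p] Gamma1_B[s,r] (spinorbital)."""
    if vt_qs.shape[0] != g1A.shape[0] or vt_qs.shape[2] != g1B.shape[0]:
        raise ValueError("shape mismatch between vtilde and the 1-RDMs")
    return float(np.einsum("pqrs,qp,sr->", vt_qs, g1A, g1B, optimize=True))


def expectation_P2k(k: int, S, gAk, gBk) -> float:
    """<P_2k> per the density-matrix expression (spinorbital tensors)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if gAk is None or gBk is None or gAk.size == 0 or np.count_nonzero(gAk) == 0 \
            or np.count_nonzero(gBk) == 0:
        return 0.0
    lo = _lab(k, 0)            # A lowers  (q_i)
    up = _lab(k, k)            # A uppers  (p_i)
    LO = _lab(k, 2 * k)        # B lowers  (s_i)
    UP = _lab(k, 3 * k)        # B uppers  (r_i)
    ops = [gAk]
    subs = ["".join(lo + up)]
    for i in range(k):
        ops.append(S)
        subs.append(up[i] + LO[i])   # S_{p_i s_i}
        ops.append(S)
        subs.append(lo[i] + UP[i])   # S_{r_i q_i} = S[q_i, r_i]
    ops.append(gBk)
    subs.append("".join(LO + UP))
    val = np.einsum(",".join(subs) + "->", *ops, optimize=True)
    return float((-1) ** k / factorial(k) ** 2 * val)


def intermediate_G(k: int, S, gA, gB) -> np.ndarray:
    """G_k[p,q,r,s]: both RDMs of rank k+1; sign-free."""
    _require_rank(gA, k + 1, "A")
    _require_rank(gB, k + 1, "B")
    lo, up = _lab(k, 0), _lab(k, k)
    LO, UP = _lab(k, 2 * k), _lab(k, 3 * k)
    P, Q, R, Sl = _LET[4 * k : 4 * k + 4]
    ops, subs = [gA], ["".join([Q] + lo + [P] + up)]
    for i in range(k):
        ops += [S, S]
        subs += [up[i] + LO[i], lo[i] + UP[i]]
    ops.append(gB)
    subs.append("".join([Sl] + LO + [R] + UP))
    out = np.einsum(",".join(subs) + "->" + P + Q + R + Sl, *ops, optimize=True)
    return out / factorial(k) ** 2


def intermediate_F(k: int, S, gA, gB) -> np.ndarray:
    """F_k[p,s1,r,s]: Gamma^k_A with Gamma^{k+1}_B; sign-free."""
    _require_rank(gA, k, "A")
    _require_rank(gB, k + 1, "B")
    lo, up = _lab(k, 0), _lab(k, k)          # l1..lk = q_i ; u2..uk used
    LO, UP = _lab(k, 2 * k), _lab(k, 3 * k)  # L1..Lk = s_i ; U1..Uk = r_i
    P, R, Sl = _LET[4 * k : 4 * k + 3]
    ops, subs = [gA], ["".join(lo + [P] + up[1:])]
    ops += [S]
    subs += [lo[0] + UP[0]]                  # S_{r1 q1}
    for i in range(1, k):
        ops += [S, S]
        subs += [up[i] + LO[i], lo[i] + UP[i]]
    ops.append(gB)
    subs.append("".join([Sl] + LO + [R] + UP))
    out = np.einsum(",".join(subs) + "->" + P + LO[0] + R + Sl, *ops, optimize=True)
    return out / (factorial(k) * factorial(k - 1))


def intermediate_D(k: int, S, gA, gB) -> np.ndarray:
    """D_k[p,q,r,q1]: Gamma^{k+1}_A with Gamma^k_B; sign-free."""
    _require_rank(gA, k + 1, "A")
    _require_rank(gB, k, "B")
    lo, up = _lab(k, 0), _lab(k, k)
    LO, UP = _lab(k, 2 * k), _lab(k, 3 * k)
    P, Q, R = _LET[4 * k : 4 * k + 3]
    ops, subs = [gA], ["".join([Q] + lo + [P] + up)]
    ops += [S]
    subs += [up[0] + LO[0]]                  # S_{p1 s1}
    for i in range(1, k):
        ops += [S, S]
        subs += [up[i] + LO[i], lo[i] + UP[i]]
    ops.append(gB)
    subs.append("".join(LO + [R] + UP[1:]))
    out = np.einsum(",".join(subs) + "->" + P + Q + R + lo[0], *ops, optimize=True)
    return out / (factorial(k) * factorial(k - 1))


def intermediate_C(k: int, S, gA, gB) -> np.ndarray:
    """C_k[p,s1,r,q1]: both RDMs of rank k; sign-free."""
    _require_rank(gA, k, "A")
    _require_rank(gB, k, "B")
    lo, up = _lab(k, 0), _lab(k, k)
    LO, UP = _lab(k, 2 * k), _lab(k, 3 * k)
    P, R = _LET[4 * k : 4 * k + 2]
    ops, subs = [gA], ["".join(lo + [P] + up[1:])]
    for i in range(1, k):
        ops += [S, S]
        subs += [up[i] + LO[i], lo[i] + UP[i]]
    ops.append(gB)
    subs.append("".join(LO + [R] + UP[1:]))
    out = np.einsum(",".join(subs) + "->" + P + LO[0] + R + lo[0], *ops, optimize=True)
    return out / factorial(k - 1) ** 2


def _require_rank(g, k, side):
    if g is None:
        raise ValueError(f"rank-{k} RDM of monomer {side} is required but missing")


def expectation_VP2k(k: int, st: SpinTensors, gammasA: dict, gammasB: dict) -> float:
    """<V P_2k> assembled from the four sign-free intermediates."""
    if k < 1:
        raise ValueError("k must be >= 1")
    gA = {kk: gammasA.get(kk) for kk in (k, k + 1)}
    gB = {kk: gammasB.get(kk) for kk in (k, k + 1)}

    def dead(g):
        return g is None or np.count_nonzero(g) == 0

    total = 0.0
    if not (dead(gA[k + 1]) or dead(gB[k + 1])):
        G = intermediate_G(k, st.S, gA[k + 1], gB[k + 1])
        total += float(np.einsum("pqrs,pqrs->", G, st.vt_qs, optimize=True))
    if not (dead(gA[k]) or dead(gB[k + 1])):
        F = intermediate_F(k, st.S, gA[k], gB[k + 1])
        total += float(np.einsum("pqrs,pqrs->", F, st.vt_ss, optimize=True))
    if not (dead(gA[k + 1]) or dead(gB[k])):
        D = intermediate_D(k, st.S, gA[k + 1], gB[k])
        total += float(np.einsum("pqrs,pqrs->", D, st.vt_qq, optimize=True))
    if not (dead(gA[k]) or dead(gB[k])):
        C = intermediate_C(k, st.S, gA[k], gB[k])
        total += float(np.einsum("pqrs,pqrs->", C, st.vt_sq, optimize=True))
    return (-1) ** k * total


# ---------------------------------------------------------------------------
# composition of the energy corrections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositionTerm:
    """One signed product of the order-2n exchange energy.

    The term is sign * <V P_{2 residual}> * prod_i <P_{2 k_i}> with the
    convention that residual 0 means the bare <V> factor.
    """

    k_list: tuple[int, ...]
    residual: int

    def __post_init__(self):
        if any(k < 1 for k in self.k_list):
            raise ValueError("all k_i must be >= 1")
        if self.residual < 0:
            raise ValueError("residual order must be >= 0")

    @property
    def s(self) -> int:
        return len(self.k_list)

    @property
    def sign(self) -> int:
        return (-1) ** self.s

    def evaluate(self, V: float, P: dict[int, float], VP: dict[int, float]) -> float:
        val = float(self.sign)
        val *= V if self.residual == 0 else VP[self.residual]
        for k in self.k_list:
            val *= P[k]
        return val


def generate_compositions(n: int) -> list[CompositionTerm]:
    """All terms of the order-S^{2n} exchange-energy expression.

    The leading term is <V P_2n>; the double sum runs over s >= 1 ordered
    tuples (k_1..k_s) of positive integers with sum <= n, each contributing
    (-1)^s <V P_{2(n - sum k_i)}> prod <P_{2 k_i}> with <V P_0> -> <V>.
    """
    if n < 1:
        raise ValueError("order n must be >= 1")
    terms = [CompositionTerm((), n)]

    def tuples(s):
        if s == 0:
            yield ()
            return
        for first in range(1, n + 1):
            for rest in tuples(s - 1):
                if first + sum(rest) <= n:
                    yield (first,) + rest

    for s in range(1, n + 1):
        for tup in tuples(s):
            terms.append(CompositionTerm(tup, n - sum(tup)))
    return terms


@dataclass
class FirstOrderDecomposition:
    """First-order SAPT energies through the double-exchange level (hartree)."""

    e_elst: float
    p2: float
    vp2: float
    p4: float = 0.0
    vp4: float = 0.0

    @property
    def exch_s2(self) -> float:
        return self.vp2 - self.e_elst * self.p2

    @property
    def exch_s4_increment(self) -> float:
        return (self.vp4 - self.vp2 * self.p2 - self.e_elst * self.p4
                + self.e_elst * self.p2 ** 2)

    @property
    def exch_s4(self) -> float:
        return self.exch_s2 + self.exch_s4_increment

    @property
    def e_int_s2(self) -> float:
        return self.e_elst + self.exch_s2

    @property
    def e_int_s4(self) -> float:
        return self.e_elst + self.exch_s4

    def as_dict(self) -> dict[str, float]:
        return {
            "E_elst": self.e_elst,
            "P2": self.p2,
            "VP2": self.vp2,
            "P4": self.p4,
            "VP4": self.vp4,
            "E_exch_S2": self.exch_s2,
            "E_exch_propS4": self.exch_s4_increment,
            "E_exch_S4": self.exch_s4,
        }


def assemble_first_order(expectations: dict) -> FirstOrderDecomposition:
    """Assemble the decomposition from {'V':, 'P2':, 'VP2':, ['P4':, 'VP4':]}."""
    try:
        dec = FirstOrderDecomposition(
            e_elst=expectations["V"],
            p2=expectations["P2"],
            vp2=expectations["VP2"],
            p4=expectations.get("P4", 0.0),
            vp4=expectations.get("VP4", 0.0),
        )
    except KeyError as exc:
        raise ValueError(f"missing expectation value {exc}") from exc
    # audit: the stored fields must satisfy the composition formulas exactly
    P = {1: dec.p2, 2: dec.p4}
    VP = {1: dec.vp2, 2: dec.vp4}
    s2 = sum(t.evaluate(dec.e_elst, P, VP) for t in generate_compositions(1))
    s4 = sum(t.evaluate(dec.e_elst, P, VP) for t in generate_compositions(2))
    assert s2 == dec.exch_s2 and s4 == dec.exch_s4_increment
    return dec


def exchange_order_general(n: int, V: float, P: dict[int, float],
                           VP: dict[int, float]) -> float:
    """E_exch(prop S^{2n}) from supplied expectation values.

    ``P[k]`` = <P_2k> and ``VP[k]`` = <V P_2k> must cover k = 1..n.
    """
    terms = generate_compositions(n)
    needed = {k for t in terms for k in t.k_list} | {
        t.residual for t in terms if t.residual > 0
    }
    missing = sorted(k for k in needed if k not in P or k not in VP)
    if missing:
        raise ValueError(f"missing expectation values for k = {missing}")
    return float(sum(t.evaluate(V, P, VP) for t in terms))


def frozen_core_correction(e_target_fc: float, e_hf: float, e_hf_fc: float) -> float:
    """Correct a frozen-core result with the all-electron/fc difference at HF level."""
    return e_target_fc + (e_hf - e_hf_fc)
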