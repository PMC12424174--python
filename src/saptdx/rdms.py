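"""Reduced density matrices of monomer wave functions.

Conventions
-----------
Dense tensors are over interleaved spinorbitals (so = 2*spatial + spin) with
factorial-free normalization: the full diagonal trace of the k-body RDM equals
N!/(N-k)!.  The index layout is Gamma[l1..lk, u1..uk] for the expectation
value <a^dag_{u1}..a^dag_{uk} a_{lk}..a_{l1}>.

The Grassmann (wedge) product used throughout is the prefactor-free
antisymmetrized product; for states on disjoint orbital sets the RDM of the
product state is Gamma^k = sum_{k1+k2=k} Gamma^{k1}_1 ^ Gamma^{k2}_2, and for
a closed-shell determinant Gamma^k = (1/k!) (Gamma^1)^(^k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import fock


# ---------------------------------------------------------------------------
# wedge product of dense antisymmetric tensors
# ---------------------------------------------------------------------------


def _subset_parity(subset: tuple[int, ...]) -> int:
    """Parity of moving the (ascending) subset positions to the front."""
    s = sum(subset) - sum(range(len(subset)))
    return -1 if s % 2 else 1


def wedge(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Prefactor-free Grassmann product of RDM-like tensors."""
    ka = A.ndim // 2
    kb = B.ndim // 2
    k = ka + kb
    n = A.shape[0]
    out = np.zeros((n,) * (2 * k))
    prod = np.multiply.outer(A, B)
    # prod axes: A-lowers, A-uppers, B-lowers, B-uppers
    for I in combinations(range(k), ka):
        sI = _subset_parity(I)
        restI = [x for x in range(k) if x not in I]
        for J in combinations(range(k), ka):
            sJ = _subset_parity(J)
            restJ = [x for x in range(k) if x not in J]
            # destination axes for (A-lowers, A-uppers, B-lowers, B-uppers)
            dest = (
                list(I)
                + [k + x for x in J]
                + restI
                + [k + x for x in restJ]
            )
            out += sI * sJ * np.moveaxis(prod, range(2 * k), dest)
    return out


# ---------------------------------------------------------------------------
# density matrix sets
# ---------------------------------------------------------------------------


@dataclass
class DensityMatrixSet:
    """Dense spinorbital k-RDMs (k = 1..3) of one monomer state.

    ``orbitals`` maps the support (spatial) orbitals to the dimer AO basis;
    tensors are over 2*m spinorbitals.
    """

    label: str
    n_elec: int
    orbitals: np.ndarray                 # (nao, m)
    gammas: dict[int, np.ndarray] = field(default_factory=dict)
    flavor: str = "spinorbital"
    convention: str = "lower-upper, factorial-free (trace = N!/(N-k)!)"

    @property
    def n_spatial(self) -> int:
        return self.orbitals.shape[1]

    def gamma(self, k: int) -> np.ndarray:
        if k > self.n_elec:
            n = 2 * self.n_spatial
            return np.zeros((n,) * (2 * k))
        if k not in self.gammas:
            raise KeyError(f"rank-{k} RDM not available (have {sorted(self.gammas)})")
        return self.gammas[k]

    def validate(self, atol: float = 1e-8) -> None:
        n = self.n_elec
        for k, g in self.gammas.items():
            if k > n:
                if np.max(np.abs(g)) > atol:
                    raise ValueError(f"Gamma^{k} must vanish for N={n}")
                continue
            expected = 1.0
            for j in range(k):
                expected *= n - j
            tr = g
            for _ in range(k):
                tr = np.trace(tr, axis1=0, axis2=tr.ndim // 2)
            if abs(float(tr) - expected) > atol * max(1.0, expected):
                raise ValueError(
                    f"Gamma^{k} trace {float(tr):.10f} != N!/(N-k)! = {expected}"
                )
        if 1 in self.gammas:
            evals = np.linalg.eigvalsh(self.gammas[1])
            if evals.min() < -atol or evals.max() > 1.0 + atol:
                raise ValueError("Gamma^1 eigenvalues outside [0, 1]")


def hf_rdms(orbitals: np.ndarray, n_occ: int, k_max: int = 3,
            label: str = "A") -> DensityMatrixSet:
    """Closed-shell determinant RDMs: Gamma^k = (1/k!) (Gamma^1)^(^k).

    ``orbitals`` are the monomer MOs in the AO basis; the first ``n_occ``
    spatial orbitals are doubly occupied and form the support.
    """
    occ = orbitals[:, :n_occ]
    m = n_occ
    g1 = np.zeros((2 * m, 2 * m))
    for i in range(m):
        g1[2 * i, 2 * i] = 1.0
        g1[2 * i + 1, 2 * i + 1] = 1.0
    gammas = {1: g1}
    acc = g1
    fact = 1
    for k in range(2, k_max + 1):
        acc = wedge(acc, g1)
        fact *= k
        gammas[k] = acc / fact
    return DensityMatrixSet(label, 2 * n_occ, occ, gammas)


def k_rdm_from_ci(ci, k: int, label: str = "A", orbitals=None) -> np.ndarray:
    """Dense spinorbital k-RDM from a CI description.

    ``ci`` is either a :class:`saptdx.fock.CIVector` or a symmetric
    two-electron CI matrix; k > 3 is rejected (supply external RDMs for the
    general-order path instead).
    """
    if k > 3:
        raise ValueError("k-RDMs beyond rank 3 are not built internally")
    if isinstance(ci, fock.CIVector):
        return fock.k_rdm_dense(ci, k)
    C = np.asarray(ci)
    vec = fock.two_electron_ci_vector(C)
    if k > 2:
        m = C.shape[0]
        return np.zeros((2 * m,) * 6)
    return fock.k_rdm_dense(vec, k, 2 * C.shape[0])


def two_electron_rdms(C: np.ndarray, orbitals: np.ndarray, label: str = "A",
                      k_max: int = 3) -> DensityMatrixSet:
    """Closed-form dense RDMs of a normalized two-electron singlet CI matrix."""
    m = C.shape[0]
    n = 2 * m
    a = slice(0, n, 2)
    b = slice(1, n, 2)
    g1 = np.zeros((n, n))
    D = C @ C.T  # spatial one-matrix per spin
    g1[a, a] = D
    g1[b, b] = D
    gammas = {1: g1}
    if k_max >= 2:
        g2 = np.zeros((n, n, n, n))
        # <a^dag_{u1} a^dag_{u2} a_{l2} a_{l1}>; amplitude of a^dag_{p a} a^dag_{q b}|0>
        # on |..>: psi(p_alpha, q_beta) = C_pq
        # alpha-beta block: l1=ka, l2=lb, u1=ia, u2=jb -> C_kl C_ij
        P = np.einsum("kl,ij->klij", C, C)
        g2[np.ix_(range(0, n, 2), range(1, n, 2), range(0, n, 2), range(1, n, 2))] = P
        g2[np.ix_(range(1, n, 2), range(0, n, 2), range(1, n, 2), range(0, n, 2))] = (
            np.einsum("lk,ji->klij", C, C)
        )
        g2[np.ix_(range(0, n, 2), range(1, n, 2), range(1, n, 2), range(0, n, 2))] = (
            -np.einsum("kl,ji->klij", C, C)
        )
        g2[np.ix_(range(1, n, 2), range(0, n, 2), range(0, n, 2), range(1, n, 2))] = (
            -np.einsum("lk,ij->klij", C, C)
        )
        gammas[2] = g2
    if k_max >= 3:
        gammas[3] = np.zeros((n,) * 6)
    return DensityMatrixSet(label, 2, orbitals, gammas)


# ---------------------------------------------------------------------------
# geminal model (APSG / GVB-PP)
# ---------------------------------------------------------------------------


@dataclass
class GeminalModel:
    """APSG/GVB-PP structure: disjoint orbital lists with expansion coefficients.

    ``orbital_sets[K]`` indexes spatial orbitals of the monomer support;
    ``coefficients[K]`` are the c_i^K (sum of squares 1).  Occupation numbers
    are n_i^K = (c_i^K)^2 per spin.
    """

    orbital_sets: list[list[int]]
    coefficients: list[np.ndarray]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for orbs, coefs in zip(self.orbital_sets, self.coefficients):
            if len(orbs) != len(coefs):
                raise ValueError("orbital list and coefficient list differ in length")
            if seen & set(orbs):
                raise ValueError("geminal orbital sets must be pairwise disjoint")
            seen |= set(orbs)
            norm = float(np.sum(np.asarray(coefs) ** 2))
            if abs(norm - 1.0) > 1e-10:
                raise ValueError(f"geminal coefficients not normalized: sum c^2 = {norm}")

    @property
    def n_geminals(self) -> int:
        return len(self.orbital_sets)

    @property
    def n_elec(self) -> int:
        return 2 * self.n_geminals

    def occupations(self, m: int) -> np.ndarray:
        """Per-spin occupations over m support orbitals."""
        n = np.zeros(m)
        for orbs, coefs in zip(self.orbital_sets, self.coefficients):
            n[list(orbs)] = np.asarray(coefs) ** 2
        return n

    def pair_amplitudes(self, m: int) -> np.ndarray:
        """Matrix Pi with Pi_ij = c_i c_j for same-geminal orbitals, else 0."""
        P = np.zeros((m, m))
        for orbs, coefs in zip(self.orbital_sets, self.coefficients):
            idx = list(orbs)
            P[np.ix_(idx, idx)] = np.outer(coefs, coefs)
        return P


def apsg_rdms(gem: GeminalModel, orbitals: np.ndarray, k_max: int = 3,
              label: str = "A") -> DensityMatrixSet:
    """Dense spin-resolved RDMs of an APSG/GVB-PP product state.

    Built as the wedge product of per-geminal two-electron RDMs (exact for
    strongly orthogonal geminals); intended for small supports and as the
    reference for the factorized geminal fast path.
    """
    m = orbitals.shape[1]
    n = 2 * m
    per_gem = []
    for orbs, coefs in zip(gem.orbital_sets, gem.coefficients):
        C = np.zeros((m, m))
        idx = list(orbs)
        C[idx, idx] = np.asarray(coefs)
        per_gem.append(two_electron_rdms(C, orbitals, label))
    gammas: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        total = np.zeros((n,) * (2 * k))

        # distribute rank k over the geminals; each geminal contributes 0..2
        def rec0(g_index, k_left, acc):
            nonlocal total
            if k_left == 0 and acc is not None:
                # remaining geminals contribute rank 0
                total += acc
                return
            if g_index == len(per_gem):
                return
            # skip this geminal
            rec0(g_index + 1, k_left, acc)
            for kk in (1, 2):
                if kk > k_left:
                    continue
                g = per_gem[g_index].gamma(kk)
                nxt = g if acc is None else wedge(acc, g)
                rec0(g_index + 1, k_left - kk, nxt)

        rec0(0, k, None)
        gammas[k] = total
    return DensityMatrixSet(label, gem.n_elec, orbitals, gammas)


def frozen_core_embed_rdms(active: DensityMatrixSet, core_spatial: list[int],
                           k_max: int = 3) -> DensityMatrixSet:
    """Embed active-space RDMs in a doubly occupied core on the same support.

    ``core_spatial`` lists support orbitals that are doubly occupied in every
    determinant; they must not carry active RDM weight.
    """
    m = active.n_spatial
    n = 2 * m
    for i in core_spatial:
        if abs(active.gamma(1)[2 * i, 2 * i]) > 1e-12:
            raise ValueError(f"core orbital {i} overlaps the active RDM support")
    if not core_spatial:
        return active
    g1c = np.zeros((n, n))
    for i in core_spatial:
        g1c[2 * i, 2 * i] = 1.0
        g1c[2 * i + 1, 2 * i + 1] = 1.0
    core_gammas = {1: g1c}
    nc = 2 * len(core_spatial)
    acc = g1c
    fact = 1
    for k in range(2, min(k_max, nc) + 1):
        acc = wedge(acc, g1c)
        fact *= k
        core_gammas[k] = acc / fact
    n_tot = active.n_elec + nc
    gammas: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        total = np.zeros((n,) * (2 * k))
        for kc in range(0, k + 1):
            ka = k - kc
            if kc > nc or ka > active.n_elec:
                continue
            if kc == 0:
                total += active.gamma(ka)
            elif ka == 0:
                if kc in core_gammas:
                    total += core_gammas[kc]
            else:
                if kc in core_gammas:
                    total += wedge(core_gammas[kc], active.gamma(ka))
        gammas[k] = total
    return DensityMatrixSet(active.label, n_tot, active.orbitals, gammas)


# ---------------------------------------------------------------------------
# CAS(n,n) -> GVB-PP mapping
# ---------------------------------------------------------------------------


@dataclass
class GvbMappingResult:
    model: GeminalModel
    score: float                  # Frobenius norm of the pairing-block mismatch
    score_per_element: float
    pairs: list[tuple[int, int]]  # (strong, weak) support indices


def map_cas_to_gvb(pair_block: np.ndarray, occupations: np.ndarray,
                   threshold: float = 1e-2) -> GvbMappingResult:
    """Pair strongly and weakly occupied active orbitals into GVB-PP geminals.

    Parameters
    ----------
    pair_block:
        P_ij = Gamma^2_{alpha beta}(i ibar; j jbar) over the active natural
        orbitals: the pairing block of the CAS 2-RDM.  For a GVB-PP state
        P_ij = c_i c_j within a geminal.
    occupations:
        Per-spin natural occupations n_i = c_i^2 (i.e. half the spin-summed
        occupation numbers).
    threshold:
        Maximum tolerated per-element mismatch before the state is declared
        not of GVB-PP type.
    """
    occupations = np.asarray(occupations, dtype=float)
    m = len(occupations)
    if int(round(2 * occupations.sum())) % 2:
        raise ValueError("odd electron count cannot map onto geminal pairs")
    order = np.argsort(-occupations)
    n_gem = int(round(occupations.sum()))
    strong = list(order[:n_gem])
    weak = [i for i in order[n_gem:] if occupations[i] > 0.0]
    if n_gem == 1:
        # CAS(2,n): a single geminal holds every active orbital, no search
        orbs = [i for i in order if occupations[i] > 0.0]
        c = np.sqrt(occupations[orbs])
        signs = np.sign(pair_block[orbs[0], orbs])
        signs[0] = 1.0
        signs[signs == 0] = 1.0
        c = c * signs
        c /= np.linalg.norm(c)
        model = GeminalModel([list(orbs)], [c])
        P_model = model.pair_amplitudes(m)
        idx = np.ix_(orbs, orbs)
        score = float(np.linalg.norm(pair_block[idx] - P_model[idx]))
        return GvbMappingResult(model, score, score / max(len(orbs), 1),
                                [(orbs[0], o) for o in orbs[1:]])
    if len(weak) < len(strong):
        raise ValueError("fewer weakly than strongly occupied orbitals")
    c_strong = np.sqrt(occupations[strong])
    c_weak = np.sqrt(occupations[weak])
    # independent pair cost: mismatch of the strong-weak coupling element
    cost = np.zeros((len(strong), len(weak)))
    for a, u in enumerate(strong):
        for b, w in enumerate(weak):
            sgn = np.sign(pair_block[u, w]) or -1.0
            cost[a, b] = (pair_block[u, w] - c_strong[a] * sgn * c_weak[b]) ** 2
            # favor pairing orbitals that actually couple
            cost[a, b] -= pair_block[u, w] ** 2
    rows, cols = linear_sum_assignment(cost)
    pairs = [(strong[a], weak[b]) for a, b in zip(rows, cols)]
    orbital_sets, coefficients = [], []
    for (u, w) in pairs:
        sgn = np.sign(pair_block[u, w]) or -1.0
        c = np.array([np.sqrt(occupations[u]), sgn * np.sqrt(occupations[w])])
        c /= np.linalg.norm(c)
        orbital_sets.append([u, w])
        coefficients.append(c)
    model = GeminalModel(orbital_sets, coefficients)
    active = strong + weak
    idx = np.ix_(active, active)
    diff = pair_block[idx] - model.pair_amplitudes(m)[idx]
    # off-geminal pairing elements of a true GVB state vanish; compare all
    score = float(np.linalg.norm(diff))
    per_el = score / len(active)
    if np.max(np.abs(diff)) > threshold:
        raise ValueError(
            "no GVB-PP pairing reproduces the 2-RDM within "
            f"{threshold:g} per element (best pairs {pairs}, max dev "
            f"{np.max(np.abs(diff)):.3e}); the state is not of GVB-PP type"
        )
    return GvbMappingResult(model, score, per_el, pairs)
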