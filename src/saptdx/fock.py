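"""Tiny occupation-number determinant algebra.

Determinants are Python integers used as bit masks over spinorbitals.  The
spinorbital ordering is interleaved, so = 2*spatial + spin (spin 0 = alpha,
1 = beta), and the phase convention is that bit 0 is the leftmost creation
operator: |n> = (a_0^dag)^{n_0} (a_1^dag)^{n_1} ... |vac>.  These routines are
deliberately simple and exact; they back the determinant-space oracle and the
reduced-density-matrix cross-checks on small systems.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def spinorb(spatial: int, spin: int) -> int:
    return 2 * spatial + spin


def phase_create(det: int, orb: int) -> int:
    """Sign of a_orb^dag |det| from commuting past occupied lower bits."""
    return -1 if bin(det & ((1 << orb) - 1)).count("1") % 2 else 1


def apply_create(det: int, orb: int):
    if det & (1 << orb):
        return None, 0
    return det | (1 << orb), phase_create(det, orb)


def apply_annihilate(det: int, orb: int):
    if not det & (1 << orb):
        return None, 0
    return det & ~(1 << orb), phase_create(det, orb)


def occ_list(det: int) -> list[int]:
    out = []
    i = 0
    while det:
        if det & 1:
            out.append(i)
        det >>= 1
        i += 1
    return out


def all_dets(n_spinorb: int, n_elec: int) -> list[int]:
    dets = []
    for occ in combinations(range(n_spinorb), n_elec):
        d = 0
        for o in occ:
            d |= 1 << o
        dets.append(d)
    return dets


class CIVector:
    """A CI expansion over determinants of a fixed particle number."""

    def __init__(self, coeffs: dict[int, float], n_spinorb: int):
        self.coeffs = {d: c for d, c in coeffs.items() if c != 0.0}
        self.n_spinorb = n_spinorb

    def norm(self) -> float:
        return float(np.sqrt(sum(c * c for c in self.coeffs.values())))

    def normalized(self) -> "CIVector":
        n = self.norm()
        return CIVector({d: c / n for d, c in self.coeffs.items()}, self.n_spinorb)

    def dot(self, other: "CIVector") -> float:
        if len(self.coeffs) > len(other.coeffs):
            self, other = other, self
        return float(sum(c * other.coeffs.get(d, 0.0) for d, c in self.coeffs.items()))


def apply_excitation(vec: CIVector, creators, annihilators) -> CIVector:
    """Apply a_{c1}^dag ... a_{cm}^dag a_{am} ... a_{a1} (operators right to left)."""
    out: dict[int, float] = {}
    for det, coef in vec.coeffs.items():
        d = det
        ph = 1
        ok = True
        for orb in reversed(annihilators):
            d, p = apply_annihilate(d, orb)
            if d is None:
                ok = False
                break
            ph *= p
        if not ok:
            continue
        for orb in reversed(creators):
            d, p = apply_create(d, orb)
            if d is None:
                ok = False
                break
            ph *= p
        if not ok:
            continue
        out[d] = out.get(d, 0.0) + ph * coef
    return CIVector(out, vec.n_spinorb)


def k_rdm_dense(vec: CIVector, k: int, n_spinorb: int | None = None) -> np.ndarray:
    """Dense spinorbital k-RDM, Gamma[l1..lk, u1..uk] = <a^dag_{u1}..a^dag_{uk} a_{lk}..a_{l1}>.

    Normalization is factorial-free: trace over all diagonals equals
    N!/(N-k)!.  Brute force over index tuples; intended for tiny spaces only.
    """
    n = n_spinorb or vec.n_spinorb
    shape = (n,) * (2 * k)
    gamma = np.zeros(shape)
    vec = vec if isinstance(vec, CIVector) else CIVector(vec, n)
    for uppers in np.ndindex(*(n,) * k):
        if len(set(uppers)) < k:
            continue
        for lowers in np.ndindex(*(n,) * k):
            if len(set(lowers)) < k:
                continue
            # x^{u}_{l} = a^dag_{u1}..a^dag_{uk} a_{lk}..a_{l1}
            new = apply_excitation(vec, list(uppers), list(lowers)[::-1])
            val = new.dot(vec)
            if val != 0.0:
                gamma[tuple(lowers) + tuple(uppers)] = val
    return gamma


def two_electron_ci_vector(C: np.ndarray) -> CIVector:
    """CI vector of Psi = sum_pq C_pq |p_alpha q_beta> over interleaved spinorbitals."""
    m = C.shape[0]
    coeffs: dict[int, float] = {}
    for p in range(m):
        for q in range(m):
            c = C[p, q]
            if c == 0.0:
                continue
            # a^dag_{p alpha} a^dag_{q beta} |vac>
            d1, ph1 = apply_create(0, spinorb(q, 1))
            d2, ph2 = apply_create(d1, spinorb(p, 0))
            coeffs[d2] = coeffs.get(d2, 0.0) + ph1 * ph2 * c
    return CIVector(coeffs, 2 * m)


def geminal_product_ci_vector(geminals) -> CIVector:
    """CI vector of a product of singlet geminals on disjoint orbital sets.

    ``geminals`` is a list of (orbital_index_list, coefficient_array).
    """
    vec = CIVector({0: 1.0}, 0)
    nmax = 0
    for orbs, coefs in geminals:
        nmax = max(nmax, 2 * (max(orbs) + 1))
        new: dict[int, float] = {}
        for det, c0 in vec.coeffs.items():
            for i, ci in zip(orbs, coefs):
                if ci == 0.0:
                    continue
                d1, p1 = apply_create(det, spinorb(i, 1))
                if d1 is None:
                    continue
                d2, p2 = apply_create(d1, spinorb(i, 0))
                if d2 is None:
                    continue
                new[d2] = new.get(d2, 0.0) + c0 * ci * p1 * p2
        vec = CIVector(new, nmax)
    vec.n_spinorb = nmax
    return vec
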