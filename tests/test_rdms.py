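"""Reduced-density-matrix builders against brute-force determinant algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saptdx import rdms, fock
from saptdx.rdms import GeminalModel, map_cas_to_gvb


def random_symmetric_ci(m, seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(m, m))
    C = (A + A.T) / 2
    return C / np.linalg.norm(C)


@pytest.mark.parametrize("seed", [0, 1])
def test_two_electron_rdms_match_determinant_algebra(seed):
    m = 3
    C = random_symmetric_ci(m, seed)
    dm = rdms.two_electron_rdms(C, np.eye(m), k_max=3)
    dm.validate()
    vec = fock.two_electron_ci_vector(C)
    for k in (1, 2):
        brute = fock.k_rdm_dense(vec, k, 2 * m)
        assert np.allclose(dm.gamma(k), brute, atol=1e-12)
    assert np.count_nonzero(dm.gamma(3)) == 0  # k > N vanishes


def test_hf_rdms_are_wick_products():
    """Determinant k-RDMs equal the antisymmetrized products of the 1-RDM."""
    hf = rdms.hf_rdms(np.eye(5), 2, k_max=3)
    hf.validate()
    det = 0b1111  # two doubly occupied spatial orbitals
    vec = fock.CIVector({det: 1.0}, 4)
    for k in (1, 2, 3):
        assert np.allclose(hf.gamma(k), fock.k_rdm_dense(vec, k, 4), atol=1e-12)


def test_hf_rdm_trace_ten_electrons():
    hf = rdms.hf_rdms(np.eye(7), 5, k_max=1)
    assert np.trace(hf.gamma(1)) == pytest.approx(10.0)


def test_apsg_rdms_match_ci_expansion():
    """Wedge-assembled APSG RDMs equal the explicit geminal-product CI."""
    gm = GeminalModel(
        [[0, 1], [2, 3]],
        [np.array([0.92, -np.sqrt(1 - 0.92**2)]), np.array([0.8, 0.6])],
    )
    dm = rdms.apsg_rdms(gm, np.eye(4), k_max=3)
    dm.validate()
    vec = fock.geminal_product_ci_vector(
        [([0, 1], [0.92, -np.sqrt(1 - 0.92**2)]), ([2, 3], [0.8, 0.6])]
    )
    for k in (1, 2, 3):
        assert np.allclose(dm.gamma(k), fock.k_rdm_dense(vec, k, 8), atol=1e-12)


def test_apsg_hf_limit():
    """A geminal with c = (1, 0) reduces exactly to the determinant RDMs."""
    gm = GeminalModel([[0, 1]], [np.array([1.0, 0.0])])
    dm = rdms.apsg_rdms(gm, np.eye(2), k_max=2)
    hf = rdms.hf_rdms(np.eye(2), 1, k_max=2)
    assert np.allclose(dm.gamma(1)[:2, :2], hf.gamma(1), atol=1e-14)
    assert np.allclose(dm.gamma(2)[:2, :2, :2, :2], hf.gamma(2), atol=1e-14)


def test_apsg_gamma3_trace_two_geminals():
    gm = GeminalModel([[0, 1], [2, 3]],
                      [np.array([0.9, np.sqrt(0.19)]), np.array([0.7, -np.sqrt(0.51)])])
    dm = rdms.apsg_rdms(gm, np.eye(4), k_max=3)
    g3 = dm.gamma(3)
    tr = np.einsum("abcabc->", g3)
    assert tr == pytest.approx(4 * 3 * 2, abs=1e-8)


def test_frozen_core_embedding_matches_full_ci():
    gm = GeminalModel([[1, 2]], [np.array([0.8, -0.6])])
    act = rdms.apsg_rdms(gm, np.eye(3), k_max=3)
    emb = rdms.frozen_core_embed_rdms(act, [0], k_max=3)
    emb.validate()
    vec = fock.geminal_product_ci_vector([([0], [1.0]), ([1, 2], [0.8, -0.6])])
    for k in (1, 2, 3):
        assert np.allclose(emb.gamma(k), fock.k_rdm_dense(vec, k, 6), atol=1e-12)


def test_frozen_core_embedding_rejects_overlap():
    gm = GeminalModel([[0, 1]], [np.array([0.8, -0.6])])
    act = rdms.apsg_rdms(gm, np.eye(3), k_max=1)
    with pytest.raises(ValueError, match="overlaps"):
        rdms.frozen_core_embed_rdms(act, [0], k_max=1)


def test_empty_core_is_identity():
    gm = GeminalModel([[0, 1]], [np.array([0.8, 0.6])])
    act = rdms.apsg_rdms(gm, np.eye(2), k_max=2)
    emb = rdms.frozen_core_embed_rdms(act, [], k_max=2)
    assert emb is act


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 10**6))
def test_two_electron_rdm_invariants(seed):
    """Trace identities and 1-RDM eigenvalue bounds for random singlet states."""
    C = random_symmetric_ci(4, seed)
    dm = rdms.two_electron_rdms(C, np.eye(4), k_max=2)
    dm.validate()
    g1 = dm.gamma(1)
    assert np.trace(g1) == pytest.approx(2.0, abs=1e-10)
    ev = np.linalg.eigvalsh(g1)
    assert ev.min() > -1e-10 and ev.max() < 1.0 + 1e-10


# ---------------------------------------------------------------------------
# CAS(n,n) -> GVB-PP mapping
# ---------------------------------------------------------------------------


def _pair_block_from_model(gm: GeminalModel, m: int) -> np.ndarray:
    return gm.pair_amplitudes(m)


def test_map_cas_to_gvb_roundtrip_shuffled():
    """A 2-RDM built exactly in GVB-PP form is recovered, pairing and signs."""
    rng = np.random.default_rng(2)
    gm = GeminalModel(
        [[0, 5], [2, 3], [4, 1]],
        [np.array([0.95, -np.sqrt(1 - 0.95**2)]),
         np.array([0.9, -np.sqrt(1 - 0.81)]),
         np.array([0.85, -np.sqrt(1 - 0.85**2)])],
    )
    m = 6
    P = _pair_block_from_model(gm, m)
    occ = gm.occupations(m)
    res = map_cas_to_gvb(P, occ)
    assert res.score < 1e-10
    # same partition of orbitals into geminals
    got = {frozenset(map(int, idx)) for idx, _ in
           zip(res.model.orbital_sets, res.model.coefficients)}
    want = {frozenset(s) for s in gm.orbital_sets}
    assert got == want
    assert np.allclose(res.model.pair_amplitudes(m), P, atol=1e-10)


def test_map_cas_to_gvb_matches_exhaustive_search():
    """The assignment solution equals brute force over all perfect matchings."""
    from itertools import permutations

    rng = np.random.default_rng(4)
    gm = GeminalModel(
        [[0, 2], [1, 3]],
        [np.array([0.93, -np.sqrt(1 - 0.93**2)]),
         np.array([0.88, -np.sqrt(1 - 0.88**2)])],
    )
    m = 4
    P = _pair_block_from_model(gm, m) + 1e-4 * rng.normal(size=(m, m))
    P = (P + P.T) / 2
    occ = gm.occupations(m)
    res = map_cas_to_gvb(P, occ, threshold=1.0)
    strong = sorted(range(m), key=lambda i: -occ[i])[:2]
    weak = [i for i in range(m) if i not in strong and occ[i] > 0]

    def score(assign):
        model = GeminalModel(
            [[u, w] for u, w in zip(strong, assign)],
            [np.array([np.sqrt(occ[u]), np.sign(P[u, w]) * np.sqrt(occ[w])])
             / np.sqrt(occ[u] + occ[w])
             for u, w in zip(strong, assign)],
        )
        active = strong + list(assign)
        idx = np.ix_(active, active)
        return float(np.linalg.norm(P[idx] - model.pair_amplitudes(m)[idx]))

    best = min(permutations(weak), key=score)
    got_pairs = {(u, w) for u, w in res.pairs}
    assert got_pairs == set(zip(strong, best))


def test_map_cas_to_gvb_single_geminal():
    """CAS(2,n): every active orbital joins one geminal, no search needed."""
    c = np.array([0.9, -0.3, -0.2, -np.sqrt(1 - 0.81 - 0.09 - 0.04)])
    gm = GeminalModel([[0, 1, 2, 3]], [c])
    P = gm.pair_amplitudes(4)
    res = map_cas_to_gvb(P, c**2)
    assert res.score < 1e-10
    assert len(res.model.orbital_sets) == 1
    got = dict(zip(map(int, res.model.orbital_sets[0]), res.model.coefficients[0]))
    assert got.keys() == {0, 1, 2, 3}
    for i, ci in enumerate(c):
        assert got[i] == pytest.approx(ci, abs=1e-10)


def test_map_cas_to_gvb_rejects_non_gvb_state():
    occ = np.array([0.9, 0.6, 0.3, 0.2])  # not GVB-representable coupling
    P = np.full((4, 4), 0.3)
    with pytest.raises(ValueError, match="not of GVB-PP type"):
        map_cas_to_gvb(P, occ, threshold=1e-3)
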