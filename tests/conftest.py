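"""Shared fixtures: tiny Gaussian bases and prebuilt model dimers.

Everything is generated at test time; the minimal bases keep the determinant
oracle (<= 20 spinorbitals) and the dense density-matrix path cheap while the
integrals remain fully real.
"""

from __future__ import annotations

import numpy as np
import pytest

from saptdx import ci, build_dimer_system, make_dimer
from saptdx.scf import rhf

# one contracted s function per H: the smallest basis with nontrivial overlap
MINIMAL_H = {"H": [(0, np.array([1.2, 0.3]), np.array([0.6, 0.5]))]}
# two s functions per H: FCI support = 4 orbitals per H2 monomer
SMALL_H = {
    "H": [
        (0, np.array([1.2, 0.3]), np.array([0.6, 0.5])),
        (0, np.array([0.12]), np.array([1.0])),
    ]
}


def t_shaped_h2h2(r_probe=1.4, r_spec=1.4, R=4.0, basis=MINIMAL_H):
    geo = make_dimer(
        ["H"] * 4,
        [[-r_probe / 2, 0, 0], [r_probe / 2, 0, 0],
         [0, 0, R - r_spec / 2], [0, 0, R + r_spec / 2]],
        "AABB",
    )
    return build_dimer_system(geo, basis)


def solve_fci_monomer(system, label, nroots=1):
    """RHF + all-orbital two-electron CI for one monomer; returns (rhf, states)."""
    r = rhf(system.core_hamiltonian(label), system.eri, system.S, 2,
            e_nuc=system.nuclear_repulsion(label))
    C = r.mo_coeff
    h = C.T @ system.core_hamiltonian(label) @ C
    t = np.tensordot(system.eri, C, axes=([0], [0]))
    t = np.tensordot(t, C, axes=([0], [0]))
    t = np.tensordot(t, C, axes=([0], [0]))
    eri = np.tensordot(t, C, axes=([0], [0]))
    states = ci.solve_two_electron_ci(h, eri, C, nroots=nroots)
    return r, states


@pytest.fixture(scope="session")
def minimal_dimer():
    """Minimal-basis T-shaped H2...H2 at moderate overlap."""
    return t_shaped_h2h2()


@pytest.fixture(scope="session")
def minimal_monomers(minimal_dimer):
    """(rhf_A, fci_A), (rhf_B, fci_B) for the minimal dimer."""
    rA, stA = solve_fci_monomer(minimal_dimer, "A")
    rB, stB = solve_fci_monomer(minimal_dimer, "B")
    return (rA, stA[0]), (rB, stB[0])


@pytest.fixture(scope="session")
def small_dimer():
    """Two-s-function H2...H2 (8 AOs): richer FCI structure, oracle still cheap."""
    return t_shaped_h2h2(basis=SMALL_H)
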