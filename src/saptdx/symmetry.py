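"""Axis-aligned mirror symmetry for excited-root classification.

The T-shaped fixtures have an exact reflection (through the plane
perpendicular to the reflected monomer's bond) that distinguishes the
gerade/ungerade character of its states; CI roots are labeled by the
expectation value of that reflection instead of bare energy ordering.
"""

from __future__ import annotations

import numpy as np

from .geometry import DimerGeometry
from .integrals.basis import BasisSet, n_sph

# sign of each spherical component under x -> -x, y -> -y, z -> -z,
# in this package's AO ordering: p = (x, y, z); d = (xy, yz, z2, xz, x2-y2)
_MIRROR_SIGNS = {
    0: {0: [1], 1: [-1, 1, 1], 2: [-1, 1, 1, -1, 1]},
    1: {0: [1], 1: [1, -1, 1], 2: [-1, -1, 1, 1, 1]},
    2: {0: [1], 1: [1, 1, -1], 2: [1, -1, 1, -1, 1]},
}


def mirror_ao_matrix(geometry: DimerGeometry, basis: BasisSet, axis: int,
                     origin: float) -> np.ndarray:
    """AO representation of the reflection x_axis -> 2*origin - x_axis.

    The geometry must map onto itself under the reflection (atom permutation
    with identical elements); raises otherwise.
    """
    coords = geometry.coords
    n_at = len(coords)
    mapping = {}
    for i in range(n_at):
        target = coords[i].copy()
        target[axis] = 2.0 * origin - target[axis]
        hits = [
            j
            for j in range(n_at)
            if np.linalg.norm(coords[j] - target) < 1e-8
            and geometry.symbols[j] == geometry.symbols[i]
        ]
        if not hits:
            raise ValueError(f"geometry is not symmetric under the requested mirror "
                             f"(atom {i} has no image)")
        mapping[i] = hits[0]
    nao = basis.nao
    P = np.zeros((nao, nao))
    # shells are generated per atom in identical order, so shell s on atom i
    # maps to the shell at the same within-atom position on mapping[i]
    shells_of_atom: dict[int, list[int]] = {}
    for idx, sh in enumerate(basis.shells):
        shells_of_atom.setdefault(sh.atom_index, []).append(idx)
    for iat, shell_ids in shells_of_atom.items():
        jat = mapping[iat]
        for pos, sid in enumerate(shell_ids):
            tid = shells_of_atom[jat][pos]
            sh = basis.shells[sid]
            signs = _MIRROR_SIGNS[axis][sh.l]
            o1 = basis.sph_offsets[sid]
            o2 = basis.sph_offsets[tid]
            for c in range(n_sph(sh.l)):
                P[o2 + c, o1 + c] = signs[c]
    return P


def mirror_mo_matrix(system, mo_coeff: np.ndarray, axis: int,
                     origin: float) -> np.ndarray:
    """Reflection operator in an orthonormal MO basis: C^T S_ao P_ao C."""
    P = mirror_ao_matrix(system.geometry, system.basis, axis, origin)
    return mo_coeff.T @ system.S @ P @ mo_coeff
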