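"""Interaction tensors between the monomers in their own MO bases.

The interaction operator in second quantization is fully described by the
modified potential

    vtilde_{pr}^{qs} = v_{pr}^{qs} + d_pq (vA)_rs / N_A + (vB)_pq d_rs / N_B
                       + V_AB/(N_A N_B) d_pq d_rs

(array layout ``vtilde[p, q, r, s]``, p,q in A, r,s in B, with
v[p,q,r,s] = (pq|rs) in chemists' notation).  The exchange contractions also
need the generalization where the "created" indices q and/or s range over the
partner monomer's orbitals; those blocks are built from the same joint-index
formula with Kronecker deltas replaced by overlap blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals.engine import DimerSystem


@dataclass
class InteractionTensors:
    """All interaction blocks over the monomer support orbitals (hartree)."""

    S: np.ndarray        # (mA, mB) intermolecular MO overlap
    vA: np.ndarray       # (mB, mB) attraction of B electrons to A nuclei
    vB: np.ndarray       # (mA, mA) attraction of A electrons to B nuclei
    v: np.ndarray        # (mA, mA, mB, mB): v[p,q,r,s] = (pq|rs)
    V_AB: float          # nuclear repulsion between the monomers
    vtilde: np.ndarray   # (mA, mA, mB, mB), modified potential
    N_A: int
    N_B: int
    # generalized vtilde blocks: second/fourth axis on the partner monomer
    vt_qs: np.ndarray    # = vtilde (alias), q in A, s in B
    vt_ss: np.ndarray    # (mA, mB, mB, mB): q-slot ranges over B (index s1)
    vt_qq: np.ndarray    # (mA, mA, mB, mA): s-slot ranges over A (index q1)
    vt_sq: np.ndarray    # (mA, mB, mB, mA): both slots swapped

    @property
    def mA(self) -> int:
        return self.S.shape[0]

    @property
    def mB(self) -> int:
        return self.S.shape[1]

    def swapped(self) -> "InteractionTensors":
        """The same tensors with the roles of A and B interchanged."""
        return InteractionTensors(
            S=self.S.T,
            vA=self.vB,
            vB=self.vA,
            v=self.v.transpose(2, 3, 0, 1),
            V_AB=self.V_AB,
            vtilde=self.vtilde.transpose(2, 3, 0, 1),
            N_A=self.N_B,
            N_B=self.N_A,
            vt_qs=self.vt_qs.transpose(2, 3, 0, 1),
            vt_ss=self.vt_qq.transpose(2, 3, 0, 1),
            vt_qq=self.vt_ss.transpose(2, 3, 0, 1),
            vt_sq=self.vt_sq.transpose(2, 3, 0, 1),
        )


def transform_interaction_tensors(system: DimerSystem, orbA: np.ndarray,
                                  orbB: np.ndarray) -> InteractionTensors:
    """Build all interaction blocks for the given monomer support orbitals.

    ``orbA``/``orbB`` are (nao, m) MO coefficient matrices over the dimer AO
    basis (the RDM support of each monomer: core + active orbitals).
    """
    if orbA.shape[0] != system.nao or orbB.shape[0] != system.nao:
        raise ValueError("orbital coefficient matrices do not match the AO dimension")
    N_A = system.n_electrons("A")
    N_B = system.n_electrons("B")
    if N_A == 0 or N_B == 0:
        raise ValueError("vtilde requires at least one electron on each monomer")
    mA = orbA.shape[1]
    mB = orbB.shape[1]
    S = orbA.T @ system.S @ orbB
    vA_BB = orbB.T @ system.Vnuc_A @ orbB
    vB_AA = orbA.T @ system.Vnuc_B @ orbA
    V_AB = system.geometry.nuclear_repulsion_between()

    # joint-index one-electron blocks
    joint = np.concatenate([orbA, orbB], axis=1)
    Sj = joint.T @ system.S @ joint
    vAj = joint.T @ system.Vnuc_A @ joint
    vBj = joint.T @ system.Vnuc_B @ joint
    SA = Sj[:mA, :]        # overlap of A-support with joint
    SB = Sj[mA:, :]

    # (p x | r y) blocks, p in A-support, r in B-support, x/y in either;
    # built via a half transform to keep the memory footprint at
    # mA * nao * mB * nao plus one block at a time
    eri = system.eri
    half = np.tensordot(eri, orbA, axes=([0], [0]))        # (b, r, s, p)
    half = np.tensordot(half, orbB, axes=([1], [0]))       # (b, s, p, r)
    half = half.transpose(2, 0, 3, 1)                      # (p, b, r, d)

    def block(x_orbs, y_orbs):
        t = np.tensordot(half, x_orbs, axes=([1], [0]))    # (p, r, d, x)
        t = np.tensordot(t, y_orbs, axes=([2], [0]))       # (p, r, x, y)
        return np.ascontiguousarray(t.transpose(0, 2, 1, 3))

    def dressed(vblk, Spx, vAry, vBpx, Sry):
        out = vblk.copy()
        out += np.einsum("px,ry->pxry", Spx, vAry / N_A, optimize=True)
        out += np.einsum("px,ry->pxry", vBpx / N_B, Sry, optimize=True)
        out += (V_AB / (N_A * N_B)) * np.einsum("px,ry->pxry", Spx, Sry,
                                                optimize=True)
        return out

    xA, xB = slice(0, mA), slice(mA, mA + mB)
    v = block(orbA, orbB)
    vt_qs = dressed(v, SA[:, xA], vAj[xB, :][:, xB], vBj[:mA, xA], SB[:, xB])
    vt_ss = dressed(block(orbB, orbB), SA[:, xB], vAj[xB, xB], vBj[:mA, xB],
                    SB[:, xB])
    vt_qq = dressed(block(orbA, orbA), SA[:, xA], vAj[xB, xA], vBj[:mA, xA],
                    SB[:, xA])
    vt_sq = dressed(block(orbB, orbA), SA[:, xB], vAj[xB, xA], vBj[:mA, xB],
                    SB[:, xA])
    del half

    return InteractionTensors(
        S=S, vA=vA_BB, vB=vB_AA, v=v, V_AB=V_AB, vtilde=vt_qs,
        N_A=N_A, N_B=N_B, vt_qs=vt_qs, vt_ss=vt_ss, vt_qq=vt_qq, vt_sq=vt_sq,
    )


def vtilde_residual(t: InteractionTensors) -> float:
    """Max deviation of vtilde - v from its defining one-electron dressing."""
    mA, mB = t.mA, t.mB
    ref = (
        np.einsum("pq,rs->pqrs", np.eye(mA), t.vA) / t.N_A
        + np.einsum("pq,rs->pqrs", t.vB, np.eye(mB)) / t.N_B
        + (t.V_AB / (t.N_A * t.N_B))
        * np.einsum("pq,rs->pqrs", np.eye(mA), np.eye(mB))
    )
    return float(np.max(np.abs(t.vtilde - t.v - ref)))
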