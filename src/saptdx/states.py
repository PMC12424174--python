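"""Monomer wave functions in the dimer-centered basis.

`solve_monomer` produces the geminal-structured state every downstream
exchange contraction consumes.  Supported methods:

- ``HF``: closed-shell RHF (partner atoms as ghosts).
- ``FCI``: exact two-valence-electron CI over all (non-core) orbitals; with a
  frozen core this is frozen-core FCI.  Any two-electron singlet CI state is
  represented exactly by its natural geminal expansion.
- ``CAS(2,n)`` / ``GVB-PP`` (n = 2): variational subspace-CI optimization of
  the n-orbital active span, state-specific for excited roots.  The span is
  optimized inside a window of leading FCI natural orbitals (default 32),
  which converges the active space to well below the accuracy of interest at
  a small fraction of the full-space cost.

Excited roots are selected by mirror-symmetry character (for fixtures with an
exact reflection), not by bare energy ordering.

A :class:`MonomerWorkspace` caches the RHF solution, transformed valence
integrals and CI roots so that several method variants (FCI vs GVB vs CAS)
for the same monomer reuse them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ci
from .geminal import GeminalState
from .integrals.engine import DimerSystem
from .scf import rhf
from .symmetry import mirror_mo_matrix


@dataclass
class MethodSpec:
    """Per-monomer electronic-structure request.

    ``kind``: 'HF', 'FCI', 'GVB' or 'CAS'.  For CAS, ``n_active`` is the
    number of active (geminal) orbitals; GVB means n_active = 2.  ``root`` is
    the root index within the (optionally symmetry-filtered) valence CI;
    ``mirror`` = (axis, origin, parity) selects roots by the expectation of an
    axis-aligned reflection.  ``frozen_core`` freezes that many lowest RHF
    orbitals; ``fc_restrict`` additionally drops them from the RDM support,
    which is the index-range-restriction style frozen-core evaluation mode
    for exchange energies.
    """

    kind: str = "FCI"
    n_active: int = 0
    root: int = 0
    mirror: tuple | None = None
    frozen_core: int = 0
    fc_restrict: bool = False
    occ_threshold: float = 1e-5   # natural-geminal amplitude cutoff |c_i|
    nroots: int = 6
    opt_window: int = 32          # NO window for the CAS/GVB span optimization

    @classmethod
    def parse(cls, text: str, **kw) -> "MethodSpec":
        t = text.strip().upper()
        if t == "HF":
            return cls(kind="HF", **kw)
        if t == "FCI":
            return cls(kind="FCI", **kw)
        if t in ("GVB", "GVB-PP"):
            return cls(kind="GVB", n_active=2, **kw)
        if t.startswith("CAS"):
            inner = t[t.index("(") + 1 : t.index(")")]
            m, n = (int(x) for x in inner.split(","))
            if m != 2:
                raise ValueError("only two-electron active spaces CAS(2,n) are supported")
            return cls(kind="CAS", n_active=n, **kw)
        raise ValueError(f"unknown method {text!r}")

    def describe(self) -> str:
        base = (f"CAS(2,{self.n_active})" if self.kind in ("CAS", "GVB") else self.kind)
        if self.frozen_core:
            base += ",fc" if self.fc_restrict else f"+core({self.frozen_core})"
        return base


@dataclass
class MonomerState:
    label: str
    spec: MethodSpec
    geminal: GeminalState
    energy: float                  # total monomer energy (with own nuclear rep.)
    rhf_energy: float
    root: int = 0
    parity: float | None = None
    info: dict = field(default_factory=dict)


def _mo_transform_eri(eri, C):
    t = np.tensordot(eri, C, axes=([0], [0]))
    t = np.tensordot(t, C, axes=([0], [0]))
    t = np.tensordot(t, C, axes=([0], [0]))
    return np.tensordot(t, C, axes=([0], [0]))


class MonomerWorkspace:
    """Cached RHF + valence CI data for one monomer of a built dimer system."""

    def __init__(self, system: DimerSystem, label: str, frozen_core: int = 0,
                 mirror: tuple | None = None, nroots: int = 6):
        self.system = system
        self.label = label
        self.ncore = frozen_core
        self.mirror = mirror
        self.n_elec = system.n_electrons(label)
        self.h_ao = system.core_hamiltonian(label)
        self.e_nuc = system.nuclear_repulsion(label)
        self.rhf = rhf(self.h_ao, system.eri, system.S, self.n_elec,
                       e_nuc=self.e_nuc, X=system.orthogonalizer())
        self._valence = None
        self._ci = None
        self.nroots = nroots

    @property
    def core(self) -> np.ndarray:
        return self.rhf.mo_coeff[:, : self.ncore]

    def _valence_integrals(self):
        if self._valence is None:
            val = self.rhf.mo_coeff[:, self.ncore :]
            if self.ncore:
                h_eff_ao, e_core = ci.core_embedded_h(self.h_ao, self.system.eri,
                                                      self.core)
            else:
                h_eff_ao, e_core = self.h_ao, 0.0
            h_val = val.T @ h_eff_ao @ val
            eri_val = _mo_transform_eri(self.system.eri, val)
            self._valence = (val, h_val, eri_val, e_core)
        return self._valence

    def ci_roots(self):
        """Valence two-electron CI roots with mirror parities."""
        if self._ci is None:
            val, h_val, eri_val, _ = self._valence_integrals()
            states = ci.solve_two_electron_ci(h_val, eri_val, val,
                                              nroots=self.nroots)
            if self.mirror is not None:
                axis, origin, _p = self.mirror
                R_val = mirror_mo_matrix(self.system, val, axis, origin)
                parities = [ci.state_parity(s, R_val) for s in states]
            else:
                R_val, parities = None, [0.0] * len(states)
            self._ci = (states, parities, R_val)
        return self._ci

    def select_root(self, root: int, target_parity):
        states, parities, _ = self.ci_roots()
        order = [
            i for i, p in enumerate(parities)
            if target_parity is None or p * target_parity > 0.5
        ]
        if root >= len(order):
            raise ValueError(
                f"requested root {root} not found "
                f"({len(order)} roots match the symmetry filter)"
            )
        return order[root]


def solve_monomer(system: DimerSystem, label: str, spec: MethodSpec,
                  workspace: MonomerWorkspace | None = None) -> MonomerState:
    """Converge the requested monomer state and return its geminal structure."""
    ws = workspace or MonomerWorkspace(system, label, spec.frozen_core,
                                       spec.mirror, spec.nroots)
    res = ws.rhf

    if spec.kind == "HF":
        occ = res.occ_coeff
        if spec.fc_restrict:
            if spec.frozen_core >= res.n_occ:
                raise ValueError("cannot freeze every occupied orbital")
            occ = occ[:, spec.frozen_core :]
        gs = GeminalState.from_rhf(occ, label)
        return MonomerState(label, spec, gs, res.energy, res.energy)

    if ws.n_elec - 2 * ws.ncore != 2:
        raise ValueError(
            f"correlated monomer solver needs two valence electrons "
            f"(N={ws.n_elec}, frozen core {ws.ncore})"
        )
    val, h_val, eri_val, e_core = ws._valence_integrals()
    target_parity = spec.mirror[2] if spec.mirror is not None else None
    states, parities, R_val = ws.ci_roots()
    idx = ws.select_root(spec.root, target_parity)
    fci_state = states[idx]
    core = None if (spec.fc_restrict or not ws.ncore) else ws.core

    if spec.kind == "FCI":
        coefs, orbs = fci_state.natural_geminal()
        gs = GeminalState.from_natural_geminal(
            coefs, orbs, core_coeff=core, threshold=spec.occ_threshold, label=label,
        )
        energy = fci_state.energy + e_core + ws.e_nuc
        return MonomerState(label, spec, gs, energy, res.energy, idx,
                            parities[idx] if R_val is not None else None,
                            info={"n_support": gs.m})

    # CAS(2,n) / GVB: optimize the active span inside a leading-NO window
    n_act = spec.n_active
    w, Vnat = np.linalg.eigh(fci_state.C)
    order = np.argsort(-np.abs(w))
    nwin = min(max(spec.opt_window, n_act), val.shape[1])
    W = Vnat[:, order[:nwin]]                    # window in valence-MO coords
    h_win = W.T @ h_val @ W
    eri_win = _mo_transform_eri(eri_val, W)
    U0 = np.zeros((nwin, n_act))
    U0[:n_act, :n_act] = np.eye(n_act)
    R_win = W.T @ R_val @ W if R_val is not None else None

    def root_select(roots, U):
        if R_win is None:
            return spec.root
        R_act = U.T @ R_win @ U
        pars = [float(np.sum((R_act @ C @ R_act.T) * C)) for _, C in roots]
        ok = [i for i, p in enumerate(pars) if p * target_parity > 0.5]
        if spec.root < len(ok):
            return ok[spec.root]
        # distorted trial spans can blur the symmetry labels; follow the
        # most target-like root so the optimizer can recover
        return int(np.argmax([p * target_parity for p in pars]))

    opt = ci.optimize_subspace_ci(
        h_win, eri_win, U0,
        root_select=root_select if (R_win is not None or spec.root) else None,
    )
    C_win = opt.U @ opt.C_act @ opt.U.T
    C_valfull = W @ C_win @ W.T
    cas_state = ci.TwoElectronState(opt.energy, C_valfull / np.linalg.norm(C_valfull),
                                    val)
    coefs, orbs = cas_state.natural_geminal(threshold=1e-12)
    gs = GeminalState.from_natural_geminal(coefs, orbs, core_coeff=core, label=label)
    parity = ci.state_parity(cas_state, R_val) if R_val is not None else None
    energy = opt.energy + e_core + ws.e_nuc
    return MonomerState(label, spec, gs, energy, res.energy, spec.root, parity,
                        info={"n_support": gs.m, "grad_norm": opt.gradient_norm,
                              "n_iter": opt.n_iter})
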