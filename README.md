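# saptdx

First-order symmetry-adapted perturbation theory (SAPT) with **single and
double exchange** — the S² and S⁴ levels of the overlap expansion — computed
from monomer reduced density matrices, for Hartree–Fock, full-CI
(two-valence-electron) and strongly orthogonal geminal (APSG/GVB-PP,
including mapped CAS(2,n)) monomer wave functions.

## The problem

The short-range repulsion between closed-shell molecules is an exchange
effect: antisymmetrizing the product wave function Ψ_A Ψ_B lets the monomers
swap electrons.  In symmetrized Rayleigh–Schrödinger theory the first-order
interaction energy is

    E_int^(1) = (⟨V⟩ + ⟨V P̂⟩) / (1 + ⟨P̂⟩),      P̂ = Σ_k P̂_2k,

where P̂_2k exchanges k electron pairs and contributes at order S^{2k} in the
intermolecular orbital overlaps.  Truncating at one pair gives the classic
single-exchange (S²) approximation,

    E_exch^(1)(∝S²) = ⟨V̂P̂₂⟩ − ⟨V̂⟩⟨P̂₂⟩,

which fails for diffuse densities, anions, excited states and metal atoms.
This package evaluates the next order — **double exchange**,

    E_exch^(1)(∝S⁴) = ⟨V̂P̂₄⟩ − ⟨V̂P̂₂⟩⟨P̂₂⟩ − ⟨V̂⟩⟨P̂₄⟩ + ⟨V̂⟩⟨P̂₂⟩²,

from monomer 1-, 2- and 3-body density matrices contracted with the overlap
matrix S and the modified interaction potential ṽ, in the dimer-centered
basis.  For geminal-product wave functions the 3-RDM factorizes into
geminal-local pieces, and a dedicated fast path evaluates all S⁴ terms
without ever building a 3-RDM, at cost bounded by the sixth power of the
number of active geminal orbitals.  An exact determinant-space oracle (and a
first-quantized transposition-sum reference) back every contraction at
machine precision on small systems.  A general-order assembler produces the
composition of any E_exch^(1)(∝S^{2n}) from supplied expectation values.

Who this is for: developers and users of multireference SAPT methods who
need exchange energies beyond the S² approximation, and anyone needing an
independently verifiable reference implementation of the first-order
overlap expansion.

## Worked example

```python
import numpy as np
from saptdx import build_dimer_system, make_dimer, solve_monomer
from saptdx.states import MethodSpec
from saptdx.workbench import first_order_decomposition

basis = {"H": [(0, np.array([1.2, 0.3]), np.array([0.6, 0.5])),
               (0, np.array([0.12]), np.array([1.0]))]}
geometry = make_dimer(["H", "H", "H", "H"],
                      [[-0.7, 0, 0], [0.7, 0, 0], [0, 0, 5.3], [0, 0, 6.7]],
                      "AABB")                       # coordinates in bohr
system = build_dimer_system(geometry, basis)
msA = solve_monomer(system, "A", MethodSpec(kind="FCI"))
msB = solve_monomer(system, "B", MethodSpec(kind="FCI"))
dec = first_order_decomposition(system, msA, msB)
for key, value in dec.as_dict().items():
    print(f"{key:<14s} {value * 1e6:12.4f} microhartree")
```

prints (`python examples/01_first_order_decomposition.py`):

```
E_elst            -167.2521 microhartree
P2               -2330.0343 microhartree
VP2                544.4801 microhartree
P4                   0.1927 microhartree
VP4                 -0.1838 microhartree
E_exch_S2          544.0904 microhartree
E_exch_propS4        1.0840 microhartree
E_exch_S4          545.1743 microhartree
```

`E_elst` is the (penetration-corrected) electrostatic energy, `E_exch_S2`
the single-exchange repulsion, and `E_exch_propS4` the double-exchange
increment — quartic in the intermolecular overlap, hence three orders of
magnitude smaller at this separation.  `P2`, `VP2`, `P4`, `VP4` are the raw
operator expectation values the energies are assembled from.

More narrative examples live in `examples/`: method comparison (how much of
the S⁴ term HF / GVB-PP / CAS(2,4) recover), oracle verification, and the
geminal fast path with the CAS→GVB mapping.  A thin CLI exposes the same
functionality: `saptdx run`, `saptdx scan`, `saptdx verify`, `saptdx map-gvb`.

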