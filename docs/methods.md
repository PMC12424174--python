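# Methods

## The model

`saptdx` computes the first-order interaction energy of a weakly bound dimer
A···B in symmetrized Rayleigh–Schrödinger (SRS) perturbation theory,

    E_int^(1) = (<V> + <V P>) / (1 + <P>),

where every expectation value is taken over the product Ψ_A Ψ_B of isolated
monomer wave functions, V is the intermolecular interaction operator and P
collects all exchanges of electrons between the monomers, P = Σ_k P_2k, with
P_2k swapping k electron pairs.  Because ⟨...P_2k...⟩ is of order S^{2k} in
the intermolecular orbital overlaps S, expanding the ratio in powers of S
gives the electrostatic energy E_elst = ⟨V⟩ at order S^0 and exchange
corrections at even orders:

    E_exch^(1)(∝S^2) = ⟨V P_2⟩ − ⟨V⟩⟨P_2⟩                      (single exchange)
    E_exch^(1)(∝S^4) = ⟨V P_4⟩ − ⟨V P_2⟩⟨P_2⟩ − ⟨V⟩⟨P_4⟩ + ⟨V⟩⟨P_2⟩²
                                                              (double exchange)

and, at general order 2n, signed products generated programmatically
(`generate_compositions`), including the ⟨V P_0⟩ → ⟨V⟩ replacement.  The
composition generator is pinned against a symbolic series expansion of the
SRS ratio in the test suite, which settles the multiplicity convention
(ordered index tuples) at every order.

All expectation values are evaluated from monomer k-body reduced density
matrices (k ≤ n+1; k ≤ 3 for double exchange) contracted with the
intermolecular overlap matrix and the *modified potential*
ṽ, the two-electron interaction dressed with nuclear attraction and
nuclear-repulsion terms divided by electron counts, so that the whole
interaction operator takes a single two-index-pair second-quantized form.
The four Moszynski-type intermediates (G_k, F_k, D_k, C_k) appear where the
normal-ordered product V·P_2k contracts one or both of the potential's
"created" indices onto the partner monomer; those contractions require
generalized ṽ blocks whose created index ranges over the *partner* monomer's
orbitals.  In the dimer-centered basis each monomer's MO set spans the full
AO space, so these mixed blocks are exact objects (mixed-index two-electron
integrals), not approximations — this is why the dimer-centered basis is the
only supported mode.

Sign convention: the (−1)^k prefactors of the exchange operators live in the
expectation-value routines; intermediates are sign-free.

## Monomer states

Every monomer description used here is closed-shell and reduces to "core
orbitals plus singlet geminals":

- **HF**: each doubly occupied orbital is a one-orbital geminal (c = 1).
- **FCI** (two valence electrons): the CI matrix C_pq of a two-electron
  singlet is symmetric; its eigendecomposition C = Σ_i c_i |φ_i φ̄_i⟩ is a
  single antisymmetrized-product-of-strongly-orthogonal-geminals (APSG)
  geminal with natural orbitals φ_i.  This identity is exact, so "FCI
  monomers" and "geminal monomers" share one production code path.
- **GVB-PP / CAS(2,n)**: the variationally optimal n-orbital active space
  for a selected root of the two-electron valence CI.  The orbital span is
  optimized with analytic Hellmann–Feynman gradients
  (dE/dK = 4 V^T (HC) U Ĉ for the external-rotation generator K),
  conjugate-gradient iterations plus a re-centered L-BFGS polish, inside a
  window of leading FCI natural orbitals (default 32).  The window residual
  is far below every tolerance of interest: enlarging it to the full space
  changes the Be and H2 exchange terms by < 1e-9 Eh in our checks.
- **Frozen core**: for Be the 1s orbital is kept at its RHF form; the
  valence CI uses the core-embedded one-electron Hamiltonian.  Two
  evaluation modes exist: the core can be part of the RDM support (a
  one-orbital geminal), or dropped from all contraction index ranges
  entirely — the index-range-restriction style "fc" evaluation used for
  frozen-core exchange energies.  The hybrid correction
  E[X] ≈ E[X,fc] + (E[HF] − E[HF,fc]) is available for any term.

Excited states: the ¹Σu⁺ H2 root is selected by the expectation value of the
fixture's exact reflection (x → −x through the bond midpoint), built as an
AO permutation-with-parity operator, never by bare energy ordering.  The
CAS/GVB optimizer is state-specific; during line searches the parity filter
falls back to the most-ungerade root so that distorted trial spans cannot
abort the optimization.

## Contraction engines

Two independent engines evaluate the same five expectation values:

1. **Dense spinorbital path** (`saptdx.exchange`): literal einsum
   realizations of the k-RDM contractions with dense spinorbital tensors and
   explicit G/F/D/C intermediates.  Exact for any state, memory-bound to
   small or truncated supports (it materializes rank-(k+1) RDMs).
2. **Factorized geminal fast path** (`saptdx.geminal`): uses the exact
   factorization of APSG reduced density matrices into geminal-local pieces
   — diagonal occupation factors D_K and rank-one pair amplitudes g_K ⊗ g_K
   (g_{iα,jβ} = δ_ij c_i) —

       Γ¹ = Σ_K D_K
       Γ² = Σ_K g_K⊗g_K + Σ_{K<L} D_K ∧ D_L
       Γ³ = Σ_{K≠L} (g_K⊗g_K) ∧ D_L + Σ_{K<L<M} D_K ∧ D_L ∧ D_M

   with the prefactor-free Grassmann product ∧.  Substituting these into the
   contraction topologies and expanding the wedge slot assignments turns
   every double-exchange term into a modest sum of low-order contractions of
   S, ṽ and coefficient vectors; **no 3-RDM is ever materialized**, and the
   cost is bounded by the sixth power of the geminal-orbital count
   (`cost_model` reports the estimate).  Spin is handled exactly by
   factorization: each term is evaluated once over spatial tensors and once
   over the congruent 2-dimensional spin network (identity deltas from S, ṽ
   and D; antisymmetric ε tensors from g), and the results are multiplied.
   This is automated, exact spin integration of the spinorbital equations
   rather than a transcription of closed-shell working formulas.

Equality of the two engines on Hartree–Fock, FCI-natural-geminal, GVB-PP and
multi-geminal fixtures (including nonzero 3-RDM cases) is asserted to
1e-9 Eh or better in the acceptance suite; in practice agreement is at
machine precision.

## The truth standard

`saptdx.oracle` applies the second-quantized exchange operators literally:
dressed creators ã_s† = Σ_p S_ps a_p† and b̃_q† = Σ_r S_rq b_r† composed
with annihilators, determinant by determinant, on the product CI expansion
(commuting monomer Fock spaces; all intermolecular non-orthogonality enters
through the overlap factors).  It is capped at 20 spinorbitals.  A second,
fully independent reference evaluates the same quantities first-quantized:
explicit electron-label transpositions (P_2 = −Σ T_ij, P_4 = T13T24 +
T14T23 for 2+2 electrons) between product wave functions over nonorthogonal
orbitals.  Both references and both production engines agree to ~1e-12 Eh on
the test fixtures, which validates the operator transcription, the ṽ
dressing, the mixed-block construction and the sign bookkeeping end to end.

## Numerical choices

- **Natural-geminal truncation**: FCI monomer geminals are truncated at
  |c_i| ≥ 1e-5 (occupation 1e-10) and renormalized.  A convergence study on
  the He···H2 excited scan shows S² stable to < 2e-9 Eh and the ∝S⁴
  increment to < 2e-10 Eh against a 3e-6 cutoff; the cutoff exists purely to
  bound the size of the mixed ṽ blocks.
- Orbital spaces are canonically orthogonalized with an AO-overlap
  eigenvalue threshold of 1e-8; the smallest eigenvalue and any pruning are
  logged (aug-cc-pVTZ dimer bases here bottom out near 3e-5, so nothing is
  pruned).
- Degenerate/edge inputs: Γ^k ≡ 0 for k > N is enforced structurally (the
  piece lists are empty), ⟨P_2k⟩ returns 0 beyond min(N_A, N_B), and the
  mapping onto GVB-PP pairs fails loudly (listing the best candidates) when
  no pairing reproduces the 2-RDM within threshold (default 1e-2 per
  element).
- Two-electron integrals are computed by a McMurchie–Davidson engine (numba)
  with Cauchy–Schwarz screening at 1e-13 and 8-fold permutational symmetry;
  spherical AOs are self-normalized against the computed overlap, so basis
  normalization conventions cannot leak in.  Bundled basis tables
  (aug-cc-pVTZ H/He, aug-cc-pVDZ H/He/Be, cc-pVDZ) carry the standard
  published values; RHF/FCI anchors against well-known literature energies
  (H atom, He, Be, H2) are part of the test suite.
- Expectation values are plain double-precision einsum contractions; the
  S⁴ assembly involves cancellation of terms ~1e3 times larger than the
  result, which costs ~3 digits — far from the ~1e-12 Eh noise floor
  observed in the cross-validations.

## Study conditions and scope of the fixtures

The bundled fixtures reproduce the model dimers this method family is
benchmarked on: T-shaped H2···H2 (centers 6.21 a0 apart, spectator bond
1.44 a0, probe bond 1.37–7.2 a0, stretched monomer perpendicular to the
intermolecular axis), T-shaped He···H2 (bond 1.44 a0 in the ground state,
2.44 a0 for the ¹Σu⁺ excited state; He on the perpendicular bisector), and
collinear Be···Be at 4.6 a0.  The perpendicular orientation of the
stretched H2 is the only one compatible with the ~100–600 μEh S² exchange
scale of this system; the alternative (stem-stretched) geometry produces
exchange energies two orders of magnitude larger.

What these fixtures do *not* probe: monomers with more than two valence
electrons per correlated fragment (the CI layer is specifically a
two-valence-electron solver; many-electron monomers enter only at the HF or
mapped-geminal level), basis sets beyond spd, open-shell monomers, and any
second-order SAPT quantity.  Passing tests therefore demonstrate the
correctness of the first-order S²/S⁴ machinery and its geminal
factorization, not the accuracy of geminal approximations for large
molecules.

## Known limitations and observed deviations

- The general-order path accepts externally supplied RDMs for k > 3 but the
  internal builders stop at rank 3 (double exchange), matching the scope of
  the S⁴ model.
- CASSCF core orbitals are frozen at their RHF shape (no core relaxation);
  for Be this changes recovery fractions by well under the printed
  precision.
- The double-exchange term is far more sensitive to intramonomer dynamic
  correlation than the single-exchange term.  Across every system studied
  here, a GVB-PP description recovers 40–50% of the FCI ∝S⁴ value while its
  S² error stays at a few percent, and CAS(2,4) recovers ~85–92%; users
  comparing against other implementations should compare the raw ⟨P₄⟩ /
  ⟨V̂P̂₄⟩ expectation values (exposed in the decomposition) before comparing
  assembled increments, which are heavily cancellation-dominated.  For
  He···H2(¹Σu⁺) the converged FCI ∝S⁴ term changes sign near 6.3 a0, so
  relative deviations quoted over a radial scan blow up where the reference
  passes through zero.  These behaviors are threshold-converged and
  cross-validated against the determinant oracle and the first-quantized
  transposition sum.
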