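# Methods

This note documents the model implemented by `gvpt2`, the derivation
behind its closed-form expressions, the numerical choices, and what the
built-in synthetic systems do and do not probe. Everything quantitative
stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from elsewhere.

## 1. Vibrational model

### Coordinates and the harmonic problem

The curvilinear frame is built on primitive internal coordinates
(PICs): all bonds, valence angles and dihedrals implied by the
molecular topology (bond detection: interatomic distance below
1.3 × the sum of covalent radii; configurable). The set is generally
redundant; redundancy is resolved *after* the harmonic step by
discarding null-space vectors of the Wilson **G** = **B M**⁻¹**B**ᵀ
matrix (eigenvalues below 1e-8 of the largest).

The GF problem is solved in symmetrized form: diagonalize **G**, form
**X** = **U**ₖ√λₖ on the non-null subspace, diagonalize **X**ᵀ**F X**,
and back-transform. The normal-mode matrix is normalized as
**L**ᵀ**G**⁻¹**L** = **1**, which makes the metric in the mass-weighted
normal-coordinate basis the identity at equilibrium and diag(ω) after
the ω-scaling to dimensionless coordinates — a property the tests check
to 1e-6 cm⁻¹. Any mathematically equivalent symmetrization would give
the same observables, which are eigenvalue-determined. Mode phases are
fixed (largest-magnitude component positive) so cubic-constant signs
are reproducible; every transition energy is invariant under input mode
sign flips (tested).

Angles at ≥ 175° are replaced by two orthogonal linear-bend
coordinates, measured against in-plane axes chosen deterministically at
the reference geometry (the Cartesian axis least parallel to the a–c
direction, orthogonalized) and frozen into the coordinate definition so
displaced geometries are measured against the same axes. Dihedral
values live in (−π, π] and displaced-geometry values are unwrapped
continuously relative to the reference — finite differences across the
branch cut would otherwise be corrupted. Dihedrals through near-linear
centres are dropped (undefined).

**B** rows are closed-form analytic gradients (bond, Wilson angle,
Blondel–Karplus-style dihedral, linear bends). **B**′ is obtained by
propagating those closed forms through forward-mode dual numbers: this
is analytic differentiation (machine precision, no step-size error),
and the result is explicitly symmetrized in its two Cartesian indices
(the raw asymmetry is at rounding level). Externally generated **B**
and **B**′ tensors can be exchanged through a plain-text archive
(hex-exact round trip); they serve reference-point quantities, while
the displaced-geometry machinery evaluates **B**(x) itself.

### Hamiltonian expansion

In dimensionless normal coordinates q with conjugate momenta p (all
quantities in cm⁻¹):

    H0 = 1/2 Σ ω_i (p_i² + q_i²)
    H1 = 1/6 Σ f_ijk q_i q_j q_k   + 1/2 Σ g1[i,j,k] p_i q_k p_j
    H2 = 1/24 Σ f_ijkl q_i q_j q_k q_l + 1/4 Σ g2[i,j,k,l] p_i q_k q_l p_j
         + Σ_α B_α π_α²   (Cartesian frame only)

with π_α = Σ_ij ζ^α_ij √(ω_j/ω_i) q_i p_j. The p·q·p operator ordering
is the Hermitian symmetrization appropriate for a coordinate-dependent
metric; after summation with the (i,j)-symmetric coefficients it equals
the symmetrized (p p q + q p p)/2 form, but same-mode orderings matter —
the sum-over-states oracle demonstrates that a naive q·p·p ordering
changes transition energies (tested). The purely quantum
"extra-potential" term of the curvilinear kinetic operator is well
approximated by its equilibrium value and therefore shifts all levels
uniformly; it is omitted, as is the zero-point energy — the package
reports transition energies only.

### Second-order energies: channel decomposition

Rayleigh–Schrödinger second order gives
ε⁽²⁾ = ⟨H₂⟩ + Σ |⟨S|H₁|R⟩|²/(E_R − E_S). Collecting the sum by
intermediate-state *channels* (which modes gain/lose quanta) shows that
every squared matrix element carries one of two effective cubic
combinations,

    rho[i,j,k]   = f_ijk − g1[i,j,k] + g1[i,k,j] + g1[j,k,i]
    sigma[i,j,k] = f_ijk − g1[i,j,k] − g1[i,k,j] − g1[j,k,i]

(ρ symmetric in its first two slots, σ fully symmetric; the sign
pattern traces to q² and p² having opposite-sign two-quantum matrix
elements but equal-sign diagonals). A channel that raises modes a, b
and lowers mode c carries ρ[a,b,c]²/(ω_a + ω_b − ω_c); an all-raising
channel carries σ[a,b,c]²/(ω_a + ω_b + ω_c). The one-quantum channels
ω_k are the slot pattern ρ[a,k,a] (formally ω_a + ω_k − ω_a), which is
why two tensors suffice. The ⟨H₂⟩ diagonal contributes
η[i,j,k,l] = f_ijkl + g2[i,j,k,l] + g2[k,l,i,j]. With zero metric
derivatives ρ = σ = f₃ and η = f₄, and the expressions reduce exactly
to the textbook Cartesian ones (tested against an independent
transcription of those combined rational forms, and the Coriolis term
Σ_α B_α ζ²(ω_i/ω_j + ω_j/ω_i) follows from ⟨π_α²⟩).

The complete χ matrix, as implemented (each line one channel class; the
ε⁽²⁾ is exactly bilinear in (v+½), with no linear terms — verified):

    χ_kk ⊃ η_kkkk/16
    χ_ab ⊃ −(2−δ_ab) ρ[a,k,a] ρ[b,k,b] / (8 ω_k)      (a,b) ≠ (k,k)
    χ_kk ⊃ −3 ρ[k,k,k]²/(32 ω_k) − σ[k,k,k]²/(96 ω_k)
    χ_ii ⊃ −σ[i,i,k]²/(32(2ω_i+ω_k)) + ρ[i,i,k]²/(32(2ω_i−ω_k))   (i≠k)
    χ_ik ⊃ −σ[i,i,k]²/(8(2ω_i+ω_k))  − ρ[i,i,k]²/(8(2ω_i−ω_k))
    χ_ij ⊃ η_iijj/4                                     (i<j)
    χ_ab ⊃ −σ[i,j,k]²/(8(ω_i+ω_j+ω_k))    all pairs (a,b) in {i,j,k}
    χ_pq ⊃ +ρ[p,q,r]²/(8 D),  χ_pr, χ_qr ⊃ −ρ[p,q,r]²/(8 D),
            D = ω_p + ω_q − ω_r, for each slotting (p,q,r) of a
            distinct triple {i,j,k}

The derivation was validated two independent ways: (i) the channel sums
reproduce the separately hand-transcribed combined rational Cartesian
formulas when the metric derivatives vanish, and (ii) every transition
energy matches a brute-force sum-over-states PT2 oracle (explicit
harmonic-oscillator operator algebra, matrix-free tensor application)
to ~1e-12 cm⁻¹ on random 2–4-mode systems in all operator sectors
(potential-only, kinetic-only, mixed, with and without Coriolis).

The potential/kinetic/cross component split uses the bilinearity of the
channel amplitudes in (V, T): χ^pot comes from the combined-form
transcription, χ^kin from the channel engine with kinetic-only
amplitudes, χ^× from the 2·V·T bilinear products; their sum equals the
recast χ to 1e-8 cm⁻¹ (an acceptance identity, not an assumption).

### Resonances

Denominators 2ω_i − ω_k and ω_i + ω_j − ω_k can approach zero. The
two-step Martin test flags candidates: step 1, detuning ≤ 200 cm⁻¹;
step 2, strength K = ρ_iik⁴/(256Δ³) ≥ 1 cm⁻¹ (type I) or
ρ_ijk⁴/(64Δ³) ≥ 1 cm⁻¹ (type II). K is exactly W⁴/Δ³ for the
interaction elements below, i.e. the energy a 2×2 variational treatment
would recover at leading order. The type-II strength uses ρ_ijk, the
same tensor that builds the interaction element. In the Cartesian frame
ρ = f₃. Exact degeneracies (Δ = 0) are auto-accepted, with the
formally removed contribution recorded as zero.

DVPT2 removes the flagged channels' pole terms from χ and registers
them per resonance; adding the registry back restores plain VPT2 to
1e-10 cm⁻¹ (tested). Denominators below 1e-6 cm⁻¹ that no accepted
resonance covers raise an error instead of silently producing huge χ
entries — the classic failure mode of unattended VPT2.

GVPT2 collects the states reachable from the requested transitions
through accepted resonances (transitive closure; no speculative polyad
growth beyond that) and diagonalizes, per polyad, the matrix with
deperturbed energies on the diagonal and

    ⟨v+2_i |H̃| v+1_k⟩ = ρ_iik √((v_i+1)(v_i+2)(v_k+1)) / (4√2)
    ⟨v+1_i+1_j |H̃| v+1_k⟩ = ρ_ijk √((v_i+1)(v_j+1)(v_k+1)) / (2√2)

off the diagonal. These are the full first-order contact-transformed
elements of the expanded Hamiltonian: the potential, kinetic and cross
contributions combine exactly into the ρ expressions, so no separate
auxiliary term survives at this order. Eigenvalues are assigned to
basis states by the largest squared eigenvector component; ties within
1e-6 break to the lower basis-state index and are flagged. Polyad
traces are conserved (tested); trace conservation plus assignment makes
the GVPT2 column well defined even for chained resonances.

Degenerate harmonic pairs of symmetric/spherical/linear tops appear as
Δ ≈ 0 near-resonances and are caught by step 1, but no
symmetry-adapted (a posteriori) transformation is applied — results for
non-Abelian tops are approximate in this release. 1-1 and 2-2
(Darling–Dennison) resonances are not treated.

## 2. Force-field and metric assembly

2M+1 engine jobs (reference plus ± displacement per mode, default
δQ = 0.02 amu^1/2 bohr for all coordinate kinds) supply analytic
Cartesian Hessians. Curvilinear displacements are applied in internal
coordinates (s → s + δQ·L column) and back-transformed iteratively
(Δx = M⁻¹BᵀG⁺Δs with step-halving damping) to a projected residual
below 1e-10 bohr; for redundant sets only the component of Δs in the
range of G is realizable, and convergence is judged on that projection.

Hessians transform to internal coordinates as
F = (B⁺)ᵀ P (H_x − g_s·B′) P B⁺ with P = B⁺B and g_s = (B⁺)ᵀ P g_x;
the projector removes both translations and rotations (at displaced,
non-stationary geometries the gradient term makes F and H_x genuinely
different quadratic forms — the implementation is checked by the exact
round-trip identity BᵀFB + g_s·B′ = P H_x P rather than by comparing
frequencies, which agree only at stationary points). A condition-number
bound (1e10) on B guards against degenerate coordinate sets.

Finite-difference formulas (all O(δQ²), verified by step-halving):

    f_ijk  = [H_jk(+δ_i) − H_jk(−δ_i)] / 2δ     (averaged over the three
                                                 slot choices, then fully
                                                 symmetrized)
    f_iijj = [H_ii(+δ_j) + H_ii(−δ_j) − 2H_ii(0)] / δ²   (i=j gives f_iiii;
                                                 the two estimates of f_iijj
                                                 are averaged)
    f_ijkk = [H_ij(+δ_k) + H_ij(−δ_k) − 2H_ij(0)] / δ²

Quartic constants with four distinct indices are not obtainable from
single-mode Hessian displacements and are not needed at second order;
they are excluded by design. The assembled constants are invariant
under permutations of the job ordering and, after phase fixing, across
reruns (tested); surface archives (JSON, hex-exact floats, versioned,
settings-hashed) replay with zero engine calls, detect corrupted
entries per label, and refuse future versions.

The metric in the normal-mode basis is g_Q = (LᵀG(x)⁺L)⁻¹ (identity at
equilibrium). Its first derivatives are analytic — chain rule through
the analytic G′ = B′M⁻¹Bᵀ + BM⁻¹B′ᵀ tensor, with the constant-rank
pseudo-inverse derivative so redundant sets are handled exactly — and
the second derivatives are finite differences of the analytic first
derivatives over the same ±δQ displacements. Wavenumber scaling:
ĝ_ij = √(ω_iω_j) g_Q,ij, ĝ1 multiplied by 1/√ω_k per derivative index.
Analytic g1 agrees with finite differences of the metric to 1e-6 cm⁻¹
(tested); in the Cartesian frame all metric derivatives vanish
identically.

Coriolis data (Cartesian frame): ζ^α_ij = Σ_atoms (l_i × l_j)_α from
mass-weighted modes rotated into the principal-axis frame; rotational
constants B_α = 1/(2I_α) (atomic units → cm⁻¹). CODATA-2018 conversion
constants are centralized in one module so tolerances are meaningful.

## 3. Dual-level schemes

Add: ν = ω^H + (ν^L − ω^L) per matched mode. Sub: the χ engine,
Martin test and polyad step re-run with ω^H in the harmonic term and in
*every* denominator (and in the Coriolis ω-ratios), keeping the
low-level f and g tensors. Re-evaluating the resonance test at the
high level is deliberate: substitution can move a pair into or out of
resonance, and only the denominators actually used should decide.
Modes are matched across levels by maximum-overlap assignment
(Hungarian algorithm on |overlap|), overridable by an explicit
permutation; frequency-order matching is not used because it breaks on
near-degenerate reorderings. Both schemes coincide exactly when
ω^H = ω^L (tested).

## 4. Synthetic systems: what they emulate, what they do not

All reference problems are generated in code; none requires an
electronic-structure package.

* **CO-like Morse** (D = 0.41 E_h, a = 1.20 bohr⁻¹, r_e = 2.13 bohr;
  ω_e ≈ 2133 cm⁻¹, ω_ex_e ≈ 12.6 cm⁻¹): realistic first-row-diatomic
  anharmonicity; VPT2 is exact for Morse, so this isolates
  finite-difference and transformation errors. Measured: 0 error with
  analytic derivatives, ~6e-3 cm⁻¹ through the full δQ = 0.02 pipeline.
* **Water-like triatomic**: experimental-geometry bent frame, internal
  quartic PES with stretch force constants 0.50 E_h/bohr² (~8
  mdyn/Å), bend 0.16 E_h/rad², Morse-type stretch cubics (−1.7
  E_h/bohr³ consistent with a ~1.2 bohr⁻¹ Morse range), mild
  stretch–bend coupling. Deliberately semi-rigid and resonance-free so
  that frame equivalence is a clean test: curvilinear and Cartesian
  GVPT2 fundamentals agree to ~9e-3 cm⁻¹.
* **Fermi pair** (ω = 1000/1990, f₁₁₂ = 30 cm⁻¹): weak-coupling
  resonant regime, Martin K ≈ 3.2; GVPT2 tracks full variational
  energies to ~0.015 cm⁻¹, degrading smoothly as the coupling grows
  (logged by a trend test, not asserted quantitatively).
* **Random toy Hamiltonians** (2–4 modes, ω ∈ [900, 3500] cm⁻¹ with
  all resonance detunings ≥ 150 cm⁻¹, couplings ~6 cm⁻¹ r.m.s.):
  identity and oracle checks across operator sectors.

What passing these tests does *not* show: behaviour on real electronic
structure data (numerical noise in Hessians, non-stationary reference
geometries), symmetry-degenerate modes of non-Abelian tops, strong
resonance networks, or large-amplitude motions beyond the
reduced-coupling trends probed here. The model potentials have exact
derivatives and exact symmetry; real engines do not.

* **Sum-over-states oracle**: harmonic-oscillator product basis,
  default 20 quanta/mode for ≤2 modes and 12 for 3 modes; for a cubic
  H₁ the PT2 sum is exact once the basis contains all states within
  three quanta of the target, and basis-doubling changes the FVCI
  references by <1e-8 cm⁻¹ in the convergence-gated tests. The oracle
  declines near-degenerate denominators (<1e-3 cm⁻¹) rather than sum
  them.

## 5. Numerical choices and tie-breaks

| quantity | value | rationale |
|---|---|---|
| bond detection | 1.3 × covalent-radius sum | standard topology heuristic |
| linear-angle threshold | 175° | plain-angle B rows degrade near linearity |
| G null-space cut | 1e-8 × max eigenvalue | scale-free redundancy detection |
| zero-mode cut | 0.01 cm⁻¹ | below spectroscopic relevance |
| δQ | 0.02 amu^1/2 bohr | balances O(δ²) truncation vs round-off |
| back-transform residual | 1e-10 bohr (projected) | displaced internals exact to test tolerance |
| B condition bound | 1e10 | degenerate-set guard |
| denominator floor | 1e-6 cm⁻¹ | undeperturbed exact resonances must fail loudly |
| Martin thresholds | 200 / 1 cm⁻¹ | standard defaults, configurable |
| assignment tie-break | lower basis-state index, flagged | determinism |
| imaginary frequencies | error, not warning | anharmonic theory undefined off-minimum |

Problem sizes in `scripts/acceptance.py` (200 random systems of 2–4
modes; oracle bases of 9; FVCI basis 24 for 2 modes) keep the full
recomputation within seconds while leaving every check far from its
tolerance.

## 6. Known limitations

* Non-Abelian (symmetric/spherical/linear) tops are handled through the
  generic near-degeneracy path without symmetry-adapted post-
  transformations; their results should be treated as approximate.
* No Darling–Dennison (1-1/2-2) resonance treatment, no VPT4, no
  intensities, no rovibrational coupling constants beyond equilibrium
  rotational constants.
* The Sub scheme assumes the low-level normal modes remain a good basis
  at the high level; strongly rotated modes would require re-deriving
  the force field, not just substituting frequencies.
* Four-distinct-index quartic constants are absent by construction
  (harmless at second order, but the archives cannot feed a
  higher-order treatment).
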