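# gvpt2 — anharmonic vibrational energies in curvilinear and Cartesian coordinates

`gvpt2` computes anharmonic vibrational transition energies of
semi-rigid molecules by generalized second-order vibrational
perturbation theory (GVPT2), in either of two frames:

* **Cartesian normal coordinates** — the textbook route: a rectilinear
  quartic force field plus Coriolis couplings ζ<sup>α</sup><sub>ij</sub>;
* **curvilinear internal coordinates** — normal modes built from the
  primitive internals (bonds, valence angles, dihedrals) via the Wilson
  GF method. Here the kinetic-energy operator is no longer diagonal: the
  metric **g**(q) = **L**ᵀ**G**⁻¹**L**-derived matrix is expanded to
  second order in the dimensionless normal coordinates, and its
  derivatives g<sub>ij,k</sub>, g<sub>ij,kl</sub> enter the perturbative
  sums alongside the cubic and quartic force constants.

The practical payoff of the curvilinear frame is that inter-mode
couplings — especially the three-mode constants, and everything
involving soft torsions — become far weaker, so low-order perturbation
theory and reduced-dimensionality truncations stay reliable where the
Cartesian description degrades.

## The model

With dimensionless normal coordinates *q* and conjugate momenta *p*
(everything in cm⁻¹), the vibrational Hamiltonian is expanded as
H₀ + H₁ + H₂ with

    H0 = 1/2 Σ ω_i (p_i² + q_i²)
    H1 = 1/6 Σ f_ijk q_i q_j q_k        + 1/2 Σ g_ij,k  p_i q_k p_j
    H2 = 1/24 Σ f_ijkl q_i q_j q_k q_l  + 1/4 Σ g_ij,kl p_i q_k q_l p_j
         (+ Σ_α B_α π_α²  in the Cartesian frame)

Second-order theory gives state energies as the bilinear form
ε(v) = Σ ω_i (v_i + ½) + Σ<sub>i≤j</sub> χ<sub>ij</sub> (v_i + ½)(v_j + ½).
All cubic-type contributions to **χ** enter through two effective
tensors,

    ρ_ijk = f_ijk − g_ij,k + g_ik,j + g_jk,i     (difference denominators ω_i + ω_j − ω_k)
    σ_ijk = f_ijk − g_ij,k − g_ik,j − g_jk,i     (sum denominators ω_i + ω_j + ω_k)

and the quartic/metric diagonal through
η<sub>ijkl</sub> = f<sub>ijkl</sub> + g<sub>ij,kl</sub> + g<sub>kl,ij</sub>,
so the curvilinear expressions are formally the Cartesian ones with
(f₃, f₄) → (ρ/σ, η). With all metric derivatives zero, ρ = σ = f₃ and
η = f₄ exactly. Fermi resonances (2ω_i ≈ ω_k and ω_i + ω_j ≈ ω_k) are
detected by the two-step Martin test on ρ (thresholds 200 and 1 cm⁻¹),
removed from the χ sums (DVPT2), and treated exactly in small variational
polyad matrices (GVPT2). Dual-level Add/Sub schemes graft high-level
harmonic frequencies onto a cheaper anharmonic force field.

Force fields are assembled from analytic Cartesian Hessians at 2M+1
displaced geometries (default step 0.02 amu<sup>1/2</sup> bohr):
Hessians are transformed to internal coordinates with the analytic
Wilson **B**/**B**′ tensors and the projector **P** = **B**⁺**B**, cubic
and semi-diagonal quartic constants follow from O(δQ²) finite
differences, and the g-matrix derivatives come from the analytic **G**′
tensor (first order) plus finite differences (second order). Any code
that returns energies/gradients/Hessians can drive the machinery through
a small adapter contract; analytic model potentials (Morse, polynomial
PES in internal coordinates) are built in, and completed surface
archives replay byte-identically.

## Worked example

Second-order perturbation theory is exact for a Morse oscillator — the
classic sanity check, run through the entire pipeline:

```bash
$ python examples/morse_exactness.py
Morse parameters: D = 0.41 Eh, a = 1.2 1/bohr, re = 2.13 bohr
w_e     =   2133.293 cm^-1
w_e x_e =     12.644 cm^-1
exact fundamental w_e - 2 w_e x_e =   2108.005 cm^-1
VPT2, analytic derivatives        =   2108.005 cm^-1 (error +0.00e+00)
VPT2, dQ = 0.02 finite differences =  2107.999 cm^-1 (error -5.95e-03)
```

The analytic-derivative route hits the exact fundamental to machine
precision; the finite-difference route is off only by the O(δQ²)
truncation. Resonance handling on a weak Fermi pair (2ω₁ ≈ ω₂,
detuning 10 cm⁻¹, coupling 30 cm⁻¹):

```bash
$ python examples/fermi_resonance.py
Martin test:
  type I  2w1 ~ w2           detuning    10.000 K      3.1641  accepted
state          VPT2      DVPT2      GVPT2       FVCI
(0, 1)      1985.59    1991.22    1987.42    1987.43
(2, 0)      2007.86    2002.23    2006.03    2006.01
```

Plain VPT2 misplaces both polyad members by several cm⁻¹; after
deperturbation and the 2×2 variational step, GVPT2 matches the full
variational reference to ~0.01 cm⁻¹. Other examples cover the
curvilinear/Cartesian frame comparison (`water_frames.py`), dual-level
composition (`dual_level.py`) and coupling statistics
(`coupling_analysis.py`). The same workflow is available as a CLI:

```bash
gvpt2 run --geometry water.xyz --frame curvilinear --engine engine.yaml \
    --delta-q 0.02 --scheme gvpt2 --archive run.json -o report.txt
```

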