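"""Second-order perturbation theory is exact for the Morse oscillator.

Builds a CO-like Morse diatomic (w_e ~ 2133 cm^-1, w_e x_e ~ 12.6 cm^-1),
runs the full curvilinear pipeline -- topology detection, Wilson GF,
displaced-geometry Hessians with the default 0.02 amu^1/2 bohr step,
finite-difference quartic force field, VPT2 -- and compares the
fundamental with the closed-form Morse result w_e - 2 w_e x_e.
"""

from gvpt2.models import co_like_morse
from gvpt2.pipeline import RunConfig, run_pipeline
from gvpt2.vpt2 import chi_from_tensors, derived_tensors, state_energy

m = co_like_morse()
print(f"Morse parameters: D = {m.D} Eh, a = {m.a} 1/bohr, re = {m.re} bohr")
print(f"w_e     = {m.omega_e_cm:10.3f} cm^-1")
print(f"w_e x_e = {m.omega_exe_cm:10.3f} cm^-1")
print(f"exact fundamental w_e - 2 w_e x_e = {m.exact_fundamental():10.3f} cm^-1")

# analytic route: exact dimensionless cubic/quartic constants
ff = m.exact_force_field()
chi = chi_from_tensors(derived_tensors(ff, None))
nu = state_energy(chi, ff.omega, (1,))
print(f"VPT2, analytic derivatives        = {nu:10.3f} cm^-1 "
      f"(error {nu - m.exact_fundamental():+.2e})")

# finite-difference route through the whole pipeline
cfg = RunConfig(geometry=m.geometry(), frame="curvilinear",
                engine={"model": "morse", "D": m.D, "a": m.a, "re": m.re,
                        "symbols": list(m.symbols)})
res = run_pipeline(cfg)
nu_fd = res.table[(1,)]["gvpt2"]
print(f"VPT2, dQ = 0.02 finite differences = {nu_fd:9.3f} cm^-1 "
      f"(error {nu_fd - m.exact_fundamental():+.2e})")
print("\nVPT2 reproduces the exact Morse anharmonicity; the only residual "
      "error is the O(dQ^2) finite-difference truncation.")
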