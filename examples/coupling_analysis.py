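"""Coupling statistics and reduced-dimensionality ladders.

Curvilinear coordinates concentrate the anharmonicity in few, mostly
diagonal constants, so truncating the force field at one- or two-mode
couplings degrades the result far less than in the Cartesian frame.
This script counts three-mode couplings above a threshold in both
frames of the water-like PES and walks the coupling-order ladder
(diagonal -> two-mode -> full).
"""

import numpy as np

from gvpt2.models import water_like_pes
from gvpt2.pipeline import RunConfig, run_pipeline
from gvpt2.vpt2 import (chi_from_tensors, count_couplings, derived_tensors,
                        restrict_coupling_order, single_mode_anharmonic,
                        state_energy)

geom, iset, pes = water_like_pes()
engine = {"model": "polynomial",
          "F": pes.F.tolist(), "C": pes.C.tolist(), "Q": pes.Q.tolist()}

runs = {f: run_pipeline(RunConfig(geometry=geom, frame=f, engine=engine))
        for f in ("curvilinear", "cartesian")}

print("three-mode constants with |value| > 1 cm^-1:")
for frame, res in runs.items():
    counts = count_couplings(res.ff, res.kin, threshold=1.0)
    print(f"  {frame:12s} {counts}")

print("\ncoupling-order ladder (GVPT2 fundamentals, cm^-1):")
eye = np.eye(3, dtype=int)
for frame, res in runs.items():
    full = None
    line = {}
    for order in (1, 2, 3):
        ff, kin = restrict_coupling_order(res.ff, res.kin, order)
        chi = chi_from_tensors(derived_tensors(ff, kin))
        nus = [state_energy(chi, ff.omega, tuple(eye[k])) for k in range(3)]
        line[order] = nus
        if order == 3:
            full = np.array(nus)
    for order in (1, 2):
        mae = np.abs(np.array(line[order]) - full).mean()
        print(f"  {frame:12s} order {order}: MAE vs full = {mae:7.3f}")

print("\nsingle-mode (fully decoupled) fundamentals, curvilinear:")
res = runs["curvilinear"]
for k in range(3):
    print(f"  nu{k + 1}: {single_mode_anharmonic(res.ff, res.kin, k):9.2f} "
          f"(full {res.table[tuple(eye[k])]['gvpt2']:9.2f})")
print("\nTruncation discards real inter-mode couplings, so the decoupled "
      "values shift -- but they stay physical. For soft torsions the same "
      "truncation in a Cartesian description can fail by thousands of "
      "wavenumbers, because rectilinear modes smear the torsional "
      "anharmonicity over many large off-diagonal constants.")
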