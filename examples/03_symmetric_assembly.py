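"""C2-symmetric rigid-body search against a simulated curve.

A dimer-of-dimers target is built at a known rotation phi = 40 deg and
axial separation t = 36 A; the search is then given the two dimeric blocks
in their reference pose plus the noisy curve, and asked to find the
arrangement. The printed table shows the ranked clash-free candidates.
"""

import numpy as np

import saxshybrid as sx

truth = sx.generate_structure(sx.ToyStructureSpec(phi_deg=40.0))
ds = sx.simulate_curve(truth, np.linspace(0.01, 0.30, 150),
                       sx.NoiseSpec(0.01, 0.001, seed=5))

ref = sx.generate_structure(sx.ToyStructureSpec(phi_deg=0.0))
res = sx.scenario_search(sx.ScenarioSpec(scenario=1, chi2_gate=2.0),
                         ref.select_chains("AB"), ref.select_chains("CD"),
                         ds.noisy)

print("rank  phi(deg)  t(A)    chi2   interface(A^2)")
for i, c in enumerate(res.survivors[:8], start=1):
    area = "" if c.interface_area is None else f"{c.interface_area:8.0f}"
    print(f"{i:>4}  {c.phi:8.1f}  {c.t_axial:5.1f}  {c.chi2:6.3f} {area}")
print()
print(f"truth was (phi, t) = (40, 36); note phi and 180-phi are congruent")
print(f"for these centrosymmetric blocks. Distinct phi minima reported: "
      f"{[round(c.phi, 1) for c in res.rotamer_pair]}")
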