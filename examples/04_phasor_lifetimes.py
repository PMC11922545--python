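"""NAD(P)H lifetime decomposition in phasor space.

Simulates a TCSPC acquisition (80 MHz, 256 x 0.0390625 ns bins) of a field
with three bound-fraction levels, then recovers the two species lifetimes
from the universal-circle intersections of the fitted phasor line and the
per-pixel bound fractions by chord projection.
"""

import numpy as np

import redoxmap as rm

alpha2 = np.zeros((48, 48))
alpha2[:16], alpha2[16:32], alpha2[32:] = 0.2, 0.5, 0.8
tau_pair = (0.4, 2.5)  # ns: free and protein-bound NAD(P)H

config = rm.GeneratorConfig(shape=(48, 48), photon_budget=1e4, seed=1)
cube = rm.generate_flim_cube(alpha2, tau_pair, config)
print(f"decay cube: {cube.counts.shape}, {cube.total_photons.sum():.2e} photons total")

field = rm.filter_phasor(rm.phasor_transform(cube))  # 3x3 median, >=15 photons
line = rm.fit_phasor_line(field)
print(f"phasor line: S = {line.slope:.4f} G + {line.intercept:.4f}  "
      f"(R^2 = {line.r_squared:.4f}, {line.n_points} px)")

report = rm.two_species_report(field, line)
print(f"two-species adequacy: {report['fraction_far_from_line'] * 100:.1f}% of "
      f"pixels farther than {report['max_distance']} from the line")

inter = rm.circle_intersections(line, field.omega)
print(f"universal-circle lifetimes: tau1 = {inter.tau1:.3f} ns (true {tau_pair[0]}), "
      f"tau2 = {inter.tau2:.3f} ns (true {tau_pair[1]})")

comp = rm.project_fractions(field, line, inter)
for level, rows in ((0.2, slice(1, 15)), (0.5, slice(17, 31)), (0.8, slice(33, 47))):
    got = np.nanmean(comp.alpha2[rows])
    taum = np.nanmean(comp.tau_m[rows])
    print(f"  band alpha2 = {level}: recovered {got:.3f}, mean lifetime {taum:.3f} ns")
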