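"""Duplex thermodynamics of the bit-0 information domain.

Computes nearest-neighbor ΔH/ΔS for the 15-bp info duplex under the
replication buffer (150 mM NaCl + 20 mM MgCl2, 400 nM total strands),
derives Tm and the two-state unbound fraction at the protocol
temperatures, and demonstrates the melting-curve fit on a synthetic
curve with sloped baselines and noise.
"""

import hairpinrep as hr
from hairpinrep import synth

lib = hr.load_packaged_library()
domain = lib.info_domains["0"]
d = hr.duplex_thermo(domain)

print(f"bit-0 info domain: 5'-{domain}-3'")
print(f"  dH = {d.dH:.1f} kcal/mol, dS = {d.dS:.1f} cal/(mol K) (salt-corrected)")
print(f"  dG(37 C) = {d.dG(37):.2f} kcal/mol")
print(f"  Tm = {hr.melting_temperature(d):.1f} C at 400 nM total strands")
for T in (45.0, 55.0, 67.0):
    print(f"  unbound fraction at {T:.0f} C: {hr.unbound_fraction(d, T):.3f}")

print(
    "\nAt the 45 C base hold the duplex is mostly bound (templating works);\n"
    "at the 67 C peak it is essentially molten (replicate separates)."
)

data = synth.gen_melting_curve(
    d.dH, d.dS,
    baselines=((0.1, 0.002), (0.9, -0.001)),
    noise=synth.NoiseSpec(sigma_rel=0.02, sigma_abs=0.0, seed=11),
)
curve, est = hr.fit_melting_curve(data.temperature_C, data.signal)
print(
    f"\nMelting-curve fit on noisy synthetic data with sloped baselines:\n"
    f"  recovered Tm = {curve.tm:.2f} C (true {hr.melting_temperature(d):.2f} C), "
    f"10-90% width = {curve.width:.1f} C"
)
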