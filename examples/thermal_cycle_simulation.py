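"""Mechanistic per-cycle simulation of replication under thermal cycling.

Builds stage probabilities from the library's own thermodynamics
(info-duplex occupancy, backbone-junction survival, hairpin
fluctuations), calibrates the two free parameters to the fitted growth
constants, and explores knockouts and protocol temperatures.
"""

import hairpinrep as hr
from hairpinrep import cyclesim as cs

lib = hr.load_packaged_library()
protocol = cs.CycleProtocol(n_cycles=6)  # 45 C base / 67 C peak
rates = cs.MechanisticRates.from_library(lib).calibrate(protocol, hr.REFERENCE_MODEL)

print("stage probabilities under the reference protocol:")
print(f"  p_bind(45 C)    = {rates.p_bind(45):.3f}   (info-domain occupancy)")
print(f"  p_zip(45 C)     = {rates.p_zip(45, 20):.3f}   (per-junction closure)")
print(f"  p_release(67 C) = {rates.p_release(67):.4f}  (replicate separation)")
print(f"  p_destroy(67 C) = {rates.p_destroy(67):.2e} (complex loss per peak)")

pool = cs.SpeciesPool.standard(template_antisense=30.0)
traj, hist = cs.run_protocol(protocol, pool, rates)
print("\nfull reaction, 30 nM template (nM per cycle):")
print(hist[["cycle", "c_nM", "c_bar_nM", "monomer_total_nM"]].round(1).to_string(index=False))

ss = hr.strands_for_template("0000", "+++-")
pool_ko = cs.SpeciesPool.standard(
    "0000", per_strand=100.0, template_antisense=15.0,
    strand_set=ss, all_sixteen=True,
)
_, hist_ko = cs.run_protocol(protocol, pool_ko, rates)
print("\nknockout '+++-' (0D missing; 1D incorporates as a mutation):")
print(hist_ko[["cycle", "c_nM", "partials_nM"]].round(2).to_string(index=False))
print("incomplete 3:4 complexes dominate over full product, as on the gels.")

scan = cs.temperature_scan(
    protocol, "t_peak", [67.0, 72.0, 74.0, 78.0, 82.0], rates,
    lambda: cs.SpeciesPool.standard(template_antisense=30.0),
)
print("\npeak-temperature scan (6-cycle yield):")
print(scan[["t_peak", "yield_nM"]].round(2).to_string(index=False))
print("amplification is robust until the peak reaches the backbone melting range.")
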