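"""Serial transfer: survival under repeated dilution.

A reaction diluted 1:1 with fresh monomer buffer every three cycles can
only maintain its concentration if it grows exponentially.  This script
simulates the survivor and the no-monomer fading control, then refits
the dilution factor from a noisy trace with (k, k0) held fixed.
"""

import numpy as np

import hairpinrep as hr
from hairpinrep import kinetics as kin, synth

spec = kin.SerialTransferSpec(cycles_per_transfer=3, dilution=0.43, n_transfers=8)

survivor = kin.simulate_serial_transfer(hr.REFERENCE_MODEL, spec, c_bar0=30.0)
control = kin.simulate_serial_transfer(
    hr.REFERENCE_MODEL,
    kin.SerialTransferSpec(3, 0.43, 8, monomer_replenished=False),
    c_bar0=30.0,
)
ends = np.isin(survivor.t, np.arange(3, 25, 3, dtype=float))
print("pre-dilution product concentration at each transfer (nM):")
print("  survivor:", np.round(survivor.c[ends], 1))
print("  control (template pool, no monomers):", np.round(control.c_bar[ends], 2))
print(
    "the growing reaction survives dilution with a slow drift; the\n"
    "control, unable to grow, fades geometrically to nothing."
)

noise = synth.NoiseSpec(sigma_rel=0.10, sigma_abs=1.0, seed=3)
df = synth.gen_serial_transfer_trace(
    hr.REFERENCE_MODEL, spec, c_bar0=30.0, noise=noise, include_control=False
)
est = kin.fit_dilution_factor(kin.frame_to_traces(df)[0], hr.REFERENCE_MODEL, spec)
print(
    f"\ndilution factor refit from the noisy trace: {est:.3f} "
    f"(generator used {spec.dilution})"
)
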