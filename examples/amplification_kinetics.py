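"""Cross-catalytic growth: generate noisy traces and refit (k, k0).

The template (c) and its complement (c̄) catalyze each other's assembly:
dc/dt = k c̄ + k0.  This script generates per-cycle amplification traces
for several initial template concentrations with gel-like 10%
multiplicative noise, jointly refits the shared rate constants, and
shows the initial-velocity line.
"""

import hairpinrep as hr
from hairpinrep import kinetics as kin, synth

model = hr.REFERENCE_MODEL  # k = 0.16 / cycle, k0 = 0.4 nM / cycle
print(f"generating model: k={model.k} cycle^-1, k0={model.k0} nM cycle^-1")

noise = synth.NoiseSpec(sigma_rel=0.10, sigma_abs=1.0, seed=42)
df = synth.gen_amplification_traces(
    model, c_bar0_list=(0.0, 5.0, 15.0, 30.0, 45.0),
    n_cycles=6, noise=noise, replicates=5,
)
fit = kin.fit_cross_catalytic(
    kin.frame_to_traces(df), total_per_strand=200.0, n_boot=100, seed=1
)
print(
    f"joint fit over {fit.n_points} points: "
    f"k = {fit.model.k:.3f} (95% CI {fit.k_ci[0]:.3f}-{fit.k_ci[1]:.3f}), "
    f"k0 = {fit.model.k0:.3f} (95% CI {fit.k0_ci[0]:.3f}-{fit.k0_ci[1]:.3f})"
)

print("\ninitial velocity v0 = k*c̄0 + k0 (linear in template -- the")
print("signature of exponential, cross-catalytic replication):")
for cb0 in (0.0, 15.0, 30.0, 45.0):
    print(f"  c̄0 = {cb0:4.0f} nM -> v0 = {kin.initial_velocity(fit.model, cb0):.2f} nM/cycle")
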