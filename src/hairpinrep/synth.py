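"""Seeded generators emulating the experiment's quantified observables.

The laboratory observables behind the analysis -- per-cycle product
concentrations quantified from gel band intensities, plate-reader
melting curves, endpoint yields of defective strand sets -- are not
deposited anywhere, so these generators produce statistically similar
tables from the package's own models.  Noise follows band-intensity
quantification behavior: multiplicative Gaussian (scaling with the
signal) plus a small additive floor for the detection limit.

Every generator is a pure function of its parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinetics, thermo
from .kinetics import CrossCatalyticModel, SerialTransferSpec, Trajectory
from .thermo import DuplexThermo, IonicConditions, REPLICATION_BUFFER


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative + additive-floor noise applied to concentrations."""

    sigma_rel: float = 0.10  # relative standard deviation
    sigma_abs: float = 1.0   # nM additive floor
    seed: int = 0

    def __post_init__(self):
        if self.sigma_rel < 0 or self.sigma_abs < 0:
            raise ValueError("noise sigmas must be nonnegative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(values: np.ndarray, noise: NoiseSpec, rng) -> np.ndarray:
    noisy = values * (1.0 + noise.sigma_rel * rng.standard_normal(values.shape))
    noisy = noisy + noise.sigma_abs * rng.standard_normal(values.shape)
    return np.clip(noisy, 0.0, None)


#: endpoint means (nM) of the defective-set experiments: the intact
#: reaction, a single knockout, and the two-knockout patterns at the
#: independence value 37 * 0.4^2
DEFAULT_ENDPOINT_MEANS = {
    "++++": 37.0,
    "+++-": 14.0,
    "++--": 37.0 * 0.16,
    "+-+-": 37.0 * 0.16,
}


def gen_amplification_traces(
    model: CrossCatalyticModel,
    c_bar0_list=(0.0, 5.0, 15.0, 30.0, 45.0),
    n_cycles: int = 6,
    noise: NoiseSpec = NoiseSpec(),
    replicates: int = 1,
) -> pd.DataFrame:
    """Noisy per-cycle amplification traces for a family of template
    concentrations, as a tidy table (cycle, concentration_nM, series,
    c_bar0_nM, replicate)."""
    rng = noise.rng()
    t = np.arange(0, n_cycles + 1, dtype=float)
    rows = []
    for rep in range(replicates):
        for cb0 in c_bar0_list:
            c, _ = kinetics.closed_form(model, 0.0, float(cb0), t)
            c_noisy = _apply_noise(c, noise, rng)
            for tt, cc in zip(t, c_noisy):
                rows.append(
                    {
                        "cycle": tt,
                        "concentration_nM": cc,
                        "series": f"cb0_{cb0:g}_rep{rep}",
                        "c_bar0_nM": float(cb0),
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def gen_serial_transfer_trace(
    model: CrossCatalyticModel,
    spec: SerialTransferSpec = SerialTransferSpec(),
    c_bar0: float = 30.0,
    noise: NoiseSpec = NoiseSpec(),
    include_control: bool = True,
) -> pd.DataFrame:
    """Serial-transfer survivor trace plus the fading no-monomer control."""
    rng = noise.rng()
    rows = []
    series = [("survivor", spec)]
    if include_control:
        from dataclasses import replace

        series.append(("control_no_monomers", replace(spec, monomer_replenished=False)))
    for name, sp in series:
        traj = kinetics.simulate_serial_transfer(model, sp, c_bar0)
        # the no-monomer control cannot form product; its observable is
        # the diluting template pool
        observed = traj.c if sp.monomer_replenished else traj.c_bar
        c_noisy = _apply_noise(observed, noise, rng)
        for tt, cc in zip(traj.t, c_noisy):
            rows.append(
                {
                    "cycle": tt,
                    "concentration_nM": cc,
                    "series": name,
                    "c_bar0_nM": c_bar0,
                }
            )
    return pd.DataFrame(rows)


def gen_melting_curve(
    dH: float,
    dS: float,
    conditions: IonicConditions = REPLICATION_BUFFER,
    baselines=((0.0, 0.0), (1.0, 0.0)),
    noise: NoiseSpec = NoiseSpec(sigma_rel=0.0, sigma_abs=0.0),
    temperatures=None,
) -> pd.DataFrame:
    """Two-state melting signal through linear baselines plus noise.

    ``baselines`` is ((lower intercept, lower slope), (upper intercept,
    upper slope)) in signal units per Celsius.
    """
    duplex = DuplexThermo(dH, dS, conditions)
    tm = thermo.melting_temperature(duplex)
    if temperatures is None:
        temperatures = np.linspace(tm - 25.0, tm + 25.0, 101)
    T = np.asarray(temperatures, dtype=float)
    f = thermo.unbound_fraction(duplex, T)
    (b0, b1), (u0, u1) = baselines
    signal = (b0 + b1 * T) * (1.0 - f) + (u0 + u1 * T) * f
    rng = noise.rng()
    signal = signal * (1.0 + noise.sigma_rel * rng.standard_normal(signal.shape))
    signal = signal + noise.sigma_abs * rng.standard_normal(signal.shape)
    return pd.DataFrame({"temperature_C": T, "signal": signal})


def gen_defect_endpoints(
    noise: NoiseSpec = NoiseSpec(),
    means: dict[str, float] | None = None,
    replicates: int = 3,
) -> pd.DataFrame:
    """Endpoint-yield table for the knockout patterns (nM after 6 cycles)."""
    means = dict(DEFAULT_ENDPOINT_MEANS if means is None else means)
    rng = noise.rng()
    rows = []
    for pattern, mean in means.items():
        vals = _apply_noise(np.full(replicates, mean), noise, rng)
        for rep, v in enumerate(vals):
            rows.append(
                {"pattern": pattern, "replicate": rep, "endpoint_nM": float(v)}
            )
    return pd.DataFrame(rows)


def gen_random_pool(
    n_strands: int = 8, length: int = 84, seed: int = 0
) -> str:
    """FASTA text of uniform-random DNA strands (agglomeration control).

    Random pools lack a shared information domain, so domain discovery
    on them must fail -- the negative control for the design checks.
    """
    rng = np.random.default_rng(seed)
    lines = []
    for i in range(n_strands):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        lines.append(f">R{i}\n{seq}")
    return "\n".join(lines) + "\n"
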