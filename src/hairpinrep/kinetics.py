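"""Cross-catalytic growth kinetics of the replicator.

The per-cycle growth of template (c) and complement (c̄) concentrations
follows a linear cross-catalytic model

    dc/dt  = k*c̄ + k0,      dc̄/dt = k*c + k0,

with t in thermal-cycle units, k the cross-catalysis rate (cycle^-1)
and k0 the spontaneous (untemplated) formation rate (nM cycle^-1).  In
sum/difference coordinates s = c + c̄, d = c - c̄ the system decouples:

    s(t) = (s0 + 2 k0/k) e^{k t} - 2 k0/k        (s(t) = s0 + 2 k0 t for k = 0)
    d(t) = d0 e^{-k t}

so for c ≈ c̄ the model is simple exponential growth.  The model has no
saturation; fits exclude points near the total strand concentration.

This module provides the closed form, a numerical integrator used as an
independent cross-check, joint least-squares fitting of (k, k0) over
trace families, initial-velocity analysis, serial-transfer simulation
and dilution-factor fitting, and a logistic fit used for sedimentation
endpoint quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares, minimize_scalar


class KineticsError(ValueError):
    pass


class FitError(KineticsError):
    pass


@dataclass(frozen=True)
class CrossCatalyticModel:
    """Rate constants of the cross-catalytic growth law."""

    k: float    # cross-catalysis rate, cycle^-1
    k0: float   # spontaneous formation rate, nM cycle^-1

    def __post_init__(self):
        if self.k < 0 or self.k0 < 0:
            raise KineticsError("rates must be nonnegative")


#: rate constants fitted to the thermal-oscillation amplification data
REFERENCE_MODEL = CrossCatalyticModel(k=0.16, k0=0.4)
#: serial-transfer dilution factor fitted with (k, k0) fixed
REFERENCE_DILUTION = 0.43


@dataclass
class Trajectory:
    """Template/complement concentrations sampled over cycles."""

    t: np.ndarray
    c: np.ndarray
    c_bar: np.ndarray | None = None
    c_bar0: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.c_bar is not None:
            self.c_bar = np.asarray(self.c_bar, dtype=float)
            if self.c_bar.shape != self.t.shape:
                raise KineticsError("c_bar and t must have the same length")
        if self.c.shape != self.t.shape:
            raise KineticsError("c and t must have the same length")


@dataclass(frozen=True)
class SerialTransferSpec:
    """Protocol of a serial-transfer experiment."""

    cycles_per_transfer: int = 3
    dilution: float = 0.5          # factor applied to product species per transfer
    n_transfers: int = 8
    monomer_replenished: bool = True

    def __post_init__(self):
        if not 0 < self.dilution <= 1:
            raise KineticsError("dilution must be in (0, 1]")
        if self.cycles_per_transfer < 1 or self.n_transfers < 1:
            raise KineticsError("counts must be positive")


def closed_form(model: CrossCatalyticModel, c0: float, c_bar0: float, t):
    """Exact trajectories (c, c̄) of the cross-catalytic model.

    ``t`` may be scalar or array, in cycle units.
    """
    if c0 < 0 or c_bar0 < 0:
        raise KineticsError("initial concentrations must be nonnegative")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise KineticsError("t must be nonnegative")
    s0 = c0 + c_bar0
    d0 = c0 - c_bar0
    k, k0 = model.k, model.k0
    if k > 1e-9:
        s = (s0 + 2 * k0 / k) * np.exp(k * t) - 2 * k0 / k
        d = d0 * np.exp(-k * t)
    else:
        # k -> 0 limit, evaluated directly to avoid cancellation in 2*k0/k
        s = s0 + 2 * k0 * t
        d = d0 * np.exp(-k * t)
    return (s + d) / 2.0, (s - d) / 2.0


def integrate_numerical(model: CrossCatalyticModel, c0: float, c_bar0: float, t):
    """Small-step numerical integration of the model (cross-check oracle)."""
    t = np.asarray(t, dtype=float)

    def rhs(_, y):
        return [model.k * y[1] + model.k0, model.k * y[0] + model.k0]

    sol = solve_ivp(
        rhs, (0.0, float(t.max()) if t.size else 0.0), [c0, c_bar0],
        t_eval=t, rtol=1e-10, atol=1e-12, method="RK45",
    )
    return sol.y[0], sol.y[1]


def initial_velocity(model: CrossCatalyticModel, c_bar0: float) -> float:
    """Initial product-formation velocity dc/dt at t=0 with c0 = 0.

    Linear (affine) in the initial template concentration: k*c̄0 + k0.
    """
    return model.k * c_bar0 + model.k0


@dataclass
class CrossCatalyticFit:
    """Joint fit result with bootstrap confidence intervals."""

    model: CrossCatalyticModel
    k_ci: tuple[float, float]
    k0_ci: tuple[float, float]
    n_points: int
    rss: float


def _fit_residuals(params, traces):
    k, k0 = params
    model = CrossCatalyticModel(max(k, 0.0), max(k0, 0.0))
    res = []
    for tr in traces:
        c, _ = closed_form(model, 0.0, tr.c_bar0, tr.t)
        res.append(c - tr.c)
    return np.concatenate(res)


def fit_cross_catalytic(
    traces: list[Trajectory],
    total_per_strand: float | None = None,
    saturation_fraction: float = 0.5,
    n_boot: int = 200,
    seed: int = 0,
) -> CrossCatalyticFit:
    """Joint least-squares fit of shared (k, k0) over a trace family.

    Each trace must carry its known initial template concentration
    ``c_bar0`` (product starts at c0 = 0).  Points above
    ``saturation_fraction * total_per_strand`` are excluded, since the
    model has no saturation.  Bootstrap (resampling traces, seeded)
    yields percentile confidence intervals.
    """
    usable = []
    for tr in traces:
        if tr.c_bar0 is None:
            raise FitError("every trace needs a known c_bar0")
        mask = np.ones_like(tr.t, dtype=bool)
        if total_per_strand is not None:
            mask &= tr.c <= saturation_fraction * total_per_strand
        if mask.sum() > 0:
            usable.append(Trajectory(tr.t[mask], tr.c[mask], c_bar0=tr.c_bar0))
    n_points = int(sum(tr.t.size for tr in usable))
    if n_points < 3:
        raise FitError(f"only {n_points} usable points (<3)")

    def solve(trs):
        best = None
        for k_init in (0.02, 0.1, 0.3, 1.0):
            for k0_init in (0.05, 0.5, 2.0):
                sol = least_squares(
                    _fit_residuals, [k_init, k0_init],
                    bounds=([0.0, 0.0], [np.inf, np.inf]), args=(trs,),
                )
                if best is None or sol.cost < best.cost:
                    best = sol
        return best

    sol = solve(usable)
    k_hat, k0_hat = sol.x

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        resampled = []
        for tr in usable:
            idx = rng.integers(0, tr.t.size, size=tr.t.size)
            resampled.append(Trajectory(tr.t[idx], tr.c[idx], c_bar0=tr.c_bar0))
        try:
            b = solve(resampled)
            boots.append(b.x)
        except Exception:
            continue
    if boots:
        boots = np.asarray(boots)
        k_ci = tuple(np.percentile(boots[:, 0], [2.5, 97.5]))
        k0_ci = tuple(np.percentile(boots[:, 1], [2.5, 97.5]))
    else:
        k_ci = k0_ci = (float("nan"), float("nan"))
    return CrossCatalyticFit(
        model=CrossCatalyticModel(float(k_hat), float(k0_hat)),
        k_ci=(float(k_ci[0]), float(k_ci[1])),
        k0_ci=(float(k0_ci[0]), float(k0_ci[1])),
        n_points=n_points,
        rss=float(2 * sol.cost),
    )


def simulate_serial_transfer(
    model: CrossCatalyticModel,
    spec: SerialTransferSpec,
    c_bar0: float,
    c0: float = 0.0,
) -> Trajectory:
    """Growth segments alternating with dilution at transfer points.

    Concentrations are sampled at integer cycles; the value recorded at
    a transfer cycle is the pre-dilution value, and the dilution factor
    is then applied to both species before the next segment.  With
    ``monomer_replenished=False`` growth is disabled throughout (the
    fading no-monomer control); the returned trajectory then decays
    geometrically, ending (post-dilution) at dilution**n_transfers of
    the start.
    """
    growth = model if spec.monomer_replenished else CrossCatalyticModel(0.0, 0.0)
    seg_t = np.arange(1, spec.cycles_per_transfer + 1, dtype=float)
    ts = [np.array([0.0])]
    cs = [np.array([c0])]
    cbs = [np.array([c_bar0])]
    c, cb = c0, c_bar0
    t_offset = 0.0
    for _ in range(spec.n_transfers):
        seg_c, seg_cb = closed_form(growth, c, cb, seg_t)
        ts.append(t_offset + seg_t)
        cs.append(seg_c)
        cbs.append(seg_cb)
        t_offset += spec.cycles_per_transfer
        c, cb = seg_c[-1] * spec.dilution, seg_cb[-1] * spec.dilution
    traj = Trajectory(
        np.concatenate(ts), np.concatenate(cs), np.concatenate(cbs), c_bar0=c_bar0
    )
    traj.final_state = (c, cb)  # post final dilution
    return traj


def fit_dilution_factor(
    trace: Trajectory,
    model: CrossCatalyticModel,
    spec: SerialTransferSpec,
    c_bar0: float | None = None,
    c0: float = 0.0,
) -> float:
    """1-D least-squares estimate of the dilution factor in (0, 1].

    (k, k0) are held fixed at the given model; the simulated trajectory
    is compared with ``trace.c`` on the trace's cycle grid.
    """
    if c_bar0 is None:
        c_bar0 = trace.c_bar0
    if c_bar0 is None:
        raise FitError("c_bar0 must be given (on the trace or explicitly)")

    def sse(d):
        sim = simulate_serial_transfer(
            model, replace(spec, dilution=float(d)), c_bar0, c0
        )
        pred = np.interp(trace.t, sim.t, sim.c)
        return float(np.sum((pred - trace.c) ** 2))

    sol = minimize_scalar(sse, bounds=(1e-3, 1.0), method="bounded")
    if not sol.success:
        raise FitError("dilution-factor fit did not converge")
    return float(sol.x)


@dataclass
class SigmoidFit:
    """Logistic fit of a sedimentation time trace.

    ``amplitude`` is the fitted relative concentration increase of the
    plateau over the first frame (c/c0 - 1); ``c_over_c0`` the plateau
    itself; ``midpoint`` and ``rate`` the logistic center and steepness.
    """

    amplitude: float
    c_over_c0: float
    midpoint: float
    rate: float
    flat: bool = False


def fit_sigmoid(time, value) -> SigmoidFit:
    """3-parameter logistic fit of ``value/value[0]`` against time."""
    t = np.asarray(time, dtype=float)
    y = np.asarray(value, dtype=float)
    if t.size < 6:
        raise FitError("need at least 6 points")
    y0 = y[0]
    if y0 == 0:
        raise FitError("first frame is zero; cannot normalize")
    yn = y / y0
    span = yn.max() - yn.min()
    if span < 1e-6:
        return SigmoidFit(0.0, 1.0, float(t.mean()), 0.0, flat=True)

    def model(tt, a, t0, r):
        return 1.0 + a / (1.0 + np.exp(-r * (tt - t0)))

    a0 = yn[-1] - 1.0
    t0_0 = float(t[np.argmin(np.abs(yn - (1 + a0 / 2)))])
    r0 = 4.0 / max(t[-1] - t[0], 1e-9)
    try:
        popt, _ = curve_fit(model, t, yn, p0=[a0, t0_0, r0], maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"sigmoid fit failed: {exc}") from exc
    a, t0, r = (float(v) for v in popt)
    return SigmoidFit(amplitude=a, c_over_c0=1.0 + a, midpoint=t0, rate=r)


# ---------------------------------------------------------------------------
# trace table I/O (TSV: cycle, concentration_nM, series, c_bar0_nM)

def traces_to_frame(traces: list[Trajectory], series_ids=None) -> pd.DataFrame:
    rows = []
    for i, tr in enumerate(traces):
        sid = series_ids[i] if series_ids is not None else f"trace{i}"
        for t, c in zip(tr.t, tr.c):
            rows.append(
                {"cycle": t, "concentration_nM": c, "series": sid,
                 "c_bar0_nM": tr.c_bar0 if tr.c_bar0 is not None else np.nan}
            )
    return pd.DataFrame(rows)


def write_traces(traces: list[Trajectory], path, series_ids=None) -> None:
    traces_to_frame(traces, series_ids).to_csv(path, sep="\t", index=False)


def read_traces(path) -> list[Trajectory]:
    df = pd.read_csv(path, sep="\t")
    return frame_to_traces(df)


def frame_to_traces(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for _, grp in df.groupby("series", sort=False):
        cb0 = grp["c_bar0_nM"].iloc[0]
        out.append(
            Trajectory(
                grp["cycle"].to_numpy(),
                grp["concentration_nM"].to_numpy(),
                c_bar0=None if pd.isna(cb0) else float(cb0),
            )
        )
    return out
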