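"""Nearest-neighbor duplex thermodynamics and two-state melting.

Free energies of short DNA duplexes are computed by summing unified
nearest-neighbor ΔH/ΔS increments (Watson-Crick steps, internal and
terminal mismatches) with duplex-initiation penalties, followed by an
empirical salt correction for the replication buffer (monovalent sodium
plus magnesium).  Everything downstream -- melting temperatures, unbound
fractions, melting-curve fits -- assumes a two-state (all-or-none)
bimolecular equilibrium A + B <=> AB with equal strand concentrations.

Parameter tables are taken from Biopython's ``Bio.SeqUtils.MeltingTemp``
(DNA_NN3 unified set, DNA_IMM1 internal-mismatch set, DNA_TMM1
terminal-mismatch set); the summation itself is done here so that ΔH and
ΔS are available individually.  Steps where both positions of a
nearest-neighbor doublet are mismatched (tandem mismatches) have no
published parameters in the unified set and contribute nothing to the
sum, which treats such a step as an unstacked internal loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt
from scipy.optimize import curve_fit

R_CAL = 1.987  # gas constant, cal/(mol*K)
_ZERO_C = 273.15

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ThermoError(ValueError):
    """Invalid input to a thermodynamic computation."""


class NoTransitionError(ThermoError):
    """Melting data contain no resolvable two-state transition."""


def complement(seq: str) -> str:
    """Base-by-base complement (keeps 5'->3' index order)."""
    return "".join(COMPLEMENT[b] for b in seq)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


@dataclass(frozen=True)
class IonicConditions:
    """Buffer and strand-concentration context for a duplex.

    Defaults are the replication buffer: 150 mM NaCl with 20 mM MgCl2,
    and 400 nM total strand concentration (two strands at 200 nM each).
    """

    monovalent: float = 150.0       # mM sodium-equivalent (before Mg term)
    divalent_mg: float = 20.0       # mM Mg2+
    total_strand_conc: float = 400e-9  # molar, per complementary pair
    salt_method: int = 5            # Bio.SeqUtils.MeltingTemp salt_correction method

    def __post_init__(self):
        if self.monovalent < 0 or self.divalent_mg < 0 or self.total_strand_conc < 0:
            raise ThermoError("ionic conditions must be nonnegative")


REPLICATION_BUFFER = IonicConditions()


@dataclass(frozen=True)
class DuplexThermo:
    """Salt-corrected ΔH (kcal/mol) and ΔS (cal/(mol*K)) of one duplex."""

    dH: float
    dS: float
    conditions: IonicConditions = REPLICATION_BUFFER

    def dG(self, temperature_c: float = 37.0) -> float:
        """Free energy ΔG(T) = ΔH - T*ΔS in kcal/mol at T in Celsius."""
        return self.dH - (temperature_c + _ZERO_C) * self.dS / 1000.0


@dataclass
class MeltingCurve:
    """Two-state melting curve: unbound fraction on a temperature grid."""

    temperatures: np.ndarray  # Celsius
    unbound_fraction: np.ndarray
    tm: float                 # Celsius, fraction = 0.5
    width: float              # Celsius, 10-90% transition span


def _lookup_step(top2: str, bot2: str, nn_table, imm_table) -> tuple[float, float]:
    """ΔH/ΔS for one nearest-neighbor doublet; (0,0) for tandem mismatches."""
    key = top2 + "/" + bot2
    for table in (imm_table, nn_table):
        if key in table:
            return tuple(table[key])
        if key[::-1] in table:
            return tuple(table[key[::-1]])
    return 0.0, 0.0


def duplex_thermo(
    top: str,
    bottom: str | None = None,
    conditions: IonicConditions = REPLICATION_BUFFER,
    *,
    nn_table=None,
    imm_table=None,
    tmm_table=None,
) -> DuplexThermo:
    """Nearest-neighbor ΔH/ΔS of ``top`` paired with ``bottom``.

    ``bottom`` is given 3'->5', aligned base-by-base against ``top``
    (antiparallel); mismatches are permitted anywhere.  If ``bottom`` is
    omitted the perfect complement is used.  The salt correction of the
    given :class:`IonicConditions` is applied to ΔS.
    """
    nn_table = nn_table or mt.DNA_NN3
    imm_table = imm_table or mt.DNA_IMM1
    tmm_table = tmm_table or mt.DNA_TMM1

    top = top.upper()
    if bottom is None:
        bottom = complement(top)
    bottom = bottom.upper()
    if len(top) != len(bottom):
        raise ThermoError("top and bottom strands must have equal length")
    if len(top) < 2:
        raise ThermoError("need at least 2 bp (one nearest-neighbor step)")
    for seq in (top, bottom):
        bad = set(seq) - set("ACGT")
        if bad:
            raise ThermoError(f"non-ACGT characters: {sorted(bad)}")

    dH = 0.0
    dS = 0.0
    t, b = top, bottom

    # Terminal mismatches consume the end step (same convention as Tm_NN).
    left = b[:2][::-1] + "/" + t[:2][::-1]
    if left in tmm_table:
        h, s = tmm_table[left]
        dH += h
        dS += s
        t, b = t[1:], b[1:]
    right = t[-2:] + "/" + b[-2:]
    if right in tmm_table:
        h, s = tmm_table[right]
        dH += h
        dS += s
        t, b = t[:-1], b[:-1]

    # Initiation and terminal base-pair penalties (based on the top strand).
    h, s = nn_table["init"]
    dH += h
    dS += s
    for end_base in (top[0], top[-1]):
        key = "init_A/T" if end_base in "AT" else "init_G/C"
        h, s = nn_table[key]
        dH += h
        dS += s

    for i in range(len(t) - 1):
        h, s = _lookup_step(t[i : i + 2], b[i : i + 2], nn_table, imm_table)
        dH += h
        dS += s

    dS += mt.salt_correction(
        Na=conditions.monovalent,
        Mg=conditions.divalent_mg,
        method=conditions.salt_method,
        seq=top,
    )
    return DuplexThermo(dH=dH, dS=dS, conditions=conditions)


def melting_temperature(duplex: DuplexThermo) -> float:
    """Two-state Tm in Celsius for a non-self-complementary duplex.

    Tm = 1000*ΔH / (ΔS + R ln(C_T/4)) - 273.15, with C_T the total
    strand concentration of the pair (equal strand concentrations).
    """
    ct = duplex.conditions.total_strand_conc
    denom = duplex.dS + R_CAL * math.log(ct / 4.0)
    if denom >= 0:
        raise ThermoError("unphysical parameters: ΔS + R ln(CT/4) must be < 0")
    return 1000.0 * duplex.dH / denom - _ZERO_C


def unbound_fraction(duplex: DuplexThermo, temperature_c):
    """Fraction of strands unbound at T (Celsius), two-state mass action.

    Solves A + B <=> AB with [A]_tot = [B]_tot = C_T/2 and
    K = exp(-ΔG(T)/RT).  Accepts a scalar or array temperature.
    """
    T = np.asarray(temperature_c, dtype=float) + _ZERO_C
    dG_cal = duplex.dH * 1000.0 - T * duplex.dS
    # association constant, clipped to avoid overflow at extreme T
    lnK = np.clip(-dG_cal / (R_CAL * T), -60.0, 60.0)
    K = np.exp(lnK)
    a_tot = duplex.conditions.total_strand_conc / 2.0
    # stable root of K x^2 + x - a_tot = 0 (free-strand concentration)
    a_free = 2.0 * a_tot / (1.0 + np.sqrt(1.0 + 4.0 * K * a_tot))
    frac = a_free / a_tot
    if np.ndim(temperature_c) == 0:
        return float(frac)
    return frac


def melting_curve(
    duplex: DuplexThermo,
    temperatures: np.ndarray | None = None,
) -> MeltingCurve:
    """Evaluate the two-state melting curve of ``duplex`` on a grid."""
    tm = melting_temperature(duplex)
    if temperatures is None:
        temperatures = np.linspace(tm - 30.0, tm + 30.0, 241)
    temperatures = np.asarray(temperatures, dtype=float)
    frac = unbound_fraction(duplex, temperatures)
    width = _transition_width(duplex)
    return MeltingCurve(temperatures, frac, tm=tm, width=width)


def _transition_width(duplex: DuplexThermo) -> float:
    """10-90% transition span in Celsius, by bisection on the fraction."""
    tm = melting_temperature(duplex)

    def solve(target: float) -> float:
        lo, hi = tm - 60.0, tm + 60.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if unbound_fraction(duplex, mid) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    return solve(0.9) - solve(0.1)


def fit_melting_curve(
    temperatures,
    signal,
    conditions: IonicConditions = REPLICATION_BUFFER,
) -> tuple[MeltingCurve, DuplexThermo]:
    """Fit a two-state transition with linear baselines to melting data.

    The model is ``signal = lower(T)*(1-f) + upper(T)*f`` with linear
    lower/upper baselines and ``f`` the two-state unbound fraction of a
    duplex with free (ΔH, ΔS).  Returns the fitted curve (baseline
    corrected) and the (ΔH, ΔS) estimate.

    Raises :class:`NoTransitionError` for flat/featureless data.
    """
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(signal, dtype=float)
    if T.size < 15:
        raise ThermoError("need at least 15 points spanning the transition")
    order = np.argsort(T)
    T, y = T[order], y[order]

    span = y.max() - y.min()
    scale = max(abs(y).max(), 1e-30)
    if span / scale < 1e-3:
        raise NoTransitionError("signal is constant: no transition in range")

    # crude baseline estimates from the ends
    n_edge = max(3, T.size // 8)
    lo_fit = np.polyfit(T[:n_edge], y[:n_edge], 1)
    hi_fit = np.polyfit(T[-n_edge:], y[-n_edge:], 1)

    lower0 = np.polyval(lo_fit, T)
    upper0 = np.polyval(hi_fit, T)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_est = np.clip((y - lower0) / np.where(upper0 != lower0, upper0 - lower0, 1.0), 0, 1)
    # Tm guess: first crossing of 0.5
    cross = np.nonzero(np.diff(np.sign(f_est - 0.5)))[0]
    tm0 = T[cross[0]] if cross.size else float(T[np.argmax(np.gradient(f_est))])

    ct = conditions.total_strand_conc

    def model(Tc, dH, dS, b0, b1, u0, u1):
        d = DuplexThermo(dH, dS, conditions)
        f = unbound_fraction(d, Tc)
        return (b0 + b1 * Tc) * (1 - f) + (u0 + u1 * Tc) * f

    best = None
    for dH0 in (-50.0, -80.0, -120.0, -160.0):
        dS0 = dH0 * 1000.0 / (tm0 + _ZERO_C) - R_CAL * math.log(ct / 4.0)
        p0 = [dH0, dS0, lo_fit[1], lo_fit[0], hi_fit[1], hi_fit[0]]
        try:
            popt, _ = curve_fit(model, T, y, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        resid = y - model(T, *popt)
        cost = float(resid @ resid)
        if popt[0] >= 0 or popt[1] >= 0:
            continue
        if best is None or cost < best[0]:
            best = (cost, popt)
    if best is None:
        raise NoTransitionError("two-state fit did not converge on these data")

    dH, dS = best[1][:2]
    est = DuplexThermo(float(dH), float(dS), conditions)
    tm = melting_temperature(est)
    if not (T.min() - 10.0 <= tm <= T.max() + 10.0):
        raise NoTransitionError("fitted transition lies outside the data range")
    curve = melting_curve(est, T)
    return curve, est
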