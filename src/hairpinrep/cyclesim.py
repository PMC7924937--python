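"""Mechanistic per-cycle simulator of the four-step replication cycle.

Each thermal oscillation is coarse-grained into one discrete cycle with
four stages: (0) fast cooling closes all free hairpins (activation),
(1) activated strands bind an assembled template at their information
domains with a two-state occupancy at the base temperature, (2) the
hairpins of neighboring bound strands interconnect (backbone closure)
with a per-junction probability during the base hold, plus a slow
spontaneous (untemplated) channel, and (3) the brief peak separates
replicates from templates at the information domains while the hotter
backbone duplexes survive -- unless the peak approaches the backbone
melting range, where complexes are destroyed and collapse ensues.

All stage probabilities derive from the thermodynamics module (info
duplex, weakest backbone junction, a configurable hairpin stability);
two free parameters (the zipping attempt rate and the spontaneous
prefactor) are calibrated once so that under the reference protocol the
ideal-limit per-cycle gain and the spontaneous rate reproduce the
fitted cross-catalytic constants.

The deterministic step integrates the effective linear cross-catalytic
rates with the exact one-cycle propagator (matrix exponential), so in
the ideal limit (full occupancy, complete release, no destruction, no
depletion) the simulator reduces exactly to the closed-form growth
model.  A stochastic variant draws Poisson/binomial copies of every
conversion at a configurable molecules-per-nM scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import expm

from . import thermo
from .kinetics import CrossCatalyticModel, Trajectory
from .sequences import POSITIONS, StrandLibrary, StrandSet, strand_id
from .thermo import DuplexThermo, IonicConditions, REPLICATION_BUFFER

R_CAL = thermo.R_CAL
_ZERO_C = 273.15
_TINY = 1e-12


class CycleSimError(ValueError):
    pass


@dataclass(frozen=True)
class CycleProtocol:
    """Thermal-oscillation protocol driving the replication."""

    t_base: float = 45.0    # Celsius, base hold
    t_peak: float = 67.0    # Celsius, separation spike
    hold_base: float = 20.0  # minutes
    hold_peak: float = 1.0   # seconds
    ramp: float = 20.0       # seconds per full cycle
    n_cycles: int = 6

    def __post_init__(self):
        if self.t_peak <= self.t_base:
            raise CycleSimError("t_peak must exceed t_base")
        if min(self.hold_base, self.hold_peak, self.ramp) <= 0:
            raise CycleSimError("durations must be positive")
        if self.n_cycles < 0:
            raise CycleSimError("n_cycles must be nonnegative")


@dataclass
class MechanisticRates:
    """Stage probabilities of one cycle, derived from thermodynamics.

    ``zip_attempt`` (min^-1) is the backbone-closure attempt rate per
    unit hairpin open-fraction; ``spont_prefactor`` (nM/cycle) scales
    the untemplated channel, which requires two free hairpins to
    fluctuate open simultaneously (hence the squared open fraction).
    ``overrides`` pins any stage probability to a constant (used for
    the ideal-limit reduction and for what-if analyses).
    """

    info: DuplexThermo | None = None
    backbone_junctions: tuple[DuplexThermo, ...] = ()
    hairpin_dH: float = -60.0   # kcal/mol, stem closing
    hairpin_tm: float = 62.0    # Celsius, unimolecular midpoint
    zip_attempt: float = 8.0    # min^-1 per unit open fraction
    spont_prefactor: float = 6000.0  # nM/cycle
    mismatch_occupancy_rel: float = 0.4
    overrides: dict = field(default_factory=dict)

    # -- stage probabilities -------------------------------------------------
    def f_open(self, temperature_c: float) -> float:
        """Unimolecular open fraction of a hairpin stem at T."""
        T = temperature_c + _ZERO_C
        dS = self.hairpin_dH * 1000.0 / (self.hairpin_tm + _ZERO_C)
        dG_cal = self.hairpin_dH * 1000.0 - T * dS
        x = min(-dG_cal / (R_CAL * T), 500.0)
        return 1.0 / (1.0 + math.exp(x))

    def p_bind(self, temperature_c: float) -> float:
        if "p_bind" in self.overrides:
            return self.overrides["p_bind"]
        return 1.0 - thermo.unbound_fraction(self.info, temperature_c)

    def p_release(self, temperature_c: float) -> float:
        if "p_release" in self.overrides:
            return self.overrides["p_release"]
        return thermo.unbound_fraction(self.info, temperature_c)

    def p_destroy(self, temperature_c: float) -> float:
        """Probability an assembled tetramer does not survive the peak.

        With the info duplexes molten at the peak, the complex stays
        assembled only if every one of its four backbone junctions
        stays bound; each junction melts independently with its own
        two-state unbound fraction.
        """
        if "p_destroy" in self.overrides:
            return self.overrides["p_destroy"]
        survive = 1.0
        for d in self.backbone_junctions:
            survive *= 1.0 - thermo.unbound_fraction(d, temperature_c)
        return 1.0 - survive

    def p_zip(self, temperature_c: float, hold_base_min: float) -> float:
        if "p_zip" in self.overrides:
            return self.overrides["p_zip"]
        return 1.0 - math.exp(
            -self.zip_attempt * self.f_open(temperature_c) * hold_base_min
        )

    def r_spont(self, temperature_c: float) -> float:
        if "r_spont" in self.overrides:
            return self.overrides["r_spont"]
        return self.spont_prefactor * self.f_open(temperature_c) ** 2

    # -- construction --------------------------------------------------------
    @classmethod
    def from_library(
        cls,
        lib: StrandLibrary,
        conditions: IonicConditions = REPLICATION_BUFFER,
        bit: str = "0",
        **kwargs,
    ) -> "MechanisticRates":
        """Derive the info and (weakest) backbone duplex from a library."""
        from .sequences import (
            SUCCESSOR,
            annotate_strand,
            find_information_domains,
            longest_complementary_stretch,
        )

        if not lib.info_domains:
            find_information_domains(lib)
        info = thermo.duplex_thermo(lib.info_domains[bit], conditions=conditions)
        junctions = []
        for pos in POSITIONS:
            s = lib[strand_id(bit, pos)]
            nxt = lib[strand_id(bit, SUCCESSOR["sense"][pos])]
            hp3 = s.sequence[slice(*annotate_strand(s, lib).hairpin3)]
            hp5 = nxt.sequence[slice(*annotate_strand(nxt, lib).hairpin5)]
            m = longest_complementary_stretch(hp3, hp5)
            junctions.append(thermo.duplex_thermo(m.top, m.bottom, conditions))
        return cls(info=info, backbone_junctions=tuple(junctions), **kwargs)

    @classmethod
    def ideal(cls, model: CrossCatalyticModel) -> "MechanisticRates":
        """Ideal-limit rates reproducing the closed-form model exactly:
        full occupancy, complete release, no destruction."""
        return cls(
            overrides={
                "p_bind": 1.0,
                "p_release": 1.0,
                "p_destroy": 0.0,
                "p_zip": model.k ** 0.25,
                "r_spont": model.k0,
            }
        )

    def calibrate(
        self,
        protocol: CycleProtocol,
        model: CrossCatalyticModel,
    ) -> "MechanisticRates":
        """Pin the two free parameters to the fitted rate constants.

        Sets ``zip_attempt`` so that the per-cycle gain under
        ``protocol`` equals ``model.k``, and ``spont_prefactor`` so the
        untemplated rate at the base temperature equals ``model.k0``.
        """
        pb = self.p_bind(protocol.t_base)
        prel = self.p_release(protocol.t_peak)
        pz4 = model.k / (pb ** 4 * prel)
        if not 0 < pz4 < 1:
            raise CycleSimError(
                f"target gain {model.k} unreachable: p_bind^4*p_release = {pb ** 4 * prel:.3g}"
            )
        pz = pz4 ** 0.25
        f = self.f_open(protocol.t_base)
        return replace(
            self,
            zip_attempt=-math.log(1.0 - pz) / (f * protocol.hold_base),
            spont_prefactor=model.k0 / f ** 2,
        )


@dataclass
class SpeciesPool:
    """Concentrations (nM) of every species class in the reactor."""

    code: str                      # template meta-sequence, e.g. "0000"
    monomers: dict[str, float]
    templates: dict[str, float]    # polarity ('sense'/'antisense') -> nM
    product: float = 0.0           # replicate:template 4:4 duplex pool
    partials: dict[str, float] = field(
        default_factory=lambda: {"sense": 0.0, "antisense": 0.0}
    )                              # incomplete (3:4-type) trimer pool, by replicate polarity

    @property
    def partials_total(self) -> float:
        return self.partials["sense"] + self.partials["antisense"]

    @classmethod
    def standard(
        cls,
        code: str = "0000",
        per_strand: float = 200.0,
        template_antisense: float = 30.0,
        strand_set: StrandSet | None = None,
        all_sixteen: bool = False,
    ) -> "SpeciesPool":
        """Monomer pool at ``per_strand`` nM each plus an assembled
        antisense template.  Without ``all_sixteen`` only the strands of
        the template's bits are stocked (the restricted subset used in
        pure amplification runs)."""
        monomers = {}
        for bit in "01":
            for i, pos in enumerate(POSITIONS):
                if not all_sixteen and bit != code[i]:
                    continue
                for anti in (False, True):
                    monomers[strand_id(bit, pos, anti)] = per_strand
        if strand_set is not None:
            monomers = {
                sid: (c if sid in strand_set.included else 0.0)
                for sid, c in monomers.items()
            }
        return cls(
            code=code,
            monomers=monomers,
            templates={"sense": 0.0, "antisense": template_antisense},
        )

    def total_strands(self) -> float:
        """Total strand material in nM-strand units (mass bookkeeping)."""
        return (
            sum(self.monomers.values())
            + 4.0 * (self.templates["sense"] + self.templates["antisense"])
            + 8.0 * self.product
            + 3.0 * self.partials_total
        )

    def copy(self) -> "SpeciesPool":
        return SpeciesPool(
            self.code, dict(self.monomers), dict(self.templates),
            self.product, dict(self.partials),
        )


def _flip(bit: str) -> str:
    return "1" if bit == "0" else "0"


def _occupancies(pool: SpeciesPool, rates: MechanisticRates, t_base: float,
                 replicate_sense: bool):
    """Per-position binding occupancy and the strand id consumed there."""
    pb = rates.p_bind(t_base)
    occ, consume = {}, {}
    for i, pos in enumerate(POSITIONS):
        bit = pool.code[i]
        sid = strand_id(bit, pos, antisense=not replicate_sense)
        alt = strand_id(_flip(bit), pos, antisense=not replicate_sense)
        if pool.monomers.get(sid, 0.0) > _TINY:
            occ[pos], consume[pos] = pb, sid
        elif pool.monomers.get(alt, 0.0) > _TINY:
            occ[pos], consume[pos] = pb * rates.mismatch_occupancy_rel, alt
        else:
            occ[pos], consume[pos] = 0.0, None
    return occ, consume


def _draw(rng, value: float, scale: float) -> float:
    """Poisson copy of a deterministic amount (stochastic variant)."""
    if rng is None or value <= 0:
        return max(value, 0.0)
    return rng.poisson(value * scale) / scale


def _survive(rng, value: float, p_destroy: float, scale: float) -> float:
    if rng is None:
        return value * (1.0 - p_destroy)
    n = int(round(value * scale))
    return rng.binomial(n, 1.0 - p_destroy) / scale if n > 0 else 0.0


def step_cycle(
    pool: SpeciesPool,
    protocol: CycleProtocol,
    rates: MechanisticRates,
    rng: np.random.Generator | None = None,
    scale: float = 1000.0,
) -> SpeciesPool:
    """Advance the reactor by one thermal cycle; returns a new pool."""
    out = pool.copy()
    pz = rates.p_zip(protocol.t_base, protocol.hold_base)
    prel = rates.p_release(protocol.t_peak)
    pdes = rates.p_destroy(protocol.t_peak)

    # stage 1+2: templated assembly during the base hold --------------------
    gain, kappa, rho, consume_by_pol, occ_by_pol, partial_rate = {}, {}, {}, {}, {}, {}
    pb = rates.p_bind(protocol.t_base)
    r0 = rates.r_spont(protocol.t_base)
    for pol, sense_flag in (("sense", True), ("antisense", False)):
        occ, consume = _occupancies(pool, rates, protocol.t_base, sense_flag)
        o = [occ[p] for p in POSITIONS]
        full = float(np.prod(o)) * pz ** 4
        # three bound neighbors close two junctions on the circular template
        part = sum(
            (1.0 - o[i]) * np.prod([o[j] for j in range(4) if j != i])
            for i in range(4)
        ) * pz ** 2
        rel_occ = float(np.prod(o)) / pb ** 4 if pb > 0 else 0.0
        gain[pol] = full
        kappa[pol] = full * prel
        rho[pol] = r0 * rel_occ
        partial_rate[pol] = part
        consume_by_pol[pol] = consume
        occ_by_pol[pol] = occ

    # exact one-cycle propagator of the effective linear system
    A = np.array(
        [
            [0.0, kappa["sense"], rho["sense"]],
            [kappa["antisense"], 0.0, rho["antisense"]],
            [0.0, 0.0, 0.0],
        ]
    )
    state = np.array([pool.templates["sense"], pool.templates["antisense"], 1.0])
    new_state = expm(A) @ state
    released = {
        "sense": max(new_state[0] - state[0], 0.0),
        "antisense": max(new_state[1] - state[1], 0.0),
    }
    formed, partial_new = {}, {}
    for pol, other in (("sense", "antisense"), ("antisense", "sense")):
        if prel > _TINY:
            formed[pol] = released[pol] / prel
        else:  # nothing separates; production is linear in the start template
            formed[pol] = gain[pol] * pool.templates[other] + rho[pol]
        partial_new[pol] = partial_rate[pol] * pool.templates[other]
        if rng is not None:
            formed[pol] = _draw(rng, formed[pol], scale)
            partial_new[pol] = _draw(rng, partial_new[pol], scale)

    # a 3:4 partial incorporates the three strands outside the weakest-
    # occupancy position (the dominant incomplete configuration)
    partial_used = {}
    for pol in ("sense", "antisense"):
        occ, consume = occ_by_pol[pol], consume_by_pol[pol]
        weakest = min(POSITIONS, key=lambda p: occ[p])
        partial_used[pol] = [
            consume[p] for p in POSITIONS if p != weakest and consume[p] is not None
        ]

    # monomer depletion: scale production by the scarcest required strand
    demand: dict[str, float] = {}
    for pol in ("sense", "antisense"):
        for sid in consume_by_pol[pol].values():
            if sid is not None:
                demand[sid] = demand.get(sid, 0.0) + formed[pol]
        for sid in partial_used[pol]:
            demand[sid] = demand.get(sid, 0.0) + partial_new[pol]
    phi = 1.0
    for sid, d in demand.items():
        if d > _TINY:
            phi = min(phi, max(pool.monomers.get(sid, 0.0), 0.0) / d)
    for pol in ("sense", "antisense"):
        formed[pol] *= phi
        partial_new[pol] *= phi
    for sid, d in demand.items():
        out.monomers[sid] = max(out.monomers.get(sid, 0.0) - d * phi, 0.0)

    # stage 3: separation at the peak ---------------------------------------
    for pol in ("sense", "antisense"):
        rel = formed[pol] * prel
        out.templates[pol] = pool.templates[pol] + rel
        out.product += formed[pol] * (1.0 - prel)
    # the standing product-duplex pool gets another chance to separate
    pool_release = pool.product * prel
    if rng is not None:
        n = int(round(pool.product * scale))
        pool_release = rng.binomial(n, prel) / scale if n > 0 else 0.0
    out.product -= pool_release
    out.templates["sense"] += pool_release
    out.templates["antisense"] += pool_release
    for pol in ("sense", "antisense"):
        out.partials[pol] = pool.partials[pol] + partial_new[pol]

    # destruction: backbone junctions melt near the peak --------------------
    # destroyed material is returned to the strands the current cycle
    # incorporates (composition bookkeeping is approximate for pools that
    # mix strand provenance; exact when no strand is knocked out)
    credits: dict[str, float] = {}

    def credit(ids, amount_per_complex, destroyed):
        if destroyed <= 0 or not ids:
            return
        per = amount_per_complex * destroyed / len(ids)
        for sid in ids:
            credits[sid] = credits.get(sid, 0.0) + per

    tetramer_ids = {
        pol: [sid for sid in consume_by_pol[pol].values() if sid is not None]
        for pol in ("sense", "antisense")
    }
    for pol in ("sense", "antisense"):
        before = out.templates[pol]
        out.templates[pol] = _survive(rng, before, pdes, scale)
        credit(tetramer_ids[pol], 4.0, before - out.templates[pol])
    before = out.product
    out.product = _survive(rng, before, pdes, scale)
    for pol in ("sense", "antisense"):
        credit(tetramer_ids[pol], 4.0, before - out.product)
    for pol in ("sense", "antisense"):
        before = out.partials[pol]
        out.partials[pol] = _survive(rng, before, pdes, scale)
        credit(partial_used[pol], 3.0, before - out.partials[pol])
    for sid, amount in credits.items():
        out.monomers[sid] = out.monomers.get(sid, 0.0) + amount
    return out



def run_protocol(
    protocol: CycleProtocol,
    pool: SpeciesPool,
    rates: MechanisticRates,
    stochastic: bool = False,
    seed: int | None = None,
    scale: float = 1000.0,
) -> tuple[Trajectory, pd.DataFrame]:
    """Iterate :func:`step_cycle` and collect the per-cycle trajectory.

    The reported concentration ``c`` counts sense-tetramer-containing
    complexes (free sense templates plus product duplexes); ``c_bar``
    counts antisense-tetramer-containing complexes (including the
    3:4-type partials, whose tetramer is the template).
    """
    rng = np.random.default_rng(seed) if stochastic else None
    rows = []

    def snapshot(cycle, p):
        rows.append(
            {
                "cycle": cycle,
                "c_nM": p.templates["sense"] + p.product,
                "c_bar_nM": p.templates["antisense"] + p.product + p.partials_total,
                "template_sense_nM": p.templates["sense"],
                "template_antisense_nM": p.templates["antisense"],
                "product_nM": p.product,
                "partials_nM": p.partials_total,
                "monomer_total_nM": sum(p.monomers.values()),
            }
        )

    snapshot(0, pool)
    current = pool
    for cycle in range(1, protocol.n_cycles + 1):
        current = step_cycle(current, protocol, rates, rng=rng, scale=scale)
        snapshot(cycle, current)
    hist = pd.DataFrame(rows)
    traj = Trajectory(
        hist["cycle"].to_numpy(dtype=float),
        hist["c_nM"].to_numpy(),
        hist["c_bar_nM"].to_numpy(),
        c_bar0=pool.templates["antisense"],
    )
    return traj, hist


def temperature_scan(
    protocol: CycleProtocol,
    variable: str,
    values,
    rates: MechanisticRates,
    pool_factory=None,
) -> pd.DataFrame:
    """Final-cycle yields as one protocol temperature is varied.

    ``variable`` is ``"t_peak"`` or ``"t_base"``.  Returns a table of
    the scanned value, the 6-cycle (or ``protocol.n_cycles``) yield and
    the spontaneous-channel rate at the base temperature.
    """
    if variable not in ("t_peak", "t_base"):
        raise CycleSimError("variable must be 't_peak' or 't_base'")
    if pool_factory is None:
        pool_factory = lambda: SpeciesPool.standard()  # noqa: E731
    rows = []
    for v in values:
        proto = replace(protocol, **{variable: float(v)})
        traj, _ = run_protocol(proto, pool_factory(), rates)
        rows.append(
            {
                variable: float(v),
                "yield_nM": float(traj.c[-1]),
                "spont_rate_nM_per_cycle": rates.r_spont(proto.t_base),
            }
        )
    return pd.DataFrame(rows)
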