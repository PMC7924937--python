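"""Sequence-space analysis of information-domain point mutants.

Enumerates every complement strand at a given Hamming distance from the
perfect complement of a 15-nt information domain, computes the duplex
free energy of each mutant against the original domain, and evaluates
the replication-tolerance criterion: a mutant duplex is rejected by the
replicator when its ΔG is still strong enough (more negative than the
threshold) to survive the thermal oscillation, i.e. the mechanism
tolerates (fails to discriminate) exactly those mutants whose binding is
weaker than or equal to the threshold.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from . import thermo
from .thermo import IonicConditions, REPLICATION_BUFFER, complement

BASES = "ACGT"

#: replication-buffer free-energy threshold (kcal/mol) equivalent to a
#: 10 Celsius drop in information-domain melting temperature
DEFAULT_THRESHOLD = -12.5


class SeqSpaceError(ValueError):
    pass


@dataclass(frozen=True)
class MutantDuplex:
    """One mutated complement paired against the original domain."""

    original: str           # the 15-nt template domain, 5'->3'
    mutant_complement: str  # complement strand, 3'->5' aligned under original
    k_mutations: int
    positions: tuple[int, ...]
    terminal_flag: bool     # any mutation at index 0 or len-1


@dataclass
class EnergyDistribution:
    """ΔG values of all mutants of one (sequence, k) neighborhood."""

    original: str
    k: int
    energies: np.ndarray            # kcal/mol, enumeration order
    positions: list[tuple[int, ...]]
    terminal_flags: np.ndarray      # bool, enumeration order
    conditions: IonicConditions = REPLICATION_BUFFER
    temperature_c: float = 37.0

    @property
    def cumulative(self) -> np.ndarray:
        """Sorted energies (the cumulative distribution's support)."""
        return np.sort(self.energies)

    def __len__(self) -> int:
        return len(self.energies)


def enumerate_mutants(seq: str, k: int) -> Iterator[MutantDuplex]:
    """Yield every complement at Hamming distance exactly ``k``.

    Deterministic order: mutated position tuples lexicographic, then
    substituted bases alphabetical.  ``k = 0`` yields the perfect
    complement alone.
    """
    seq = seq.upper()
    n = len(seq)
    if not 0 <= k <= n:
        raise SeqSpaceError(f"k={k} outside [0, {n}]")
    perfect = complement(seq)
    for positions in itertools.combinations(range(n), k):
        choices = [[b for b in BASES if b != perfect[p]] for p in positions]
        for combo in itertools.product(*choices):
            mutant = list(perfect)
            for p, b in zip(positions, combo):
                mutant[p] = b
            yield MutantDuplex(
                original=seq,
                mutant_complement="".join(mutant),
                k_mutations=k,
                positions=positions,
                terminal_flag=any(p in (0, n - 1) for p in positions),
            )


def _cache_key(seq: str, k: int, cond: IonicConditions, temperature_c: float) -> str:
    tag = f"{seq}|{k}|{cond.monovalent}|{cond.divalent_mg}|{cond.total_strand_conc}|{cond.salt_method}|{temperature_c}"
    return hashlib.sha256(tag.encode()).hexdigest()[:16]


def energy_distribution(
    seq: str,
    k: int,
    conditions: IonicConditions = REPLICATION_BUFFER,
    temperature_c: float = 37.0,
    cache_dir: str | Path | None = None,
) -> EnergyDistribution:
    """ΔG (at ``temperature_c``) of every mutant duplex at distance ``k``.

    With ``cache_dir`` set, the distribution is written to / reloaded
    from a TSV keyed by (sequence, k, conditions); the round trip is
    lossless (full float precision).
    """
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / (
            f"mutants_{seq}_k{k}_{_cache_key(seq, k, conditions, temperature_c)}.tsv"
        )
        if cache_path.exists():
            return _read_distribution(cache_path, seq, k, conditions, temperature_c)

    energies = []
    positions = []
    terminal = []
    for m in enumerate_mutants(seq, k):
        d = thermo.duplex_thermo(m.original, m.mutant_complement, conditions)
        energies.append(d.dG(temperature_c))
        positions.append(m.positions)
        terminal.append(m.terminal_flag)
    dist = EnergyDistribution(
        original=seq,
        k=k,
        energies=np.asarray(energies),
        positions=positions,
        terminal_flags=np.asarray(terminal, dtype=bool),
        conditions=conditions,
        temperature_c=temperature_c,
    )
    if cache_path is not None:
        _write_distribution(dist, cache_path)
    return dist


def _write_distribution(dist: EnergyDistribution, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "positions": [",".join(map(str, p)) for p in dist.positions],
            "terminal": dist.terminal_flags.astype(int),
            "dG_kcal_mol": [repr(float(e)) for e in dist.energies],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _read_distribution(path, seq, k, conditions, temperature_c) -> EnergyDistribution:
    df = pd.read_csv(
        path, sep="\t", dtype={"positions": str}, keep_default_na=False,
        float_precision="round_trip",
    )
    positions = [
        tuple(int(x) for x in p.split(",")) if p else ()
        for p in df["positions"]
    ]
    return EnergyDistribution(
        original=seq,
        k=k,
        energies=df["dG_kcal_mol"].astype(float).to_numpy(),
        positions=positions,
        terminal_flags=df["terminal"].to_numpy(dtype=bool),
        conditions=conditions,
        temperature_c=temperature_c,
    )


def fraction_meeting_criterion(
    dist: EnergyDistribution, threshold: float = DEFAULT_THRESHOLD
) -> float:
    """Fraction of mutant duplexes with ΔG >= threshold (binding weaker
    than or equal to the tolerance criterion)."""
    if len(dist) == 0:
        raise SeqSpaceError("empty distribution")
    return float(np.mean(dist.energies >= threshold))


def tolerance_fraction(
    seq: str,
    k: int,
    threshold: float = DEFAULT_THRESHOLD,
    conditions: IonicConditions = REPLICATION_BUFFER,
    exactly: bool = True,
    **kwargs,
) -> float:
    """Criterion fraction for mutants at distance exactly ``k`` or, with
    ``exactly=False``, pooled over distances 1..k."""
    ks = [k] if exactly else list(range(1, k + 1))
    energies = np.concatenate(
        [energy_distribution(seq, kk, conditions, **kwargs).energies for kk in ks]
    )
    return float(np.mean(energies >= threshold))


def split_by_position_class(
    dist: EnergyDistribution,
) -> tuple[EnergyDistribution, EnergyDistribution]:
    """Partition into (internal-mutations-only, terminal-containing)."""
    internal_mask = ~dist.terminal_flags

    def take(mask):
        idx = np.nonzero(mask)[0]
        return EnergyDistribution(
            original=dist.original,
            k=dist.k,
            energies=dist.energies[idx],
            positions=[dist.positions[i] for i in idx],
            terminal_flags=dist.terminal_flags[idx],
            conditions=dist.conditions,
            temperature_c=dist.temperature_c,
        )

    return take(internal_mask), take(~internal_mask)


def summary(dist: EnergyDistribution) -> dict:
    e = dist.energies
    return {
        "k": dist.k,
        "n": int(e.size),
        "mean_dG": float(e.mean()),
        "min_dG": float(e.min()),
        "max_dG": float(e.max()),
    }
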