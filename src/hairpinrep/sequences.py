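"""The double-hairpin strand library: parsing, annotation, design checks.

The replicator is built from 16 DNA strands of 82-84 nt.  Each strand
folds into two stem-loops (the "backbone" hairpins) flanking a central
unpaired 15-nt information domain that encodes one binary symbol.  A
strand is identified by its bit (0/1), its position in the periodic
meta-sequence (A-D), and its sense; antisense strands carry a trailing
``*`` in their identifier (``0A*``).

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import thermo
from .thermo import IonicConditions, REPLICATION_BUFFER, reverse_complement, complement

POSITIONS = "ABCD"
BITS = "01"

#: successor position of each position, per strand pool.  Within the
#: sense pool the replicate runs A->B->C->D->A; the printed antisense
#: sequences pair in the opposite direction (3' hairpin of X* matches
#: the 5' hairpin of the predecessor-position strand).
SUCCESSOR = {
    "sense": {"A": "B", "B": "C", "C": "D", "D": "A"},
    "antisense": {"A": "D", "B": "A", "C": "B", "D": "C"},
}

_ID_RE = re.compile(r"^([01])([A-D])(\*)?(?:[-_](\w+))?$")


class LibraryError(ValueError):
    """Malformed or incomplete strand library."""


class DomainError(LibraryError):
    """Information-domain discovery failed."""


class AnnotationError(LibraryError):
    """Strand could not be annotated unambiguously."""


@dataclass(frozen=True)
class Strand:
    """One double-hairpin strand of the library."""

    id: str
    sequence: str
    bit: str        # '0' or '1'
    position: str   # 'A'..'D'
    sense: str      # 'sense' or 'antisense'
    dye: str | None = None

    def __post_init__(self):
        if not 82 <= len(self.sequence) <= 84:
            raise LibraryError(
                f"strand {self.id}: length {len(self.sequence)} outside 82-84 nt"
            )
        for i, b in enumerate(self.sequence):
            if b not in "ACGT":
                raise LibraryError(
                    f"strand {self.id}: non-ACGT character {b!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """Spans (0-based, half-open) of the three domains of one strand."""

    hairpin5: tuple[int, int]
    info: tuple[int, int]
    hairpin3: tuple[int, int]

    def __post_init__(self):
        h5, info, h3 = self.hairpin5, self.info, self.hairpin3
        if not (h5[1] == info[0] and info[1] == h3[0] and h5[0] == 0):
            raise AnnotationError("spans must tile a contiguous region")
        if info[1] - info[0] != 15:
            raise AnnotationError("info span must be exactly 15 nt")
        for name, (a, b) in (("hairpin5", h5), ("hairpin3", h3)):
            if not 30 <= b - a <= 37:
                raise AnnotationError(f"{name} span length {b - a} outside [30, 37]")


@dataclass
class StrandLibrary:
    """The 16 annotated strands, keyed by id, plus the two info domains."""

    strands: dict[str, Strand]
    info_domains: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, strand_id: str) -> Strand:
        return self.strands[strand_id]

    def __len__(self) -> int:
        return len(self.strands)

    def subset(self, ids) -> "StrandLibrary":
        return StrandLibrary(
            {i: self.strands[i] for i in ids}, dict(self.info_domains)
        )

    def select(self, bit=None, sense=None) -> list[Strand]:
        out = []
        for s in self.strands.values():
            if bit is not None and s.bit != str(bit):
                continue
            if sense is not None and s.sense != sense:
                continue
            out.append(s)
        return sorted(out, key=lambda s: (s.bit, s.position))


@dataclass(frozen=True)
class MetaSequence:
    """A 4-symbol binary string indexed by positions A-D; periodic."""

    code: str
    periodic: bool = True

    def __post_init__(self):
        if len(self.code) != 4 or set(self.code) - set("01"):
            raise LibraryError(f"meta-sequence must be 4 symbols over 0/1: {self.code!r}")
        if not self.periodic:
            raise LibraryError("this system is periodic; periodic must be True")

    def bit_at(self, position: str) -> str:
        return self.code[POSITIONS.index(position)]


@dataclass(frozen=True)
class StrandSet:
    """A (possibly defective) selection of strand ids for one reaction."""

    included: frozenset[str]
    defect_pattern: str = "++++"


def strand_id(bit, position: str, antisense: bool = False) -> str:
    return f"{bit}{position}{'*' if antisense else ''}"


def parse_strand_id(header: str):
    """Parse a FASTA header into (bit, position, sense, dye); None if not a strand id."""
    m = _ID_RE.match(header.strip())
    if not m:
        return None
    bit, pos, star, dye = m.groups()
    return bit, pos, "antisense" if star else "sense", dye


def load_library(path) -> StrandLibrary:
    """Parse a FASTA strand library and validate completeness.

    Records whose headers do not encode a strand id (e.g. random-pool
    strands) are ignored.  Raises :class:`LibraryError` if any of the 16
    (bit, position, sense) combinations is missing or a strand contains
    a non-ACGT character.  Information domains are not yet identified.
    """
    strands: dict[str, Strand] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        parsed = parse_strand_id(record.id)
        if parsed is None:
            continue
        bit, pos, sense, dye = parsed
        sid = strand_id(bit, pos, sense == "antisense")
        if sid in strands:
            raise LibraryError(f"duplicate strand id {sid!r}")
        strands[sid] = Strand(
            id=sid,
            sequence=str(record.seq).upper(),
            bit=bit,
            position=pos,
            sense=sense,
            dye=dye,
        )
    missing = [
        (bit, pos, sense)
        for bit in BITS
        for pos in POSITIONS
        for sense in ("sense", "antisense")
        if strand_id(bit, pos, sense == "antisense") not in strands
    ]
    if missing:
        raise LibraryError(f"missing strands for (bit, position, sense): {missing}")
    return StrandLibrary(strands)


def packaged_library_path() -> Path:
    """Path to the packaged 16-strand FASTA fixture."""
    return Path(resources.files("hairpinrep") / "data" / "strand_library.fasta")


def load_packaged_library(annotate: bool = True) -> StrandLibrary:
    lib = load_library(packaged_library_path())
    if annotate:
        find_information_domains(lib)
    return lib


def find_information_domains(lib: StrandLibrary) -> dict[str, str]:
    """Identify the 15-nt information domain of each bit.

    For each bit the domain is the unique 15-mer present in all four
    sense strands of that bit whose reverse complement is present in all
    four antisense strands of the bit.  The result is stored on the
    library and returned.
    """
    domains: dict[str, str] = {}
    for bit in BITS:
        sense = lib.select(bit=bit, sense="sense")
        anti = lib.select(bit=bit, sense="antisense")
        if not sense or not anti:
            raise DomainError(
                f"bit {bit}: need both sense and antisense strands to confirm a domain"
            )
        first = sense[0].sequence
        candidates = {first[i : i + 15] for i in range(len(first) - 14)}
        for s in sense[1:]:
            candidates = {c for c in candidates if c in s.sequence}
        for s in anti:
            candidates = {c for c in candidates if reverse_complement(c) in s.sequence}
        if len(candidates) != 1:
            raise DomainError(
                f"bit {bit}: expected exactly one shared 15-mer, found "
                f"{len(candidates)}: {sorted(candidates)}"
            )
        domains[bit] = candidates.pop()
    lib.info_domains = domains
    return domains


def annotate_strand(strand: Strand, lib: StrandLibrary) -> DomainAnnotation:
    """Locate the information domain and the flanking hairpin spans."""
    if not lib.info_domains:
        raise AnnotationError("info domains not yet identified; run find_information_domains")
    domain = lib.info_domains[strand.bit]
    target = domain if strand.sense == "sense" else reverse_complement(domain)
    n = strand.sequence.count(target)
    if n != 1:
        raise AnnotationError(
            f"strand {strand.id}: info domain occurs {n} times (expected once)"
        )
    i = strand.sequence.index(target)
    return DomainAnnotation(
        hairpin5=(0, i), info=(i, i + 15), hairpin3=(i + 15, len(strand.sequence))
    )


@dataclass(frozen=True)
class StretchMatch:
    """Longest complementary stretch between two hairpin regions."""

    length: int
    mismatches: int
    top: str     # subsequence of the 3' hairpin, 5'->3'
    bottom: str  # aligned partner bases, 3'->5' under ``top``


def longest_complementary_stretch(a: str, b: str, max_mismatches: int = 3) -> StretchMatch:
    """Longest antiparallel-complementary window between ``a`` and ``b``.

    Slides ``reverse_complement(b)`` along ``a`` and finds, over all
    offsets, the longest window with at most ``max_mismatches``
    mismatching positions (two-pointer scan per offset).
    """
    A = a
    B = reverse_complement(b)
    best = None  # (length, -mismatches, offset, start)
    for off in range(-len(B) + 1, len(A)):
        lo, hi = max(0, off), min(len(A), len(B) + off)
        if hi - lo < 2:
            continue
        mism = [0 if A[i] == B[i - off] else 1 for i in range(lo, hi)]
        start = 0
        total = 0
        for end in range(len(mism)):
            total += mism[end]
            while total > max_mismatches:
                total -= mism[start]
                start += 1
            cand = (end - start + 1, -total, off, lo + start)
            if best is None or cand[:2] > best[:2]:
                best = cand
    if best is None:
        return StretchMatch(0, 0, "", "")
    length, neg_mm, off, start = best
    top = A[start : start + length]
    bottom = complement(B[start - off : start - off + length])
    return StretchMatch(length, -neg_mm, top, bottom)


@dataclass
class DesignReport:
    """Backbone-complementarity and melting-order report for a library."""

    pairs: pd.DataFrame          # one row per consecutive backbone pair
    info_tm: dict[str, float]    # bit -> Tm of the info duplex (Celsius)
    min_backbone_tm: float
    max_info_tm: float

    @property
    def ordering_ok(self) -> bool:
        """Tm(info duplexes) below Tm(every backbone duplex)."""
        return self.max_info_tm < self.min_backbone_tm

    def to_json(self) -> str:
        return json.dumps(
            {
                "pairs": self.pairs.to_dict(orient="records"),
                "info_tm": self.info_tm,
                "min_backbone_tm": self.min_backbone_tm,
                "max_info_tm": self.max_info_tm,
                "ordering_ok": self.ordering_ok,
            },
            indent=2,
        )


def validate_design(
    lib: StrandLibrary,
    conditions: IonicConditions = REPLICATION_BUFFER,
    max_mismatches: int = 3,
    min_stretch: int = 20,
) -> DesignReport:
    """Check backbone complementarity and the melting-temperature order.

    For every consecutive pair within each pool (sense A->B->C->D->A and
    the reversed antisense succession) the longest complementary stretch
    between the 3' hairpin of the strand and the 5' hairpin of its
    successor is located (tolerating ``max_mismatches`` designed
    mismatches) and its duplex Tm computed.  Pairs whose stretch is
    shorter than ``min_stretch`` are flagged.  The report also carries
    the info-duplex Tm of each bit and the ordering check
    Tm(info) < Tm(backbone).
    """
    if not lib.info_domains:
        find_information_domains(lib)
    rows = []
    for sense in ("sense", "antisense"):
        anti = sense == "antisense"
        succ = SUCCESSOR[sense]
        for bit in BITS:
            for pos in POSITIONS:
                sid = strand_id(bit, pos, anti)
                nid = strand_id(bit, succ[pos], anti)
                s, nxt = lib[sid], lib[nid]
                ann_s = annotate_strand(s, lib)
                ann_n = annotate_strand(nxt, lib)
                hp3 = s.sequence[slice(*ann_s.hairpin3)]
                hp5 = nxt.sequence[slice(*ann_n.hairpin5)]
                match = longest_complementary_stretch(hp3, hp5, max_mismatches)
                if match.length >= 2:
                    d = thermo.duplex_thermo(match.top, match.bottom, conditions)
                    tm = thermo.melting_temperature(d)
                else:
                    tm = float("nan")
                rows.append(
                    {
                        "strand": sid,
                        "successor": nid,
                        "stretch_nt": match.length,
                        "mismatches": match.mismatches,
                        "backbone_tm_C": tm,
                        "ok": match.length >= min_stretch,
                    }
                )
    pairs = pd.DataFrame(rows)
    info_tm = {
        bit: thermo.melting_temperature(
            thermo.duplex_thermo(lib.info_domains[bit], conditions=conditions)
        )
        for bit in BITS
    }
    return DesignReport(
        pairs=pairs,
        info_tm=info_tm,
        min_backbone_tm=float(pairs.loc[pairs.ok, "backbone_tm_C"].min()),
        max_info_tm=max(info_tm.values()),
    )


def strands_for_template(
    code: MetaSequence | str, defects: str = "++++"
) -> StrandSet:
    """The 16-strand set minus the sense strands knocked out by ``defects``.

    ``defects`` is a 4-character pattern over ``+``/``-`` indexed by
    positions A-D; a ``-`` removes the sense strand that would faithfully
    copy the template at that position.  ``"++++"`` returns all 16.
    """
    if isinstance(code, str):
        code = MetaSequence(code)
    defects = defects.replace("−", "-")  # accept the typographic minus
    if len(defects) != 4 or set(defects) - set("+-"):
        raise LibraryError(f"defect pattern must be 4 symbols over +/-: {defects!r}")
    ids = {
        strand_id(bit, pos, anti)
        for bit in BITS
        for pos in POSITIONS
        for anti in (False, True)
    }
    for pos, flag in zip(POSITIONS, defects):
        if flag == "-":
            ids.discard(strand_id(code.bit_at(pos), pos, antisense=False))
    return StrandSet(included=frozenset(ids), defect_pattern=defects)
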