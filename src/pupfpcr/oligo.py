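"""IUPAC degeneracy algebra and basic oligonucleotide QC.

Degenerate primers represent a set of concrete oligos through IUPAC
ambiguity codes (Y = C/T, K = G/T, ...).  This module provides the set
algebra over those codes — consensus construction, expansion, reverse
complement, base matching — plus advisory QC (length, GC%, Wallace-rule
Tm) for primers and hydrolysis probes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "IUPAC_TO_BASES",
    "BASES_TO_IUPAC",
    "iupac_consensus",
    "count_degenerate_positions",
    "expand",
    "revcomp",
    "matches",
    "oligo_qc",
    "QCBounds",
    "QCReport",
]

IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

_COMPLEMENT_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}

CONCRETE_BASES = frozenset("ACGT")


def _validate(s: str) -> str:
    if not s:
        raise ValueError("empty IUPAC string")
    s = s.upper()
    bad = set(s) - set(IUPAC_TO_BASES)
    if bad:
        raise ValueError(f"invalid IUPAC symbol(s) {sorted(bad)} in {s!r}")
    return s


def iupac_consensus(rows: list[str]) -> str:
    """Minimal IUPAC cover of a gap-free block of equal-length rows.

    Each output symbol is the smallest ambiguity code whose base set
    equals the set of bases observed in that column.
    """
    if not rows:
        raise ValueError("need at least one row")
    rows = [_validate(r) for r in rows]
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError(f"ragged rows: lengths {sorted({len(r) for r in rows})}")
    out = []
    for col in zip(*rows):
        bases: set[str] = set()
        for sym in col:
            bases |= IUPAC_TO_BASES[sym]
        out.append(BASES_TO_IUPAC[frozenset(bases)])
    return "".join(out)


def count_degenerate_positions(s: str) -> int:
    """Number of symbols outside {A, C, G, T}."""
    s = _validate(s)
    return sum(1 for sym in s if sym not in CONCRETE_BASES)


def expand(s: str, cap: int = 1024) -> set[str]:
    """All concrete sequences covered by a degenerate oligo.

    Cardinality is the product of per-symbol set sizes; refuses to
    expand past `cap` members to bound memory.
    """
    s = _validate(s)
    card = 1
    for sym in s:
        card *= len(IUPAC_TO_BASES[sym])
    if card > cap:
        raise ValueError(f"expansion of {s!r} has {card} members, exceeds cap {cap}")
    pools = [sorted(IUPAC_TO_BASES[sym]) for sym in s]
    return {"".join(p) for p in itertools.product(*pools)}


def revcomp(s: str) -> str:
    """Reverse complement; the complement of a code is the code of the
    complemented base set (Y<->R, K<->M, S/W/N self-complementary)."""
    s = _validate(s)
    out = []
    for sym in reversed(s):
        comp = frozenset(_COMPLEMENT_BASE[b] for b in IUPAC_TO_BASES[sym])
        out.append(BASES_TO_IUPAC[comp])
    return "".join(out)


def matches(base: str, code: str) -> bool:
    """True iff concrete `base` is a member of the base set of `code`."""
    if base not in CONCRETE_BASES:
        raise ValueError(f"{base!r} is not a concrete nucleotide")
    if code not in IUPAC_TO_BASES:
        raise ValueError(f"{code!r} is not an IUPAC symbol")
    return base in IUPAC_TO_BASES[code]


def codes_compatible(a: str, b: str) -> bool:
    """True iff the base sets of two IUPAC codes intersect (used for
    degenerate-vs-degenerate matching in binding-site scans)."""
    return bool(IUPAC_TO_BASES[a] & IUPAC_TO_BASES[b])


# ---------------------------------------------------------------------------
# QC


@dataclass(frozen=True)
class QCBounds:
    """Advisory bounds for oligo QC (lengths in nt, GC in percent)."""

    primer_len: tuple[int, int] = (17, 25)
    probe_len: tuple[int, int] = (13, 30)
    gc_pct: tuple[float, float] = (30.0, 80.0)


@dataclass
class QCReport:
    sequence: str
    role: str
    length: int
    gc_pct_range: tuple[float, float]
    tm_range: tuple[float, float]
    five_prime_g: bool
    passed: bool
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "role": self.role,
            "length": self.length,
            "gc_pct_min": self.gc_pct_range[0],
            "gc_pct_max": self.gc_pct_range[1],
            "tm_min": self.tm_range[0],
            "tm_max": self.tm_range[1],
            "five_prime_g": self.five_prime_g,
            "passed": self.passed,
            "warnings": ";".join(self.warnings),
        }


def oligo_qc(s: str, role: str, bounds: QCBounds | None = None) -> QCReport:
    """Length / GC% / Wallace-Tm report for a primer or probe.

    GC% and Tm are reported as ranges over the expansions of a
    degenerate oligo (computed symbol-wise, without materialising the
    expansion).  Wallace rule: Tm = 2(A+T) + 4(G+C).  Probes must be
    degeneracy-free; a probe starting with G is flagged (quenching of
    the 5' fluorophore) but not failed.
    """
    if role not in ("primer", "probe"):
        raise ValueError(f"role must be 'primer' or 'probe', got {role!r}")
    s = _validate(s)
    bounds = bounds or QCBounds()
    n_deg = count_degenerate_positions(s)
    if role == "probe" and n_deg:
        raise ValueError(f"probe {s!r} contains {n_deg} degenerate symbol(s)")

    # per-symbol min/max count of G/C among the symbol's base set
    gc_min = gc_max = 0
    for sym in s:
        fracs = [1 if b in "GC" else 0 for b in IUPAC_TO_BASES[sym]]
        gc_min += min(fracs)
        gc_max += max(fracs)
    n = len(s)
    gc_range = (100.0 * gc_min / n, 100.0 * gc_max / n)
    # Wallace: AT contributes 2, GC contributes 4
    tm_range = (2.0 * (n - gc_max) + 4.0 * gc_max, 2.0 * (n - gc_min) + 4.0 * gc_min)
    tm_range = (min(tm_range), max(tm_range))

    five_prime_g = role == "probe" and s[0] == "G"
    warnings = []
    if five_prime_g:
        warnings.append("probe starts with G adjacent to the 5' fluorophore")

    lo, hi = bounds.primer_len if role == "primer" else bounds.probe_len
    ok_len = lo <= n <= hi
    ok_gc = bounds.gc_pct[0] <= gc_range[0] and gc_range[1] <= bounds.gc_pct[1]
    if not ok_len:
        warnings.append(f"length {n} outside [{lo}, {hi}]")
    if not ok_gc:
        warnings.append(f"GC% range {gc_range} outside {bounds.gc_pct}")
    return QCReport(
        sequence=s,
        role=role,
        length=n,
        gc_pct_range=gc_range,
        tm_range=tm_range,
        five_prime_g=five_prime_g,
        passed=ok_len and ok_gc,
        warnings=warnings,
    )
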