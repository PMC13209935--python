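"""In-silico PCR: primer binding, amplicon prediction, probe calls.

Predicts whether a degenerate universal primer pair amplifies a given
template and which fluorescence channels light up, reproducing the
specificity logic of a multiplex hydrolysis-probe assay on arbitrary
sequences.  Matching is IUPAC-aware (degenerate symbol vs degenerate
symbol matches iff the base sets intersect); primer binding allows a
bounded number of mismatches but requires an exact 3' anchor, since 3'
mismatches dominate PCR failure.  Detection is boolean — no
amplification kinetics or Ct values are modelled here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AssayDefinition, SequenceRecord
from .oligo import IUPAC_TO_BASES, revcomp

__all__ = [
    "BindingSite",
    "Amplicon",
    "ChannelCall",
    "find_binding_sites",
    "predict_amplicons",
    "call_probe",
    "simulate_multiplex",
]


@dataclass(frozen=True)
class BindingSite:
    """One primer annealing position.  `position` is the plus-strand
    coordinate of the primer's 5' end: window start for a + site, window
    end - 1 for a - site."""

    template_id: str
    position: int
    strand: str  # "+" | "-"
    mismatches: int
    window: tuple[int, int]  # half-open plus-strand footprint

    def __post_init__(self):
        if self.strand not in "+-" or len(self.strand) != 1:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")


@dataclass(frozen=True)
class Amplicon:
    """A predicted product on the plus strand, running from the forward
    primer's 5' end to the reverse primer's 5' end inclusive."""

    template_id: str
    span: tuple[int, int]
    sequence: str

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    def __post_init__(self):
        if len(self.sequence) != self.length:
            raise ValueError("sequence length must equal span width")


@dataclass(frozen=True)
class ChannelCall:
    template_id: str
    channel: str  # reporter dye
    species: str  # probe species label
    detected: bool
    probe_mismatches: int | None


def _mismatches_at(primer: str, window: str, three_prime_from_end: int,
                   max_mm: int) -> int | None:
    """IUPAC-aware mismatch count of `primer` against an equal-length
    template window, or None if the 3'-anchor or budget is violated.
    The final `three_prime_from_end` primer symbols must match."""
    n = len(primer)
    anchor_start = n - three_prime_from_end
    mm = 0
    for i in range(n - 1, -1, -1):  # 3' end first: cheap anchor rejection
        if IUPAC_TO_BASES[primer[i]] & IUPAC_TO_BASES[window[i]]:
            continue
        if i >= anchor_start:
            return None
        mm += 1
        if mm > max_mm:
            return None
    return mm


def find_binding_sites(
    primer: str,
    template: SequenceRecord,
    max_mm: int = 2,
    three_prime_exact: int = 2,
) -> list[BindingSite]:
    """Scan both strands for primer annealing sites.

    A position qualifies iff total IUPAC-aware mismatches <= max_mm and
    the 3'-terminal `three_prime_exact` symbols match exactly.  On the
    minus strand the reverse complement of the primer is compared to the
    plus-strand window; the 3' anchor then sits at the window *start*.
    """
    if max_mm < 0 or three_prime_exact < 0:
        raise ValueError("budgets must be >= 0")
    primer = primer.upper()
    seq = template.residues
    n, m = len(primer), len(seq)
    if n >= m:
        raise ValueError("primer must be shorter than the template")
    sites: list[BindingSite] = []
    rc = revcomp(primer)
    for start in range(m - n + 1):
        window = seq[start : start + n]
        mm = _mismatches_at(primer, window, three_prime_exact, max_mm)
        if mm is not None:
            sites.append(BindingSite(template.id, start, "+", mm, (start, start + n)))
        # minus strand: primer 3' end maps to the window start, so anchor
        # the *first* symbols of the reverse complement
        mm = _mismatches_at(rc[::-1], window[::-1], three_prime_exact, max_mm)
        if mm is not None:
            sites.append(BindingSite(template.id, start + n - 1, "-", mm, (start, start + n)))
    return sites


def predict_amplicons(
    fwd: str,
    rev: str,
    template: SequenceRecord,
    max_len: int = 1000,
    max_mm: int = 2,
    three_prime_exact: int = 2,
) -> list[Amplicon]:
    """All products of a convergent primer pair on one template.

    Every + site of one primer is paired with every downstream - site of
    the other (both orientations), with product length (5' end to 5' end
    inclusive) <= max_len.  Swapping fwd and rev yields the same set.
    """
    seq = template.residues
    spans: set[tuple[int, int]] = set()
    for left, right in ((fwd, rev), (rev, fwd)):
        plus = [s for s in find_binding_sites(left, template, max_mm, three_prime_exact)
                if s.strand == "+"]
        minus = [s for s in find_binding_sites(right, template, max_mm, three_prime_exact)
                 if s.strand == "-"]
        for p in plus:
            for q in minus:
                length = q.position + 1 - p.position
                if length < max(len(left), len(right)) or length > max_len:
                    continue
                # primers must not extend past each other
                if q.window[0] < p.window[0] or q.window[1] < p.window[1]:
                    continue
                spans.add((p.position, q.position + 1))
    return [Amplicon(template.id, span, seq[span[0]:span[1]])
            for span in sorted(spans)]


def call_probe(probe: str, amplicon: Amplicon, max_mm: int = 0) -> tuple[bool, int | None]:
    """Does the probe hybridise anywhere inside the amplicon (either
    strand) within the mismatch budget?  Returns (detected, best
    mismatch count or None)."""
    probe = probe.upper()
    n = len(probe)
    if n > amplicon.length:
        raise ValueError("probe longer than the amplicon")
    best: int | None = None
    for target in (amplicon.sequence, revcomp(amplicon.sequence)):
        for start in range(len(target) - n + 1):
            mm = 0
            for a, b in zip(probe, target[start : start + n]):
                if not IUPAC_TO_BASES[a] & IUPAC_TO_BASES[b]:
                    mm += 1
                    if best is not None and mm > best:
                        break
            else:
                if best is None or mm < best:
                    best = mm
    if best is None or best > max_mm:
        return False, None
    return True, best


def simulate_multiplex(
    assay: AssayDefinition,
    templates: list[SequenceRecord],
    max_len: int = 1000,
    max_mm: int = 2,
    three_prime_exact: int = 2,
    probe_max_mm: int = 0,
) -> list[ChannelCall]:
    """Per template x channel: detected iff the universal primer pair
    yields an amplicon on which that channel's probe hybridises.
    Undetected templates appear as all-negative rows; a template may
    light several channels."""
    calls: list[ChannelCall] = []
    for template in templates:
        amplicons = predict_amplicons(
            assay.forward, assay.reverse, template,
            max_len=max_len, max_mm=max_mm, three_prime_exact=three_prime_exact,
        )
        for species, probe in assay.probes.items():
            detected, mm = False, None
            for amp in amplicons:
                if len(probe.sequence) > amp.length:
                    continue
                hit, n_mm = call_probe(probe.sequence, amp, max_mm=probe_max_mm)
                if hit and (mm is None or n_mm < mm):
                    detected, mm = True, n_mm
            calls.append(ChannelCall(template.id, probe.reporter, species, detected, mm))
    return calls


def calls_to_tsv(calls: list[ChannelCall]) -> str:
    out = ["template\tchannel\tspecies\tdetected\tprobe_mismatches"]
    for c in calls:
        mm = "." if c.probe_mismatches is None else str(c.probe_mismatches)
        out.append(f"{c.template_id}\t{c.channel}\t{c.species}\t{int(c.detected)}\t{mm}")
    return "\n".join(out) + "\n"
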