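"""Assay design from a multiple sequence alignment.

Given an MSA of target-species orthologs plus non-target outgroups,
locate (i) conserved windows shared by all targets but mismatching every
non-target — candidates for a degenerate universal primer pair — and
(ii) internal windows where one target species carries at least two
private substitutions — candidates for species-specific hydrolysis
probes.  Feasible primer/probe combinations are assembled into ranked
assay designs.

Column classification is the primitive everything builds on:

* ``invariant``        — all targets share one base, ungapped
* ``species_specific`` — exactly one target deviates from the rest,
                         which are mutually identical and ungapped
* ``degenerate_ok``    — ungapped targets with exactly two distinct
                         bases (a two-fold IUPAC site, e.g. Y or K),
                         not attributable to a single species
* ``gapped``           — any target carries a gap
* ``other``            — anything else (>=3 distinct bases)

Non-target rows are recorded per column but never influence the class;
they enter only through the exclusivity (mismatch) requirement on
primer windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import MsaRecord
from .oligo import IUPAC_TO_BASES, iupac_consensus, count_degenerate_positions, revcomp

__all__ = [
    "ColumnProfile",
    "PrimerWindow",
    "ProbeWindow",
    "AssayDesign",
    "profile_columns",
    "find_conserved_windows",
    "find_probe_windows",
    "assemble_assays",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnProfile:
    index: int
    target_bases: dict[str, str]
    nontarget_bases: dict[str, str]
    klass: str  # invariant | degenerate_ok | species_specific | gapped | other
    specific_species: str | None = None

    def __post_init__(self):
        if (self.klass == "species_specific") != (self.specific_species is not None):
            raise ValueError("specific_species set iff klass is species_specific")


@dataclass(frozen=True)
class PrimerWindow:
    """A candidate primer footprint on the MSA: all-target IUPAC
    consensus with bounded degeneracy, mismatching every non-target."""

    span: tuple[int, int]  # half-open MSA columns
    consensus: str
    degeneracy_count: int
    min_nontarget_mismatches: int

    def __post_init__(self):
        if len(self.consensus) != self.span[1] - self.span[0]:
            raise ValueError("consensus length must equal span width")


@dataclass(frozen=True)
class ProbeWindow:
    """A candidate probe footprint: that species' own ungapped bases
    over a window holding >= 2 of its private substitutions."""

    species: str
    span: tuple[int, int]
    sequence: str
    n_specific_sites: int

    def __post_init__(self):
        if self.n_specific_sites < 2:
            raise ValueError("a probe window needs >= 2 species-specific sites")


@dataclass(frozen=True)
class AssayDesign:
    """One universal primer pair plus one probe per species.  The
    reverse primer is reported as the reverse complement of its window
    consensus (the oligo as synthesised)."""

    forward: PrimerWindow
    reverse: PrimerWindow
    probes: dict[str, ProbeWindow]
    amplicon_len: tuple[int, int]  # (min, max) ungapped bp over target species

    @property
    def forward_oligo(self) -> str:
        return self.forward.consensus

    @property
    def reverse_oligo(self) -> str:
        return revcomp(self.reverse.consensus)

    def __post_init__(self):
        f_end = self.forward.span[1]
        r_start = self.reverse.span[0]
        for sp, pw in self.probes.items():
            if not (f_end <= pw.span[0] and pw.span[1] <= r_start):
                raise ValueError(f"probe for {sp!r} not strictly between the primers")


# ---------------------------------------------------------------------------


def profile_columns(msa: list[MsaRecord], target_labels: set[str]) -> list[ColumnProfile]:
    """Classify every MSA column by its pattern across the target rows."""
    labels = {r.species_label for r in msa}
    unknown = set(target_labels) - labels
    if unknown:
        raise ValueError(f"target label(s) {sorted(unknown)} not present in the MSA")
    if len(target_labels) < 2:
        raise ValueError("need at least two target labels")
    targets = [r for r in msa if r.species_label in target_labels]
    nontargets = [r for r in msa if r.species_label not in target_labels]
    n_cols = len(msa[0].aligned_residues)

    profiles = []
    for i in range(n_cols):
        tb = {r.species_label: r.aligned_residues[i] for r in targets}
        nb = {r.species_label: r.aligned_residues[i] for r in nontargets}
        profiles.append(
            ColumnProfile(index=i, target_bases=tb, nontarget_bases=nb,
                          **_classify(tb))
        )
    return profiles


def _classify(target_bases: dict[str, str]) -> dict:
    vals = list(target_bases.values())
    if "-" in vals:
        return {"klass": "gapped"}
    distinct = set(vals)
    if len(distinct) == 1:
        return {"klass": "invariant"}
    # species-specific: one target deviates, the rest identical (>=3 rows
    # needed, otherwise "the deviating species" is ambiguous)
    if len(target_bases) >= 3:
        counts = {b: vals.count(b) for b in distinct}
        singles = [b for b, c in counts.items() if c == 1]
        if len(distinct) == 2 and len(singles) == 1:
            species = next(sp for sp, b in target_bases.items() if b == singles[0])
            return {"klass": "species_specific", "specific_species": species}
    if len(distinct) == 2:
        return {"klass": "degenerate_ok"}
    return {"klass": "other"}


# ---------------------------------------------------------------------------


def _window_consensus(profiles: list[ColumnProfile]) -> str | None:
    """IUPAC consensus of the target rows over a gap-free run of
    columns; None if any column is gapped or unusable (>= 3 bases)."""
    for p in profiles:
        if p.klass in ("gapped", "other"):
            return None
    labels = sorted(profiles[0].target_bases)
    rows = ["".join(p.target_bases[sp] for p in profiles) for sp in labels]
    return iupac_consensus(rows)


def _nontarget_mismatches(profiles: list[ColumnProfile], consensus: str) -> int:
    """Minimum, over non-target rows, of the number of window positions
    where the row's base falls outside the consensus symbol's base set.
    A gap in a non-target row counts as a mismatch at that position."""
    if not profiles[0].nontarget_bases:
        return 0
    worst = None
    for sp in profiles[0].nontarget_bases:
        mm = 0
        for p, sym in zip(profiles, consensus):
            b = p.nontarget_bases[sp]
            if b == "-" or b not in IUPAC_TO_BASES or b not in IUPAC_TO_BASES[sym]:
                mm += 1
        worst = mm if worst is None else min(worst, mm)
    return worst


def find_conserved_windows(
    profiles: list[ColumnProfile],
    min_len: int = 17,
    max_len: int = 25,
    max_degenerate: int = 2,
    min_nontarget_mm: int = 3,
) -> list[PrimerWindow]:
    """All windows of length in [min_len, max_len] whose target consensus
    carries <= max_degenerate degenerate symbols and which every
    non-target row mismatches at >= min_nontarget_mm positions.

    Sorted by (min_nontarget_mismatches desc, degeneracy_count asc,
    start asc, length asc).
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    out = []
    n = len(profiles)
    for start in range(n):
        for length in range(min_len, max_len + 1):
            end = start + length
            if end > n:
                break
            block = profiles[start:end]
            consensus = _window_consensus(block)
            if consensus is None:
                break  # a gapped/unusable column kills all longer windows too
            deg = count_degenerate_positions(consensus)
            if deg > max_degenerate:
                continue
            mm = _nontarget_mismatches(block, consensus)
            if profiles[0].nontarget_bases and mm < min_nontarget_mm:
                continue
            if not profiles[0].nontarget_bases:
                continue  # no non-targets -> exclusivity cannot be established
            out.append(PrimerWindow((start, end), consensus, deg, mm))
    out.sort(key=lambda w: (-w.min_nontarget_mismatches, w.degeneracy_count,
                            w.span[0], w.span[1] - w.span[0]))
    return out


def find_probe_windows(
    profiles: list[ColumnProfile],
    species: str,
    search_span: tuple[int, int],
    min_len: int = 13,
    max_len: int = 30,
    min_specific: int = 2,
) -> list[ProbeWindow]:
    """All windows inside search_span containing >= min_specific columns
    private to `species`, gap-free across targets.  The window sequence
    is the species' own bases.  Sorted by (n_specific_sites desc,
    length asc, start asc)."""
    lo, hi = search_span
    if not (0 <= lo <= hi <= len(profiles)):
        raise ValueError(f"search_span {search_span} outside the MSA")
    if not profiles or species not in profiles[0].target_bases:
        raise ValueError(f"{species!r} is not a target species")
    out = []
    for start in range(lo, hi):
        for length in range(min_len, max_len + 1):
            end = start + length
            if end > hi:
                break
            block = profiles[start:end]
            if any(p.klass == "gapped" for p in block):
                break
            n_spec = sum(
                1 for p in block
                if p.klass == "species_specific" and p.specific_species == species
            )
            if n_spec < min_specific:
                continue
            seq = "".join(p.target_bases[species] for p in block)
            out.append(ProbeWindow(species, (start, end), seq, n_spec))
    out.sort(key=lambda w: (-w.n_specific_sites, w.span[1] - w.span[0], w.span[0]))
    return out


def _ungapped_len(msa_row: str, span: tuple[int, int]) -> int:
    return sum(1 for c in msa_row[span[0]:span[1]] if c != "-")


def _overlap_cols(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def assemble_assays(
    primer_windows: list[PrimerWindow],
    probe_windows: dict[str, list[ProbeWindow]],
    msa: list[MsaRecord],
    target_labels: set[str],
    amplicon_bounds: tuple[int, int] = (60, 250),
    max_primer_windows: int = 100,
) -> list[AssayDesign]:
    """Combine primer windows pairwise (forward upstream of reverse)
    with the best probe window per species strictly between them.

    Amplicon length per target is the ungapped span from the forward
    window start to the reverse window end in that species' row; the
    (min, max) range must fall inside amplicon_bounds.  Designs are
    ranked by (total min_nontarget_mismatches desc, total degeneracy
    asc, forward start asc).  Only the `max_primer_windows` best-ranked
    primer windows are paired (the design ranking depends only on the
    primer windows, so the top design is unaffected as long as both of
    its windows survive the cut).  When no feasible combination exists
    an empty list is returned and a diagnostic names the species
    lacking probes.
    """
    target_rows = {r.species_label: r.aligned_residues
                   for r in msa if r.species_label in target_labels}
    # prefix counts of non-gap characters per target row: O(1) ungapped
    # span lengths inside the pair loop
    prefix = {}
    for sp, row in target_rows.items():
        acc = [0]
        for ch in row:
            acc.append(acc[-1] + (ch != "-"))
        prefix[sp] = acc

    # non-maximum suppression: overlapping shifted variants of one locus
    # would otherwise crowd out the other flank entirely
    windows: list[PrimerWindow] = []
    for w in primer_windows:
        if len(windows) >= max_primer_windows:
            break
        if all(_overlap_cols(w.span, kept.span)
               < 0.5 * min(w.span[1] - w.span[0], kept.span[1] - kept.span[0])
               for kept in windows):
            windows.append(w)
    designs: list[AssayDesign] = []
    missing_probe_species: set[str] = set()
    for fwd in windows:
        for rev in windows:
            if rev.span[0] < fwd.span[1]:
                continue
            lo, hi = fwd.span[0], rev.span[1]
            lens = [acc[hi] - acc[lo] for acc in prefix.values()]
            if min(lens) < amplicon_bounds[0] or max(lens) > amplicon_bounds[1]:
                continue
            chosen: dict[str, ProbeWindow] = {}
            for sp, wlist in probe_windows.items():
                for w in wlist:  # sorted best-first
                    if fwd.span[1] <= w.span[0] and w.span[1] <= rev.span[0]:
                        chosen[sp] = w
                        break
                else:
                    missing_probe_species.add(sp)
                    break
            if len(chosen) == len(probe_windows):
                designs.append(
                    AssayDesign(forward=fwd, reverse=rev, probes=chosen,
                                amplicon_len=(min(lens), max(lens)))
                )
    if not designs and missing_probe_species:
        logger.warning(
            "no feasible assay: no in-amplicon probe window for species %s",
            sorted(missing_probe_species),
        )
    designs.sort(key=lambda d: (
        -(d.forward.min_nontarget_mismatches + d.reverse.min_nontarget_mismatches),
        d.forward.degeneracy_count + d.reverse.degeneracy_count,
        d.forward.span[0],
    ))
    return designs
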