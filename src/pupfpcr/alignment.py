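"""Local pairwise alignment and the candidate-screening predicates.

Marker screening asks, for each candidate nuclear-DNA sequence: does it
align to every *target* genome inside an identity band that leaves room
for species-discriminating variation (default 85-95% over >200 aligned
bp, E < 1e-5), while every *non-target* genome either fails to align or
aligns too weakly?  This module supplies a self-contained local aligner
(affine-gap Smith-Waterman, via Bio.Align.PairwiseAligner), a
Karlin-Altschul E-value, the pass/fail predicates, and a screen driver
producing a per-candidate, per-species report.  Externally computed
tabular hits can be substituted for the built-in aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align

from .io_formats import SequenceRecord

__all__ = [
    "ScoringScheme",
    "PairwiseHit",
    "ScreenCriteria",
    "ScreenRow",
    "ScreenReport",
    "smith_waterman",
    "evalue_of",
    "passes_target_criteria",
    "passes_nontarget_exclusion",
    "screen_candidates",
]


@dataclass(frozen=True)
class ScoringScheme:
    """BLASTN-like affine scoring.  A gap of length L scores
    gap_open + L * gap_extend.  karlin_lambda / karlin_k parameterise the
    E-value; defaults are the standard ungapped nucleotide values —
    E-values here serve as comparative thresholds, not physical claims."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    karlin_lambda: float = 1.37
    karlin_k: float = 0.711

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin parameters must be positive")


@dataclass(frozen=True)
class PairwiseHit:
    """One local-alignment result.  Spans are 0-based half-open on the
    respective sequence; identity is computed over aligned columns
    including gap columns (BLAST pident convention)."""

    query_id: str
    subject_id: str
    score: int
    identity_pct: float
    aln_len: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    evalue: float

    def __post_init__(self):
        if self.aln_len < 1:
            raise ValueError("alignment length must be >= 1")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct must lie in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds for the two-sided screen: targets must fall inside the
    identity band over a long-enough alignment, non-targets must stay
    below the exclusion identity (initial mode) or fail one of the
    target-grade criteria (validation mode)."""

    min_query_len: int = 200
    nontarget_max_identity: float = 80.0
    target_identity_band: tuple[float, float] = (85.0, 95.0)
    max_evalue: float = 1e-5

    def __post_init__(self):
        lo, hi = self.target_identity_band
        if not lo < hi:
            raise ValueError("identity band must satisfy low < high")
        for v in (self.min_query_len, self.nontarget_max_identity, lo, hi, self.max_evalue):
            if not math.isfinite(v):
                raise ValueError("all thresholds must be finite")


def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    # PairwiseAligner charges open_gap_score for the first gapped residue;
    # our convention charges gap_open once plus gap_extend per residue.
    a.open_gap_score = scoring.gap_open + scoring.gap_extend
    a.extend_gap_score = scoring.gap_extend
    return a


def smith_waterman(
    query: SequenceRecord,
    subject: SequenceRecord,
    scoring: ScoringScheme | None = None,
    subject_space: int | None = None,
) -> PairwiseHit | None:
    """Maximal-scoring local alignment under affine gaps.

    Returns None when the best local score is not positive (no local
    alignment).  Identity counts gap columns as non-matches.
    `subject_space` overrides the search-space size n used for the
    E-value (e.g. total length of a multi-record genome set).
    """
    scoring = scoring or ScoringScheme()
    for rec in (query, subject):
        if not rec.residues:
            raise ValueError(f"empty sequence {rec.id!r}")
        extra = set(rec.residues) - set("ACGT")
        if extra:
            raise ValueError(
                f"sequence {rec.id!r} contains non-concrete symbols {sorted(extra)}; "
                "the local aligner requires an A/C/G/T alphabet"
            )
    aligner = _aligner(scoring)
    score = aligner.score(query.residues, subject.residues)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(query.residues, subject.residues)))
    counts = aln.counts()  # gaps, identities, mismatches over the local block
    aln_len = counts.gaps + counts.identities + counts.mismatches
    coords = aln.coordinates
    q_span = (int(coords[0].min()), int(coords[0].max()))
    s_span = (int(coords[1].min()), int(coords[1].max()))
    n = subject_space if subject_space is not None else len(subject.residues)
    return PairwiseHit(
        query_id=query.id,
        subject_id=subject.id,
        score=int(round(score)),
        identity_pct=100.0 * counts.identities / aln_len,
        aln_len=aln_len,
        query_span=q_span,
        subject_span=s_span,
        evalue=evalue_of(int(round(score)), len(query.residues), n, scoring),
    )


def evalue_of(score: int, query_len: int, subject_len: int, scoring: ScoringScheme | None = None) -> float:
    """Karlin-Altschul expected number of chance hits:
    E = K * m * n * exp(-lambda * S)."""
    scoring = scoring or ScoringScheme()
    if query_len < 1 or subject_len < 1:
        raise ValueError("sequence lengths must be >= 1")
    return scoring.karlin_k * query_len * subject_len * math.exp(-scoring.karlin_lambda * score)


def passes_target_criteria(hit: PairwiseHit, c: ScreenCriteria | None = None) -> bool:
    """Target-grade hit: long enough, inside the identity band, significant."""
    c = c or ScreenCriteria()
    lo, hi = c.target_identity_band
    return (
        hit.aln_len > c.min_query_len
        and lo <= hit.identity_pct <= hi
        and hit.evalue < c.max_evalue
    )


def passes_nontarget_exclusion(
    best_hit: PairwiseHit | None,
    c: ScreenCriteria | None = None,
    mode: str = "initial",
) -> bool:
    """Non-target exclusion.  `initial` mode (first-pass screen): best
    hit identity must stay below nontarget_max_identity (no hit at all
    also passes).  `validation` mode: the hit must fail at least one of
    the three target-grade criteria (length, identity-band low end,
    E-value)."""
    c = c or ScreenCriteria()
    if best_hit is None:
        return True
    if mode == "initial":
        return best_hit.identity_pct < c.nontarget_max_identity
    if mode == "validation":
        lo, _hi = c.target_identity_band
        return (
            best_hit.aln_len < c.min_query_len
            or best_hit.identity_pct < lo
            or best_hit.evalue >= c.max_evalue
        )
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Screen driver


@dataclass
class ScreenRow:
    candidate_id: str
    species: str
    klass: str  # "target" | "nontarget"
    hit: PairwiseHit | None
    passed: bool


@dataclass
class ScreenReport:
    rows: list[ScreenRow] = field(default_factory=list)
    verdicts: dict[str, bool] = field(default_factory=dict)

    def to_tsv(self) -> str:
        out = ["candidate\tspecies\tclass\taln_len\tidentity\tevalue\tpass"]
        for r in self.rows:
            if r.hit is None:
                out.append(f"{r.candidate_id}\t{r.species}\t{r.klass}\t.\t.\t.\t{r.passed}")
            else:
                out.append(
                    f"{r.candidate_id}\t{r.species}\t{r.klass}\t{r.hit.aln_len}"
                    f"\t{r.hit.identity_pct:.2f}\t{r.hit.evalue:.3g}\t{r.passed}"
                )
        out.append("")
        out.append("candidate\tverdict")
        for cid, v in sorted(self.verdicts.items()):
            out.append(f"{cid}\t{'pass' if v else 'fail'}")
        return "\n".join(out) + "\n"


def _best_hit(
    candidate: SequenceRecord,
    records: list[SequenceRecord],
    scoring: ScoringScheme,
) -> PairwiseHit | None:
    """Best-scoring local hit of a candidate against a species' record
    set; E-value uses the total residue count of the set as the search
    space."""
    total = sum(len(r.residues) for r in records)
    best: PairwiseHit | None = None
    for rec in records:
        hit = smith_waterman(candidate, rec, scoring, subject_space=total)
        if hit is not None and (best is None or hit.score > best.score):
            best = hit
    return best


def screen_candidates(
    candidates: list[SequenceRecord],
    targets: dict[str, list[SequenceRecord]],
    nontargets: dict[str, list[SequenceRecord]],
    c: ScreenCriteria | None = None,
    scoring: ScoringScheme | None = None,
    nontarget_mode: str = "initial",
) -> ScreenReport:
    """Screen each candidate against every target and non-target species
    set.  Overall verdict per candidate: all target species yield a
    target-grade best hit AND every non-target species is excluded.
    Report rows are sorted by candidate id, then species.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    if not targets:
        raise ValueError("need at least one target species set")
    c = c or ScreenCriteria()
    scoring = scoring or ScoringScheme()
    report = ScreenReport()
    for cand in sorted(candidates, key=lambda r: r.id):
        verdict = True
        for sp in sorted(targets):
            hit = _best_hit(cand, targets[sp], scoring)
            ok = hit is not None and passes_target_criteria(hit, c)
            report.rows.append(ScreenRow(cand.id, sp, "target", hit, ok))
            verdict &= ok
        for sp in sorted(nontargets):
            hit = _best_hit(cand, nontargets[sp], scoring)
            ok = passes_nontarget_exclusion(hit, c, mode=nontarget_mode)
            report.rows.append(ScreenRow(cand.id, sp, "nontarget", hit, ok))
            verdict &= ok
        report.verdicts[cand.id] = verdict
    return report
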