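"""Readers and writers for every external representation the toolkit
touches, plus the bundled multiplex poultry assay definition.

Formats: FASTA (sequences), aligned FASTA and Clustal (multiple sequence
alignments), 12-column BLAST-style tabular hit files, and a YAML assay
config.  Parsing is delegated to Biopython; this layer adds the
validation the toolkit relies on (unique ids, nucleotide alphabet,
equal-length alignment rows) and normalises case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import AlignIO, SeqIO

from .oligo import IUPAC_TO_BASES, count_degenerate_positions

__all__ = [
    "SequenceRecord",
    "MsaRecord",
    "AssayDefinition",
    "ProbeSpec",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_msa",
    "write_msa",
    "read_hits_tabular",
    "read_assay_config",
    "write_assay_config",
    "builtin_pup_assay",
]

_VALID_RESIDUES = frozenset(IUPAC_TO_BASES)  # A,C,G,T + ambiguity codes
_VALID_ALIGNED = _VALID_RESIDUES | {"-"}


class ParseError(ValueError):
    """Raised for malformed input files; carries file/line context."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, the unit of all I/O.

    residues are uppercase over {A,C,G,T,N} plus IUPAC ambiguity codes.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a whitespace-free token, got {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residue(s) {sorted(bad)}; "
                "allowed: A,C,G,T,N and IUPAC ambiguity codes"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MsaRecord:
    """One row of a multiple sequence alignment; gap character is '-'."""

    species_label: str
    aligned_residues: str

    def __post_init__(self):
        object.__setattr__(self, "aligned_residues", self.aligned_residues.upper())
        bad = set(self.aligned_residues) - _VALID_ALIGNED
        if bad:
            raise ValueError(
                f"MSA row {self.species_label!r}: invalid symbol(s) {sorted(bad)}"
            )

    def ungapped(self) -> str:
        return self.aligned_residues.replace("-", "")


@dataclass(frozen=True)
class ProbeSpec:
    """A hydrolysis (TaqMan) probe: concrete sequence plus label chemistry."""

    sequence: str
    reporter: str
    quencher: str

    def __post_init__(self):
        if count_degenerate_positions(self.sequence) != 0:
            raise ValueError(f"probe sequence {self.sequence!r} contains degenerate codes")


@dataclass(frozen=True)
class AssayDefinition:
    """One universal primer pair plus per-species probes.

    The forward/reverse primers may carry IUPAC degeneracy; probes are
    concrete.  `probes` maps species label -> ProbeSpec.
    """

    name: str
    forward: str
    reverse: str
    probes: dict[str, ProbeSpec]

    def __post_init__(self):
        if not self.probes:
            raise ValueError("an assay needs at least one probe")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())
        for s in (self.forward, self.reverse):
            bad = set(s) - _VALID_RESIDUES
            if bad:
                raise ValueError(f"primer {s!r}: invalid symbol(s) {sorted(bad)}")

    @property
    def channels(self) -> dict[str, str]:
        """species label -> reporter dye."""
        return {sp: p.reporter for sp, p in self.probes.items()}


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into SequenceRecords, preserving order.

    Lowercase input is uppercased; duplicate ids, empty sequences and
    invalid residues are rejected with the offending line number.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    # line-aware pass so errors can name a line; Bio.SeqIO validates shape
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}:1: expected FASTA header '>', got {first.strip()!r}")
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq)
        if not residues:
            line = _find_header_line(path, rec.id)
            raise ParseError(f"{path}:{line}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            line = _find_header_line(path, rec.id, skip=seen[rec.id])
            raise ParseError(f"{path}:{line}: duplicate sequence id {rec.id!r}")
        seen[rec.id] = 1
        try:
            records.append(
                SequenceRecord(id=rec.id, residues=residues,
                               description=_strip_id(rec.description, rec.id))
            )
        except ValueError as exc:
            line = _find_header_line(path, rec.id)
            raise ParseError(f"{path}:{line}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def _find_header_line(path: Path, rec_id: str, skip: int = 0) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split(None, 1)[0] == rec_id:
                if skip:
                    skip -= 1
                    continue
                return i
    return 0


def _strip_id(description: str, rec_id: str) -> str:
    if description.startswith(rec_id):
        return description[len(rec_id):].strip()
    return description


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MSA


def read_msa(path: str | Path, dialect: str = "aligned-fasta") -> list[MsaRecord]:
    """Read an MSA in aligned-FASTA or Clustal dialect.

    All rows must have equal aligned length; species labels are taken
    from the record ids.
    """
    fmt = {"aligned-fasta": "fasta", "clustal": "clustal"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown MSA dialect {dialect!r}")
    path = Path(path)
    if fmt == "fasta":
        # AlignIO requires equal lengths up front; go through SeqIO so the
        # raggedness error can name the offending rows.
        rows = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    else:
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise ParseError(f"{path}: not a valid Clustal alignment: {exc}") from exc
        rows = [(r.id, str(r.seq)) for r in aln]
    if not rows:
        raise ParseError(f"{path}: no alignment rows found")
    ref_label, ref = rows[0][0], len(rows[0][1])
    for label, seq in rows[1:]:
        if len(seq) != ref:
            raise ParseError(
                f"{path}: ragged alignment — row {label!r} has length {len(seq)}, "
                f"row {ref_label!r} has length {ref}"
            )
    labels = [label for label, _ in rows]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"{path}: duplicate species label(s) {dup}")
    return [MsaRecord(species_label=label, aligned_residues=seq) for label, seq in rows]


def write_msa(records: list[MsaRecord], path: str | Path) -> None:
    """Write an MSA as aligned FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.species_label}\n{rec.aligned_residues}\n")


# ---------------------------------------------------------------------------
# BLAST-style tabular hits

_TABULAR_COLUMNS = 12


def read_hits_tabular(path: str | Path):
    """Parse a 12-column tab-separated hit file (the standard BLAST
    tabular layout: qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore) into PairwiseHit objects.

    Start/end columns are 1-based closed as emitted by BLAST; they are
    converted to 0-based half-open spans.
    """
    from .alignment import PairwiseHit  # local import to avoid a cycle

    path = Path(path)
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _TABULAR_COLUMNS:
                raise ParseError(
                    f"{path}:{lineno}: expected {_TABULAR_COLUMNS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                (qid, sid, pident, length, _mm, _go,
                 qstart, qend, sstart, send, evalue, bitscore) = fields
                qs, qe = int(qstart), int(qend)
                ss, se = int(sstart), int(send)
                hits.append(
                    PairwiseHit(
                        query_id=qid,
                        subject_id=sid,
                        score=int(round(float(bitscore))),
                        identity_pct=float(pident),
                        aln_len=int(length),
                        query_span=(min(qs, qe) - 1, max(qs, qe)),
                        subject_span=(min(ss, se) - 1, max(ss, se)),
                        evalue=float(evalue),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# Assay configs


def read_assay_config(path: str | Path) -> AssayDefinition:
    """Load an assay definition from YAML with keys
    name/forward/reverse/probes, each probe a mapping with
    sequence/reporter/quencher."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        probes = {
            sp: ProbeSpec(
                sequence=p["sequence"], reporter=p["reporter"], quencher=p["quencher"]
            )
            for sp, p in doc["probes"].items()
        }
        return AssayDefinition(
            name=doc["name"], forward=doc["forward"], reverse=doc["reverse"], probes=probes
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: malformed assay config ({exc})") from exc


def write_assay_config(assay: AssayDefinition, path: str | Path) -> None:
    doc = {
        "name": assay.name,
        "forward": assay.forward,
        "reverse": assay.reverse,
        "probes": {
            sp: {"sequence": p.sequence, "reporter": p.reporter, "quencher": p.quencher}
            for sp, p in assay.probes.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def builtin_pup_assay() -> AssayDefinition:
    """The bundled published poultry multiplex assay: one degenerate
    universal primer pair (two degenerate sites forward, one reverse)
    and four species-specific hydrolysis probes for chicken, quail,
    duck and goose."""
    return AssayDefinition(
        name="pup-fpcr-poultry",
        forward="GYTGGGCCCCCAYTACCT",
        reverse="CTGGATGGKCTCCAGCTC",
        probes={
            "chicken": ProbeSpec("CGTGGGGTACCGCTTT", reporter="TAMRA", quencher="MGB"),
            "quail": ProbeSpec("AGGCCCAGAAGGGAACGACATCCGTCGT", reporter="CY5", quencher="BHQ3"),
            "duck": ProbeSpec("TGACATTCGGCGCAC", reporter="ROX", quencher="MGB"),
            "goose": ProbeSpec("TGTCGTTGCCCTCCGGG", reporter="VIC", quencher="MGB"),
        },
    )
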