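"""Validation data shipped with the bundled poultry assay.

Two small tables accompany the bundled multiplex assay: the genomic
screen summary of the candidate chicken exons it was selected from, and
the composite-mixture quantification results used to validate its
accuracy and precision.  They serve as worked inputs for the screening
predicates and the R.D./R.S.D. metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CandidateExon", "CANDIDATE_EXONS", "MixtureRow", "VALIDATION_MIXTURES",
           "LOD_SERIES_TOP_NG_UL", "LOD_SERIES_LEVELS", "LOD_SERIES_FOLD"]


@dataclass(frozen=True)
class CandidateExon:
    """One candidate nuclear marker from the genomic screen: exon id,
    gene symbol, aligned length (bp) and the range of local-alignment
    identity (%) against the other three target poultry species."""

    exon_id: str
    gene: str
    chromosome: str
    length_bp: int
    identity_range_pct: tuple[float, float]


#: The five exons that passed the genomic screen for the bundled assay.
#: The AMPD2 exon (226 bp) is the marker the assay amplifies.
CANDIDATE_EXONS: tuple[CandidateExon, ...] = (
    CandidateExon("ENSGALE00010061152", "FZD8", "2", 384, (90.63, 94.01)),
    CandidateExon("ENSGALE00010059626", "MOGS", "4", 207, (89.37, 92.75)),
    CandidateExon("ENSGALE00010292250", "ZBTB7B", "25", 349, (92.84, 93.12)),
    CandidateExon("ENSGALE00010292045", "AMPD2", "26", 226, (88.89, 93.30)),
    CandidateExon("ENSGALE00010285483", "JUND", "28", 347, (87.33, 89.94)),
)

#: Amplicon length (bp) of the bundled assay's marker exon.
MARKER_AMPLICON_BP = 226


@dataclass(frozen=True)
class MixtureRow:
    """One species in one validation mixture: spiked (actual) and
    measured (detected) DNA proportion in percent, with the published
    accuracy (R.D.) and precision (R.S.D.) over triplicates.  Background
    (pig) rows carry detected=None: no signal on any poultry channel."""

    mixture: str
    species: str
    actual_pct: float
    detected_pct: float | None
    rd_pct: float | None
    rsd_pct: float | None


#: Triplicate quantification of three poultry-in-pig composite DNA
#: mixtures measured with the bundled assay.
VALIDATION_MIXTURES: tuple[MixtureRow, ...] = (
    MixtureRow("I", "chicken", 10, 9.71, 2.85, 3.39),
    MixtureRow("I", "quail", 10, 9.53, 4.74, 4.79),
    MixtureRow("I", "duck", 10, 10.41, 4.13, 0.94),
    MixtureRow("I", "goose", 10, 9.76, 2.39, 7.85),
    MixtureRow("I", "pig", 60, None, None, None),
    MixtureRow("II", "chicken", 5, 5.25, 5.05, 3.74),
    MixtureRow("II", "quail", 15, 15.29, 1.92, 7.59),
    MixtureRow("II", "duck", 25, 24.64, 1.45, 1.01),
    MixtureRow("II", "goose", 35, 34.58, 1.20, 13.84),
    MixtureRow("II", "pig", 20, None, None, None),
    MixtureRow("III", "chicken", 15, 15.60, 3.99, 3.32),
    MixtureRow("III", "quail", 15, 14.88, 0.80, 3.83),
    MixtureRow("III", "duck", 20, 19.62, 1.92, 4.21),
    MixtureRow("III", "goose", 20, 19.52, 2.41, 0.96),
    MixtureRow("III", "pig", 30, None, None, None),
)

#: Sensitivity dilution series design: 10-fold from 5 ng/uL over four
#: levels (5, 0.5, 0.05, 0.005), measured in triplicate.
LOD_SERIES_TOP_NG_UL = 5.0
LOD_SERIES_FOLD = 10.0
LOD_SERIES_LEVELS = 4
LOD_SERIES_REPLICATES = 3
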