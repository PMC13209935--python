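"""Seeded generators for ortholog families with planted assay structure
and for simulated Ct tables.

``simulate_family`` emulates the sequence regime a universal-primer
multiplex assay exploits: an ancestor sequence from which four target
species diverge at ~5% per site (putting pairwise target identities in
the high-80s/low-90s) and non-targets at ~25%, with an optional planted
design — conserved primer flanks shared by all targets (with declared
two-fold degenerate columns), per-species private substitutions between
the flanks, and forced flank corruption in every non-target so the
flanks are target-exclusive.  Substitution-only evolution keeps planted
coordinates exact; an optional deletion rate (outside planted regions)
exercises gap handling.

``simulate_ct_table`` and ``dilution_series`` draw replicate Ct values
from a standard-curve model with Gaussian cycle noise, for testing
quantification and limit-of-detection logic.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import MsaRecord, SequenceRecord
from .quant import CtMeasurement, StandardCurve, TOTAL_CYCLES

__all__ = [
    "PlantedDesignSpec",
    "FamilySpec",
    "FamilyTruth",
    "simulate_family",
    "simulate_ct_table",
    "dilution_series",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedDesignSpec:
    """Geometry of the planted assay inside the family.

    The amplicon runs flank-to-flank; per-species probe regions with
    `specific_sites` private substitutions each are laid out between
    the flanks in target-label order.
    """

    flank_len: int = 18
    fwd_degenerate_sites: int = 2
    rev_degenerate_sites: int = 1
    specific_sites: int = 2
    amplicon_len: int = 226
    nontarget_flank_mismatches: int = 3

    def __post_init__(self):
        if self.specific_sites < 2:
            raise ValueError("need >= 2 species-specific sites per probe")
        if self.amplicon_len < 2 * self.flank_len + 1:
            raise ValueError("amplicon too short for two flanks")


@dataclass(frozen=True)
class FamilySpec:
    """Conditions for one simulated ortholog family.

    Divergences are average per-site substitution probabilities versus
    the ancestor (0.05 puts pairwise target identity near 90%, the
    regime a universal-primer assay is designed in; 0.25 for outgroups).
    Site rates are heterogeneous: each column is drawn once as
    `constrained` or `variable` (shared by all species, emulating
    purifying selection), with multipliers averaging 1 so the stated
    divergence is preserved.  This makes chance target-conserved windows
    fall mostly in columns where non-targets are conserved too — only
    the planted flanks are simultaneously target-conserved and
    non-target-divergent, which is the exclusivity regime the assay
    relies on.
    """

    base_length: int = 260
    target_labels: tuple[str, ...] = ("chicken", "quail", "duck", "goose")
    nontarget_labels: tuple[str, ...] = ("pig", "cow")
    target_divergence: float = 0.05
    nontarget_divergence: float = 0.25
    constrained_fraction: float = 0.5
    constrained_rate_multiplier: float = 0.15
    planted_design: PlantedDesignSpec | None = None
    deletion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for d in (self.target_divergence, self.nontarget_divergence):
            if not 0.0 <= d < 1.0:
                raise ValueError("divergence must lie in [0, 1)")
        if self.planted_design is not None:
            if self.planted_design.amplicon_len + 20 > self.base_length:
                raise ValueError("planted amplicon does not fit inside base_length")


@dataclass
class FamilyTruth:
    """Ground truth for one simulated family."""

    spec: FamilySpec
    sequences: dict[str, SequenceRecord]
    msa: list[MsaRecord]
    fwd_flank_span: tuple[int, int] | None = None
    rev_flank_span: tuple[int, int] | None = None
    specific_sites: dict[str, list[int]] = field(default_factory=dict)
    probe_spans: dict[str, tuple[int, int]] = field(default_factory=dict)
    amplicon_span: tuple[int, int] | None = None
    expected_amplicons: dict[str, str] = field(default_factory=dict)

    @property
    def target_labels(self) -> tuple[str, ...]:
        return self.spec.target_labels

    def msa_row(self, label: str) -> str:
        for r in self.msa:
            if r.species_label == label:
                return r.aligned_residues
        raise KeyError(label)


def _mutate(rng: np.random.Generator, seq: np.ndarray, site_rates: np.ndarray,
            protected: np.ndarray) -> np.ndarray:
    """Substitute each unprotected site i with probability site_rates[i],
    always to a different base."""
    out = seq.copy()
    hit = (rng.random(len(seq)) < site_rates) & ~protected
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def simulate_family(spec: FamilySpec) -> FamilyTruth:
    """Generate one ortholog family; deterministic given spec.seed.

    With a planted design: flank columns are identical across targets
    except at the declared degenerate columns, where targets split into
    two bases; each probe region carries `specific_sites` columns where
    exactly one target deviates; every non-target receives at least
    `nontarget_flank_mismatches` forced substitutions inside each flank
    (to a base different from both target variants).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.base_length
    ancestor = _BASES[rng.integers(4, size=n)]

    # shared site-rate multipliers (two classes, mean 1)
    p, m = spec.constrained_fraction, spec.constrained_rate_multiplier
    variable_mult = (1.0 - p * m) / (1.0 - p) if p < 1.0 else m
    multipliers = np.where(rng.random(n) < p, m, variable_mult)

    plant = spec.planted_design
    protected = np.zeros(n, dtype=bool)
    truth = FamilyTruth(spec=spec, sequences={}, msa=[])

    degenerate_cols: dict[int, tuple[str, str]] = {}
    if plant is not None:
        amp_start = (n - plant.amplicon_len) // 2
        amp_end = amp_start + plant.amplicon_len
        fwd_span = (amp_start, amp_start + plant.flank_len)
        rev_span = (amp_end - plant.flank_len, amp_end)
        truth.amplicon_span = (amp_start, amp_end)
        truth.fwd_flank_span = fwd_span
        truth.rev_flank_span = rev_span
        # only the flanks (and, below, the planted specific-site columns)
        # are held fixed; the amplicon interior diverges like the rest of
        # the sequence, mirroring the ~90% intra-amplicon identity regime
        # a real ortholog family shows
        protected[fwd_span[0]:fwd_span[1]] = True
        protected[rev_span[0]:rev_span[1]] = True

        # degenerate flank columns: targets split into two variants;
        # keep them off the 3'-proximal ends so the anchor stays exact
        for span, k, off in ((fwd_span, plant.fwd_degenerate_sites, 2),
                             (rev_span, plant.rev_degenerate_sites, 2)):
            cols = rng.choice(np.arange(span[0] + off, span[1] - off),
                              size=k, replace=False)
            for c in sorted(int(c) for c in cols):
                b1 = ancestor[c]
                b2 = [b for b in "ACGT" if b != b1][rng.integers(3)]
                degenerate_cols[c] = (str(b1), b2)

        # per-species probe regions between the flanks
        interior = (fwd_span[1] + 1, rev_span[0] - 1)
        n_targets = len(spec.target_labels)
        region_w = (interior[1] - interior[0]) // n_targets
        if region_w < plant.specific_sites + 4:
            raise ValueError("interior too short for the requested probe regions")
        for j, sp in enumerate(spec.target_labels):
            r0 = interior[0] + j * region_w
            r1 = r0 + region_w
            truth.probe_spans[sp] = (r0, r1)
            # spread the private sites across a probe-sized window
            w = min(region_w - 2, max(plant.specific_sites + 8, 16))
            cols = rng.choice(np.arange(r0 + 1, r0 + 1 + w),
                              size=plant.specific_sites, replace=False)
            truth.specific_sites[sp] = sorted(int(c) for c in cols)

    # derive each species from the ancestor
    aligned: dict[str, np.ndarray] = {}
    for i, sp in enumerate(spec.target_labels):
        seq = _mutate(rng, ancestor,
                      np.minimum(spec.target_divergence * multipliers, 0.95),
                      protected)
        for c, (b1, b2) in degenerate_cols.items():
            # split targets between the two variants (never all on one)
            seq[c] = b1 if i % 2 == 0 else b2
        for other_sp, cols in truth.specific_sites.items():
            for c in cols:
                if sp == other_sp:
                    b = ancestor[c]
                    seq[c] = [x for x in "ACGT" if x != b][rng.integers(3)]
                else:
                    seq[c] = ancestor[c]
        aligned[sp] = seq

    # non-target lineages: flank columns evolve at the full variable-class
    # rate (the flanks are conserved in targets because they are functional
    # *there*; in outgroups they are low-homology), plus forced mismatches
    # as a floor
    nt_rates = np.minimum(spec.nontarget_divergence * multipliers, 0.95)
    if plant is not None:
        nt_var = min(spec.nontarget_divergence * variable_mult, 0.95)
        for span in (truth.fwd_flank_span, truth.rev_flank_span):
            nt_rates[span[0]:span[1]] = nt_var
    for sp in spec.nontarget_labels:
        seq = _mutate(rng, ancestor, nt_rates, np.zeros(n, dtype=bool))
        if plant is not None:
            for span in (truth.fwd_flank_span, truth.rev_flank_span):
                # prefer columns still matching the target consensus, so the
                # forced mismatches add to (not absorb) the random ones
                span_cols = list(range(span[0], span[1]))
                still_match = [c for c in span_cols if str(seq[c]) == str(ancestor[c])]
                pool = still_match if len(still_match) >= plant.nontarget_flank_mismatches else span_cols
                cols = rng.choice(np.asarray(pool),
                                  size=plant.nontarget_flank_mismatches,
                                  replace=False)
                for c in cols:
                    c = int(c)
                    forbidden = set(degenerate_cols.get(c, ())) | {str(ancestor[c])}
                    allowed = [b for b in "ACGT" if b not in forbidden]
                    seq[c] = allowed[rng.integers(len(allowed))]
        aligned[sp] = seq

    # optional deletions -> gapped MSA rows; target rows never gap inside
    # the planted amplicon so planted coordinates stay exact
    gap_masks: dict[str, np.ndarray] = {}
    deletable = np.ones(n, dtype=bool)
    if plant is not None:
        deletable[truth.amplicon_span[0]:truth.amplicon_span[1]] = False
    for sp, seq in aligned.items():
        mask = np.zeros(n, dtype=bool)
        if spec.deletion_rate > 0:
            allowed = deletable if sp in spec.target_labels else np.ones(n, dtype=bool)
            mask = (rng.random(n) < spec.deletion_rate) & allowed
        gap_masks[sp] = mask

    order = list(spec.target_labels) + list(spec.nontarget_labels)
    for sp in order:
        row = aligned[sp].copy().astype(object)
        row[gap_masks[sp]] = "-"
        aligned_str = "".join(row)
        truth.msa.append(MsaRecord(species_label=sp, aligned_residues=aligned_str))
        truth.sequences[sp] = SequenceRecord(
            id=sp, residues=aligned_str.replace("-", ""),
            description=f"synthetic ortholog (seed={spec.seed})",
        )

    if plant is not None:
        a0, a1 = truth.amplicon_span
        for sp in spec.target_labels:
            truth.expected_amplicons[sp] = truth.msa_row(sp)[a0:a1].replace("-", "")
    return truth


def design_matches_truth(design, truth: FamilyTruth) -> bool:
    """Does an assembled assay design recover the planted one?

    True iff the forward and reverse primer windows overlap the planted
    flank spans (a window shifted by a few columns against the flank is
    the same assay in practice) and every probe window carries at least
    two genuinely species-specific columns, re-verified directly from
    the MSA rows.  Private substitutions also arise naturally from
    background divergence, so a probe sitting on natural rather than
    planted diagnostic sites is still a correct design; what is unique
    to the planted structure — and therefore what recovery tests — is
    the placement of the primers on the target-exclusive flanks.
    """
    if truth.fwd_flank_span is None:
        raise ValueError("family was generated without a planted design")

    def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
        return a[0] < b[1] and b[0] < a[1]

    if not _overlaps(design.forward.span, truth.fwd_flank_span):
        return False
    if not _overlaps(design.reverse.span, truth.rev_flank_span):
        return False
    rows = {sp: truth.msa_row(sp) for sp in truth.target_labels}
    for sp, window in design.probes.items():
        lo, hi = window.span
        n_specific = 0
        for c in range(lo, hi):
            own = rows[sp][c]
            others = {rows[o][c] for o in rows if o != sp}
            if own != "-" and "-" not in others and len(others) == 1 and own not in others:
                n_specific += 1
        if n_specific < 2:
            return False
    return True


# ---------------------------------------------------------------------------
# Ct simulation


def simulate_ct_table(
    curves: dict[str, StandardCurve],
    proportions: dict[str, float],
    replicates: int = 3,
    noise_sd: float = 0.15,
    seed: int = 0,
    sample_id: str = "mix",
) -> list[CtMeasurement]:
    """Replicate Ct table from the standard-curve model:
    ct = a * log10(p/100) + b + eps, eps ~ N(0, noise_sd^2) i.i.d."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[CtMeasurement] = []
    for sp in proportions:
        p = proportions[sp]
        if p <= 0:
            raise ValueError(f"non-positive proportion for {sp!r}")
        curve = curves[sp]
        for rep in range(1, replicates + 1):
            ct = curve.ct_of(np.log10(p / 100.0)) + rng.normal(0.0, noise_sd)
            out.append(CtMeasurement(sample_id, sp, rep, float(ct)))
    return out


def dilution_series(
    curve: StandardCurve,
    top_conc: float = 5.0,
    fold: float = 10.0,
    levels: int = 4,
    replicates: int = 3,
    noise_sd: float = 0.15,
    dropout_below: float | None = None,
    seed: int = 0,
    channel: str = "target",
) -> dict[float, list[CtMeasurement]]:
    """Serial dilution for LOD determination: concentrations
    top / fold^k for k = 0..levels-1; every replicate at a
    concentration strictly below `dropout_below` is undetected."""
    if levels < 1:
        raise ValueError("need >= 1 level")
    rng = np.random.default_rng(seed)
    series: dict[float, list[CtMeasurement]] = {}
    for k in range(levels):
        conc = top_conc / fold**k
        reps: list[CtMeasurement] = []
        for rep in range(1, replicates + 1):
            if dropout_below is not None and conc < dropout_below:
                ct = None
            else:
                ct = float(curve.ct_of(np.log10(conc)) + rng.normal(0.0, noise_sd))
                ct = min(ct, TOTAL_CYCLES - 1e-6)
            reps.append(CtMeasurement(f"dil_{conc:g}", channel, rep, ct))
        series[conc] = reps
    return series
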