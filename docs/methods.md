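# Methods

This note documents the models, conventions and design choices behind
`pupfpcr`, and what the synthetic-data tests do and do not establish.

## The assay model

A universal-primer multiplex fluorescent PCR assay consists of one
degenerate primer pair and one hydrolysis (TaqMan) probe per target
species. The primers sit on flanking sequence that is conserved across
all target species *and only* the target species; IUPAC degenerate
bases (Y = C/T, K = G/T, …) absorb the residual polymorphism among
targets so that one oligo pair amplifies every target with comparable
efficiency. Each probe sits on the internal, hypervariable part of the
amplicon and must cover at least two substitutions private to its
species, so that under stringent hybridisation only the matching
species' amplicon releases that probe's fluorophore. The toolkit
treats these two placement rules — target-exclusive conserved flanks,
≥2 species-specific sites per probe — as the defining constraints of
the design problem.

## Candidate screening

Screening asks whether a candidate nuclear marker aligns to every
target genome inside a band that guarantees both conservation (enough
shared flank for a universal primer) and divergence (enough internal
variation for probes), while being absent or weak in non-targets.

* Target-grade hit: aligned length > 200 bp, identity within
  [85, 95] %, E-value < 10⁻⁵.
* Non-target exclusion, `initial` mode: best-hit identity < 80 %
  (no hit passes trivially). `validation` mode: the hit must fail at
  least one of the three target-grade axes (length < 200, identity
  < 85 %, E ≥ 10⁻⁵). Both thresholds appear in the screening
  literature for this assay family; the mode switch exposes both
  rather than guessing a single intent.

The built-in aligner is affine-gap local (Smith-Waterman) alignment
via `Bio.Align.PairwiseAligner` with BLASTN-like scores (match +2,
mismatch −3, gap open −5, extend −2; a gap of length L costs
open + L·extend). Identity is computed over aligned columns including
gap columns (the BLAST `pident` convention the thresholds were set
against). "Query length" in the criteria is interpreted as the aligned
length on the query: a 226 bp marker cannot otherwise satisfy
"> 200 bp" per hit. E-values use the Karlin-Altschul form
E = K·m·n·e^(−λS) with the standard ungapped nucleotide parameters
λ = 1.37, K = 0.711. These E-values are comparative thresholds for
screening, not calibrated significance claims; reproducing NCBI
E-values bit-exactly is out of scope. Externally computed hits in the
12-column tabular dialect can be substituted for the built-in aligner.

## Design from an MSA

Each alignment column is classified from the target rows only:
`invariant`, `species_specific(s)` (exactly one target deviates from
the rest, which are mutually identical and ungapped; requires ≥3
target rows for the deviant to be well-defined), `degenerate_ok`
(ungapped, exactly two distinct bases not attributable to one species
— the two-fold degeneracy a Y/K-style primer site can absorb),
`gapped` (any target gapped), or `other` (≥3 distinct bases). Columns
with ≥3 bases are excluded from primer windows because the bundled
assay's degenerate sites are all two-fold and higher-fold degeneracy
dilutes per-variant primer concentration.

Primer windows (default 17–25 nt) must be gap-free across targets,
carry ≤2 degenerate consensus symbols (the bundled primers carry 2 and
1), and mismatch every non-target row at ≥3 positions (a non-target
gap counts as a mismatch). Windows are ordered by (non-target
mismatches desc, degeneracy asc, start asc). Probe windows (default
13–30 nt) must be gap-free across targets and contain ≥2 columns
private to their species; ordering is (specific sites desc, length
asc, start asc), preferring short probes saturated with diagnostic
sites. Probes are reported on the sense strand; antisense placement is
not considered.

Assembly pairs primer windows (forward strictly upstream of reverse)
whose flank-to-flank ungapped span lies within the amplicon bounds
(default 60–250 bp — qPCR-scale products bounded above by the 226 bp
marker family this design style was built around), inserts the
best-ranked in-between probe window per species, and ranks designs by
(total non-target mismatches desc, total degeneracy asc). Because
shifted variants of one locus would otherwise crowd out the rest of
the ranking, assembly applies non-maximum suppression: a window
overlapping an already-kept window by ≥50 % of the shorter length is
dropped, keeping up to 100 windows. The design ranking depends only on
the primer windows, so the top design is unchanged as long as both of
its windows survive the cut.

## In-silico PCR

Primer binding is scanned on both strands with IUPAC-aware matching
(two codes match iff their base sets intersect — the permissive choice,
which is conservative for specificity screening). A site must have ≤2
total mismatches and an exact 3′-terminal 2-symbol anchor, since 3′
mismatches dominate polymerase extension failure. Amplicons run from
forward 5′ end to reverse 5′ end inclusive; each convergent site pair
within the length bound yields one product, and the predicted set is
symmetric under swapping the primer arguments. A channel is called
detected when some amplicon contains that channel's probe (either
strand) within the probe mismatch budget, which defaults to 0 —
strict probe matching mirrors hydrolysis-probe specificity. Detection
is boolean: no amplification kinetics, competition or Ct values are
modelled here, so the Ct < 36 positivity rule of real instruments has
no in-silico analogue and lives in the quantification layer instead.

## Quantification

The standard curve is an ordinary least-squares fit of Ct against
log₁₀ template amount; R² is the squared Pearson correlation (exactly
1 for two points) and efficiency = 10^(−1/slope) − 1 (slope −3.32 ↔
100 %). For mixtures the x-variable is log₁₀ of the *fraction* of
total DNA — the only convention consistent with the ×100 factor in
the back-calculation C = 10^((y−b)/a) × 100 %. Proportions above 100 %
are reported unclamped with a flag rather than silently truncated.

Each replicate Ct is converted to a proportion *before* averaging, so
precision (R.S.D., sample n−1 standard deviation over mean) is defined
over replicate proportions, matching the paired accuracy/precision
columns of mixture validation tables. Accuracy (R.D.) uses the
absolute difference |detected − actual|/actual, since both over- and
under-estimates are reported as positive deviations. No normalisation
across species is applied to detected proportions. Undetected wells
are an explicit sentinel (None), never Ct = 40: conflating "no signal"
with "cycle 40" would bias proportions. The limit of detection is the
lowest concentration level of a dilution series at which every
replicate yields a signal below the Ct cutoff (default 36 cycles).
ENGL acceptance (curve R² ≥ 0.98, R.D. ≤ 25 %, R.S.D. ≤ 25 %) is
checked per species and summarised in a compliance report.

Oligo QC is advisory: Wallace-rule Tm = 2(A+T) + 4(G+C) and GC %
reported as ranges over a degenerate oligo's expansions (computed
symbol-wise), length bounds 17–25 nt (primers) / 13–30 nt (probes), GC
30–80 %, and a warning (not failure) for probes starting with G, which
can quench the 5′ fluorophore. Nearest-neighbour thermodynamics,
dimer/hairpin ΔG and salt corrections are deliberately omitted — QC
here flags pathologies, it does not select designs.

## Synthetic data generator

`simulate_family` emulates the sequence regime the assay is designed
in: an ancestor of 260 bp (the neighbourhood of a ~226 bp marker) from
which four target species diverge at an average 5 % per site — putting
pairwise target identity near 90 %, the band the screen demands — and
non-target outgroups at 25 %. Site rates are heterogeneous: each
column is drawn once as constrained (rate ×0.15) or variable (×1.85),
50/50, shared by **all** species. This emulates purifying selection,
under which a region conserved among targets is normally conserved in
outgroups too; without it, chance target-conserved windows with high
non-target divergence would arise uniformly along the sequence, and
"target-exclusive conserved flank" would not be a distinguishable
property. The class proportions were chosen once as a generic
two-class rate model; the multipliers average to 1 so the stated mean
divergences are preserved.

A planted design (optional) fixes an 18 + 190 + 18 = 226 bp amplicon in
the centre: flanks identical across targets except two (forward) and
one (reverse) declared two-fold degenerate columns kept off the 3′
ends; two private substitutions per species in laid-out probe regions;
and, in every non-target, flank columns evolving at the full
variable-class rate (the flanks are conserved in targets because they
are functional there; in outgroups they are low-homology) plus ≥3
forced mismatches placed on columns still matching the target
consensus, so the floor is additive. Evolution is substitution-only by
default; an optional deletion rate gaps the MSA outside the planted
amplicon (target rows) to exercise gap handling. All generators are
pure functions of (spec, seed).

Recovery of a planted design is judged structurally: the top-ranked
design's primer windows must overlap the planted flank spans (a window
shifted a few columns is the same assay in practice) and each probe
window must contain ≥2 genuinely species-specific columns re-verified
from the raw MSA. Private substitutions also arise from background
divergence, so probes on natural rather than planted diagnostic sites
are correct designs; the uniquely planted structure is the flank
placement. Under these conditions the planted design is recovered
rank-1 in ≥95 % of seeds (measured 97.5 % over 120 seeds).

`simulate_ct_table` draws Ct = a·log₁₀(p/100) + b + ε with
ε ~ N(0, σ²) i.i.d. per well (default σ = 0.15 cycles, a realistic
replicate scatter for probe-based qPCR); `dilution_series` produces
the 10-fold, 4-level, triplicate design (5 → 0.005 ng/µL) used for LOD
determination, with an optional dropout concentration below which
replicates are undetected. Under the delta method the relative error
of a triplicate-mean proportion is ln10·σ/(|a|·√3) ≈ 6 %, so landing
within 10 % of truth has probability ≈ 0.90 per species — the test
suite checks the simulation against this closed form.

## What the synthetic tests do and do not show

The generator reproduces the *identity structure* real ortholog
families show (conserved flanks, hypervariable interior, diverged
outgroups) but not their biology: no transition/transversion bias, no
indel-rich regions inside amplicons, no paralogs, no base-composition
skew, and the Ct model has no amplification competition, inhibitors or
probe chemistry. Passing tests therefore establish that the algorithms
are correct against their stated rules and self-consistent end-to-end
(designed assays detect exactly their targets in-silico; simulated
mixtures quantify within ENGL bounds at realistic noise), not that a
designed assay will behave in a wet lab. Real-genome validation of a
specific assay additionally requires the genome homologs, which this
package deliberately does not download.

## Problem sizes and numerics

Default problem sizes (260 bp families, 50-seed recovery batches,
200-seed Ct simulations, 1000-point round-trip grids) were chosen so
the full suite characterises behaviour statistically while running in
well under a minute each. Ties in window and design rankings are
broken deterministically (start coordinate, then length); two runs on
identical inputs and seed are byte-identical. Degenerate-oligo
expansion is capped at 1024 variants to bound memory. The proportion
round-trip is exact to <10⁻⁹ over (0, 100]; curve fitting rejects
degenerate inputs (identical x, zero slope) explicitly.
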