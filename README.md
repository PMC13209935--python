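# pupfpcr

An in-silico toolkit for designing and evaluating **universal-primer
multiplex fluorescent PCR (PUP-fPCR)** assays: single-tube species
authentication of poultry meat (chicken, quail, duck, goose) with one
degenerate primer pair and per-species TaqMan probes.

Meat adulteration — substituting cheap poultry for pricier species — is
hard to catch by inspection because the meats look and taste alike.
DNA-based multiplex qPCR can identify and quantify each species in a
single reaction, but conventional designs need one primer pair per
species and suffer primer competition. The universal-primer design
instead amplifies *all* target species with a single degenerate pair
placed on flanking sequence conserved across the targets (and only the
targets), and discriminates species with hydrolysis probes placed on
internal hypervariable windows that carry at least two species-specific
substitutions each.

The toolkit covers the full dry-lab side of that workflow:

| stage | module | what it does |
|---|---|---|
| marker screen | `pupfpcr.alignment` | local alignment (affine Smith-Waterman) + dual screening criteria: targets must align at >200 bp, 85% ≤ identity ≤ 95%, E < 10⁻⁵; non-targets must fail (identity < 80% in the initial screen) |
| assay design | `pupfpcr.marker_finder`, `pupfpcr.oligo` | MSA column classification, target-exclusive conserved primer windows with an IUPAC-degeneracy budget, probe windows with ≥2 species-specific sites, ranked assay assembly |
| in-silico PCR | `pupfpcr.insilico_pcr` | IUPAC-aware primer binding with mismatch budget and 3′ anchor, amplicon prediction, per-channel probe calls |
| quantification | `pupfpcr.quant` | standard curves `y = a·x + b` (Ct vs log₁₀ amount), proportion back-calculation `C = 10^((y−b)/a) × 100%`, LOD, R.D./R.S.D., ENGL compliance (R² ≥ 0.98, R.D. and R.S.D. ≤ 25%) |
| synthetic data | `pupfpcr.synthetic` | seeded ortholog families with planted assay structure; simulated Ct tables and dilution series |
| I/O | `pupfpcr.io_formats` | FASTA, aligned FASTA / Clustal MSAs, 12-column tabular hits, YAML assay configs, plus the bundled published poultry assay |

## Worked example

```python
>>> from pupfpcr import builtin_pup_assay
>>> from pupfpcr.oligo import count_degenerate_positions
>>> assay = builtin_pup_assay()
>>> assay.forward, count_degenerate_positions(assay.forward)
('GYTGGGCCCCCAYTACCT', 2)
>>> assay.reverse, count_degenerate_positions(assay.reverse)
('CTGGATGGKCTCCAGCTC', 1)
```

The bundled universal primers carry two degenerate sites upstream
(Y = C/T) and one downstream (K = G/T) — the polymorphic positions
among the four poultry targets. Design and detection close the loop on
synthetic data:

```python
>>> from pupfpcr import FamilySpec, PlantedDesignSpec, simulate_family
>>> from pupfpcr import profile_columns, find_conserved_windows, find_probe_windows, assemble_assays
>>> fam = simulate_family(FamilySpec(planted_design=PlantedDesignSpec(), seed=11))
>>> labels = set(fam.target_labels)
>>> profiles = profile_columns(fam.msa, labels)
>>> designs = assemble_assays(
...     find_conserved_windows(profiles),
...     {sp: find_probe_windows(profiles, sp, (0, len(profiles))) for sp in labels},
...     fam.msa, labels)
>>> designs[0].forward.span, designs[0].amplicon_len
((9, 31), (232, 232))
>>> fam.fwd_flank_span
(17, 35)
```

The top-ranked design's forward window overlaps the planted forward
flank (columns 17–35) and brackets a 232 bp amplicon around the planted
226 bp one.
Quantification inverts a standard curve exactly:

```python
>>> from pupfpcr import StandardCurve, proportion_from_ct
>>> curve = StandardCurve(slope_a=-3.3219, intercept_b=21.0, r_squared=1.0, n_points=4)
>>> round(proportion_from_ct(curve.ct_of(-1.0), curve), 6)   # Ct at 10% template
10.0
>>> round(100 * curve.efficiency, 1)
100.0
```

The same workflow is available from a shell via the `pup` CLI
(`pup simulate | screen | design | epcr | quant`); every run writes its
tables plus a `manifest.json` with parameters and input digests.

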