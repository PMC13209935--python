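import numpy as np
import pytest

from pupfpcr.insilico_pcr import (
    call_probe,
    find_binding_sites,
    predict_amplicons,
    simulate_multiplex,
)
from pupfpcr.io_formats import AssayDefinition, ProbeSpec, SequenceRecord
from pupfpcr.marker_finder import (
    assemble_assays,
    find_conserved_windows,
    find_probe_windows,
    profile_columns,
)
from pupfpcr.oligo import revcomp
from pupfpcr.synthetic import FamilySpec, PlantedDesignSpec, simulate_family

REPORTERS = {"chicken": "TAMRA", "quail": "CY5", "duck": "ROX", "goose": "VIC"}


def _random_bases(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(123)


class TestBindingSites:
    def test_exact_forward_expansion_found(self, assay, rng):
        primer_x = "GCTGGGCCCCCACTACCT"  # one expansion of the forward primer
        template = SequenceRecord("t", _random_bases(rng, 40) + primer_x + _random_bases(rng, 40))
        sites = [s for s in find_binding_sites(assay.forward, template) if s.strand == "+"]
        assert any(s.position == 40 and s.mismatches == 0 for s in sites)

    def test_mismatch_budget_enforced(self, assay, rng):
        primer_x = "GCTGGGCCCCCACTACCT"
        mutated = "GCT" + "AAA" + primer_x[6:]  # 3 internal mismatches
        template = SequenceRecord("t", _random_bases(rng, 30) + mutated + _random_bases(rng, 30))
        sites = find_binding_sites(assay.forward, template, max_mm=2)
        assert not any(s.mismatches == 3 for s in sites)
        assert find_binding_sites(assay.forward, template, max_mm=3)

    def test_minus_strand_site(self, assay, rng):
        primer_x = "GCTGGGCCCCCACTACCT"
        template = SequenceRecord("t", _random_bases(rng, 25) + revcomp(primer_x) + _random_bases(rng, 25))
        sites = [s for s in find_binding_sites(assay.forward, template) if s.strand == "-"]
        # 5' end of a minus-strand site maps to the window's right edge
        assert any(s.position == 25 + len(primer_x) - 1 for s in sites)

    def test_three_prime_anchor_rejects(self):
        primer = "ACGTACGTAC"
        template = SequenceRecord("t", "TTTT" + primer[:-1] + "G" + "TTTT")  # 3' base wrong
        sites = find_binding_sites(primer, template, max_mm=2, three_prime_exact=1)
        # the otherwise-perfect site at offset 4 is rejected on its 3' base
        assert not any(s.strand == "+" and s.position == 4 for s in sites)
        relaxed = find_binding_sites(primer, template, max_mm=2, three_prime_exact=0)
        assert any(s.strand == "+" and s.position == 4 for s in relaxed)


class TestPredictAmplicons:
    def _template(self, assay, rng, insert=190):
        fwd_x = assay.forward.replace("Y", "C", 1).replace("Y", "T", 1)
        rev_x = assay.reverse.replace("K", "G")
        mid = _random_bases(rng, insert)
        return SequenceRecord("t", _random_bases(rng, 10) + fwd_x + mid
                              + revcomp(rev_x) + _random_bases(rng, 10))

    def test_published_amplicon_length(self, assay, rng):
        """fwd(18) + 190 + rev(18) lays out the marker's 226 bp product."""
        template = self._template(assay, rng, insert=190)
        (amp,) = predict_amplicons(assay.forward, assay.reverse, template)
        assert amp.length == 226
        assert amp.span == (10, 236)

    def test_length_bound(self, assay, rng):
        template = self._template(assay, rng, insert=500)
        assert predict_amplicons(assay.forward, assay.reverse, template, max_len=250) == []

    def test_orientation_symmetric(self, assay, rng):
        template = self._template(assay, rng)
        a1 = predict_amplicons(assay.forward, assay.reverse, template)
        a2 = predict_amplicons(assay.reverse, assay.forward, template)
        assert [a.span for a in a1] == [a.span for a in a2]

    def test_amplicon_ends_carry_primer_matches(self, assay, rng):
        from pupfpcr.oligo import IUPAC_TO_BASES
        template = self._template(assay, rng)
        (amp,) = predict_amplicons(assay.forward, assay.reverse, template)
        head = amp.sequence[: len(assay.forward)]
        assert all(h in IUPAC_TO_BASES[c] for h, c in zip(head, assay.forward))
        tail = amp.sequence[-len(assay.reverse):]
        rc = revcomp(assay.reverse)
        assert all(t in IUPAC_TO_BASES[c] for t, c in zip(tail, rc))


class TestCallProbe:
    def test_planted_probe_detected(self, assay, rng):
        probe = assay.probes["chicken"].sequence
        amp_seq = _random_bases(rng, 30) + probe + _random_bases(rng, 30)
        from pupfpcr.insilico_pcr import Amplicon
        amp = Amplicon("t", (0, len(amp_seq)), amp_seq)
        assert call_probe(probe, amp) == (True, 0)

    def test_mismatch_budget(self, assay, rng):
        probe = assay.probes["duck"].sequence
        mutated = "CA" + probe[2:]
        amp_seq = _random_bases(rng, 20) + mutated + _random_bases(rng, 20)
        from pupfpcr.insilico_pcr import Amplicon
        amp = Amplicon("t", (0, len(amp_seq)), amp_seq)
        detected, _ = call_probe(probe, amp, max_mm=0)
        mm_budget = call_probe(probe, amp, max_mm=2)
        assert not detected
        assert mm_budget[0] and mm_budget[1] <= 2

    def test_reverse_strand_probe_detected(self, assay, rng):
        probe = assay.probes["goose"].sequence
        amp_seq = _random_bases(rng, 25) + revcomp(probe) + _random_bases(rng, 25)
        from pupfpcr.insilico_pcr import Amplicon
        amp = Amplicon("t", (0, len(amp_seq)), amp_seq)
        assert call_probe(probe, amp)[0]


@pytest.fixture(scope="module")
def designed():
    family = simulate_family(FamilySpec(planted_design=PlantedDesignSpec(), seed=11))
    labels = set(family.target_labels)
    profiles = profile_columns(family.msa, labels)
    primers = find_conserved_windows(profiles)
    probes = {sp: find_probe_windows(profiles, sp, (0, len(profiles)))
              for sp in labels}
    design = assemble_assays(primers, probes, family.msa, labels)[0]
    assay = AssayDefinition(
        "synthetic", design.forward_oligo, design.reverse_oligo,
        {sp: ProbeSpec(w.sequence, REPORTERS[sp], "MGB")
         for sp, w in design.probes.items()})
    return family, assay


class TestMultiplex:
    def test_panel_matches_ground_truth(self, designed):
        """Singleplex-style panel: each species' template lights exactly
        its own channel; non-targets stay dark on all four."""
        family, assay = designed
        calls = simulate_multiplex(assay, list(family.sequences.values()))
        assert len(calls) == 6 * 4
        for c in calls:
            assert c.detected == (c.template_id == c.species), c

    def test_mixture_lights_all_channels(self, designed):
        family, assay = designed
        targets = [family.sequences[sp] for sp in family.target_labels]
        calls = simulate_multiplex(assay, targets)
        lit = {c.species for c in calls if c.detected}
        assert lit == set(family.target_labels)

    def test_empty_template_list(self, designed):
        _, assay = designed
        assert simulate_multiplex(assay, []) == []

    def test_detection_monotone_in_budget(self, designed):
        family, assay = designed
        templates = list(family.sequences.values())
        strict = {(c.template_id, c.species)
                  for c in simulate_multiplex(assay, templates, max_mm=1)
                  if c.detected}
        loose = {(c.template_id, c.species)
                 for c in simulate_multiplex(assay, templates, max_mm=3)
                 if c.detected}
        assert strict <= loose

    def test_ground_truth_across_seeds(self):
        for seed in (0, 7, 23):
            family = simulate_family(FamilySpec(planted_design=PlantedDesignSpec(), seed=seed))
            labels = set(family.target_labels)
            profiles = profile_columns(family.msa, labels)
            design = assemble_assays(
                find_conserved_windows(profiles),
                {sp: find_probe_windows(profiles, sp, (0, len(profiles))) for sp in labels},
                family.msa, labels)[0]
            assay = AssayDefinition(
                "synthetic", design.forward_oligo, design.reverse_oligo,
                {sp: ProbeSpec(w.sequence, REPORTERS[sp], "MGB")
                 for sp, w in design.probes.items()})
            calls = simulate_multiplex(assay, list(family.sequences.values()))
            assert all(c.detected == (c.template_id == c.species) for c in calls)
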