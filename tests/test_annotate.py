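"""Fragmentation annotation: losses, diagnostics, head group, structures."""

import pytest

from salpipe.annotate import (
    AcylSpec,
    Peak,
    Spectrum,
    assemble_hypothesis,
    assign_head_group,
    build_acyl_library,
    build_fragmentation_tree,
    detect_sulfonate_signature,
    head_ion_to_neutral,
    infer_label_count,
    lock_mass_correct,
    match_neutral_losses,
    propose_structure,
)
from salpipe.formula import format_formula, monoisotopic_mass


class TestAcylSpec:
    @pytest.mark.parametrize(
        "spec, formula, mass",
        [
            (AcylSpec(18, 1, 0, "free_acid"), "C18H34O2", 282.2559),
            (AcylSpec(16, 0, 0, "ketene"), "C16H30O", 238.2297),
            (AcylSpec(18, 1, 0, "carboxylate_anion"), "C18H33O2", 281.2481),
            (AcylSpec(16, 0, 1, "free_acid"), "C16H32O3", 272.2351),
        ],
    )
    def test_species_formulas(self, spec, formula, mass):
        assert format_formula(spec.formula()) == formula
        assert spec.mass() == pytest.approx(mass, abs=2e-4)

    def test_library_contains_named_species_and_nominals(self, acyl_library):
        entries = {
            (s.c, s.d, s.x, s.species): (m, n) for s, m, n in acyl_library
        }
        mono, nominal = entries[(18, 1, 0, "free_acid")]
        assert mono == pytest.approx(282.2559, abs=2e-4)
        assert nominal == 282
        assert entries[(16, 0, 0, "ketene")][0] == pytest.approx(238.2297, abs=2e-4)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            build_acyl_library(range(16, 19), [], (0,))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            AcylSpec(1, 0)
        with pytest.raises(ValueError):
            AcylSpec(16, 7)
        with pytest.raises(ValueError):
            AcylSpec(16, 0, 2)


class TestLockMass:
    def test_unit_ratio_is_identity(self):
        s = Spectrum(level=2, peaks=(Peak(374.2364),), precursor_mz=656.4882)
        theo = monoisotopic_mass("C18H33O2")
        out = lock_mass_correct(s, theo, "C18H33O2")
        assert out.peaks[0].mz == pytest.approx(374.2364, abs=1e-12)

    def test_observed_lock_rescales_all_mz(self):
        s = Spectrum(level=2, peaks=(Peak(374.2364), Peak(136.0045)),
                     precursor_mz=656.4882)
        out = lock_mass_correct(s, 281.2480, "C18H33O2")
        theo = monoisotopic_mass("C18H33O2")
        ratio = theo / 281.2480
        assert ratio == pytest.approx(1 + 2e-7, rel=1e-7)
        for before, after in zip(s.peaks, out.peaks):
            assert after.mz == pytest.approx(before.mz * ratio, rel=1e-12)
            assert after.intensity == before.intensity

    def test_far_lock_rejected(self):
        s = Spectrum(level=2, peaks=(Peak(374.2364),), precursor_mz=656.4882)
        with pytest.raises(ValueError, match="deviates"):
            lock_mass_correct(s, 280.0, "C18H33O2")

    def test_idempotent_once_corrected(self):
        s = Spectrum(level=2, peaks=(Peak(374.2364),), precursor_mz=656.4882)
        once = lock_mass_correct(s, 281.2480, "C18H33O2")
        # the corrected lock peak now sits at the theoretical value
        corrected_lock = 281.2480 * monoisotopic_mass("C18H33O2") / 281.2480
        twice = lock_mass_correct(once, corrected_lock, "C18H33O2")
        for a, b in zip(once.peaks, twice.peaks):
            assert abs(b.mz - a.mz) / a.mz < 1e-10


class TestNeutralLosses:
    def test_printed_transitions_match_181_acid(self, acyl_library):
        for precursor, fragment in [(672.4875, 390.2317), (656.4882, 374.2364)]:
            s = Spectrum(level=2, peaks=(Peak(fragment),), precursor_mz=precursor)
            ann = match_neutral_losses(s, acyl_library)[0]
            assert ann.kind == "neutral_loss"
            assert (ann.acyl.c, ann.acyl.d, ann.acyl.species) == (18, 1, "free_acid")
        # printed-value arithmetic: deviations ~0.3 and ~-14.5 ppm of the loss
        s = Spectrum(level=2, peaks=(Peak(390.2317),), precursor_mz=672.4875)
        assert match_neutral_losses(s, acyl_library)[0].ppm_error == pytest.approx(
            -0.284, abs=0.01
        )
        s = Spectrum(level=2, peaks=(Peak(374.2364),), precursor_mz=656.4882)
        assert match_neutral_losses(s, acyl_library)[0].ppm_error == pytest.approx(
            -14.46, abs=0.05
        )

    def test_peak_at_precursor_unassigned(self, acyl_library):
        s = Spectrum(level=2, peaks=(Peak(656.4882),), precursor_mz=656.4882)
        ann = match_neutral_losses(s, acyl_library)[0]
        assert ann.kind == "unassigned"
        assert "precursor" in ann.note

    def test_absolute_da_window(self, acyl_library):
        # a 0.004 Da deviation is ~14 ppm of the 282 loss: rejected at
        # 5 ppm-on-loss but accepted in a 10 mDa absolute window
        s = Spectrum(level=2, peaks=(Peak(374.2364),), precursor_mz=656.4882)
        strict = match_neutral_losses(s, acyl_library, tolerance_ppm=5.0)
        assert strict[0].kind == "unassigned"
        loose = match_neutral_losses(s, acyl_library, tolerance_da=0.010)
        assert loose[0].kind == "neutral_loss"

    def test_missing_precursor_rejected(self, acyl_library):
        s = Spectrum(level=1, peaks=(Peak(374.2364),))
        with pytest.raises(ValueError):
            match_neutral_losses(s, acyl_library)


class TestSulfonateSignature:
    def test_all_four_ions_found_with_printed_errors(self, sulfonate_spectrum):
        report = detect_sulfonate_signature(sulfonate_spectrum)
        assert report.present and report.n_hits == 4
        printed = {"SO3": 0.182, "HSO3": 4.194, "SO2": 12.506, "HSO2": 8.08}
        for ion, expected in printed.items():
            _peak, dev = report.hits[ion]
            assert round(abs(dev), 3 if ion != "HSO2" else 2) == expected

    def test_empty_spectrum_negative(self):
        s = Spectrum(level=3, peaks=(), precursor_mz=374.2364)
        report = detect_sulfonate_signature(s)
        assert report.n_hits == 0 and not report.present

    def test_single_ion_below_threshold(self):
        s = Spectrum(level=3, peaks=(Peak(79.9568),), precursor_mz=374.2364)
        report = detect_sulfonate_signature(s)
        assert report.n_hits == 1 and not report.present

    def test_positive_mode_rejected(self, sulfonate_spectrum):
        s = Spectrum(level=3, peaks=sulfonate_spectrum.peaks,
                     precursor_mz=374.2364, polarity="+")
        with pytest.raises(ValueError):
            detect_sulfonate_signature(s)


class TestHeadGroup:
    def test_aminosulfonate_is_top_plausible_candidate(self):
        s = Spectrum(level=3, peaks=(Peak(136.0045),), precursor_mz=374.2364)
        out = assign_head_group(s, (100.0, 200.0))
        top = out[136.0045][0]
        assert top.formula == {"C": 3, "H": 6, "N": 1, "O": 3, "S": 1}

    def test_phospho_head_excluding_ns_is_empty(self):
        s = Spectrum(level=3, peaks=(Peak(136.0045),), precursor_mz=374.2364)
        out = assign_head_group(
            s, (100.0, 200.0), must_contain={"P"}, must_not_contain={"N", "S"}
        )
        assert out[136.0045] == []

    def test_empty_window_empty_result(self):
        s = Spectrum(level=3, peaks=(Peak(136.0045),), precursor_mz=374.2364)
        assert assign_head_group(s, (300.0, 400.0)) == {}

    def test_plausibility_filters_can_be_disabled(self):
        s = Spectrum(level=3, peaks=(Peak(136.0045),), precursor_mz=374.2364)
        unfiltered = assign_head_group(
            s, (100.0, 200.0), even_electron=False, require_rdbe_nonneg=False
        )[136.0045]
        filtered = assign_head_group(s, (100.0, 200.0))[136.0045]
        assert len(unfiltered) > len(filtered)
        # unfiltered ranking is purely by |ppm|: a closer radical-composition
        # candidate outranks the chemically plausible aminosulfonate
        assert unfiltered[0].formula == {"C": 1, "H": 4, "N": 4, "O": 2, "S": 1}


class TestLabelCount:
    @pytest.mark.parametrize(
        "unlabeled, labeled, expected",
        [
            (656.4951, 657.4903, 1),
            (656.4951, 656.4951, 0),
            (656.4951, 658.4892, 2),
        ],
    )
    def test_shift_counts(self, unlabeled, labeled, expected):
        count, residual = infer_label_count(unlabeled, labeled)
        assert count == expected
        assert abs(residual) < 0.5

    def test_residual_reports_instrument_deviation(self):
        # the printed labelled mass sits 1.8 mDa below one exact 15N shift
        _count, residual = infer_label_count(656.4951, 657.4903)
        assert residual == pytest.approx(-0.0018, abs=2e-4)

    def test_negative_shift_rejected(self):
        with pytest.raises(ValueError):
            infer_label_count(657.0, 656.0)


class TestFragmentationTree:
    def test_two_level_tree_with_labeled_edge(self, acyl_library):
        ms2 = Spectrum(level=2, peaks=(Peak(374.2364), Peak(281.2480)),
                       precursor_mz=656.4882)
        ms3 = Spectrum(level=3, peaks=(Peak(136.0045), Peak(79.9568)),
                       precursor_mz=374.2364)
        tree = build_fragmentation_tree([ms2, ms3], library=acyl_library)
        assert (656.4882, 2) in tree.nodes and (374.2364, 3) in tree.nodes
        parent, child, loss, name = tree.edges[0]
        assert (parent, child) == (656.4882, 374.2364)
        assert name == "18:1 free acid"
        assert not tree.orphans

    def test_single_ms2_has_no_edges(self):
        ms2 = Spectrum(level=2, peaks=(Peak(374.2364),), precursor_mz=656.4882)
        tree = build_fragmentation_tree([ms2])
        assert tree.edges == [] and tree.orphans == []

    def test_unlinked_ms3_precursor_flagged_orphan(self):
        ms2 = Spectrum(level=2, peaks=(Peak(374.2364),), precursor_mz=656.4882)
        ms3 = Spectrum(level=3, peaks=(Peak(79.9568),), precursor_mz=500.0)
        tree = build_fragmentation_tree([ms2, ms3])
        assert tree.orphans == [500.0]


class TestStructureHypotheses:
    def _evidence(self, acyl_library, precursor=656.4882):
        ms2 = Spectrum(level=2, peaks=(Peak(precursor - 282.2518),),
                       precursor_mz=precursor)
        losses = match_neutral_losses(ms2, acyl_library)
        head_s = Spectrum(level=3, peaks=(Peak(136.0045),), precursor_mz=374.2364)
        heads = assign_head_group(head_s, (100.0, 200.0))[136.0045]
        return losses, heads

    def test_sal_hypothesis_mass_and_ppm(self, acyl_library):
        losses, heads = self._evidence(acyl_library)
        hyps = propose_structure(656.4882, losses, heads, nitrogen_count=1)
        sal = next(
            h for h in hyps
            if (h.amide_acyl.c, h.amide_acyl.d, h.amide_acyl.x) == (16, 0, 1)
            and (h.ester_acyl.c, h.ester_acyl.d, h.ester_acyl.x) == (18, 1, 0)
            and format_formula(h.head_group_neutral) == "C3H9NO3S"
        )
        assert format_formula(sal.total_deprotonated_formula) == "C37H70NO6S"
        assert sal.theoretical_mh_minus == pytest.approx(656.4924, abs=2e-4)
        assert abs(sal.ppm_vs_precursor) == pytest.approx(6.37, abs=0.05)
        assert sal.isomer_ambiguous

    def test_hydroxylated_variant_matches_printed_precursor(self):
        hyp = assemble_hypothesis(
            "C3H9NO3S", AcylSpec(16, 0, 1), AcylSpec(18, 1, 1), 672.4875
        )
        assert hyp.theoretical_mh_minus == pytest.approx(672.4873, abs=2e-4)
        assert hyp.ppm_vs_precursor == pytest.approx(0.30, abs=0.05)

    def test_nitrogen_count_zero_drops_nitrogen_heads(self, acyl_library):
        losses, heads = self._evidence(acyl_library)
        hyps = propose_structure(656.4882, losses, heads, nitrogen_count=0)
        assert hyps == []

    def test_mass_additivity_formula_vs_components(self, acyl_library):
        losses, heads = self._evidence(acyl_library)
        for hyp in propose_structure(656.4882, losses, heads, nitrogen_count=1):
            component_sum = (
                monoisotopic_mass(hyp.head_group_neutral)
                + hyp.amide_acyl.mass()
                + hyp.ester_acyl.mass()
                - 2 * monoisotopic_mass("H2O")
                - monoisotopic_mass("H")
            )
            assert abs(hyp.theoretical_mh_minus - component_sum) < 1e-6

    def test_head_ion_to_neutral_restores_hydrogens(self):
        # the 136.0045 fragment maps back to neutral homotaurine
        assert format_formula(head_ion_to_neutral("C3H6NO3S")) == "C3H9NO3S"

    def test_no_evidence_rejected(self, acyl_library):
        with pytest.raises(ValueError):
            propose_structure(656.4882, [], [])
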