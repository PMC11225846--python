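"""Target matching, intensity filtering and the two isotopic corrections."""

import numpy as np
import pytest

from hilipid.annotate_correct import (
    AnnotatedSpecies,
    annotate_and_correct,
    correct_type1,
    correct_type2,
    filter_by_intensity,
    match_targets,
)
from hilipid.errors import DataError
from hilipid.lipid_chem import (
    LipidClass,
    SumComposition,
    isotope_pattern,
    target_for,
)
from hilipid.spectra import ClassSpectrum


def make_spectrum(mz, intensity, polarity="positive"):
    order = np.argsort(mz)
    return ClassSpectrum(
        polarity=polarity, rt_window=(10.0, 11.0),
        mz=np.asarray(mz, float)[order], intensity=np.asarray(intensity, float)[order],
    )


def annotation(cls, c, d, raw, is_standard=False, deuterium=0):
    ion = target_for(SumComposition(cls, c, d), deuterium=deuterium,
                     is_internal_standard=is_standard)
    return AnnotatedSpecies(ion=ion, experimental_mz=ion.theoretical_mz,
                            raw_m0_intensity=raw)


PC = LipidClass.PC


class TestMatchTargets:
    def test_observed_pc320_peak_matches_within_tolerance(self):
        target = target_for(SumComposition(PC, 32, 0))
        spectrum = make_spectrum([734.5675], [1000.0])
        matches = match_targets(spectrum, [target])
        assert len(matches) == 1
        assert matches[0].delta_mz == pytest.approx(-0.0019, abs=1e-4)

    def test_peak_outside_tolerance_unmatched(self):
        target = target_for(SumComposition(PC, 32, 0))
        assert match_targets(make_spectrum([734.64], [1000.0]), [target]) == []

    def test_contested_peak_goes_to_nearer_target(self):
        t_near = target_for(SumComposition(PC, 32, 0))      # 734.5694
        t_far = target_for(SumComposition(PC, 31, 0))       # odd-C decoy nearby? use O-form
        spectrum = make_spectrum([734.5694 + 0.01], [100.0])
        matches = match_targets(spectrum, [t_far, t_near], tol_mz=0.05)
        labels = [m.species.label for m in matches]
        assert labels == ["PC 32:0"]

    def test_each_peak_serves_one_target(self):
        # two targets, one peak between them: only the nearer gets it
        t1 = target_for(SumComposition(PC, 32, 0))
        t2 = target_for(SumComposition(PC, 32, 1))
        spectrum = make_spectrum([t1.theoretical_mz - 0.001], [50.0])
        matches = match_targets(spectrum, [t1, t2])
        assert [m.species.label for m in matches] == ["PC 32:0"]


class TestIntensityFilter:
    def test_threshold_arithmetic(self):
        anns = [annotation(PC, 32, d, raw) for d, raw in ((0, 100.0), (1, 5.0), (2, 0.5))]
        kept = filter_by_intensity(anns)
        assert sorted(a.raw_m0_intensity for a in kept) == [5.0, 100.0]

    def test_internal_standard_always_retained(self):
        anns = [
            annotation(PC, 32, 0, 100.0),
            annotation(PC, 33, 1, 0.1, is_standard=True, deuterium=7),
        ]
        kept = filter_by_intensity(anns)
        assert any(a.is_internal_standard for a in kept)

    def test_equal_intensities_all_survive(self):
        anns = [annotation(PC, 32, d, 7.0) for d in range(3)]
        assert len(filter_by_intensity(anns)) == 3

    def test_no_endogenous_rejected(self):
        anns = [annotation(PC, 33, 1, 1.0, is_standard=True, deuterium=7)]
        with pytest.raises(DataError, match="endogenous"):
            filter_by_intensity(anns)


def forward_m0(totals: dict[int, float], cls=PC, c=32) -> dict[int, float]:
    """Observed M+0 per D when each species' M+2 lands on its D-1 neighbour."""
    observed = {}
    for d, total in totals.items():
        pattern = isotope_pattern(target_for(SumComposition(cls, c, d)).formula)
        observed[d] = observed.get(d, 0.0) + total * pattern.f0
        if d - 1 in totals:
            observed[d - 1] = observed.get(d - 1, 0.0) + total * pattern.f(2)
    return observed


class TestTypeTwoCorrection:
    def test_single_species_untouched(self):
        a = annotation(PC, 32, 0, 123.0)
        correct_type2([a])
        assert a.type2_corrected_m0_intensity == 123.0

    def test_pair_round_trip(self):
        """PC 32:1 (total 100) + PC 32:0 (total 50): correction recovers 50*f0."""
        totals = {1: 100.0, 0: 50.0}
        observed = forward_m0(totals)
        anns = [annotation(PC, 32, d, observed[d]) for d in (1, 0)]
        correct_type2(anns)
        f0_320 = isotope_pattern(target_for(SumComposition(PC, 32, 0)).formula).f0
        corrected = next(a for a in anns if a.species.double_bonds == 0)
        assert corrected.type2_corrected_m0_intensity == pytest.approx(
            50.0 * f0_320, rel=1e-9)

    def test_three_member_cascade(self):
        totals = {2: 80.0, 1: 40.0, 0: 20.0}
        observed = forward_m0(totals)
        anns = [annotation(PC, 32, d, observed[d]) for d in totals]
        correct_type2(anns)
        for a in anns:
            f0 = a.pattern.f0
            assert a.type2_corrected_m0_intensity == pytest.approx(
                totals[a.species.double_bonds] * f0, rel=1e-9)

    def test_gap_in_d_does_not_interfere(self):
        anns = [annotation(PC, 32, 2, 100.0), annotation(PC, 32, 0, 10.0)]
        correct_type2(anns)
        assert anns[1].type2_corrected_m0_intensity == 10.0

    def test_never_increases_and_non_negative(self):
        rng = np.random.default_rng(3)
        anns = [annotation(PC, 34, d, float(r)) for d, r in
                enumerate(rng.uniform(0, 100, 6))]
        correct_type2(anns)
        for a in anns:
            assert 0.0 <= a.type2_corrected_m0_intensity <= a.raw_m0_intensity

    def test_cascade_causality(self):
        """Removing the most unsaturated member leaves higher-D members alone."""
        totals = {3: 50.0, 2: 30.0, 1: 20.0}
        observed = forward_m0(totals)
        full = [annotation(PC, 36, d, observed[d]) for d in (3, 2, 1)]
        correct_type2(full)
        partial = [annotation(PC, 36, d, observed[d]) for d in (3, 2)]
        correct_type2(partial)
        for a_partial in partial:
            a_full = next(a for a in full
                          if a.species.double_bonds == a_partial.species.double_bonds)
            assert a_partial.type2_corrected_m0_intensity == pytest.approx(
                a_full.type2_corrected_m0_intensity, rel=1e-12)

    def test_duplicate_species_rejected(self):
        anns = [annotation(PC, 32, 1, 10.0), annotation(PC, 32, 1, 20.0)]
        with pytest.raises(DataError, match="duplicate"):
            correct_type2(anns)

    def test_overcorrection_clamps_to_zero(self):
        anns = [annotation(PC, 32, 1, 1000.0), annotation(PC, 32, 0, 1.0)]
        correct_type2(anns)
        assert anns[1].type2_corrected_m0_intensity == 0.0


class TestTypeOneCorrection:
    def test_divides_by_monoisotopic_fraction(self):
        a = annotation(PC, 32, 0, 1000.0)
        a.type2_corrected_m0_intensity = 1000.0
        correct_type1([a])
        f0 = a.pattern.f0
        assert a.type1_corrected_total_intensity == pytest.approx(1000.0 / f0)
        assert a.type1_corrected_total_intensity >= a.type2_corrected_m0_intensity

    def test_against_enumeration_oracle(self, oracle_pattern):
        a = annotation(PC, 32, 0, 1000.0)
        a.type2_corrected_m0_intensity = 1000.0
        correct_type1([a])
        f0_oracle = oracle_pattern(a.ion.formula)[0]
        assert a.type1_corrected_total_intensity == pytest.approx(
            1000.0 / f0_oracle, rel=1e-6)

    def test_requires_type_two_first(self):
        with pytest.raises(DataError, match="type-II"):
            correct_type1([annotation(PC, 32, 0, 10.0)])


class TestEndToEndConservation:
    def test_noise_free_delta_d_series_recovered(self):
        """Forward-rendered averaged spectrum -> annotate chain recovers totals."""
        from hilipid.lipid_chem import isotopologue_mz

        totals = {d: v for d, v in zip(range(5), (500.0, 400.0, 250.0, 120.0, 60.0))}
        peaks: dict[float, float] = {}
        for d, total in totals.items():
            ion = target_for(SumComposition(PC, 34, d))
            pattern = isotope_pattern(ion.formula)
            for k, f in enumerate(pattern.fractions):
                mz = isotopologue_mz(ion, k)
                # the +2 Da isotopologue coincides with the D-1 monoisotopic
                # peak after averaging: emulate the merge by snapping
                if d - 1 in totals and k == 2:
                    mz = isotopologue_mz(target_for(SumComposition(PC, 34, d - 1)), 0)
                peaks[mz] = peaks.get(mz, 0.0) + total * f
        spectrum = make_spectrum(list(peaks), list(peaks.values()))
        targets = [target_for(SumComposition(PC, 34, d)) for d in totals]
        anns = annotate_and_correct(spectrum, targets, threshold_fraction=0.01)
        assert len(anns) == len(totals)
        for a in anns:
            assert a.type1_corrected_total_intensity == pytest.approx(
                totals[a.species.double_bonds], rel=5e-3)
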