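"""Ground-truth generation and instrument rendering of the forward model."""

import numpy as np
import pytest

from hilipid.errors import ConfigError
from hilipid.lipid_chem import DIAGNOSTIC_IONS, LipidClass, SumComposition, target_for, isotope_pattern
from hilipid.quantify import CellLine, SampleRecord
from hilipid.spectra import average_spectrum, detect_class_band
from hilipid.synthetic_data import (
    DEFAULT_APEX_RT,
    EffectConfig,
    InstrumentModel,
    line_template,
    simulate_lipidome,
    simulate_run,
)


def noise_free(design, seed=0):
    return simulate_lipidome(design, cv_biological=0.0, cv_extraction=0.0,
                             scale_cv=0.0, seed=seed)


QUIET = InstrumentModel(run_calibration_ppm=0.0, scan_drift_ppm=0.0,
                        centroid_jitter_ppm=0.0, intensity_cv=0.0)


class TestLipidomeGeneration:
    def test_zero_noise_replicates_identical(self):
        design = [SampleRecord(CellLine.WT, b, e) for b in (1, 2, 3) for e in (1, 2)]
        lipidomes = noise_free(design)
        reference = lipidomes[design[0]].concentrations
        for rec in design[1:]:
            assert lipidomes[rec].concentrations == reference

    def test_cl72_exclusive_to_wt(self):
        for line in (CellLine.OPA1_KO, CellLine.MFN12_KO):
            template = line_template(line)
            assert not any(
                sp.lipid_class is LipidClass.CL and sp.carbons == 72 for sp in template)
        assert any(sp.lipid_class is LipidClass.CL and sp.carbons == 72
                   for sp in line_template(CellLine.WT))

    def test_planted_ether_ordering_in_every_noise_free_sample(self):
        design = [SampleRecord(line, 1, 1) for line in CellLine]
        lipidomes = noise_free(design)
        ratios = {rec.cell_line: lipidomes[rec].ratios()["PE O/PE"] for rec in design}
        assert ratios[CellLine.WT] > ratios[CellLine.OPA1_KO] > ratios[CellLine.MFN12_KO]

    def test_planted_class_ratios_exact_without_noise(self):
        rec = SampleRecord(CellLine.WT, 1, 1)
        ratios = noise_free([rec])[rec].ratios()
        effects = EffectConfig()
        assert ratios["CL/PC"] == pytest.approx(effects.cl_to_pc[CellLine.WT], rel=1e-12)
        assert ratios["PE O/PE"] == pytest.approx(
            effects.pe_ether_ratio[CellLine.WT], rel=1e-12)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ConfigError):
            EffectConfig(cl_to_pc={line: -0.1 for line in CellLine})

    def test_seed_subsetting_consistency(self):
        """A subset design reproduces the matching samples of the full design."""
        full = [SampleRecord(CellLine.WT, b, e) for b in (1, 2) for e in (1, 2)]
        sub = [full[3]]
        a = simulate_lipidome(full, seed=5)[full[3]]
        b = simulate_lipidome(sub, seed=5)[full[3]]
        assert a.concentrations == b.concentrations


class TestInstrumentModel:
    def test_elution_order_enforced(self):
        apexes = dict(DEFAULT_APEX_RT)
        apexes[LipidClass.PI], apexes[LipidClass.PC] = (
            apexes[LipidClass.PC], apexes[LipidClass.PI])
        with pytest.raises(ConfigError, match="elution order"):
            InstrumentModel(apex_rt=apexes)

    def test_mass_error_envelope_enforced(self):
        with pytest.raises(ConfigError, match="5 ppm"):
            InstrumentModel(run_calibration_ppm=6.0)


class TestRunRendering:
    def test_bit_identical_given_seed(self):
        rec = SampleRecord(CellLine.WT, 1, 1)
        truth = simulate_lipidome([rec], seed=2)[rec]
        a = simulate_run(truth, polarity="negative", seed=99)
        b = simulate_run(truth, polarity="negative", seed=99)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.mz, sb.mz)
            np.testing.assert_array_equal(sa.intensity, sb.intensity)

    def test_full_and_aif_scans_interleaved(self):
        rec = SampleRecord(CellLine.WT, 1, 1)
        truth = noise_free([rec])[rec]
        scans = simulate_run(truth, QUIET, polarity="positive", seed=0)
        levels = {s.level for s in scans}
        assert levels == {"full_scan", "AIF"}

    def test_delta_d_pair_creates_m2_interference(self):
        """Rendered M+0 of the D-1 member is inflated by the D member's M+2."""
        rec = SampleRecord(CellLine.WT, 1, 1)
        sp_hi = SumComposition(LipidClass.PC, 32, 1)
        sp_lo = SumComposition(LipidClass.PC, 32, 0)
        truth = noise_free([rec])[rec]
        truth.concentrations = {sp_hi: 10.0, sp_lo: 5.0}
        scans = simulate_run(truth, QUIET, polarity="positive", seed=0)
        full = [s for s in scans if s.level == "full_scan"]
        window = (DEFAULT_APEX_RT[LipidClass.PC] - 0.3, DEFAULT_APEX_RT[LipidClass.PC] + 0.3)
        avg = average_spectrum(full, window, "positive")
        ion_lo = target_for(sp_lo)
        idx = int(np.argmin(np.abs(avg.mz - ion_lo.theoretical_mz)))
        observed_m0 = avg.intensity[idx]
        pat_hi = isotope_pattern(target_for(sp_hi).formula)
        pat_lo = isotope_pattern(ion_lo.formula)
        # expected inflation ratio: (5 f0_lo + 10 f2_hi) / (5 f0_lo)
        expected_ratio = (5.0 * pat_lo.f0 + 10.0 * pat_hi.f(2)) / (5.0 * pat_lo.f0)
        ratio = observed_m0 / (avg.intensity.max() / (10.0 * pat_hi.f0) * 5.0 * pat_lo.f0)
        assert ratio == pytest.approx(expected_ratio, rel=1e-3)

    def test_band_recovered_within_one_scan_interval(self):
        """Band detection brackets the generating apex at zero noise."""
        rec = SampleRecord(CellLine.WT, 1, 1)
        truth = noise_free([rec])[rec]
        scans = simulate_run(truth, QUIET, polarity="negative", seed=0)
        aif = [s for s in scans if s.level == "AIF"]
        lo, hi = detect_class_band(aif, DIAGNOSTIC_IONS[LipidClass.PI])
        apex = DEFAULT_APEX_RT[LipidClass.PI]
        width = QUIET.band_sigma_min * np.sqrt(2 * np.log(20))
        assert lo == pytest.approx(apex - width, abs=QUIET.full_scan_interval_min)
        assert hi == pytest.approx(apex + width, abs=QUIET.full_scan_interval_min)

    def test_noise_free_render_round_trip(self):
        """Full renderer -> annotate chain recovers the quantities downstream
        stages consume: subclass totals within 3% and most species tightly.

        Two honest residuals keep this looser than the ΔD-series round trip:
        merged M+4 isotopologues of the D+2 neighbour (not removed by the
        M+0/M+2-only correction) and occasional isotopologue peaks annotated
        as absent species under the 0.05 m/z tolerance, whose type-II term
        then over-corrects the ΔD=1 neighbour.
        """
        from hilipid.annotate_correct import annotate_and_correct
        from hilipid.lipid_chem import generate_target_list

        rec = SampleRecord(CellLine.WT, 1, 1)
        truth = noise_free([rec])[rec]
        targets = generate_target_list()
        for family, polarity in ((LipidClass.PC, "positive"), (LipidClass.PI, "negative")):
            scans = simulate_run(truth, QUIET, polarity, seed=0)
            full = [s for s in scans if s.level == "full_scan"]
            apexes = [DEFAULT_APEX_RT[c] for c in LipidClass
                      if c.family is family and c in DEFAULT_APEX_RT]
            window = (min(apexes) - 0.5, max(apexes) + 0.5)
            avg = average_spectrum(full, window, polarity)
            fam_targets = [t for t in targets if t.species.lipid_class.family is family]
            anns = annotate_and_correct(avg, fam_targets)
            is_ann = next(a for a in anns if a.is_internal_standard)
            scale = QUIET.spike_ug_ml / is_ann.type1_corrected_total_intensity
            errors, totals_rec, totals_true = [], {}, {}
            for a in anns:
                if a.is_internal_standard:
                    continue
                recovered = a.type1_corrected_total_intensity * scale
                sub = a.species.lipid_class
                totals_rec[sub] = totals_rec.get(sub, 0.0) + recovered
                planted = truth.concentrations.get(a.species)
                if planted is not None:
                    errors.append(abs(recovered / planted - 1))
            for sp, conc in truth.concentrations.items():
                if sp.lipid_class.family is family:
                    totals_true[sp.lipid_class] = totals_true.get(sp.lipid_class, 0.0) + conc
            for sub, true_total in totals_true.items():
                assert totals_rec[sub] == pytest.approx(true_total, rel=0.03), sub.value
            errors = np.sort(errors)
            assert np.median(errors) < 0.02
            assert (errors < 0.05).mean() >= 0.8

    def test_internal_standards_rendered_in_every_run(self):
        rec = SampleRecord(CellLine.MFN12_KO, 2, 2)
        truth = noise_free([rec])[rec]
        scans = simulate_run(truth, QUIET, polarity="negative", seed=1)
        full = [s for s in scans if s.level == "full_scan"]
        cl_is = target_for(SumComposition(LipidClass.CL, 56, 0))
        found = any(np.any(np.abs(s.mz - cl_is.theoretical_mz) < 0.01) for s in full)
        assert found
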