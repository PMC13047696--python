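import base64
import random
import zlib

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dimerpop.constants import ELECTRON_MASS_DA
from dimerpop.ms_adducts import (
    AdductSpec,
    FormulaError,
    adduct_mz,
    annotate_peaks,
    monoisotopic_mass,
    nominal_mass,
    parse_formula,
    read_peaklist_mzml,
    read_peaklist_text,
    write_peaklist_text,
)
from dimerpop.synthetic_data import GeneratorConfig, make_peaklist


class TestMasses:
    @pytest.mark.parametrize("formula,expected", [
        ("C21H30O2", 314.2246),   # the shared cannabinoid-isomer formula
        ("H2O", 18.0106),         # hand sum 2*1.007825 + 15.994915
        ("C42H61O4", 629.4570),
    ])
    def test_monoisotopic_to_four_decimals(self, formula, expected):
        assert round(monoisotopic_mass(formula), 4) == expected

    def test_empty_formula_is_zero(self):
        assert monoisotopic_mass("") == 0.0

    def test_agrees_with_independent_mass_library(self):
        from pyteomics import mass as pt_mass
        for f in ("C21H30O2", "C42H61O4", "H2O", "C6H9NO2S"):
            assert monoisotopic_mass(f) == pytest.approx(
                pt_mass.calculate_mass(formula=f), abs=5e-5)

    @pytest.mark.parametrize("formula,expected", [
        ("C42H60O4", 628), ("C21H30O2", 314), ("H", 1),
    ])
    def test_nominal_masses(self, formula, expected):
        assert nominal_mass(formula) == expected

    def test_unknown_element_rejected(self):
        with pytest.raises(FormulaError, match="Xx"):
            monoisotopic_mass("C2Xx")

    def test_malformed_formula_rejected(self):
        with pytest.raises(FormulaError):
            parse_formula("c21h30")

    @given(st.dictionaries(st.sampled_from(["C", "H", "N", "O", "S"]),
                           st.integers(1, 40), min_size=1))
    def test_mass_additivity_over_elements(self, counts):
        total = sum(n * monoisotopic_mass(el) for el, n in counts.items())
        assert monoisotopic_mass(counts) == pytest.approx(total, abs=1e-9)


class TestAdductMz:
    def test_protonated_monomer_printed_value(self):
        assert round(adduct_mz("C21H30O2", "[M+H]+"), 4) == 315.2324

    def test_proton_bound_dimer_value(self):
        # 2 x 314.2246 + 1.0078, printed as nominal m/z 629
        assert round(adduct_mz("C21H30O2", "[2M+H]+"), 4) == 629.4570
        assert nominal_mass("C42H61O4") == 629

    def test_radical_dimer_is_twice_the_monomer(self):
        assert adduct_mz("C21H30O2", "[2M]+.") == pytest.approx(
            2 * monoisotopic_mass("C21H30O2"), abs=1e-12)

    def test_internal_consistency_identity(self):
        m = monoisotopic_mass("C21H30O2")
        lhs = adduct_mz("C21H30O2", "[2M+H]+")
        rhs = 2 * m + adduct_mz("C21H30O2", "[M+H]+") - m
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_proton_convention_subtracts_electron_mass(self):
        strict = AdductSpec("[M+H]+p", 1, "H", electron_convention="proton")
        assert adduct_mz("C21H30O2", strict) == pytest.approx(
            adduct_mz("C21H30O2", "[M+H]+") - ELECTRON_MASS_DA, abs=1e-12)

    def test_multiply_charged_rejected(self):
        with pytest.raises(ValueError, match="singly charged"):
            AdductSpec("[M+2H]2+", 1, "H2", charge=2)


class TestAnnotation:
    CANDIDATES = (["C21H30O2"], ["[M+H]+", "[2M+H]+", "[2M]+."])

    def test_planted_adducts_recovered(self):
        peaks = [(adduct_mz("C21H30O2", "[M+H]+"), 1e6),
                 (adduct_mz("C21H30O2", "[2M+H]+"), 5e3)]
        ann, unmatched = annotate_peaks(peaks, *self.CANDIDATES, tol_ppm=5)
        assert [a.adduct for a in ann] == ["[M+H]+", "[2M+H]+"]
        assert unmatched == []

    def test_peak_outside_window_unmatched(self):
        ann, unmatched = annotate_peaks([(315.40, 1.0)], *self.CANDIDATES, tol_ppm=5)
        assert ann == [] and len(unmatched) == 1

    def test_trace_dimer_relative_intensity(self):
        """Base peak 1e6 and a dimer peak at 7e3 -> 0.7% relative intensity."""
        peaks = [(adduct_mz("C21H30O2", "[M+H]+"), 1.0e6),
                 (adduct_mz("C21H30O2", "[2M+H]+"), 7.0e3)]
        ann, _ = annotate_peaks(peaks, *self.CANDIDATES, tol_ppm=5)
        dimer = next(a for a in ann if a.adduct == "[2M+H]+")
        assert dimer.relative_intensity == pytest.approx(0.7)

    def test_ppm_sign_convention(self):
        calc = adduct_mz("C21H30O2", "[M+H]+")
        high = calc * (1 + 3e-6)
        ann, _ = annotate_peaks([(high, 1.0)], *self.CANDIDATES, tol_ppm=5)
        assert ann[0].error_ppm == pytest.approx(3.0, abs=1e-6)
        low = calc * (1 - 3e-6)
        ann, _ = annotate_peaks([(low, 1.0)], *self.CANDIDATES, tol_ppm=5)
        assert ann[0].error_ppm == pytest.approx(-3.0, abs=1e-6)

    def test_permutation_invariance(self):
        cfg = GeneratorConfig(seed=41, noise_peaks=8)
        peaks, _ = make_peaklist("C21H30O2",
                                 {"[M+H]+": 100.0, "[2M+H]+": 0.5}, cfg)
        ref_ann, ref_un = annotate_peaks(peaks, *self.CANDIDATES, tol_ppm=5)
        rng = random.Random(0)
        for _ in range(3):
            shuffled = peaks[:]
            rng.shuffle(shuffled)
            ann, un = annotate_peaks(shuffled, *self.CANDIDATES, tol_ppm=5)
            assert ann == ref_ann and sorted(un) == sorted(ref_un)

    def test_empty_peak_list_is_not_an_error(self):
        assert annotate_peaks([], *self.CANDIDATES) == ([], [])

    def test_generator_round_trip_no_false_positives(self):
        cfg = GeneratorConfig(seed=43, mz_jitter_ppm=2.0, noise_peaks=10)
        planted_spec = {"[M+H]+": 100.0, "[2M+H]+": 0.5}
        peaks, planted = make_peaklist("C21H30O2", planted_spec, cfg)
        ann, _ = annotate_peaks(peaks, *self.CANDIDATES, tol_ppm=5)
        assert sorted(a.adduct for a in ann) == sorted(planted_spec)

    def test_jitter_beyond_tolerance_unmatched(self):
        cfg = GeneratorConfig(seed=44, mz_jitter_ppm=20.0, noise_peaks=0)
        # jitter is uniform in [-20, +20] ppm; seed chosen arbitrarily, so
        # only assert that any recovered peak is within tolerance
        peaks, _ = make_peaklist("C21H30O2", {"[M+H]+": 100.0}, cfg)
        ann, unmatched = annotate_peaks(peaks, *self.CANDIDATES, tol_ppm=5)
        assert all(abs(a.error_ppm) <= 5 for a in ann)
        assert len(ann) + len(unmatched) == len(peaks)


class TestPeakListIO:
    def test_text_round_trip(self):
        peaks = [(315.2324, 1e6), (629.4570, 7e3)]
        text = write_peaklist_text(peaks)
        assert read_peaklist_text(text) == peaks

    def test_comment_and_csv_forms(self):
        assert read_peaklist_text("# header\n100.5, 20\n200.25\t30\n") == [
            (100.5, 20.0), (200.25, 30.0)]

    def test_minimal_mzml(self, tmp_path):
        mz = np.array([315.2324, 629.4570], dtype="<f8")
        inten = np.array([1e6, 7e3], dtype="<f4")
        raw_mz = base64.b64encode(zlib.compress(mz.tobytes())).decode()
        raw_in = base64.b64encode(inten.tobytes()).decode()
        doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
 <run id="r"><spectrumList count="1">
  <spectrum index="0" id="scan=1" defaultArrayLength="2">
   <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
   <binaryDataArrayList count="2">
    <binaryDataArray><cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
     <cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>
     <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
     <binary>{raw_mz}</binary></binaryDataArray>
    <binaryDataArray><cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>
     <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
     <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
     <binary>{raw_in}</binary></binaryDataArray>
   </binaryDataArrayList>
  </spectrum>
 </spectrumList></run>
</mzML>"""
        path = tmp_path / "synthetic_two_peaks.mzML"
        path.write_text(doc)
        peaks = read_peaklist_mzml(path)
        assert peaks[0][0] == pytest.approx(315.2324)
        assert peaks[1][1] == pytest.approx(7e3, rel=1e-6)
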