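"""Wide/tight assignment, calibration-point pooling and the error-curve fit."""

import numpy as np
import pytest

from mscurate.chem import formula_ion_mz, ion_formula, parse_adduct, parse_formula
from mscurate.io import Fragment, Ms2Spectrum, SpectrumType
from mscurate.recalibration import (
    CalibrationPoint,
    apply_recalibration,
    assign_wide,
    collect_calibration_points,
    fit_recal_curve,
    identity_model,
    reassign_tight,
    wide_tolerance,
)
from tests.test_io import make_scan


def spectrum_with_peaks(peaks, polarity="pos", cid="C1"):
    mz = [p[0] for p in peaks]
    inten = [p[1] for p in peaks]
    scan = make_scan(mz=tuple(mz), intensity=tuple(inten), polarity=polarity)
    stype = SpectrumType(polarity, 30.0, "auto")
    return Ms2Spectrum.from_scan(scan, stype, cid)


GLUCOSE_POOL = ion_formula(parse_formula("C6H12O6"), parse_adduct("[M+H]+"))


class TestWideAssignment:
    def test_tiered_tolerance_boundary(self):
        assert wide_tolerance(120.0) == 15.0  # boundary is in the low-mass tier
        assert wide_tolerance(120.001) == 10.0
        assert wide_tolerance(60.0) == 15.0

    def test_assignment_respects_tier(self):
        # plant peaks offset by 12 ppm: accepted below the boundary, not above
        low_true = formula_ion_mz({"C": 3, "H": 7, "O": 3}, "pos")   # ~91
        high_true = formula_ion_mz({"C": 6, "H": 13, "O": 6}, "pos")  # ~181
        spec = spectrum_with_peaks([
            (low_true * (1 + 12e-6), 100.0),
            (high_true * (1 + 12e-6), 100.0),
        ])
        assign_wide(spec, GLUCOSE_POOL)
        low_frag = min(spec.fragments, key=lambda f: f.mz)
        high_frag = max(spec.fragments, key=lambda f: f.mz)
        assert any(c.counts == {"C": 3, "H": 7, "O": 3} for c in low_frag.candidates)
        assert not any(c.counts == {"C": 6, "H": 13, "O": 6} for c in high_frag.candidates)


class TestCalibrationPoints:
    def test_unique_and_intense_only(self):
        mz_true = formula_ion_mz({"C": 6, "H": 13, "O": 6}, "pos")
        spec = spectrum_with_peaks([
            (mz_true, 999.0),       # unique but below intensity floor
            (mz_true + 30.0, 5000.0),  # no candidate at all
        ])
        assign_wide(spec, GLUCOSE_POOL)
        assert collect_calibration_points([spec]) == []

    def test_intensity_floor_is_inclusive(self):
        mz_true = formula_ion_mz({"C": 6, "H": 13, "O": 6}, "pos")
        for intensity, expected in [(999.0, 0), (1000.0, 1)]:
            spec = spectrum_with_peaks([(mz_true, intensity)])
            assign_wide(spec, GLUCOSE_POOL)
            assert len(collect_calibration_points([spec])) == expected

    def test_multiply_assigned_fragments_excluded(self, default_run):
        params, scans, truth = default_run
        # on the dense peptide pool most mid-mass fragments are ambiguous
        from mscurate.io import extract_compound_spectra
        from mscurate.synth import compound_metadata

        entry = [e for e in compound_metadata(params) if e.compound_id == "SYN-003"][0]
        grouped = extract_compound_spectra(scans, entry)
        pool = ion_formula(entry.formula, entry.ions[0])
        specs = [s for st, v in grouped.items() if st.polarity == "pos" for s in v]
        for s in specs[:5]:
            assign_wide(s, pool)
        points = collect_calibration_points(specs[:5])
        for p in points:
            src = next(s for s in specs[:5] if s.spectrum_id == p.spectrum_id)
            frag = next(f for f in src.fragments if f.mz == p.mz)
            assert len(frag.candidates) == 1
            assert frag.intensity >= 1e3


class TestCurveFit:
    def test_constant_field_recovered(self):
        pts = [CalibrationPoint(mz, 8.0, 1e4, "s") for mz in np.linspace(100, 900, 40)]
        model = fit_recal_curve(pts, "pos")
        grid = np.linspace(100, 900, 50)
        assert np.max(np.abs(model.predict_ppm(grid) - 8.0)) < 0.1

    def test_no_points_gives_identity(self):
        model = fit_recal_curve([], "neg")
        assert model.method == "identity"
        assert np.all(model.predict_ppm([100.0, 500.0]) == 0.0)

    def test_few_points_gives_constant_median(self):
        pts = [CalibrationPoint(m, e, 1e4, "s") for m, e in
               [(100, 2.0), (200, 3.0), (300, 4.0)]]
        model = fit_recal_curve(pts, "pos", min_points=10)
        assert model.method == "constant-median"
        assert model.predict_ppm([500.0])[0] == pytest.approx(3.0)

    def test_planted_linear_field_recovered_within_1ppm(self):
        rng = np.random.default_rng(11)
        mzs = rng.uniform(100, 900, 200)
        ppm = 2.0 + 0.01 * (mzs - 100.0) + rng.normal(0, 0.5, 200)
        pts = [CalibrationPoint(m, e, 1e4, "s") for m, e in zip(mzs, ppm)]
        model = fit_recal_curve(pts, "pos")
        grid = np.linspace(mzs.min(), mzs.max(), 200)
        planted = 2.0 + 0.01 * (grid - 100.0)
        assert np.max(np.abs(model.predict_ppm(grid) - planted)) < 1.0

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(3)
        pts = [CalibrationPoint(float(m), float(e), 1e4, "s")
               for m, e in zip(rng.uniform(100, 900, 50), rng.normal(5, 1, 50))]
        m1 = fit_recal_curve(pts, "pos")
        m2 = fit_recal_curve(list(pts), "pos")
        grid = np.linspace(100, 900, 77)
        np.testing.assert_array_equal(m1.predict_ppm(grid), m2.predict_ppm(grid))


class TestApplyRecalibration:
    def test_identity_model_is_identity(self):
        spec = spectrum_with_peaks([(100.0, 1.0), (500.0, 2.0)])
        before = [f.mz for f in spec.fragments]
        apply_recalibration(spec, identity_model("pos"))
        assert [f.mz for f in spec.fragments] == before

    def test_constant_offset_corrected(self):
        spec = spectrum_with_peaks([(500.0050, 10.0)])
        model = fit_recal_curve(
            [CalibrationPoint(m, 10.0, 1e4, "s") for m in np.linspace(100, 900, 30)],
            "pos",
        )
        apply_recalibration(spec, model)
        assert spec.fragments[0].mz == pytest.approx(500.0, abs=1e-5)
        assert spec.fragments[0].raw_mz == 500.0050  # provenance kept

    def test_polarity_mismatch_rejected(self):
        spec = spectrum_with_peaks([(100.0, 1.0)], polarity="neg")
        with pytest.raises(ValueError, match="polarity"):
            apply_recalibration(spec, identity_model("pos"))


class TestTightReassignment:
    def test_exact_5ppm_excluded_strictly(self):
        mz_true = formula_ion_mz({"C": 6, "H": 13, "O": 6}, "pos")
        spec = spectrum_with_peaks([(mz_true * (1 + 5.0e-6), 1.0)])
        reassign_tight(spec, GLUCOSE_POOL, tol_ppm=5.0)
        assert spec.fragments[0].assignment is None

    def test_small_error_assigned(self):
        mz_true = formula_ion_mz({"C": 6, "H": 13, "O": 6}, "pos")
        spec = spectrum_with_peaks([(mz_true * (1 + 1.0e-6), 1.0)])
        reassign_tight(spec, GLUCOSE_POOL)
        assert spec.fragments[0].assignment is not None
        assert abs(spec.fragments[0].assignment.ppm) < 5.0

    def test_gas_adduct_rescue_flagged(self):
        target = formula_ion_mz({"C": 6, "H": 13, "O": 6, "N": 2}, "pos")
        spec = spectrum_with_peaks([(target, 1.0)])
        reassign_tight(spec, GLUCOSE_POOL)
        frag = spec.fragments[0]
        assert frag.assignment is not None
        assert frag.assignment.gas_adduct == "N2"

    def test_wide_candidates_discarded(self):
        mz_true = formula_ion_mz({"C": 6, "H": 13, "O": 6}, "pos")
        spec = spectrum_with_peaks([(mz_true * (1 + 8e-6), 1.0)])
        assign_wide(spec, GLUCOSE_POOL)
        assert spec.fragments[0].candidates  # wide hit at 8 ppm
        reassign_tight(spec, GLUCOSE_POOL)
        assert spec.fragments[0].assignment is None


class TestPipelineRecovery:
    def test_planted_drift_recovered_on_benchmark(self, default_curation):
        """After recalibration with the fitted per-polarity models, at least
        95% of planted true fragments reassign at < 5 ppm."""
        params, scans, truth, result = default_curation
        total = assigned = 0
        for comp in result.compounds:
            for spec in comp.spectra:
                for frag in spec.fragments:
                    row = truth.lookup(frag.scan_id, frag.raw_mz)
                    if row is None or row["label"] != "true_fragment":
                        continue
                    total += 1
                    if frag.assignment is not None and abs(frag.assignment.ppm) < 5.0:
                        assigned += 1
        assert total > 1000
        assert assigned / total >= 0.95

    def test_median_abs_error_decreases_after_recalibration(self, default_curation):
        params, scans, truth, result = default_curation
        raw_err, cal_err = [], []
        for comp in result.compounds:
            for spec in comp.spectra:
                for frag in spec.fragments:
                    row = truth.lookup(frag.scan_id, frag.raw_mz)
                    if row is None or row["label"] != "true_fragment":
                        continue
                    if not np.isfinite(row["ppm_planted"]):
                        continue
                    raw_err.append(abs(row["ppm_planted"]))
                    theo = frag.raw_mz / (1 + row["ppm_planted"] / 1e6)
                    cal_err.append(abs((frag.mz - theo) / theo * 1e6))
        assert np.median(cal_err) < np.median(raw_err)
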