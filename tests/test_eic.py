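"""EIC extraction, co-elution scoring, cutoff selection, categorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscurate.eic import (
    CutoffResult,
    EicTrace,
    categorize_fragments,
    correlate_traces,
    determine_cutoff,
    extract_eic,
    f_beta,
)
from mscurate.io import Fragment, Ms2Spectrum, SpectrumType
from tests.test_io import make_scan


def trace(rts, intens, mz=100.0, ms_level=2):
    return EicTrace(mz, 10.0, ms_level, np.array(rts, float), np.array(intens, float))


class TestExtractEic:
    def test_apex_matches_planted_rt(self, small_run):
        params, scans, _ = small_run
        spec = params.compounds[0]
        from mscurate.chem import ion_mz, parse_adduct, parse_formula

        pmz = ion_mz(parse_formula(spec.formula), parse_adduct("[M+H]+"))
        pos_ms1 = [s for s in scans if s.polarity == "pos"]
        t = extract_eic(pos_ms1, pmz, 25.0, ms_level=1)
        apex_rt = t.rt[np.argmax(t.intensity)]
        assert abs(apex_rt - spec.rt) <= params.grid.ms1_interval

    def test_absent_mz_gives_all_zero_trace(self, small_run):
        _, scans, _ = small_run
        t = extract_eic([s for s in scans if s.ms_level == 1], 999.77, 5.0, ms_level=1)
        assert len(t.rt) > 0
        assert np.all(t.intensity == 0.0)

    def test_type_restriction_filters_scans(self, small_run):
        _, scans, _ = small_run
        stype = SpectrumType("pos", 40.0, "fixed40")
        t = extract_eic(scans, 100.0, 10.0, ms_level=2, restrict_type=stype)
        from mscurate.io import classify_spectrum_type

        allowed = {s.rt for s in scans if s.ms_level == 2
                   and classify_spectrum_type(s) == stype}
        assert set(t.rt) <= allowed

    def test_empty_scan_list(self):
        t = extract_eic([], 100.0, 10.0)
        assert len(t.rt) == 0


class TestCorrelate:
    def test_proportional_traces_score_one(self):
        p = trace([1, 2, 3, 4], [10, 40, 40, 10], ms_level=1)
        f = trace([1, 2, 3, 4], [3, 12, 12, 3])
        assert correlate_traces(f, p).score == pytest.approx(1.0)

    def test_disjoint_supports_score_zero(self):
        p = trace([1, 2, 3, 4], [5, 9, 0, 0], ms_level=1)
        f = trace([1, 2, 3, 4], [0, 0, 3, 7])
        assert correlate_traces(f, p).score == pytest.approx(0.0)

    def test_reference_cosine_value(self):
        # cos((1,2,1),(2,4,1)) = 11 / (sqrt(6)*sqrt(21))
        p = trace([1, 2, 3], [2, 4, 1], ms_level=1)
        f = trace([1, 2, 3], [1, 2, 1])
        assert correlate_traces(f, p).score == pytest.approx(0.9800, abs=1e-4)

    def test_scale_invariance(self):
        p = trace([1, 2, 3, 4, 5], [1, 5, 9, 5, 1], ms_level=1)
        f = trace([1, 2, 3, 4, 5], [2, 4, 9, 3, 2])
        s1 = correlate_traces(f, p).score
        f2 = trace([1, 2, 3, 4, 5], np.array([2, 4, 9, 3, 2]) * 0.3)
        assert correlate_traces(f2, p).score == pytest.approx(s1)

    def test_too_few_points_flagged(self):
        p = trace([1, 2, 3], [1, 2, 1], ms_level=1)
        f = trace([1, 2], [1, 2])
        score = correlate_traces(f, p, min_points=3)
        assert score.score == 0.0 and not score.valid

    def test_zero_norm_flagged(self):
        p = trace([1, 2, 3], [1, 2, 1], ms_level=1)
        f = trace([1, 2, 3], [0, 0, 0])
        score = correlate_traces(f, p)
        assert score.score == 0.0 and not score.valid

    def test_pearson_decorrelates_flat_background(self):
        p = trace([1, 2, 3, 4, 5], [1, 5, 9, 5, 1], ms_level=1)
        flat = trace([1, 2, 3, 4, 5], [4, 4.2, 3.9, 4.1, 4.0])
        assert correlate_traces(flat, p).score > 0.8  # cosine is fooled
        assert correlate_traces(flat, p, method="pearson").score < 0.4


class TestFBeta:
    @pytest.mark.parametrize("p,r,expected", [
        (1.0, 1.0, 1.0),
        (1.0, 0.0, 0.0),
        (0.0, 0.0, 0.0),
        (0.8, 0.6, 0.65),  # 3.25*0.48/2.4
    ])
    def test_reference_values(self, p, r, expected):
        assert f_beta(p, r, beta=1.5) == pytest.approx(expected, abs=1e-10)

    def test_beta_weights_recall(self):
        assert f_beta(0.5, 1.0, 1.5) > f_beta(1.0, 0.5, 1.5)


def brute_force_cutoff(scored, beta=1.5):
    """Oracle: evaluate F_beta on a dense grid of every achievable split."""
    uniq = sorted({s for s, _ in scored})
    candidates = [0.0, 1.0] + [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]
    best_t, best_f = None, -1.0
    for t in sorted(candidates):
        tp = sum(1 for s, l in scored if s >= t and l)
        fp = sum(1 for s, l in scored if s >= t and not l)
        fn = sum(1 for s, l in scored if s < t and l)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = f_beta(p, r, beta)
        if f > best_f + 1e-12:
            best_t, best_f = t, f
    return best_t, best_f


class TestDetermineCutoff:
    def test_separable_labels_midpoint_with_tiebreak(self):
        scored = [(0.9, True), (0.95, True), (0.1, False), (0.2, False)]
        res = determine_cutoff(scored)
        assert res.threshold == pytest.approx(0.55)
        assert res.f_score == pytest.approx(1.0)
        assert res.provenance == "auto"

    def test_single_class_falls_back(self):
        res = determine_cutoff([(0.9, True), (0.3, True)])
        assert res.threshold == 0.5
        assert res.provenance == "auto-degenerate"

    @given(st.lists(
        st.tuples(st.floats(0, 1, allow_nan=False), st.booleans()),
        min_size=2, max_size=60,
    ))
    @settings(derandomize=True, max_examples=80)
    def test_matches_exhaustive_search(self, scored):
        labels = {l for _, l in scored}
        if len(labels) < 2:
            return
        res = determine_cutoff(scored)
        t, f = brute_force_cutoff(scored)
        assert res.threshold == pytest.approx(t)
        assert res.f_score == pytest.approx(f)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            determine_cutoff([])

    def test_fscore_consistent_with_stored_pr(self):
        rng = np.random.default_rng(2)
        scored = [(float(s), bool(l)) for s, l in
                  zip(rng.uniform(0, 1, 50), rng.integers(0, 2, 50))]
        res = determine_cutoff(scored)
        assert res.f_score == pytest.approx(f_beta(res.precision, res.recall, 1.5))


def spectrum_with_fragments(frag_specs):
    scan = make_scan(mz=tuple(m for m, *_ in frag_specs),
                     intensity=tuple(1.0 for _ in frag_specs))
    spec = Ms2Spectrum.from_scan(scan, SpectrumType("pos", 30.0, "auto"), "C1")
    from mscurate.chem import FormulaCandidate

    for frag, (mz, score, has_formula, valid) in zip(spec.fragments, frag_specs):
        frag.eic_score = score
        frag.score_valid = valid
        if has_formula:
            frag.assignment = FormulaCandidate((("C", 1), ("H", 3)), mz, 0.0)
    return spec


class TestCategorize:
    CUT = CutoffResult(0.7, 1.0, 1.0, 1.0, 1, 1)

    def test_four_quadrants(self):
        spec = spectrum_with_fragments([
            (100.0, 0.99, True, True),   # A
            (110.0, 0.95, False, True),  # B -> review
            (120.0, 0.10, True, True),   # C
            (130.0, 0.20, False, True),  # D
        ])
        cats = [c for _, c in categorize_fragments(spec, self.CUT)]
        assert cats == ["A", "B", "C", "D"]
        assert spec.fragments[1].review

    def test_partition_is_exhaustive(self, rng):
        specs = [(100.0 + i, float(rng.uniform(0, 1)), bool(rng.integers(0, 2)), True)
                 for i in range(40)]
        spec = spectrum_with_fragments(specs)
        cats = [c for _, c in categorize_fragments(spec, self.CUT)]
        assert len(cats) == 40
        assert set(cats) <= {"A", "B", "C", "D"}

    def test_raising_threshold_is_monotone(self, rng):
        specs = [(100.0 + i, float(rng.uniform(0, 1)), bool(rng.integers(0, 2)), True)
                 for i in range(40)]
        lo = spectrum_with_fragments(specs)
        hi = spectrum_with_fragments(specs)
        kept_lo = {f.mz for f, c in categorize_fragments(
            lo, CutoffResult(0.3, 1, 1, 1, 1, 1)) if c in ("A", "B")}
        kept_hi = {f.mz for f, c in categorize_fragments(
            hi, CutoffResult(0.8, 1, 1, 1, 1, 1)) if c in ("A", "B")}
        assert kept_hi <= kept_lo

    def test_invalid_score_with_formula_kept_for_review(self):
        spec = spectrum_with_fragments([(100.0, 0.0, True, False),
                                        (110.0, 0.0, False, False)])
        cats = [c for _, c in categorize_fragments(spec, self.CUT)]
        assert cats == ["A", "D"]
        assert spec.fragments[0].review


class TestBenchmarkSeparation:
    def test_interference_rejected_and_true_kept(self, default_curation):
        """With the co-eluting interference offset by 2 peak-sigmas, at least
        90% of its fragments fall in C/D while at least 90% of genuine
        formula-matched fragments stay in A."""
        params, scans, truth, result = default_curation
        inter_cd = inter_total = 0
        true_a = true_total = 0
        for comp in result.compounds:
            for spec in comp.spectra:
                for frag in spec.fragments:
                    row = truth.lookup(frag.scan_id, frag.raw_mz)
                    if row is None:
                        continue
                    if row["label"] == "interference":
                        inter_total += 1
                        inter_cd += frag.category in ("C", "D")
                    elif row["label"] == "true_fragment" and frag.has_formula:
                        true_total += 1
                        true_a += frag.category == "A"
        assert inter_total > 500 and true_total > 2000
        assert inter_cd / inter_total >= 0.90
        assert true_a / true_total >= 0.90
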