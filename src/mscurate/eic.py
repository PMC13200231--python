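"""Orthogonal quality control by fragment-to-precursor co-elution.

A genuine fragment of a compound must co-elute with its precursor: its
extracted ion chromatogram (EIC) over the MS2 scans of one spectrum type
should be proportional to the precursor's MS1 EIC. Each fragment receives a
cosine score between the two traces (precursor interpolated onto the
fragment's RT grid). The quality cutoff on that score is chosen
automatically to maximize the F_1.5 score for predicting "formula
assigned" from "good EIC", so the orthogonal evidence is calibrated
against the formula evidence. Fragments are then categorized:

  A  formula assigned, good EIC      -> kept
  B  no formula, good EIC            -> kept, flagged for review
  C  formula assigned, poor EIC      -> removed (spurious formula match)
  D  no formula, poor EIC            -> removed
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Fragment, Ms2Spectrum, MsScan, SpectrumType, classify_spectrum_type

MIN_CORR_POINTS = 3
DEFAULT_FALLBACK_THRESHOLD = 0.5
CATEGORIES = ("A", "B", "C", "D")


@dataclass
class EicTrace:
    """Intensity of a target m/z (+/- ppm tolerance) against retention time."""

    mz: float
    tol_ppm: float
    ms_level: int
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.rt) <= 0):
            raise ValueError("EIC retention times must be strictly increasing")


def extract_eic(
    scans: list[MsScan],
    mz: float,
    tol_ppm: float,
    ms_level: int = 1,
    restrict_type: SpectrumType | None = None,
    rt_range: tuple[float, float] | None = None,
    precursor_mz: float | None = None,
    precursor_tol_ppm: float = 10.0,
) -> EicTrace:
    """Sum matching peak intensities per qualifying scan.

    Scans qualify by MS level, optionally by spectrum type (MS2 only),
    precursor m/z and RT range; a qualifying scan with no matching peak
    contributes an explicit zero, so absences count against co-elution.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    half = mz * tol_ppm / 1e6
    rts, ints = [], []
    for scan in sorted(scans, key=lambda s: s.rt):
        if scan.ms_level != ms_level:
            continue
        if rt_range is not None and not (rt_range[0] <= scan.rt <= rt_range[1]):
            continue
        if restrict_type is not None:
            if scan.ms_level != 2:
                continue
            if classify_spectrum_type(scan) != restrict_type:
                continue
        if precursor_mz is not None:
            if scan.precursor_mz is None:
                continue
            if abs(scan.precursor_mz - precursor_mz) > precursor_mz * precursor_tol_ppm / 1e6:
                continue
        lo = np.searchsorted(scan.mz, mz - half, side="left")
        hi = np.searchsorted(scan.mz, mz + half, side="right")
        rts.append(scan.rt)
        ints.append(float(scan.intensity[lo:hi].sum()))
    if not rts:
        return EicTrace(mz, tol_ppm, ms_level, np.empty(0), np.empty(0))
    rt = np.array(rts)
    inten = np.array(ints)
    # merge coincident RTs (co-scheduled scans) by summing
    if np.any(np.diff(rt) <= 0):
        uniq, inv = np.unique(rt, return_inverse=True)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inv, inten)
        rt, inten = uniq, summed
    return EicTrace(mz, tol_ppm, ms_level, rt, inten)


@dataclass(frozen=True)
class CorrelationScore:
    """Cosine of a fragment EIC against the interpolated precursor EIC."""

    score: float
    n_points: int
    valid: bool

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def correlate_traces(
    fragment: EicTrace,
    precursor: EicTrace,
    min_points: int = MIN_CORR_POINTS,
    method: str = "cosine",
) -> CorrelationScore:
    """Score fragment/precursor co-elution on the fragment's RT grid.

    The precursor trace is linearly interpolated onto the fragment RTs and
    the normalized dot product (cosine) of the two non-negative vectors is
    returned. Traces shorter than ``min_points`` or with zero norm score 0
    and are flagged invalid. ``method='pearson'`` mean-centers first
    (unstable on very short traces; cosine is the default).
    """
    n = len(fragment.rt)
    if n < min_points or len(precursor.rt) == 0:
        return CorrelationScore(0.0, n, False)
    p = np.interp(fragment.rt, precursor.rt, precursor.intensity)
    f = fragment.intensity
    if method == "pearson":
        f = f - f.mean()
        p = p - p.mean()
    nf, np_ = np.linalg.norm(f), np.linalg.norm(p)
    if nf == 0.0 or np_ == 0.0:
        return CorrelationScore(0.0, n, False)
    score = float(np.dot(f, p) / (nf * np_))
    return CorrelationScore(min(max(score, 0.0), 1.0), n, True)


def f_beta(precision: float, recall: float, beta: float = 1.5) -> float:
    """F_beta = (1+b^2) P R / (b^2 P + R); 0 when the denominator is 0.

    beta = 1.5 weights recall above precision: losing genuine fragments
    costs more than keeping a doubtful one (which stays reviewable).
    """
    denom = beta * beta * precision + recall
    if denom == 0.0:
        return 0.0
    return (1.0 + beta * beta) * precision * recall / denom


@dataclass(frozen=True)
class CutoffResult:
    """Chosen EIC-score cutoff with the operating point that selected it."""

    threshold: float
    f_score: float
    precision: float
    recall: float
    n_positive: int
    n_negative: int
    scope: str = "compound"
    provenance: str = "auto"


def determine_cutoff(
    scored: list[tuple[float, bool]],
    beta: float = 1.5,
    scope: str = "compound",
    fallback: float = DEFAULT_FALLBACK_THRESHOLD,
) -> CutoffResult:
    """Pick the score cutoff maximizing F_beta for predicting formula match.

    The classifier is "score >= t => formula expected"; positives are the
    formula-assigned fragments. Candidate thresholds are the midpoints of
    consecutive unique scores plus {0, 1}; ties resolve to the smallest
    threshold (retains more fragments). With only one label class present
    the optimization is vacuous and the fallback threshold is returned with
    provenance "auto-degenerate".
    """
    if not scored:
        raise ValueError("at least one scored fragment required")
    labels = [bool(l) for _, l in scored]
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        p, r = _precision_recall(scored, fallback)
        return CutoffResult(fallback, f_beta(p, r, beta), p, r, n_pos, n_neg,
                            scope, "auto-degenerate")
    uniq = sorted({s for s, _ in scored})
    candidates = sorted(
        {0.0, 1.0} | {(a + b) / 2.0 for a, b in zip(uniq, uniq[1:])}
    )
    best_t, best_f, best_p, best_r = None, -1.0, 0.0, 0.0
    for t in candidates:
        p, r = _precision_recall(scored, t)
        f = f_beta(p, r, beta)
        if f > best_f + 1e-12:
            best_t, best_f, best_p, best_r = t, f, p, r
    return CutoffResult(best_t, best_f, best_p, best_r, n_pos, n_neg, scope, "auto")


def _precision_recall(scored: list[tuple[float, bool]], t: float) -> tuple[float, float]:
    tp = sum(1 for s, l in scored if s >= t and l)
    fp = sum(1 for s, l in scored if s >= t and not l)
    fn = sum(1 for s, l in scored if s < t and l)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def categorize_fragments(
    spectrum: Ms2Spectrum, cutoff: CutoffResult
) -> list[tuple[Fragment, str]]:
    """Assign the A/B/C/D category to every fragment of a spectrum.

    Fragments whose correlation was invalid (too few trace points) default
    to the poor-EIC side unless a formula was assigned, in which case they
    are kept with a review flag.
    """
    out = []
    for frag in spectrum.fragments:
        score = frag.eic_score if frag.eic_score is not None else 0.0
        good = score >= cutoff.threshold
        if not frag.score_valid:
            good = False
            if frag.has_formula:
                good = True
                frag.review = True
        if frag.has_formula:
            cat = "A" if good else "C"
        else:
            cat = "B" if good else "D"
        if cat == "B":
            frag.review = True
        frag.category = cat
        out.append((frag, cat))
    return out
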