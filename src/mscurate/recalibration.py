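"""Mass recalibration from confidently annotated fragments.

Workflow: (a) assign candidate subformulas to every fragment at a wide,
mass-tiered tolerance (+/-15 ppm at m/z <= 120, +/-10 ppm above); (b) pool
uniquely assigned, intense fragments into calibration points; (c) fit a
robust local regression of ppm error against m/z per ionization mode;
(d) divide every fragment m/z by (1 + predicted_ppm/1e6); (e) re-run the
assignment at a strict < 5 ppm tolerance, allowing N2/O collision-gas
adducts for still-unassigned peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .chem import ElementCounts, enumerate_subformulas
from .io import Fragment, Ms2Spectrum

WIDE_TOL_LOW_PPM = 15.0   # |m/z| <= boundary
WIDE_TOL_HIGH_PPM = 10.0  # above the boundary
LOW_MASS_BOUNDARY = 120.0  # boundary itself uses the low-mass (wider) tier
TIGHT_TOL_PPM = 5.0        # strict: |error| < 5 ppm
MIN_CALIB_INTENSITY = 1e3


def wide_tolerance(mz: float, boundary: float = LOW_MASS_BOUNDARY,
                   low: float = WIDE_TOL_LOW_PPM, high: float = WIDE_TOL_HIGH_PPM) -> float:
    return low if mz <= boundary else high


def assign_wide(spectrum: Ms2Spectrum, precursor_ion: ElementCounts,
                boundary: float = LOW_MASS_BOUNDARY,
                low_ppm: float = WIDE_TOL_LOW_PPM,
                high_ppm: float = WIDE_TOL_HIGH_PPM,
                dbe_filter: bool = False) -> None:
    """First-pass candidate assignment at the mass-tiered wide tolerance.

    Stores every candidate on the fragment; a fragment with exactly one
    candidate counts as uniquely assigned for calibration purposes. No
    collision-gas adducts at this stage.
    """
    pol = spectrum.scan.polarity
    for frag in spectrum.fragments:
        tol = wide_tolerance(frag.mz, boundary, low_ppm, high_ppm)
        frag.candidates = enumerate_subformulas(
            precursor_ion, frag.mz, tol, pol, gas_adducts=False, dbe_filter=dbe_filter
        )
        frag.assignment = frag.candidates[0] if frag.candidates else None


@dataclass(frozen=True)
class CalibrationPoint:
    """A uniquely assigned, intense fragment contributing to the fit."""

    mz: float
    ppm: float
    intensity: float
    spectrum_id: str


def collect_calibration_points(
    spectra: list[Ms2Spectrum], min_intensity: float = MIN_CALIB_INTENSITY
) -> list[CalibrationPoint]:
    """Pool calibration points: exactly one wide-tolerance candidate and
    intensity >= ``min_intensity`` (default 1e3 counts)."""
    points = []
    for spec in spectra:
        for frag in spec.fragments:
            if len(frag.candidates) == 1 and frag.intensity >= min_intensity:
                points.append(
                    CalibrationPoint(
                        mz=frag.mz,
                        ppm=frag.candidates[0].ppm,
                        intensity=frag.intensity,
                        spectrum_id=spec.spectrum_id,
                    )
                )
    return points


@dataclass
class RecalModel:
    """Fitted ppm-error-vs-m/z correction curve for one ionization mode.

    Outside the fitted m/z range the boundary value is used (constant
    extrapolation). ``method`` is one of local-regression, constant-median
    or identity.
    """

    polarity: str
    method: str
    n_points: int
    residual_ppm: float
    _predict: Callable[[np.ndarray], np.ndarray]

    def predict_ppm(self, mz) -> np.ndarray:
        mz = np.atleast_1d(np.asarray(mz, dtype=float))
        return self._predict(mz)

    def summary(self) -> dict:
        return {
            "polarity": self.polarity,
            "method": self.method,
            "n_points": self.n_points,
            "residual_ppm": round(float(self.residual_ppm), 4),
        }


def identity_model(polarity: str) -> RecalModel:
    return RecalModel(polarity, "identity", 0, 0.0, lambda mz: np.zeros_like(mz))


def fit_recal_curve(
    points: list[CalibrationPoint],
    polarity: str,
    min_points: int = 10,
    span: float = 0.5,
) -> RecalModel:
    """Fit the mass-error curve, degrading gracefully with few points.

    >= ``min_points``: robust lowess of ppm error on m/z (span 0.5, 3
    robustifying iterations), evaluated by linear interpolation between
    fitted values. 1..min_points-1: constant median. 0: identity (warns
    via the returned method tag).
    """
    if not points:
        return identity_model(polarity)
    x = np.array([p.mz for p in points])
    y = np.array([p.ppm for p in points])
    if len(points) < min_points or np.ptp(x) == 0.0:
        med = float(np.median(y))
        resid = float(np.median(np.abs(y - med)))
        return RecalModel(
            polarity, "constant-median", len(points), resid,
            lambda mz, c=med: np.full_like(mz, c),
        )
    fitted = lowess(y, x, frac=span, it=3, return_sorted=True)
    fx, fy = fitted[:, 0], fitted[:, 1]
    # collapse duplicate m/z grid points for interpolation
    ux, idx = np.unique(fx, return_index=True)
    uy = fy[idx]
    resid = float(np.median(np.abs(y - np.interp(x, ux, uy))))
    return RecalModel(
        polarity, "local-regression", len(points), resid,
        lambda mz, gx=ux, gy=uy: np.interp(mz, gx, gy),
    )


def apply_recalibration(spectrum: Ms2Spectrum, model: RecalModel) -> Ms2Spectrum:
    """Correct every fragment m/z in place: mz -> mz / (1 + ppm_pred/1e6).

    Intensities and peak order are untouched; the raw m/z stays recorded on
    each fragment. The precursor m/z is left as acquired.
    """
    if model.polarity != spectrum.scan.polarity:
        raise ValueError(
            f"model polarity {model.polarity} != spectrum polarity {spectrum.scan.polarity}"
        )
    if spectrum.fragments:
        mzs = np.array([f.mz for f in spectrum.fragments])
        corr = model.predict_ppm(mzs)
        for frag, c in zip(spectrum.fragments, corr):
            frag.mz = frag.mz / (1.0 + c / 1e6)
    return spectrum


def reassign_tight(
    spectrum: Ms2Spectrum,
    precursor_ion: ElementCounts,
    tol_ppm: float = TIGHT_TOL_PPM,
    dbe_filter: bool = False,
) -> Ms2Spectrum:
    """Strict re-assignment after recalibration (|error| < tol_ppm).

    Wide-tolerance candidates are discarded. Fragments that stay unassigned
    are retried allowing N2 and/or O collision-gas addition; a match found
    only that way carries the gas-adduct flag.
    """
    pol = spectrum.scan.polarity
    for frag in spectrum.fragments:
        cands = enumerate_subformulas(
            precursor_ion, frag.mz, tol_ppm, pol, gas_adducts=False, dbe_filter=dbe_filter
        )
        cands = [c for c in cands if abs(c.ppm) < tol_ppm]
        if not cands:
            cands = [
                c
                for c in enumerate_subformulas(
                    precursor_ion, frag.mz, tol_ppm, pol, gas_adducts=True,
                    dbe_filter=dbe_filter,
                )
                if abs(c.ppm) < tol_ppm
            ]
        frag.candidates = cands
        frag.assignment = cands[0] if cands else None
    return spectrum
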