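"""Cross-spectrum multiplicity filtering and replicate merging.

Each spectrum type is acquired with several replicates across the elution
peak. Fragments seen in fewer than two spectra of a compound (within one
polarity) are discarded as irreproducible; the surviving replicates of each
spectrum type are merged into one consensus spectrum whose m/z values are
intensity-weighted means and whose intensities are rescaled to the MassBank
1-999 relative scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Fragment, Ms2Spectrum, SpectrumType

DEFAULT_MIN_COUNT = 2
DEFAULT_MATCH_TOL_PPM = 5.0
DEFAULT_MATCH_TOL_DA = 0.002


def _match_tol(mz: float, tol_ppm: float, tol_da: float) -> float:
    return max(mz * tol_ppm / 1e6, tol_da)


def _fragment_key(frag: Fragment) -> tuple | None:
    """Identity of a fragment across spectra: its assigned formula if any."""
    if frag.assignment is not None:
        return (frag.assignment.counts_key, frag.assignment.gas_adduct)
    return None


def _group_by_mz(frags: list[Fragment], tol_ppm: float, tol_da: float) -> list[list[Fragment]]:
    """Greedy single-linkage grouping of unassigned fragments by m/z."""
    groups: list[list[Fragment]] = []
    for frag in sorted(frags, key=lambda f: f.mz):
        if groups and frag.mz - groups[-1][-1].mz <= _match_tol(frag.mz, tol_ppm, tol_da):
            groups[-1].append(frag)
        else:
            groups.append([frag])
    return groups


def group_fragments(
    spectra: list[Ms2Spectrum],
    tol_ppm: float = DEFAULT_MATCH_TOL_PPM,
    tol_da: float = DEFAULT_MATCH_TOL_DA,
) -> list[list[Fragment]]:
    """Match fragments across spectra: by assigned formula when present,
    otherwise by m/z proximity."""
    by_formula: dict[tuple, list[Fragment]] = {}
    unassigned: list[Fragment] = []
    for spec in spectra:
        for frag in spec.fragments:
            key = _fragment_key(frag)
            if key is None:
                unassigned.append(frag)
            else:
                by_formula.setdefault(key, []).append(frag)
    groups = list(by_formula.values())
    groups.extend(_group_by_mz(unassigned, tol_ppm, tol_da))
    return groups


def multiplicity_filter(
    spectra: list[Ms2Spectrum],
    min_count: int = DEFAULT_MIN_COUNT,
    tol_ppm: float = DEFAULT_MATCH_TOL_PPM,
    tol_da: float = DEFAULT_MATCH_TOL_DA,
) -> list[Ms2Spectrum]:
    """Drop fragments occurring in fewer than ``min_count`` spectra.

    Occurrences are counted across all spectra of the compound (one
    polarity), across collision energies and scan modes. Fragments are
    removed in place from every spectrum; the spectra list is returned for
    chaining.
    """
    for group in group_fragments(spectra, tol_ppm, tol_da):
        n_spectra = len({f.scan_id for f in group})
        if n_spectra < min_count:
            doomed = {id(f) for f in group}
            for spec in spectra:
                spec.fragments = [f for f in spec.fragments if id(f) not in doomed]
    return spectra


@dataclass
class ConsensusPeak:
    """One merged fragment with provenance back to contributing scans."""

    mz: float
    intensity: float
    rel_intensity: int
    formula: str | None = None
    gas_adduct: str = "none"
    review: bool = False
    ppm: float | None = None
    sources: list[tuple[str, float]] = field(default_factory=list)  # (scan id, raw m/z)


@dataclass
class ConsensusSpectrum:
    """Per-(compound, spectrum type) consensus over surviving replicates."""

    compound_id: str
    spectrum_type: SpectrumType
    peaks: list[ConsensusPeak]
    n_replicates: int
    precursor_mz: float
    precursor_type: str
    cutoff: float
    raw_precursor_mz: float | None = None  # median as-acquired, pre-correction

    def base_peak(self) -> ConsensusPeak:
        return max(self.peaks, key=lambda p: p.intensity)


def merge_replicates(
    replicates: list[Ms2Spectrum],
    precursor_mz: float,
    precursor_type: str,
    cutoff: float,
    keep_categories: tuple[str, ...] = ("A", "B"),
    tol_ppm: float = DEFAULT_MATCH_TOL_PPM,
    tol_da: float = DEFAULT_MATCH_TOL_DA,
) -> ConsensusSpectrum | None:
    """Merge replicate spectra of one type into a consensus spectrum.

    Only fragments in the kept categories (A: formula + good EIC,
    B: good EIC without formula, review-flagged) contribute. Per matched
    group: consensus m/z is the intensity-weighted mean, consensus
    intensity the arithmetic mean; relative intensities are
    round(999 * I / I_max) floored at 1. Returns None when nothing
    survives.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    kept = []
    for spec in replicates:
        filtered = Ms2Spectrum(
            scan=spec.scan, spectrum_type=spec.spectrum_type,
            compound_id=spec.compound_id,
            fragments=[f for f in spec.fragments if f.category in keep_categories],
        )
        kept.append(filtered)
    peaks: list[ConsensusPeak] = []
    for group in group_fragments(kept, tol_ppm, tol_da):
        inten = np.array([f.intensity for f in group])
        mzs = np.array([f.mz for f in group])
        w = inten / inten.sum() if inten.sum() > 0 else np.full(len(group), 1.0 / len(group))
        rep = group[0]
        ppms = [f.assignment.ppm for f in group if f.assignment is not None]
        peaks.append(
            ConsensusPeak(
                mz=float(np.dot(w, mzs)),
                intensity=float(inten.mean()),
                rel_intensity=0,
                formula=rep.assignment.formula if rep.assignment else None,
                gas_adduct=rep.assignment.gas_adduct if rep.assignment else "none",
                review=any(f.review for f in group),
                ppm=float(np.mean(ppms)) if ppms else None,
                sources=[(f.scan_id, f.raw_mz) for f in group],
            )
        )
    if not peaks:
        return None
    peaks.sort(key=lambda p: p.mz)
    imax = max(p.intensity for p in peaks)
    for p in peaks:
        p.rel_intensity = max(1, round(999.0 * p.intensity / imax))
    return ConsensusSpectrum(
        compound_id=replicates[0].compound_id,
        spectrum_type=replicates[0].spectrum_type,
        peaks=peaks,
        n_replicates=len(replicates),
        precursor_mz=precursor_mz,
        precursor_type=precursor_type,
        cutoff=cutoff,
    )


class OverrideError(KeyError):
    """Raised when an override references an unknown compound/spectrum id."""


def validate_overrides(overrides: dict, valid_compounds: list[str]) -> None:
    """Check that every override key references an existing compound id."""
    unknown = [k for k in overrides.get("compounds", {}) if k not in valid_compounds]
    if unknown:
        raise OverrideError(
            f"unknown compound ids in overrides: {unknown}; valid ids: {sorted(valid_compounds)}"
        )


def compound_override(overrides: dict | None, compound_id: str) -> dict:
    """The override block for one compound (empty dict when absent).

    Recognized fields: ``exclude`` (bool), ``threshold`` (float, replaces
    the auto cutoff, provenance 'override'), ``exclude_spectra`` (list of
    spectrum-type strings), ``exclude_fragments`` (list of m/z values,
    matched at the consensus tolerance).
    """
    if not overrides:
        return {}
    return overrides.get("compounds", {}).get(compound_id, {}) or {}
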