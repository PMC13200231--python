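"""End-to-end curation: raw scans + metadata -> MassBank records + QC report.

Per batch: (1) targeted MS2 extraction per compound; (2) wide-tolerance
subformula assignment; (3) pooling of uniquely assigned intense fragments
into calibration points per ionization mode; (4) recalibration of all
spectra; (5) strict < 5 ppm reassignment with (6) N2/O collision-gas-adduct
check; (7) >= 2-spectra multiplicity filter; (8) EIC-correlation scoring
against the precursor with an F_1.5-optimized cutoff per compound;
(9) categorization (A/B kept, C/D removed), curator overrides, consensus
merging and MassBank export. A failure in one compound never aborts the
batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem import ion_formula
from .config import PipelineConfig
from .consensus import (
    ConsensusSpectrum,
    compound_override,
    merge_replicates,
    multiplicity_filter,
    validate_overrides,
)
from .eic import (
    CutoffResult,
    categorize_fragments,
    correlate_traces,
    determine_cutoff,
    extract_eic,
)
from .io import (
    CompoundEntry,
    Ms2Spectrum,
    MsScan,
    SpectrumType,
    extract_compound_spectra,
    read_compound_table,
    read_raw_scans,
)
from .massbank import MassBankRecord, build_record, make_accession, serialize_record
from .recalibration import (
    RecalModel,
    apply_recalibration,
    assign_wide,
    collect_calibration_points,
    fit_recal_curve,
    reassign_tight,
)

log = logging.getLogger("mscurate")

OUTCOME_NOT_DETECTED = "not_detected"
OUTCOME_FAILED = "failed_processing"
OUTCOME_APPROVED = "approved"

REASON_LOW_INTENSITY = "insufficient intensity of the precursor peak"
REASON_INTERFERENCES = "too many interferences"


@dataclass
class CompoundResult:
    """Everything the pipeline decided about one compound."""

    compound_id: str
    outcome: str
    reason: str | None = None
    spectra: list[Ms2Spectrum] = field(default_factory=list)
    consensus: list[ConsensusSpectrum] = field(default_factory=list)
    records: list[MassBankRecord] = field(default_factory=list)
    cutoffs: dict[str, CutoffResult] = field(default_factory=dict)  # per polarity

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)


@dataclass
class CurationResult:
    """Batch-level result: per-compound outcomes plus fitted models."""

    compounds: list[CompoundResult]
    recal_models: dict[str, RecalModel]
    config: PipelineConfig

    def outcome_counts(self) -> dict[str, int]:
        counts = {OUTCOME_NOT_DETECTED: 0, OUTCOME_FAILED: 0, OUTCOME_APPROVED: 0}
        for c in self.compounds:
            counts[c.outcome] = counts.get(c.outcome, 0) + 1
        return counts

    @property
    def records(self) -> list[MassBankRecord]:
        return [r for c in self.compounds for r in c.records]


def _assign_all_wide(per_compound: dict, compounds: list[CompoundEntry],
                     config: PipelineConfig) -> None:
    for entry in compounds:
        ions = {ion.polarity: ion for ion in entry.ions}
        for stype, specs in per_compound[entry.compound_id].items():
            ion = ions[stype.polarity]
            prec = ion_formula(entry.formula, ion)
            for spec in specs:
                assign_wide(
                    spec, prec,
                    boundary=config.low_mass_boundary,
                    low_ppm=config.wide_tol_low_ppm,
                    high_ppm=config.wide_tol_high_ppm,
                    dbe_filter=config.dbe_filter,
                )


def _score_compound_eics(
    scans: list[MsScan],
    entry: CompoundEntry,
    grouped: dict[SpectrumType, list[Ms2Spectrum]],
    config: PipelineConfig,
) -> None:
    """Attach fragment-to-precursor EIC cosine scores to every fragment.

    Fragment EICs are built per (fragment m/z, spectrum type) from the MS2
    scans attributed to the compound; the precursor EIC comes from MS1.
    EICs target the as-acquired m/z domain (scans are never rewritten by
    recalibration), so fragments use their raw m/z and the precursor window
    is widened by the wide assignment tolerance to absorb instrument drift.
    """
    ions = {ion.polarity: ion for ion in entry.ions}
    rt_range = (entry.rt - config.rt_window, entry.rt + config.rt_window)
    prec_traces = {}
    for pol, ion in ions.items():
        pol_scans = [s for s in scans if s.polarity == pol]
        prec_traces[pol] = extract_eic(
            pol_scans, entry.expected_mz(ion),
            config.eic_tol_ppm + config.wide_tol_high_ppm,
            ms_level=1, rt_range=rt_range,
        )
    for stype, specs in grouped.items():
        type_scans = [spec.scan for spec in specs]
        prec = prec_traces.get(stype.polarity)
        for spec in specs:
            for frag in spec.fragments:
                trace = extract_eic(
                    type_scans, frag.raw_mz, config.eic_tol_ppm, ms_level=2,
                )
                score = correlate_traces(
                    trace, prec, min_points=config.min_corr_points,
                    method=config.correlation_method,
                ) if prec is not None and len(prec.rt) else None
                if score is None:
                    frag.eic_score, frag.score_valid = 0.0, False
                else:
                    frag.eic_score, frag.score_valid = score.score, score.valid


def process_compound(
    scans: list[MsScan],
    entry: CompoundEntry,
    grouped: dict[SpectrumType, list[Ms2Spectrum]],
    recal_models: dict[str, RecalModel],
    config: PipelineConfig,
    overrides: dict | None = None,
) -> CompoundResult:
    """Steps 4-9 for one compound whose spectra are already wide-assigned."""
    cid = entry.compound_id
    over = compound_override(overrides, cid)
    if over.get("exclude"):
        return CompoundResult(cid, OUTCOME_FAILED, reason="excluded by override")
    if not grouped:
        return CompoundResult(cid, OUTCOME_NOT_DETECTED,
                              reason=REASON_LOW_INTENSITY)
    ions = {ion.polarity: ion for ion in entry.ions}
    excluded_types = set(over.get("exclude_spectra", []) or [])

    # recalibrate + strict reassignment
    for stype, specs in grouped.items():
        ion = ions[stype.polarity]
        prec = ion_formula(entry.formula, ion)
        model = recal_models.get(stype.polarity)
        for spec in specs:
            if model is not None:
                apply_recalibration(spec, model)
            reassign_tight(spec, prec, tol_ppm=config.tight_tol_ppm,
                           dbe_filter=config.dbe_filter)

    # multiplicity filter within each polarity
    for pol in {st.polarity for st in grouped}:
        pol_specs = [s for st, specs in grouped.items() if st.polarity == pol
                     for s in specs]
        multiplicity_filter(pol_specs, min_count=config.multiplicity_min_count,
                            tol_ppm=config.match_tol_ppm, tol_da=config.match_tol_da)

    # EIC correlation scoring
    _score_compound_eics(scans, entry, grouped, config)

    # cutoff per compound (pooled over all spectra), optional override.
    # The classifier predicts CONFIDENT formula match: positives are
    # fragments with a non-gas assignment and intensity at or above the
    # calibration floor. Low-intensity peaks and N2/O gas-adduct rescues
    # keep their formulas for export, but their assignments are too often
    # coincidental to define the cutoff — with them in the positive class
    # the optimization degenerates toward keeping everything.
    scored = [
        (frag.eic_score or 0.0,
         frag.has_formula
         and frag.assignment.gas_adduct == "none"
         and frag.intensity >= config.min_calib_intensity)
        for specs in grouped.values() for spec in specs
        for frag in spec.fragments
        if frag.score_valid
    ]
    all_specs = [s for specs in grouped.values() for s in specs]
    if not scored:
        return CompoundResult(cid, OUTCOME_FAILED, reason=REASON_INTERFERENCES,
                              spectra=all_specs)
    cutoff = determine_cutoff(scored, beta=config.f_beta,
                              fallback=config.fallback_threshold)
    if "threshold" in over:
        cutoff = CutoffResult(
            threshold=float(over["threshold"]), f_score=cutoff.f_score,
            precision=cutoff.precision, recall=cutoff.recall,
            n_positive=cutoff.n_positive, n_negative=cutoff.n_negative,
            scope="compound", provenance="override",
        )
    else:
        floor = config.effective_threshold_floor(entry.level)
        if floor is not None and cutoff.threshold < floor:
            cutoff = CutoffResult(
                threshold=floor, f_score=cutoff.f_score,
                precision=cutoff.precision, recall=cutoff.recall,
                n_positive=cutoff.n_positive, n_negative=cutoff.n_negative,
                scope="compound", provenance="preset-strict",
            )

    # categorize and merge; a per-spectrum-type threshold override takes
    # precedence over the compound-level cutoff
    spectrum_overrides = over.get("spectra", {}) or {}
    consensus: list[ConsensusSpectrum] = []
    raw_precursors: dict = {}
    excluded_frag_mzs = [float(m) for m in over.get("exclude_fragments", []) or []]
    for stype in sorted(grouped):
        if str(stype) in excluded_types:
            continue
        specs = grouped[stype]
        type_cutoff = cutoff
        type_over = spectrum_overrides.get(str(stype), {}) or {}
        if "threshold" in type_over:
            type_cutoff = CutoffResult(
                threshold=float(type_over["threshold"]), f_score=cutoff.f_score,
                precision=cutoff.precision, recall=cutoff.recall,
                n_positive=cutoff.n_positive, n_negative=cutoff.n_negative,
                scope="spectrum", provenance="override",
            )
        raw_precursors[stype] = float(
            np.median([s.scan.precursor_mz for s in specs])
        )
        for spec in specs:
            categorize_fragments(spec, type_cutoff)
            if excluded_frag_mzs:
                spec.fragments = [
                    f for f in spec.fragments
                    if not any(abs(f.mz - m) <= max(f.mz * config.match_tol_ppm / 1e6,
                                                    config.match_tol_da)
                               for m in excluded_frag_mzs)
                ]
        ion = ions[stype.polarity]
        cons = merge_replicates(
            specs,
            precursor_mz=entry.expected_mz(ion),
            precursor_type=ion.label,
            cutoff=type_cutoff.threshold,
            tol_ppm=config.match_tol_ppm,
            tol_da=config.match_tol_da,
        )
        if cons is not None:
            cons.raw_precursor_mz = raw_precursors[stype]
            consensus.append(cons)
    if not consensus:
        return CompoundResult(cid, OUTCOME_FAILED, reason=REASON_INTERFERENCES,
                              spectra=all_specs,
                              cutoffs={"pooled": cutoff})
    return CompoundResult(cid, OUTCOME_APPROVED, spectra=all_specs,
                          consensus=consensus, cutoffs={"pooled": cutoff})


def run_curation(
    scans: list[MsScan],
    compounds: list[CompoundEntry],
    config: PipelineConfig | None = None,
    overrides: dict | None = None,
) -> CurationResult:
    """Run the full curation workflow on loaded scans and metadata."""
    config = config or PipelineConfig()
    log.info("effective config: %s", json.dumps(config.to_dict(), sort_keys=True))
    if overrides:
        validate_overrides(overrides, [c.compound_id for c in compounds])

    per_compound: dict[str, dict[SpectrumType, list[Ms2Spectrum]]] = {}
    for entry in compounds:
        per_compound[entry.compound_id] = extract_compound_spectra(
            scans, entry,
            mz_tol_ppm=config.precursor_match_ppm,
            rt_window=config.rt_window,
            first_mass_threshold=config.first_mass_threshold,
        )
    _assign_all_wide(per_compound, compounds, config)

    # pooled calibration per ionization mode, across all compounds
    recal_models: dict[str, RecalModel] = {}
    for pol in ("pos", "neg"):
        pool = [
            spec
            for grouped in per_compound.values()
            for stype, specs in grouped.items()
            if stype.polarity == pol
            for spec in specs
        ]
        points = collect_calibration_points(pool, config.min_calib_intensity)
        model = fit_recal_curve(points, pol, min_points=config.min_calib_points,
                                span=config.lowess_span)
        recal_models[pol] = model
        log.info("recalibration[%s]: %s", pol, model.summary())

    results: list[CompoundResult] = []
    for entry in compounds:
        try:
            res = process_compound(
                scans, entry, per_compound[entry.compound_id],
                recal_models, config, overrides,
            )
        except Exception as exc:  # per-compound isolation
            log.exception("compound %s failed", entry.compound_id)
            res = CompoundResult(entry.compound_id, OUTCOME_FAILED,
                                 reason=f"processing error: {exc}")
        results.append(res)

    # build records for approved compounds
    entry_by_id = {c.compound_id: c for c in compounds}
    counter = 1
    for res in results:
        if res.outcome != OUTCOME_APPROVED:
            continue
        entry = entry_by_id[res.compound_id]
        for cons in res.consensus:
            rec = build_record(
                cons, entry,
                accession=make_accession(config.contributor, counter),
                instrument=config.instrument,
                instrument_type=config.instrument_type,
                resolution=config.resolution,
                license_=config.license,
                date=config.record_date,
                raw_precursor_mz=cons.raw_precursor_mz,
            )
            res.records.append(rec)
            counter += 1
    return CurationResult(results, recal_models, config)


def qc_table(result: CurationResult) -> pd.DataFrame:
    """Fragment-level QC report: one row per fragment with its decision."""
    rows = []
    for comp in result.compounds:
        cutoff = comp.cutoffs.get("pooled")
        for spec in comp.spectra:
            for frag in spec.fragments:
                rows.append({
                    "compound_id": comp.compound_id,
                    "spectrum_type": str(spec.spectrum_type),
                    "scan_id": frag.scan_id,
                    "mz": round(frag.mz, 5),
                    "raw_mz": round(frag.raw_mz, 5),
                    "intensity": round(frag.intensity, 1),
                    "formula": frag.assignment.formula if frag.assignment else "",
                    "ppm": round(frag.assignment.ppm, 3) if frag.assignment else None,
                    "gas_adduct": frag.assignment.gas_adduct if frag.assignment else "",
                    "eic_score": round(frag.eic_score, 4) if frag.eic_score is not None else None,
                    "category": frag.category or "",
                    "kept": frag.category in ("A", "B"),
                    "review": frag.review,
                    "cutoff": round(cutoff.threshold, 4) if cutoff else None,
                })
    return pd.DataFrame(rows)


def write_outputs(result: CurationResult, out_dir: str | Path) -> dict:
    """Write records, QC report, batch summary and run manifest to disk."""
    from .massbank import summarize_batch

    out = Path(out_dir)
    records_dir = out / "records"
    records_dir.mkdir(parents=True, exist_ok=True)
    for rec in result.records:
        (records_dir / f"{rec.accession}.txt").write_text(serialize_record(rec))
    qc = qc_table(result)
    qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    summary = summarize_batch(result.records)
    pd.DataFrame([
        {"metric": "n_records", "value": summary.n_records},
        {"metric": "n_compounds", "value": summary.n_compounds},
        *({"metric": f"level_{k}", "value": v} for k, v in sorted(summary.per_level.items())),
        *({"metric": f"polarity_{k}", "value": v}
          for k, v in summary.polarity_availability.items()),
    ]).to_csv(out / "batch_summary.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "config": result.config.to_dict(),
        "outcomes": result.outcome_counts(),
        "failures": [
            {"compound_id": c.compound_id, "reason": c.reason}
            for c in result.compounds if c.outcome != OUTCOME_APPROVED
        ],
        "recalibration": {pol: m.summary() for pol, m in result.recal_models.items()},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_curation_files(
    mzml_paths: list[str | Path],
    metadata_path: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    overrides_path: str | Path | None = None,
) -> CurationResult:
    """File-level entry point: read inputs, run the workflow, write outputs."""
    scans: list[MsScan] = []
    for path in mzml_paths:
        scans.extend(read_raw_scans(path))
    compounds = read_compound_table(metadata_path)
    overrides = None
    if overrides_path:
        with open(overrides_path) as fh:
            overrides = yaml.safe_load(fh) or {}
    result = run_curation(scans, compounds, config, overrides)
    write_outputs(result, out_dir)
    return result
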