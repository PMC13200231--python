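"""MassBank flat-file record serialization, parsing and batch summaries.

A MassBank record is a line-oriented text format: one ``TAG: value`` line
per field, multi-valued tags repeated (CH$NAME once per isomer name),
COMMENT lines carrying free-text annotations, and a fixed-width
``PK$PEAK:`` table of (m/z, intensity, relative intensity) rows terminated
by ``//``. Records for compounds below confidence Level 1 carry
"TENTATIVE" in the record title.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

from .chem import format_formula, monoisotopic_mass
from .consensus import ConsensusSpectrum
from .io import CompoundEntry

# canonical tag order for serialization
_HEADER_TAGS = ["ACCESSION", "RECORD_TITLE", "DATE", "AUTHORS", "LICENSE",
                "COPYRIGHT", "PUBLICATION", "PROJECT"]
_CH_TAGS = ["CH$NAME", "CH$COMPOUND_CLASS", "CH$FORMULA", "CH$EXACT_MASS",
            "CH$SMILES", "CH$IUPAC", "CH$LINK"]
_AC_TAGS = ["AC$INSTRUMENT", "AC$INSTRUMENT_TYPE", "AC$MASS_SPECTROMETRY",
            "AC$CHROMATOGRAPHY"]
_MS_TAGS = ["MS$FOCUSED_ION", "MS$DATA_PROCESSING"]


@dataclass
class MassBankRecord:
    """Structured MassBank record; ``fields`` maps tag -> list of values."""

    accession: str
    fields: "OrderedDict[str, list[str]]" = field(default_factory=OrderedDict)
    peaks: list[tuple[float, float, int]] = field(default_factory=list)
    annotations: list[tuple] = field(default_factory=list)  # (m/z, formula, ppm) rows

    @property
    def title(self) -> str:
        return self.fields.get("RECORD_TITLE", [""])[0]

    @property
    def names(self) -> list[str]:
        return list(self.fields.get("CH$NAME", []))

    def comment(self, prefix: str) -> str | None:
        for value in self.fields.get("COMMENT", []):
            if value.startswith(prefix):
                return value
        return None

    @property
    def confidence_level(self) -> str | None:
        c = self.comment("CONFIDENCE")
        if c is None:
            return None
        return c.split("Level", 1)[1].strip().split()[0].rstrip(";,") if "Level" in c else None

    @property
    def ion_mode(self) -> str | None:
        for value in self.fields.get("AC$MASS_SPECTROMETRY", []):
            if value.startswith("ION_MODE"):
                return value.split(None, 1)[1].strip()
        return None


class MassBankFormatError(ValueError):
    """Raised for structurally invalid record text."""


def build_record(
    consensus: ConsensusSpectrum,
    compound: CompoundEntry,
    accession: str,
    instrument: str = "Orbitrap Exploris 240 (Thermo Fisher Scientific)",
    instrument_type: str = "LC-ESI-QFT",
    resolution: int = 15000,
    license_: str = "CC BY",
    date: str = "2024.01.01",
    chromatography: list[str] | None = None,
    raw_precursor_mz: float | None = None,
) -> MassBankRecord:
    """Assemble a complete MassBank record from a consensus spectrum.

    The record title is "<name>; <instrument type>; MS2; NCE <n>%;
    <precursor type>" with "; TENTATIVE" appended for any confidence level
    other than 1. Level-3 entries write one CH$NAME line per isomer name.
    """
    for fname, value in [("accession", accession), ("authors", compound.authors),
                         ("names", compound.names)]:
        if not value:
            raise ValueError(f"missing required metadata field: {fname}")
    st = consensus.spectrum_type
    f = OrderedDict()
    title = (f"{compound.names[0]}; {instrument_type}; MS2; "
             f"NCE {st.nce:g}%; {consensus.precursor_type}")
    if compound.level != "1":
        title += "; TENTATIVE"
    f["ACCESSION"] = [accession]
    f["RECORD_TITLE"] = [title]
    f["DATE"] = [date]
    f["AUTHORS"] = [compound.authors]
    f["LICENSE"] = [license_]
    comments = [f"CONFIDENCE Level {compound.level}"]
    if compound.citation:
        comments.append(f"CITATION {compound.citation}")
    comments.append(f"EIC correlation cutoff {consensus.cutoff:.4f}")
    n_review = sum(1 for p in consensus.peaks if p.review)
    if n_review:
        comments.append(f"REVIEW {n_review} peak(s) without formula kept on EIC evidence")
    if raw_precursor_mz is not None:
        comments.append(f"RAW_PRECURSOR_MZ {raw_precursor_mz:.4f} (as acquired)")
    f["COMMENT"] = comments
    f["CH$NAME"] = list(compound.names)
    f["CH$COMPOUND_CLASS"] = ["Natural Product"]
    f["CH$FORMULA"] = [format_formula(compound.formula)]
    f["CH$EXACT_MASS"] = [f"{monoisotopic_mass(compound.formula):.4f}"]
    f["CH$SMILES"] = [compound.smiles or "N/A"]
    f["AC$INSTRUMENT"] = [instrument]
    f["AC$INSTRUMENT_TYPE"] = [instrument_type]
    f["AC$MASS_SPECTROMETRY"] = [
        "MS_TYPE MS2",
        f"ION_MODE {'POSITIVE' if st.polarity == 'pos' else 'NEGATIVE'}",
        f"FRAGMENTATION_MODE HCD",
        f"COLLISION_ENERGY NCE {st.nce:g} % (HCD)",
        f"RESOLUTION {resolution}",
    ]
    f["AC$CHROMATOGRAPHY"] = chromatography or ["COLUMN_NAME N/A"]
    f["MS$FOCUSED_ION"] = [
        f"PRECURSOR_M/Z {consensus.precursor_mz:.4f}",
        f"PRECURSOR_TYPE {consensus.precursor_type}",
    ]
    f["MS$DATA_PROCESSING"] = [
        "RECALIBRATE fitted m/z-error curve from uniquely assigned fragments",
        "REANALYZE subformula assignment < 5 ppm with N2/O gas-adduct check",
        "WHOLE EIC-correlation quality filter (F1.5-optimized cutoff)",
    ]
    record = MassBankRecord(accession=accession, fields=f)
    record.peaks = [(p.mz, p.intensity, p.rel_intensity) for p in consensus.peaks]
    record.annotations = [
        (p.mz, p.formula, p.ppm) for p in consensus.peaks if p.formula
    ]
    return record


def serialize_record(record: MassBankRecord) -> str:
    """Render a record in the MassBank flat-file dialect."""
    lines: list[str] = []
    order = _HEADER_TAGS + ["COMMENT"] + _CH_TAGS + _AC_TAGS + _MS_TAGS
    seen = set()
    for tag in order:
        for value in record.fields.get(tag, []):
            lines.append(f"{tag}: {value}")
        seen.add(tag)
    for tag, values in record.fields.items():  # unknown tags pass through
        if tag not in seen:
            for value in values:
                lines.append(f"{tag}: {value}")
    if record.annotations:
        lines.append("PK$ANNOTATION: m/z formula error(ppm)")
        for mz, formula, ppm in record.annotations:
            ppm_s = f"{ppm:.2f}" if ppm is not None else "NA"
            lines.append(f"  {mz:.4f} {formula} {ppm_s}")
    lines.append(f"PK$NUM_PEAK: {len(record.peaks)}")
    lines.append("PK$PEAK: m/z int. rel.int.")
    for mz, inten, rel in record.peaks:
        lines.append(f"  {mz:.4f} {inten:.1f} {rel:d}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def parse_record(text: str) -> MassBankRecord:
    """Parse MassBank record text back into a structured record.

    Unknown tags are preserved verbatim; a PK$NUM_PEAK that disagrees with
    the peak table raises.
    """
    fields: "OrderedDict[str, list[str]]" = OrderedDict()
    peaks: list[tuple[float, float, int]] = []
    annotations: list[tuple] = []
    declared = None
    mode = None  # None | "peaks" | "annotation"
    for raw in text.splitlines():
        if raw.strip() == "//":
            mode = None
            continue
        if raw.startswith("  ") and mode == "peaks":
            mz_s, int_s, rel_s = raw.split()
            peaks.append((float(mz_s), float(int_s), int(rel_s)))
            continue
        if raw.startswith("  ") and mode == "annotation":
            mz_s, formula, ppm_s = raw.split()
            annotations.append((float(mz_s), formula, None if ppm_s == "NA" else float(ppm_s)))
            continue
        if not raw.strip():
            continue
        if ":" not in raw:
            raise MassBankFormatError(f"malformed line: {raw!r}")
        tag, _, value = raw.partition(":")
        tag, value = tag.strip(), value.strip()
        if tag == "PK$NUM_PEAK":
            declared = int(value)
            continue
        if tag == "PK$PEAK":
            mode = "peaks"
            continue
        if tag == "PK$ANNOTATION":
            mode = "annotation"
            continue
        fields.setdefault(tag, []).append(value)
    if "ACCESSION" not in fields:
        raise MassBankFormatError("record lacks ACCESSION")
    if declared is not None and declared != len(peaks):
        raise MassBankFormatError(
            f"PK$NUM_PEAK declares {declared} peaks but table has {len(peaks)}"
        )
    return MassBankRecord(accession=fields["ACCESSION"][0], fields=fields,
                          peaks=peaks, annotations=annotations)


def make_accession(contributor: str, index: int) -> str:
    """MSBNK-<contributor>-<zero-padded id> accession string."""
    return f"MSBNK-{contributor}-{index:06d}"


@dataclass
class BatchSummary:
    """Counts over an exported batch: confidence levels, polarity classes."""

    n_records: int
    n_compounds: int
    per_level: dict[str, int]
    polarity_availability: dict[str, int]  # both | pos_only | neg_only
    spectra_per_compound: dict[str, int]

    @property
    def total_by_level(self) -> int:
        return sum(self.per_level.values())


def summarize_batch(records: list[MassBankRecord]) -> BatchSummary:
    """Aggregate a record batch by compound (keyed on first CH$NAME set).

    Per-level counts sum to the number of unique compounds; the polarity
    classes both / pos-only / neg-only partition the compounds.
    """
    per_compound_levels: dict[tuple, str] = {}
    per_compound_modes: dict[tuple, set] = {}
    spectra_counts: dict[str, int] = {}
    for rec in records:
        key = tuple(rec.names)
        level = rec.confidence_level or "3"
        per_compound_levels[key] = level
        mode = rec.ion_mode or ""
        per_compound_modes.setdefault(key, set()).add(mode)
        name = rec.names[0] if rec.names else rec.accession
        spectra_counts[name] = spectra_counts.get(name, 0) + 1
    per_level: dict[str, int] = {}
    for level in per_compound_levels.values():
        per_level[level] = per_level.get(level, 0) + 1
    polarity = {"both": 0, "pos_only": 0, "neg_only": 0}
    for modes in per_compound_modes.values():
        has_pos = "POSITIVE" in modes
        has_neg = "NEGATIVE" in modes
        if has_pos and has_neg:
            polarity["both"] += 1
        elif has_pos:
            polarity["pos_only"] += 1
        elif has_neg:
            polarity["neg_only"] += 1
    return BatchSummary(
        n_records=len(records),
        n_compounds=len(per_compound_levels),
        per_level=per_level,
        polarity_availability=polarity,
        spectra_per_compound=spectra_counts,
    )
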