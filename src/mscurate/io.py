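"""Reading mzML runs and compound metadata; scan models and spectrum typing.

Scans are modelled close to the mzML schema: MS1 survey scans and dd-MS2
scans carrying precursor m/z, isolation width, normalized collision energy
(NCE) and the scan window. Each MS2 scan is classified into a
``SpectrumType`` — the (polarity, NCE, scan-range mode) cell of the
acquisition grid; the default grid of 9 NCEs x 2 polarities x 2 scan modes
gives 36 types.
"""

from __future__ import annotations

import base64
import csv
import warnings
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem import (
    ElementCounts,
    FormulaCandidate,
    IonSpec,
    ion_mz,
    parse_adduct,
    parse_formula,
)

DEFAULT_NCE_LIST = (15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)
CONFIDENCE_LEVELS = ("1", "2a", "2b", "3")


@dataclass
class MsScan:
    """One centroided scan (MS1 or MS2) with acquisition metadata."""

    scan_id: str
    ms_level: int
    rt: float  # minutes
    polarity: str  # pos | neg
    mz: np.ndarray
    intensity: np.ndarray
    scan_window: tuple[float, float]
    precursor_mz: float | None = None
    isolation_width: float | None = None
    nce: float | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")


@dataclass(frozen=True, order=True)
class SpectrumType:
    """One cell of the acquisition grid: polarity, NCE and scan-range mode."""

    polarity: str
    nce: float
    mode: str  # auto | fixed40

    def __str__(self) -> str:
        return f"{self.polarity}_NCE{self.nce:g}_{self.mode}"


def default_spectrum_grid(nce_list=DEFAULT_NCE_LIST) -> list[SpectrumType]:
    """Enumerate the full acquisition grid (36 types for the default NCEs)."""
    return [
        SpectrumType(pol, float(nce), mode)
        for pol in ("pos", "neg")
        for nce in nce_list
        for mode in ("auto", "fixed40")
    ]


def classify_spectrum_type(scan: MsScan, first_mass_threshold: float = 41.0) -> SpectrumType:
    """Classify an MS2 scan into its grid cell.

    The scan-range mode is ``fixed40`` when the scan-window start is at or
    below ``first_mass_threshold`` (the acquisition fixes the first mass to
    m/z 40), else ``auto`` (window scaled from the precursor).
    """
    if scan.ms_level != 2:
        raise ValueError(f"scan {scan.scan_id} is MS{scan.ms_level}, not MS2")
    if scan.nce is None:
        raise ValueError(f"MS2 scan {scan.scan_id} lacks collision energy")
    mode = "fixed40" if scan.scan_window[0] <= first_mass_threshold else "auto"
    return SpectrumType(scan.polarity, float(scan.nce), mode)


@dataclass
class Fragment:
    """One MS2 peak tracked through annotation, recalibration and QC.

    ``mz`` is the working (possibly recalibrated) m/z; ``raw_mz`` the value
    as acquired. ``assignment`` is the selected formula candidate (or None),
    ``eic_score`` the fragment-to-precursor EIC cosine, ``category`` one of
    A/B/C/D after categorization.
    """

    mz: float
    intensity: float
    scan_id: str
    raw_mz: float = 0.0
    candidates: list[FormulaCandidate] = field(default_factory=list)
    assignment: FormulaCandidate | None = None
    eic_score: float | None = None
    score_valid: bool = True
    category: str | None = None
    review: bool = False

    def __post_init__(self):
        if not self.raw_mz:
            self.raw_mz = self.mz

    @property
    def has_formula(self) -> bool:
        return self.assignment is not None


@dataclass
class Ms2Spectrum:
    """An MS2 scan attributed to a compound, with per-peak fragment state."""

    scan: MsScan
    spectrum_type: SpectrumType
    compound_id: str
    fragments: list[Fragment] = field(default_factory=list)

    @classmethod
    def from_scan(cls, scan: MsScan, stype: SpectrumType, compound_id: str) -> "Ms2Spectrum":
        frags = [
            Fragment(mz=float(m), intensity=float(i), scan_id=scan.scan_id)
            for m, i in zip(scan.mz, scan.intensity)
        ]
        return cls(scan=scan, spectrum_type=stype, compound_id=compound_id, fragments=frags)

    @property
    def spectrum_id(self) -> str:
        return f"{self.compound_id}:{self.spectrum_type}:{self.scan.scan_id}"


@dataclass
class CompoundEntry:
    """One suspect compound from the metadata table."""

    compound_id: str
    names: list[str]
    smiles: str
    formula: ElementCounts
    rt: float  # minutes
    ions: list[IonSpec]
    level: str
    authors: str = ""
    citation: str | None = None

    def __post_init__(self):
        if self.level not in CONFIDENCE_LEVELS:
            raise ValueError(
                f"confidence level must be one of {CONFIDENCE_LEVELS}, got {self.level!r}"
            )
        if not self.ions:
            raise ValueError(f"compound {self.compound_id}: at least one expected ion required")
        if not self.names:
            raise ValueError(f"compound {self.compound_id}: at least one name required")

    def expected_mz(self, ion: IonSpec) -> float:
        return ion_mz(self.formula, ion)


REQUIRED_COLUMNS = ["id", "name", "smiles", "formula", "rt_min", "adducts", "level", "authors"]


def read_compound_table(path: str | Path) -> list[CompoundEntry]:
    """Read the compound metadata CSV.

    Required columns: id, name, smiles, formula, rt_min, adducts, level,
    authors; optional: citation. Multi-valued cells (names of unresolved
    isomers, several expected adducts) are '|'-separated.
    """
    entries: list[CompoundEntry] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"metadata table missing required columns: {missing}")
        for row_no, row in enumerate(reader, start=2):
            try:
                entry = CompoundEntry(
                    compound_id=row["id"].strip(),
                    names=[n.strip() for n in row["name"].split("|") if n.strip()],
                    smiles=row["smiles"].strip(),
                    formula=parse_formula(row["formula"]),
                    rt=float(row["rt_min"]),
                    ions=[parse_adduct(a.strip()) for a in row["adducts"].split("|") if a.strip()],
                    level=row["level"].strip(),
                    authors=row["authors"].strip(),
                    citation=(row.get("citation") or "").strip() or None,
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"metadata row {row_no}: {exc}") from exc
            entries.append(entry)
    return entries


def write_compound_table(entries: list[CompoundEntry], path: str | Path) -> None:
    """Write entries back to the metadata CSV dialect (inverse of reading)."""
    from .chem import format_formula

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS + ["citation"])
        for e in entries:
            writer.writerow([
                e.compound_id, "|".join(e.names), e.smiles, format_formula(e.formula),
                f"{e.rt:g}", "|".join(i.label for i in e.ions), e.level, e.authors,
                e.citation or "",
            ])


# cvParam accessions used when reading mzML (PSI-MS ontology)
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_POSITIVE = "MS:1000130"
_ACC_NEGATIVE = "MS:1000129"
_ACC_RT = "MS:1000016"
_ACC_WINDOW_LO = "MS:1000501"
_ACC_WINDOW_HI = "MS:1000500"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LO = "MS:1000828"
_ACC_ISO_HI = "MS:1000829"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_NCE = "MS:1000138"
_ACC_CE = "MS:1000045"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem: ET.Element) -> dict[str, dict]:
    """Accession -> attribute dict for the direct cvParam children."""
    return {
        child.get("accession", ""): child.attrib
        for child in elem
        if _strip_ns(child.tag) == "cvParam"
    }


def _find(elem: ET.Element, *path: str) -> ET.Element | None:
    cur = elem
    for name in path:
        nxt = None
        for child in cur:
            if _strip_ns(child.tag) == name:
                nxt = child
                break
        if nxt is None:
            return None
        cur = nxt
    return cur


def _decode_binary_arrays(spectrum: ET.Element) -> tuple[np.ndarray, np.ndarray]:
    mz = intensity = None
    bdal = _find(spectrum, "binaryDataArrayList")
    for bda in bdal if bdal is not None else []:
        if _strip_ns(bda.tag) != "binaryDataArray":
            continue
        params = _cv_params(bda)
        binary = _find(bda, "binary")
        raw = base64.b64decode(binary.text or "") if binary is not None else b""
        if _ACC_ZLIB in params:
            raw = zlib.decompress(raw)
        dtype = "<f4" if _ACC_F32 in params else "<f8"
        arr = np.frombuffer(raw, dtype=dtype).astype(float)
        if _ACC_MZ_ARRAY in params:
            mz = arr
        elif _ACC_INT_ARRAY in params:
            intensity = arr
    if mz is None or intensity is None:
        raise ValueError("spectrum lacks m/z or intensity binary array")
    return mz, intensity


def _parse_spectrum(spectrum: ET.Element, path: str) -> MsScan | None:
    params = _cv_params(spectrum)
    spec_id = spectrum.get("id", "")
    if _ACC_PROFILE in params and _ACC_CENTROID not in params:
        raise ValueError(
            f"{path}: spectrum {spec_id} is profile mode; centroid upstream "
            "(e.g. MSConvert vendor peak picking)"
        )
    ms_level = int(params.get(_ACC_MS_LEVEL, {}).get("value", 1))
    if _ACC_POSITIVE in params:
        polarity = "pos"
    elif _ACC_NEGATIVE in params:
        polarity = "neg"
    else:
        raise ValueError(f"{path}: spectrum {spec_id} lacks polarity")
    scan = _find(spectrum, "scanList", "scan")
    rt = 0.0
    window = (0.0, float("inf"))
    if scan is not None:
        sp = _cv_params(scan)
        if _ACC_RT in sp:
            rt = float(sp[_ACC_RT]["value"])
            if sp[_ACC_RT].get("unitName") == "second":
                rt /= 60.0
        sw = _find(scan, "scanWindowList", "scanWindow")
        if sw is not None:
            wp = _cv_params(sw)
            window = (
                float(wp.get(_ACC_WINDOW_LO, {}).get("value", 0.0)),
                float(wp.get(_ACC_WINDOW_HI, {}).get("value", float("inf"))),
            )
    precursor_mz = isolation_width = nce = None
    if ms_level == 2:
        prec = _find(spectrum, "precursorList", "precursor")
        if prec is None:
            warnings.warn(f"{path}: MS2 spectrum {spec_id} lacks precursor metadata; skipped")
            return None
        iso = _find(prec, "isolationWindow")
        ip = _cv_params(iso) if iso is not None else {}
        sel = _find(prec, "selectedIonList", "selectedIon")
        if sel is not None and _ACC_SELECTED_MZ in _cv_params(sel):
            precursor_mz = float(_cv_params(sel)[_ACC_SELECTED_MZ]["value"])
        elif _ACC_ISO_TARGET in ip:
            # fall back to the isolation-window center
            precursor_mz = float(ip[_ACC_ISO_TARGET]["value"])
        else:
            warnings.warn(f"{path}: MS2 spectrum {spec_id} lacks precursor metadata; skipped")
            return None
        lo = float(ip.get(_ACC_ISO_LO, {}).get("value", 0.5))
        hi = float(ip.get(_ACC_ISO_HI, {}).get("value", 0.5))
        isolation_width = lo + hi
        act = _find(prec, "activation")
        if act is not None:
            ap = _cv_params(act)
            for acc in (_ACC_NCE, _ACC_CE):
                if acc in ap:
                    nce = float(ap[acc]["value"])
                    break
    mz, inten = _decode_binary_arrays(spectrum)
    return MsScan(
        scan_id=spec_id,
        ms_level=ms_level,
        rt=rt,
        polarity=polarity,
        mz=mz,
        intensity=inten,
        scan_window=window,
        precursor_mz=precursor_mz,
        isolation_width=isolation_width,
        nce=nce,
    )


def read_raw_scans(path: str | Path) -> list[MsScan]:
    """Read all MS1/MS2 scans from a centroided mzML 1.1 file.

    Streams the document with ElementTree iterparse, resolving cvParams by
    accession; supports 32/64-bit float peak arrays, zlib-compressed or
    plain. Profile-mode spectra raise (centroiding is an upstream
    responsibility); MS2 scans without precursor metadata are skipped with
    a warning.
    """
    scans: list[MsScan] = []
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if _strip_ns(elem.tag) != "spectrum":
            continue
        scan = _parse_spectrum(elem, str(path))
        if scan is not None:
            scans.append(scan)
        elem.clear()
    return scans


def extract_compound_spectra(
    scans: list[MsScan],
    compound: CompoundEntry,
    mz_tol_ppm: float = 10.0,
    rt_window: float = 0.5,
    first_mass_threshold: float = 41.0,
) -> dict[SpectrumType, list[Ms2Spectrum]]:
    """Targeted extraction of a compound's MS2 spectra, grouped by type.

    An MS2 scan is attributed to the compound when its selected precursor
    m/z is within ``mz_tol_ppm`` of any declared expected ion and its RT is
    within ``rt_window`` minutes of the compound RT.
    """
    if mz_tol_ppm <= 0 or rt_window <= 0:
        raise ValueError("tolerances must be positive")
    expected = [
        (ion, compound.expected_mz(ion)) for ion in compound.ions
    ]
    grouped: dict[SpectrumType, list[Ms2Spectrum]] = {}
    for scan in sorted(scans, key=lambda s: (s.rt, s.scan_id)):
        if scan.ms_level != 2 or scan.precursor_mz is None:
            continue
        if abs(scan.rt - compound.rt) > rt_window:
            continue
        match = any(
            scan.polarity == ion.polarity
            and abs(scan.precursor_mz - mz) <= mz * mz_tol_ppm / 1e6
            for ion, mz in expected
        )
        if not match:
            continue
        stype = classify_spectrum_type(scan, first_mass_threshold)
        grouped.setdefault(stype, []).append(
            Ms2Spectrum.from_scan(scan, stype, compound.compound_id)
        )
    return grouped
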