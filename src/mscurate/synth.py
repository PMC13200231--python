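"""Ground-truthed synthetic LC-HRMS/MS runs for end-to-end validation.

The generator emulates a targeted dd-MS2 acquisition of (semi)purified
natural-product samples: Gaussian elution peaks sampled by interleaved
MS1/MS2 scans; the full acquisition grid (9 NCEs x 2 polarities x 2
scan-range modes = 36 spectrum types) with several replicates per type;
NCE-dependent precursor survival and fragment breakdown curves; a smooth
m/z-dependent ppm mass-error field plus per-peak noise; a co-eluting
interference compound whose precursor sits inside the isolation window but
whose elution profile is shifted in RT; and random noise peaks. Every
generated MS2 peak carries exactly one ground-truth label
(true_fragment / interference / noise).

The default compound panel mixes polyketide-like CHO formulas (sparse
formula space, fragments uniquely assignable -> they feed the
recalibration) with a peptide-like CHNO formula (dense formula space, the
hard case for spurious matches).
"""

from __future__ import annotations

import base64
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .chem import (
    ElementCounts,
    formula_ion_mz,
    ion_formula,
    ion_mz,
    parse_adduct,
    parse_formula,
)
from .io import CompoundEntry, MsScan

DEFAULT_NCE_LIST = (15.0, 20.0, 25.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)


@dataclass
class SynthCompound:
    """Specification of one planted compound."""

    compound_id: str
    name: str
    formula: str
    rt: float  # minutes
    adducts: tuple[str, ...] = ("[M+H]+", "[M-H]-")
    sigma: float = 0.04           # chromatographic peak sigma, minutes
    intensity: float = 5e5        # precursor apex intensity, counts
    n_fragments: int = 8
    level: str = "2b"
    smiles: str = "CC(C)CC(=O)O"  # synthetic placeholder structure
    authors: str = "Synthetic Benchmark Team"
    # co-isolated chimeric compound; None disables interference for this
    # compound even when the batch-level interference spec is enabled
    interference_formula: str | None = None


@dataclass
class InterferenceSpec:
    """Co-eluting interference compound: its precursor falls inside the
    target's isolation window (chimeric MS2) but its elution profile is
    shifted by ``delta_rt_sigma`` peak widths. Its fragments are
    subformulas of its own molecular formula, so spurious matches against
    the target's formula pool occur at a natural rate."""

    enabled: bool = True
    delta_rt_sigma: float = 2.0
    intensity_scale: float = 0.3
    n_fragments: int = 2
    shared_fraction: float = 0.0  # fraction of target fragments it shares


@dataclass
class BackgroundSpec:
    """Persistent low-mass chemical background (solvent clusters, ambient
    ions) co-isolated into every MS2 scan. Background survives the
    multiplicity filter — it occurs in every spectrum — so it is the main
    junk class the EIC-correlation cutoff has to learn to reject; its
    intensities sit below the calibration floor, which is why calibration
    uses an intensity threshold in the first place."""

    n_per_polarity: int = 8
    mz_range: tuple[float, float] = (60.0, 150.0)
    log10_intensity: tuple[float, float] = (2.0, 2.9)
    jitter: tuple[float, float] = (0.7, 1.3)


@dataclass
class ErrorField:
    """Smooth instrument mass-error field: ppm(m/z) = a + b*(m/z - ref)
    plus independent Gaussian noise per peak."""

    intercept_ppm: float = 2.0
    slope_ppm_per_da: float = 0.01
    ref_mz: float = 100.0
    noise_ppm: float = 0.5

    def systematic(self, mz: float) -> float:
        return self.intercept_ppm + self.slope_ppm_per_da * (mz - self.ref_mz)

    def perturb(self, mz: float, rng: np.random.Generator) -> tuple[float, float]:
        ppm = self.systematic(mz) + rng.normal(0.0, self.noise_ppm)
        return mz * (1.0 + ppm / 1e6), ppm


@dataclass
class AcquisitionGrid:
    """Scheduling of the acquisition: NCE list, polarities, scan modes,
    replicates per spectrum type, MS1 sampling interval."""

    nce_list: tuple[float, ...] = DEFAULT_NCE_LIST
    polarities: tuple[str, ...] = ("pos", "neg")
    modes: tuple[str, ...] = ("auto", "fixed40")
    n_replicates: int = 8
    ms1_interval: float = 0.01    # minutes
    rep_span_sigma: float = 4.0   # replicates spread over rt +/- span/2 sigmas
    trigger_threshold: float = 1e4  # MS1 precursor intensity to trigger dd-MS2
    min_peak_intensity: float = 20.0
    ms1_window: tuple[float, float] = (100.0, 1000.0)

    def n_types(self) -> int:
        return len(self.nce_list) * len(self.polarities) * len(self.modes)


def default_compounds() -> list[SynthCompound]:
    """Default panel: two polyketide-like CHO compounds (sparse formula
    space, fragments uniquely assignable) and one peptide-like CHNO
    compound (dense formula space). Interference formulas are chlorinated
    congeners — common among these organisms' metabolites — whose chimeric
    precursor sits 0.2-0.3 Da from the target, inside the 1.0 Da isolation
    window, and whose halogen-retaining fragments mostly fall off the
    target's CHNO subformula lattice."""
    return [
        SynthCompound("SYN-001", "synthacutiphycin", "C38H54O8", rt=4.0,
                      interference_formula="C21H17BrCl2N2O12"),
        SynthCompound("SYN-002", "synthobacterin", "C44H58O10", rt=6.0,
                      interference_formula="C22H22BrCl3N6O12"),
        SynthCompound("SYN-003", "synthocystin-LR", "C49H74N10O12", rt=8.0,
                      n_fragments=10, interference_formula="C41H54BrCl3N4O13"),
    ]


@dataclass
class SynthParams:
    """Full parameter set; a fixed seed gives bit-reproducible output."""

    seed: int = 1
    compounds: list[SynthCompound] = field(default_factory=default_compounds)
    interference: InterferenceSpec = field(default_factory=InterferenceSpec)
    error_field: ErrorField = field(default_factory=ErrorField)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    noise_rate: float = 1.0       # mean transient noise peaks per MS2 scan
    grid: AcquisitionGrid = field(default_factory=AcquisitionGrid)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthParams":
        d = dict(d)
        compounds = [SynthCompound(**c) if isinstance(c, dict) else c
                     for c in d.get("compounds", default_compounds())]
        for c in compounds:
            if isinstance(c.adducts, list):
                c.adducts = tuple(c.adducts)
        interference = d.get("interference", InterferenceSpec())
        if isinstance(interference, dict):
            interference = InterferenceSpec(**interference)
        error_field = d.get("error_field", ErrorField())
        if isinstance(error_field, dict):
            error_field = ErrorField(**error_field)
        background = d.get("background", BackgroundSpec())
        if isinstance(background, dict):
            for k in ("mz_range", "log10_intensity", "jitter"):
                if k in background and isinstance(background[k], list):
                    background[k] = tuple(background[k])
            background = BackgroundSpec(**background)
        grid = d.get("grid", AcquisitionGrid())
        if isinstance(grid, dict):
            for k in ("nce_list", "polarities", "modes", "ms1_window"):
                if k in grid and isinstance(grid[k], list):
                    grid[k] = tuple(grid[k])
            grid = AcquisitionGrid(**grid)
        return cls(
            seed=int(d.get("seed", 1)),
            compounds=compounds,
            interference=interference,
            error_field=error_field,
            background=background,
            noise_rate=float(d.get("noise_rate", 1.0)),
            grid=grid,
        )


@dataclass
class _FragmentModel:
    """One planted fragment: ion formula, breakdown-curve parameters."""

    counts: ElementCounts
    share: float
    nce_mid: float
    nce_k: float

    def intensity_factor(self, nce: float) -> float:
        return self.share / (1.0 + math.exp(-self.nce_k * (nce - self.nce_mid)))


def _precursor_survival(nce: float, mid: float = 35.0, k: float = 0.15) -> float:
    return 1.0 / (1.0 + math.exp(k * (nce - mid)))


def _sample_fragments(neutral: ElementCounts, n: int,
                      rng: np.random.Generator) -> list[_FragmentModel]:
    """Draw distinct subformulas of the neutral molecule as true fragments.

    Counts are bounded so the fragment is a subformula of both the
    protonated and the deprotonated ion pools; masses are kept well
    separated so peaks never collide within assignment tolerances.
    """
    prec_mass = formula_ion_mz(neutral, "pos")
    frags: list[_FragmentModel] = []
    masses: list[float] = []
    attempts = 0
    while len(frags) < n and attempts < 400:
        attempts += 1
        counts: ElementCounts = {}
        for e, cnt in neutral.items():
            hi = cnt - 1 if e == "H" else cnt
            if hi <= 0:
                continue
            # fragments always keep some C/H backbone; halogens are retained
            # (cleavage rarely ejects the halogenated core)
            lo = 1 if e in ("C", "H", "Cl", "Br") else 0
            counts[e] = int(rng.integers(lo, hi + 1))
        counts = {e: c for e, c in counts.items() if c > 0}
        if counts.get("C", 0) < 3:
            continue
        mz = formula_ion_mz(counts, "pos")
        if not (80.0 <= mz <= prec_mass - 20.0):
            continue
        if any(abs(mz - m) < 0.06 for m in masses):
            continue
        frags.append(
            _FragmentModel(
                counts=counts,
                share=float(rng.uniform(0.15, 1.0)),
                nce_mid=float(rng.uniform(18.0, 55.0)),
                nce_k=float(rng.uniform(0.15, 0.4)),
            )
        )
        masses.append(mz)
    return frags


class GroundTruth:
    """Per-peak labels for a generated run, with fast (scan, m/z) lookup."""

    LABELS = ("true_fragment", "interference", "noise")

    def __init__(self, rows: list[dict]):
        self.table = pd.DataFrame(
            rows,
            columns=["scan_id", "mz", "intensity", "label", "ppm_planted",
                     "compound_id", "formula"],
        )
        self._index: dict[str, tuple[np.ndarray, pd.DataFrame]] = {}
        for scan_id, sub in self.table.groupby("scan_id", sort=False):
            sub = sub.sort_values("mz").reset_index(drop=True)
            self._index[scan_id] = (sub["mz"].to_numpy(), sub)

    def lookup(self, scan_id: str, mz: float, tol: float = 1e-4) -> dict | None:
        """The truth row for a peak, joined on (scan id, m/z within tol)."""
        entry = self._index.get(scan_id)
        if entry is None:
            return None
        mzs, sub = entry
        i = int(np.searchsorted(mzs, mz))
        best, best_d = None, tol
        for j in (i - 1, i):
            if 0 <= j < len(mzs) and abs(mzs[j] - mz) <= best_d:
                best, best_d = j, abs(mzs[j] - mz)
        return sub.iloc[best].to_dict() if best is not None else None

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t", keep_default_na=False,
                         dtype={"compound_id": str, "formula": str, "label": str})
        return cls(df.to_dict("records"))


def generate_run(params: SynthParams) -> tuple[list[MsScan], GroundTruth]:
    """Generate the full interleaved MS1/MS2 scan list plus ground truth."""
    rng = np.random.default_rng(params.seed)
    grid = params.grid
    ef = params.error_field

    compounds = []
    for spec in params.compounds:
        neutral = parse_formula(spec.formula)
        frags = _sample_fragments(neutral, spec.n_fragments, rng)
        ions = {}
        for label in spec.adducts:
            ion = parse_adduct(label)
            ions[ion.polarity] = (ion, ion_mz(neutral, ion))
        inter = None
        if params.interference.enabled and spec.interference_formula:
            isp = params.interference
            i_neutral = parse_formula(spec.interference_formula)
            n_shared = int(round(isp.shared_fraction * isp.n_fragments))
            shared = [f.counts for f in frags[:n_shared]]
            own = _sample_fragments(i_neutral, isp.n_fragments - n_shared, rng)
            i_ions = {
                pol: ion_mz(i_neutral, ion) for pol, (ion, _) in ions.items()
            }
            inter = {
                "rt": spec.rt + isp.delta_rt_sigma * spec.sigma,
                "intensity": isp.intensity_scale * spec.intensity,
                "neutral": i_neutral,
                "frags": own,
                "shared": shared,
                "prec_mz": i_ions,
            }
        compounds.append({"spec": spec, "neutral": neutral, "frags": frags,
                          "ions": ions, "inter": inter})

    # persistent background ions, drawn once per polarity
    bg = params.background
    background: dict[str, list[tuple[float, float]]] = {}
    for pol in grid.polarities:
        background[pol] = [
            (float(rng.uniform(*bg.mz_range)),
             float(10 ** rng.uniform(*bg.log10_intensity)))
            for _ in range(bg.n_per_polarity)
        ]

    events: list[dict] = []  # unsorted scan drafts

    # --- MS1 schedule, per polarity, across the whole run
    rt_lo = min(c["spec"].rt for c in compounds) - 0.3
    rt_hi = max(c["spec"].rt for c in compounds) + 0.3
    n_ms1 = int(round((rt_hi - rt_lo) / grid.ms1_interval)) + 1
    for pol in grid.polarities:
        for i in range(n_ms1):
            t = rt_lo + i * grid.ms1_interval
            peaks = []  # (mz, intensity, label, ppm, compound, formula)
            for c in compounds:
                if pol not in c["ions"]:
                    continue
                ion, pmz = c["ions"][pol]
                s = c["spec"]
                inten = s.intensity * math.exp(-((t - s.rt) ** 2) / (2 * s.sigma**2))
                if inten >= grid.min_peak_intensity:
                    omz, ppm = ef.perturb(pmz, rng)
                    peaks.append((omz, inten, "true_fragment", ppm, s.compound_id,
                                  c["neutral"]))
                if c["inter"] is not None and pol in c["inter"]["prec_mz"]:
                    it = c["inter"]
                    i_inten = it["intensity"] * math.exp(
                        -((t - it["rt"]) ** 2) / (2 * s.sigma**2)
                    )
                    if i_inten >= grid.min_peak_intensity:
                        omz, ppm = ef.perturb(it["prec_mz"][pol], rng)
                        peaks.append((omz, i_inten, "interference", ppm,
                                      s.compound_id, None))
            if not peaks:
                continue
            events.append({"ms_level": 1, "rt": t, "polarity": pol,
                           "peaks": peaks, "window": grid.ms1_window,
                           "precursor": None, "nce": None})

    # --- dd-MS2 schedule per compound
    for c in compounds:
        s = c["spec"]
        for pol in grid.polarities:
            if pol not in c["ions"]:
                continue
            ion, pmz = c["ions"][pol]
            prec_counts = ion_formula(c["neutral"], ion)
            for rep in range(grid.n_replicates):
                frac = (rep + 0.5) / grid.n_replicates - 0.5
                t_rep = s.rt + frac * grid.rep_span_sigma * s.sigma
                apex = s.intensity * math.exp(-((t_rep - s.rt) ** 2) / (2 * s.sigma**2))
                if apex < grid.trigger_threshold:
                    continue
                cell = 0
                for nce in grid.nce_list:
                    for mode in grid.modes:
                        dt = cell * grid.rep_span_sigma * s.sigma / (
                            grid.n_replicates * grid.n_types()
                        )
                        cell += 1
                        t = t_rep + dt
                        g = math.exp(-((t - s.rt) ** 2) / (2 * s.sigma**2))
                        if mode == "fixed40":
                            window = (40.0, 1000.0)
                        else:
                            window = (pmz / 15.0, min(1000.0, pmz + 10.0))
                        peaks = []
                        # surviving precursor
                        p_int = s.intensity * g * _precursor_survival(nce)
                        if p_int >= grid.min_peak_intensity:
                            omz, ppm = ef.perturb(pmz, rng)
                            peaks.append((omz, p_int, "true_fragment", ppm,
                                          s.compound_id, prec_counts))
                        # true fragments
                        for fm in c["frags"]:
                            fmz = formula_ion_mz(fm.counts, pol)
                            if not (window[0] <= fmz <= window[1]):
                                continue
                            f_int = s.intensity * g * fm.intensity_factor(nce)
                            if f_int < grid.min_peak_intensity:
                                continue
                            omz, ppm = ef.perturb(fmz, rng)
                            peaks.append((omz, f_int, "true_fragment", ppm,
                                          s.compound_id, fm.counts))
                        # interference fragments (chimeric isolation)
                        if c["inter"] is not None:
                            it = c["inter"]
                            gi = math.exp(-((t - it["rt"]) ** 2) / (2 * s.sigma**2))
                            # surviving chimeric precursor
                            ip_int = it["intensity"] * gi * _precursor_survival(nce)
                            if (pol in it["prec_mz"]
                                    and window[0] <= it["prec_mz"][pol] <= window[1]
                                    and ip_int >= grid.min_peak_intensity):
                                omz, ppm = ef.perturb(it["prec_mz"][pol], rng)
                                peaks.append((omz, ip_int, "interference", ppm,
                                              s.compound_id, None))
                            for fm in it["frags"]:
                                fmz = formula_ion_mz(fm.counts, pol)
                                if not (window[0] <= fmz <= window[1]):
                                    continue
                                f_int = it["intensity"] * gi * fm.intensity_factor(nce)
                                if f_int < grid.min_peak_intensity:
                                    continue
                                omz, ppm = ef.perturb(fmz, rng)
                                peaks.append((omz, f_int, "interference", ppm,
                                              s.compound_id, None))
                            for counts in it["shared"]:
                                fmz = formula_ion_mz(counts, pol)
                                if not (window[0] <= fmz <= window[1]):
                                    continue
                                f_int = it["intensity"] * gi * 0.3
                                if f_int < grid.min_peak_intensity:
                                    continue
                                omz, ppm = ef.perturb(fmz, rng)
                                peaks.append((omz, f_int, "interference", ppm,
                                              s.compound_id, None))
                        # persistent chemical background
                        for bmz, bint in background[pol]:
                            if not (window[0] <= bmz <= window[1]):
                                continue
                            omz, ppm = ef.perturb(bmz, rng)
                            b_int = bint * float(rng.uniform(*bg.jitter))
                            peaks.append((omz, b_int, "noise", ppm,
                                          s.compound_id, None))
                        # transient random noise peaks
                        n_noise = int(rng.poisson(params.noise_rate))
                        for _ in range(n_noise):
                            nmz = float(rng.uniform(window[0] + 5.0,
                                                    min(window[1], pmz + 5.0)))
                            n_int = float(10 ** rng.uniform(1.5, 3.2))
                            peaks.append((nmz, n_int, "noise", float("nan"),
                                          s.compound_id, None))
                        if not peaks:
                            continue
                        events.append({"ms_level": 2, "rt": t, "polarity": pol,
                                       "peaks": peaks, "window": window,
                                       "precursor": pmz, "nce": nce})

    events.sort(key=lambda e: (e["rt"], e["ms_level"], e["polarity"],
                               e["nce"] or 0.0))
    scans: list[MsScan] = []
    truth_rows: list[dict] = []
    for idx, ev in enumerate(events, start=1):
        scan_id = f"scan={idx}"
        peaks = _merge_colocated(sorted(ev["peaks"], key=lambda p: p[0]))
        mz = np.array([p[0] for p in peaks])
        inten = np.array([p[1] for p in peaks])
        scans.append(
            MsScan(
                scan_id=scan_id,
                ms_level=ev["ms_level"],
                rt=ev["rt"],
                polarity=ev["polarity"],
                mz=mz,
                intensity=inten,
                scan_window=ev["window"],
                precursor_mz=ev["precursor"],
                isolation_width=1.0 if ev["ms_level"] == 2 else None,
                nce=ev["nce"],
            )
        )
        if ev["ms_level"] == 2:
            from .chem import format_formula

            for omz, i_, label, ppm, cid, counts in peaks:
                truth_rows.append({
                    "scan_id": scan_id, "mz": omz, "intensity": i_,
                    "label": label, "ppm_planted": ppm, "compound_id": cid,
                    "formula": format_formula(counts) if counts else "",
                })
    return scans, GroundTruth(truth_rows)


def _merge_colocated(peaks: list[tuple], tol: float = 0.002) -> list[tuple]:
    """Merge peaks closer than the centroiding resolution; the dominant
    contributor provides the label so every peak is labeled exactly once."""
    merged: list[list] = []
    for p in peaks:
        if merged and p[0] - merged[-1][0] < tol:
            prev = merged[-1]
            dominant = p if p[1] > prev[1] else prev
            merged[-1] = [dominant[0], prev[1] + p[1], dominant[2], dominant[3],
                          dominant[4], dominant[5]]
        else:
            merged.append(list(p))
    return [tuple(p) for p in merged]


def compound_metadata(params: SynthParams) -> list[CompoundEntry]:
    """Metadata-table entries matching the planted compounds."""
    entries = []
    for spec in params.compounds:
        entries.append(
            CompoundEntry(
                compound_id=spec.compound_id,
                names=[spec.name],
                smiles=spec.smiles,
                formula=parse_formula(spec.formula),
                rt=spec.rt,
                ions=[parse_adduct(a) for a in spec.adducts],
                level=spec.level,
                authors=spec.authors,
            )
        )
    return entries


# --------------------------------------------------------------------------
# mzML 1.1 serialization (minimal but standards-conformant: CV-parameterized
# spectra with 64-bit little-endian uncompressed binary arrays)

_CV_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="synthetic_run">
    <spectrumList count="{count}">
"""

_CV_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _binary_array(arr: np.ndarray, kind: str) -> str:
    enc = _b64(arr)
    if kind == "mz":
        name = ('<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" '
                'value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>')
    else:
        name = ('<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" '
                'value="" unitCvRef="MS" unitAccession="MS:1000131" '
                'unitName="number of detector counts"/>')
    return (
        f'          <binaryDataArray encodedLength="{len(enc)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f"            {name}\n"
        f"            <binary>{enc}</binary>\n"
        "          </binaryDataArray>\n"
    )


def _spectrum_xml(scan: MsScan, index: int) -> str:
    pol = ('<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
           if scan.polarity == "pos"
           else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>')
    level_param = (
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        if scan.ms_level == 1
        else '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
    )
    parts = [
        f'      <spectrum index="{index}" id="{escape(scan.scan_id)}" '
        f'defaultArrayLength="{len(scan.mz)}">\n'
        f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{scan.ms_level}"/>\n'
        f"        {level_param}\n"
        f"        {pol}\n"
        '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
        '        <scanList count="1">\n'
        '          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
        "          <scan>\n"
        f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
        f'value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>\n'
        '            <scanWindowList count="1">\n'
        "              <scanWindow>\n"
        f'                <cvParam cvRef="MS" accession="MS:1000501" name="scan window lower limit" '
        f'value="{scan.scan_window[0]!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
        f'                <cvParam cvRef="MS" accession="MS:1000500" name="scan window upper limit" '
        f'value="{scan.scan_window[1]!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
        "              </scanWindow>\n"
        "            </scanWindowList>\n"
        "          </scan>\n"
        "        </scanList>\n"
    ]
    if scan.ms_level == 2:
        half = (scan.isolation_width or 1.0) / 2.0
        parts.append(
            '        <precursorList count="1">\n'
            "          <precursor>\n"
            "            <isolationWindow>\n"
            f'              <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" '
            f'value="{scan.precursor_mz!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            f'              <cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" '
            f'value="{half!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            f'              <cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" '
            f'value="{half!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            "            </isolationWindow>\n"
            '            <selectedIonList count="1">\n'
            "              <selectedIon>\n"
            f'                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" '
            f'value="{scan.precursor_mz!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>\n'
            "              </selectedIon>\n"
            "            </selectedIonList>\n"
            "            <activation>\n"
            '              <cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/>\n'
            f'              <cvParam cvRef="MS" accession="MS:1000138" name="normalized collision energy" '
            f'value="{scan.nce!r}" unitCvRef="UO" unitAccession="UO:0000187" unitName="percent"/>\n'
            "            </activation>\n"
            "          </precursor>\n"
            "        </precursorList>\n"
        )
    parts.append('        <binaryDataArrayList count="2">\n')
    parts.append(_binary_array(scan.mz, "mz"))
    parts.append(_binary_array(scan.intensity, "intensity"))
    parts.append("        </binaryDataArrayList>\n      </spectrum>\n")
    return "".join(parts)


def write_run(scans: list[MsScan], path: str | Path) -> None:
    """Write scans as a plain (non-indexed) mzML 1.1 file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_CV_HEADER.format(count=len(scans)))
        for i, scan in enumerate(scans):
            fh.write(_spectrum_xml(scan, i))
        fh.write(_CV_FOOTER)


# --------------------------------------------------------------------------
# scoring a pipeline result against the ground truth


def score_pipeline_result(truth: GroundTruth, result) -> dict:
    """Fragment-level metrics of a curation result against planted labels.

    Exported consensus peaks are joined back to raw peaks through their
    source (scan id, as-acquired m/z) pairs within 1e-4 Da; a peak's label
    is the intensity-dominant contributor. Returns precision of exported
    peaks vs true_fragment labels, interference leakage, recall over
    distinct planted fragment formulas, and recalibration residuals (ppm,
    consensus m/z vs theoretical) for formula-correct exported peaks.
    """
    from .chem import formula_ion_mz, parse_formula as _pf

    tp = fp_noise = fp_inter = total = 0
    resid = []
    exported_formulas: dict[str, set] = {}
    for comp in result.compounds:
        for record_consensus in comp.consensus:
            pol = record_consensus.spectrum_type.polarity
            for peak in record_consensus.peaks:
                total += 1
                labels = []
                for scan_id, raw_mz in peak.sources:
                    row = truth.lookup(scan_id, raw_mz)
                    if row is not None:
                        labels.append(row)
                if not labels:
                    fp_noise += 1
                    continue
                dominant = max(labels, key=lambda r: r["intensity"])
                if dominant["label"] == "true_fragment":
                    tp += 1
                    if peak.formula and peak.formula == dominant["formula"]:
                        theo = formula_ion_mz(_pf(peak.formula), pol)
                        resid.append((peak.mz - theo) / theo * 1e6)
                        exported_formulas.setdefault(
                            comp.compound_id, set()).add(peak.formula)
                elif dominant["label"] == "interference":
                    fp_inter += 1
                else:
                    fp_noise += 1
    planted: dict[str, set] = {}
    ms2_truth = truth.table[truth.table["label"] == "true_fragment"]
    for cid, sub in ms2_truth.groupby("compound_id"):
        planted[cid] = set(sub["formula"])
    recalls = []
    for cid, formulas in planted.items():
        got = exported_formulas.get(cid, set())
        if formulas:
            recalls.append(len(got & formulas) / len(formulas))
    return {
        "n_exported_peaks": total,
        "precision": tp / total if total else float("nan"),
        "interference_leakage": fp_inter / total if total else float("nan"),
        "noise_leakage": fp_noise / total if total else float("nan"),
        "formula_recall": float(np.mean(recalls)) if recalls else float("nan"),
        "recal_median_abs_ppm": float(np.median(np.abs(resid))) if resid else float("nan"),
    }
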