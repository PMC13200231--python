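# mscurate

Automated curation of LC-HRMS/MS reference spectra for natural-product
libraries.

Reference spectral libraries for specialized metabolites (cyanobacterial
peptides, polyketides, alkaloids, ...) are built from targeted
data-dependent MS² acquisitions of semipurified samples. Turning those raw
runs into trustworthy library records requires more than peak extraction:
fragment peaks must be explained by subformulas of the precursor ion, the
instrument's m/z error must be corrected, irreproducible peaks removed, and
— hardest of all — co-isolated interference and chemical background must be
kept out of the exported spectrum. `mscurate` implements that pipeline and
exports MassBank-format records.

## The method

For each suspect compound (metadata: ID, name, SMILES, molecular formula,
retention time, expected adduct), the workflow is:

1. **Extraction** of MS² scans whose precursor matches an expected ion
   (default 10 ppm) near the expected RT, grouped by *spectrum type* —
   the (polarity, NCE, scan-range mode) cell of the acquisition grid.
   The default grid (9 collision energies × 2 ionization modes × 2 scan
   modes) has 36 types.
2. **Wide subformula assignment**: each fragment m/z is matched against
   all elemental subformulas of the precursor ion, ±15 ppm for m/z ≤ 120
   and ±10 ppm above.
3. **Recalibration curve**: fragments with exactly one candidate and
   intensity ≥ 10³ counts become calibration points; a robust local
   regression (lowess) of ppm error vs m/z is fitted per ionization mode.
4. **Recalibration** of every fragment m/z:
   `mz → mz / (1 + ppm̂(mz)/10⁶)`.
5. **Strict reassignment** at < 5 ppm, discarding the wide candidates.
6. **Collision-gas check**: still-unassigned fragments are retried
   allowing N₂ and/or O addition (adducts formed with the collision gas);
   matches carry a gas-adduct flag.
7. **Multiplicity filter**: fragments observed in fewer than two spectra
   of the compound are removed.
8. **EIC-correlation QC**: for every fragment, an extracted ion
   chromatogram over the MS² scans of its spectrum type is scored against
   the precursor's MS1 EIC (cosine of the interpolated traces). The score
   cutoff is chosen per compound to maximize the recall-weighted
   **F₁.₅ score** for predicting confident formula match from EIC
   co-elution:
   `F_β = (1+β²)·P·R / (β²·P + R)`, β = 1.5.
9. **Categorization** (A: formula + good EIC, kept; B: good EIC without
   formula, kept and flagged for review; C: formula but poor EIC, dropped
   as a spurious match; D: neither, dropped), followed by curator
   overrides, consensus merging of replicates, and MassBank export with
   Schymanski confidence levels (records below Level 1 are titled
   TENTATIVE; Level-3 records carry one CH$NAME per unresolved isomer).

A ground-truthed synthetic data generator (`mscurate.synth`) emulates the
acquisition — Gaussian elution sampled by interleaved MS1/MS² scans, the
36-type grid with 5–15 replicates per type, NCE-dependent breakdown
curves, a smooth ppm-error field, a co-eluting halogenated interference
compound inside the isolation window, and persistent low-mass chemical
background — so every stage is testable without instrument data.

## Worked example

Generate a synthetic batch, curate it, and summarize the records:

```
$ mscurate synth --seed 1 --out demo/raw
wrote 1122 scans to demo/raw/synthetic.mzML

$ mscurate curate --metadata demo/raw/metadata.csv \
    --mzml demo/raw/synthetic.mzML --out demo/run
approved 3, failed 0, not detected 0; 108 records written to demo/run/records

$ mscurate summarize demo/run/records
records: 108  compounds: 3
per level: {'2b': 3}
polarity availability: {'both': 3, 'pos_only': 0, 'neg_only': 0}
```

All three planted compounds are approved; each yields one consensus record
per populated spectrum type (36 types × 3 compounds = 108 records). A
record begins:

```
ACCESSION: MSBNK-SYNLAB-000001
RECORD_TITLE: synthacutiphycin; LC-ESI-QFT; MS2; NCE 15%; [M-H]-; TENTATIVE
COMMENT: CONFIDENCE Level 2b
COMMENT: EIC correlation cutoff 0.9932
CH$FORMULA: C38H54O8
MS$FOCUSED_ION: PRECURSOR_M/Z 637.3746
```

The title is marked TENTATIVE because the compound is Level 2b (identified
by prior MS² annotation, not a reference standard); the COMMENT records the
automatically fitted EIC cutoff (0.9932 — genuine fragments co-elute almost
perfectly with the precursor, while the interference offset by two peak
widths scores ≈ 0.46 and the flat chemical background ≈ 0.9).

The same run from Python:

```python
from mscurate.synth import SynthParams, generate_run, compound_metadata
from mscurate.pipeline import run_curation

params = SynthParams(seed=1)
scans, truth = generate_run(params)
result = run_curation(scans, compound_metadata(params))
print(result.outcome_counts())
# {'not_detected': 0, 'failed_processing': 0, 'approved': 3}
```

`demo/run/qc_report.tsv` lists every fragment with its formula, ppm error,
EIC score, category and kept/dropped decision; a YAML override file
(`--overrides`) can exclude spectra or compounds or replace a compound's
cutoff, mirroring the curator's case-by-case judgement.

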