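# Methods

This note documents the models, parameter choices and numerical decisions
behind `mscurate`, and what the synthetic benchmark does and does not
establish about real data.

## Ion physics and formula arithmetic

Monoisotopic masses are hard-coded CODATA/AME values (`chem.MONOISOTOPIC_MASS`)
for C, H, N, O, S, P, Cl, Br, F, I, Na, K. All ion m/z values include the
electron mass (m_e = 0.000549 Da): at the ±10 ppm assignment tolerance the
electron term exceeds the window below m/z ≈ 55 and is a large fraction of
it up to m/z ≈ 120, so omitting it would silently bias low-mass
assignments. Adduct labels use the MassBank `PRECURSOR_TYPE` dialect
(`[M+H]+`, `[M-H]-`, `[M+2H]2+`, composite losses like `[M+H-H2O]+`).

Fragment candidates are **ion formulas drawn from the precursor-ion
element pool** (M plus adduct atoms), not neutral-loss bookkeeping; a
fragment of an [M−H]⁻ precursor is any elementwise subformula of the
deprotonated ion. Enumeration tabulates the full subformula lattice of a
pool once (sorted masses plus a count matrix; a 1 kDa natural product has
a few hundred thousand lattice points) and answers each query by binary
search; pools above 2×10⁶ lattice points fall back to a mass-bounded DFS.
Candidates are returned sorted by |ppm error|. An optional
ring-double-bond-equivalent filter (RDBE ≥ −0.5) exists but is off by
default — the processing protocol this package implements does not
mention one, and the synthetic benchmark does not rely on it.

Collision-gas adducts: a fragment not explicable from the pool is retried
with the pool extended by N₂, O, or N₂O (adduct formation with the
nitrogen collision gas / residual oxygen). A formula reachable without the
extension is never flagged; flagged candidates record which extension was
needed.

## Mass recalibration

Calibration points are fragments with **exactly one** candidate at the
wide, mass-tiered tolerance (±15 ppm for m/z ≤ 120, boundary inclusive;
±10 ppm above) and intensity ≥ 10³ counts. Both conditions matter:
ambiguous fragments contribute wrong-by-construction errors, and
low-intensity peaks carry too much centroiding jitter and too many
coincidental matches (see the cutoff discussion below — the same floor
reappears there for the same reason).

The error curve is a robust locally weighted regression
(`statsmodels` lowess, span 0.5, three robustifying iterations) of ppm
error on m/z, fitted **per ionization mode per batch**, pooled across
compounds: per-compound fits would starve on compounds whose formula
space is dense (few unique assignments). Prediction interpolates between
fitted values and extrapolates as a constant beyond the observed range —
a deliberate conservative choice; a linear extrapolation would amplify
edge noise. Degenerate inputs degrade gracefully: fewer than 10 points →
constant median; no points → identity model (no correction). The fit is
deterministic.

Recalibration rewrites fragment m/z in place
(`mz → mz/(1 + ppm̂/10⁶)`); the as-acquired m/z is kept on every fragment
(`raw_mz`) both for provenance and because EIC extraction must target the
raw m/z domain — the scans themselves are never rewritten. Precursor m/z
is left as acquired. MS1 traces are not recalibrated.

Strict reassignment uses |error| < 5 ppm (strict inequality; a fragment at
exactly 5.0 ppm is not assigned), discards all wide-stage candidates, and
then applies the gas-adduct check to whatever remains unassigned.

## EIC-correlation quality control

Genuine fragments co-elute with their precursor. Each fragment's EIC is
built per (fragment raw m/z, spectrum type) from the MS² scans attributed
to the compound — intensity varies strongly with collision energy, so
types are never mixed — with explicit zeros for scans where the peak is
absent. The precursor EIC comes from the MS1 scans of the same polarity,
with the tolerance widened by the wide-assignment tolerance to absorb
uncorrected instrument drift. The score is the cosine of the two
non-negative vectors after linearly interpolating the precursor trace
onto the fragment's RT grid. Pearson correlation is available via
configuration; cosine is the default because mean-centering 5–15-point
traces is unstable, but note the trade-off: cosine cannot distinguish a
flat (background) trace from a co-eluting one as sharply as Pearson (a
constant trace scores ≈ 0.9 against a Gaussian). Traces with fewer than 3
points, or zero norm, score 0 and are flagged invalid; an invalid-score
fragment defaults to the poor-EIC side unless it carries a formula, in
which case it is kept with a review flag.

The cutoff on the score is chosen per compound (pooling all its spectra)
to maximize F₁.₅ for predicting **confident formula match** from EIC
co-elution. Candidate thresholds are the midpoints of consecutive unique
scores plus {0, 1}; ties resolve to the smallest threshold (retains more
fragments). β = 1.5 weights recall over precision: a lost genuine
fragment is gone, while a doubtful kept fragment remains visible and
reviewable.

**What counts as a positive label.** Positives are fragments with a
non-gas assignment *and* intensity at or above the 10³ calibration floor.
Two classes of assignments are excluded from the label set (never from
the export): gas-adduct rescues, and assignments on low-intensity peaks.
Both are disproportionately coincidental — for a ~1 kDa precursor the
subformula lattice at < 5 ppm is dense enough that 30–70% of arbitrary
mid-mass m/z values match something, and the gas extension multiplies the
pool by four. If such peaks sit in the positive class, the recall-weighted
objective is maximized by keeping everything (threshold 0) and the filter
does nothing; with the floor, junk feeds the negative class and the
optimum lands between the background scores and the genuine fragments.
This is the same confidence principle as the calibration intensity floor,
applied to labels instead of points.

Categories follow the four-quadrant scheme: A (formula, good EIC) and B
(no formula, good EIC — kept, flagged for review; typically second
precursors in the isolation window or peaks below the well-calibrated
range) are exported; C (formula, poor EIC — the spurious matches the
filter exists to kill) and D (neither) are dropped. A stricter fixed
threshold floor for reference-material (Level 1) compounds is available
as a configuration preset, and a YAML override file can replace the
cutoff or exclude spectra/compounds per curator judgement; overridden
thresholds are marked with provenance `override` in the records.

## Consensus and export

Multiplicity is counted across all spectra of a compound within one
polarity, across collision energies (the more permissive reading of
"at least two spectra"); fragments are matched by assigned formula when
present, else by m/z within max(5 ppm, 0.002 Da). Consensus m/z is the
intensity-weighted mean over replicates (robust to low-intensity jitter;
median available behind the same grouping), consensus intensity the
arithmetic mean, and relative intensities are `round(999·I/I_max)`
floored at 1, so exactly one base peak reads 999. Every consensus peak
keeps its (scan id, raw m/z) sources, which is how the benchmark scorer
joins exported peaks back to ground truth.

MassBank records are flat text with canonical tag order; unknown tags
survive a parse→serialize round trip verbatim. Accessions are
`MSBNK-<contributor>-<6-digit id>`. Confidence levels are written as a
`CONFIDENCE Level <x>` COMMENT; any level other than 1 adds `TENTATIVE`
to the title; Level-3 records write one `CH$NAME` per isomer name.
External-database links and SPLASH hashes are out of scope (offline
operation).

## The synthetic benchmark

The generator emulates a targeted dd-MS² acquisition:

- **Compounds** (defaults): two polyketide-like CHO formulas (C38H54O8,
  C44H58O10) and one peptide-like CHNO formula (C49H74N10O12), Gaussian
  elution (σ = 0.04 min), apex precursor intensity 5×10⁵ counts, 8–10
  planted fragments each with logistic NCE breakdown curves (precursor
  survival decays with NCE; fragment shares rise with per-fragment
  midpoint and steepness). The CHO compounds have sparse formula spaces —
  their fragments are uniquely assignable and feed the recalibration; the
  peptide's space is dense, the hard case for spurious matching.
- **Acquisition**: the full 36-type grid, 8 replicates per type spread
  over ±2σ of the elution peak, MS1 every 0.01 min, dd-MS² triggered only
  when the precursor exceeds 10⁴ counts (a compound planted below that is
  reported `not_detected`).
- **Mass error**: ppm(m/z) = 2 + 0.01·(m/z − 100) plus N(0, 0.5 ppm) per
  peak, applied to every generated m/z.
- **Interference**: a halogenated congener per compound (Br/Cl
  metabolites are documented for the producing organisms) whose [M+H]⁺ /
  [M−H]⁻ sits 0.2–0.45 Da from the target — inside the 1.0 Da isolation
  window, outside the precursor-match tolerance — eluting 2σ later at 0.3×
  intensity, contributing its surviving precursor and two
  halogen-retaining fragments to every chimeric MS² scan. At a 2σ offset
  the cosine against the precursor trace is ≈ 0.46: low enough to reject,
  high enough that the cutoff has to be learned, not assumed.
- **Chemical background**: 8 persistent ions per polarity at m/z 60–150
  with intensities 10²–10³ (below the calibration floor) and ±30% scan
  jitter, present in every MS² scan. This class is essential: it survives
  the multiplicity filter by construction, and it supplies the negative
  labels that make the F₁.₅ optimization reject the keep-everything
  threshold. Its m/z range reflects where real solvent/background ions
  concentrate — and, not coincidentally, where the subformula lattice is
  sparse enough (≈10% match rate) that most background stays unassigned.
- **Transient noise**: Poisson(1) random peaks per MS² scan; almost all
  are removed by the multiplicity filter.

Early design iterations placed interference fragments at arbitrary m/z
with no background class; the resulting label contamination made
keep-everything optimal — which emulates the compounds the original
protocol *rejected* for "too many interferences", not the ones it passed.
The defaults above represent a semipurified sample that should pass.

Determinism: a fixed seed yields bit-identical scan lists, mzML bytes and
ground-truth tables. Every MS² peak carries exactly one label
(true_fragment with its formula / interference / noise); co-located
contributions within 2 mDa are merged and labeled by the dominant
contributor.

**What passing does not show.** The generator has no isotope envelopes,
no profile peak shapes, no chromatographic tailing, no intensity noise on
genuine fragments (their EIC cosines are near-exact 1.0), and its
compounds are three idealized formulas. Results on it validate the
pipeline's logic — assignment, recalibration recovery, cutoff selection,
categorization, export — not instrument-grade performance on real
extracts, where EIC scores of genuine fragments spread lower and
per-compound manual thresholds (the override file) matter more.

## File formats and I/O

mzML is read with a namespace-agnostic ElementTree parser resolving
cvParams by accession (32/64-bit float arrays, zlib or uncompressed,
minute/second RT units, selected-ion m/z with isolation-window fallback);
profile-mode spectra are rejected with advice to centroid upstream, and
MS² scans without precursor metadata are skipped with a warning. The
generator writes plain (non-indexed) mzML 1.1 with standard cvParams, and
the write→read round trip is exact. The compound table is UTF-8 CSV with
required columns `id, name, smiles, formula, rt_min, adducts, level,
authors` (optional `citation`); multi-valued cells use `|`. SMILES is
carried as opaque metadata — formulas come from the formula column, never
derived from structure.

## Problem sizes

The default benchmark (3 compounds × 36 types × 8 replicates plus MS1,
≈ 1100 scans, ≈ 25 000 labeled peaks) processes end to end in under ten
seconds on one CPU, which is the size the test suite and the acceptance
script use throughout; the pipeline itself streams per compound and has
no intrinsic batch-size limit.
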