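"""Elemental-formula arithmetic and fragment subformula enumeration.

Formulas are plain ``dict[str, int]`` element-count maps (``ElementCounts``).
Ion m/z always includes the electron mass: at 10 ppm tolerance below
m/z 120 the ~0.00055 Da electron term is larger than the tolerance window.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

ElementCounts = dict[str, int]

# Monoisotopic masses of the most abundant isotope, Da.
# Source: CODATA-2018 / AME2020 atomic mass evaluation.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "F": 18.99840322,
    "I": 126.904473,
}

ELECTRON_MASS = 0.000548579909  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported formula strings."""


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-notation formula string into an element-count map.

    >>> parse_formula("C6H12O6")
    {'C': 6, 'H': 12, 'O': 6}
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: ElementCounts = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        if not m.group(0):
            break
        sym, num = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        n = int(num) if num else 1
        if n < 0:
            raise FormulaError(f"negative count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return {k: v for k, v in counts.items() if v > 0}


def format_formula(counts: ElementCounts) -> str:
    """Serialize element counts in Hill order (C, H, then alphabetical)."""
    parts = []
    order = [e for e in ("C", "H") if counts.get(e)]
    order += sorted(e for e in counts if e not in ("C", "H") and counts[e])
    for e in order:
        n = counts[e]
        parts.append(e if n == 1 else f"{e}{n}")
    return "".join(parts)


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Sum of most-abundant-isotope atomic masses, Da."""
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in counts.items())


def add_counts(a: ElementCounts, b: ElementCounts, sign: int = 1) -> ElementCounts:
    out = dict(a)
    for e, n in b.items():
        out[e] = out.get(e, 0) + sign * n
    return {e: n for e, n in out.items() if n != 0}


@dataclass(frozen=True)
class IonSpec:
    """An adduct/charge specification such as [M+H]+ or [M+2H]2+.

    ``delta`` is the signed element change relative to the neutral molecule;
    ``polarity`` is "pos" or "neg"; ``charge`` is the absolute charge z >= 1.
    """

    label: str
    polarity: str
    charge: int
    delta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.polarity not in ("pos", "neg"):
            raise ValueError(f"polarity must be pos|neg, got {self.polarity!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")


_ADDUCT_RE = re.compile(r"^\[M(?P<body>(?:[+−–-]\d*[A-Za-z][A-Za-z0-9]*)*)\](?P<z>\d*)(?P<sign>[+−–-])$")
_ADDUCT_PART = re.compile(r"([+−–-])(\d*)([A-Za-z][A-Za-z0-9]*)")


def parse_adduct(label: str) -> IonSpec:
    """Parse an adduct label in the MassBank PRECURSOR_TYPE dialect.

    Supports e.g. ``[M+H]+``, ``[M-H]-``, ``[M+2H]2+``, ``[M+Na]+``,
    ``[M+H-H2O]+``. Unicode minus signs are accepted.
    """
    m = _ADDUCT_RE.match(label.strip())
    if not m:
        raise ValueError(f"cannot parse adduct label {label!r}")
    z = int(m.group("z")) if m.group("z") else 1
    polarity = "pos" if m.group("sign") == "+" else "neg"
    delta: ElementCounts = {}
    for sign_c, mult, part in _ADDUCT_PART.findall(m.group("body")):
        sign = 1 if sign_c == "+" else -1
        mult_n = int(mult) if mult else 1
        delta = add_counts(delta, {e: n * mult_n for e, n in parse_formula(part).items()}, sign)
    return IonSpec(label=label.strip().replace("−", "-").replace("–", "-"),
                   polarity=polarity, charge=z, delta=delta)


def ion_formula(neutral: ElementCounts, ion: IonSpec) -> ElementCounts:
    """Element counts of the intact ion (neutral plus adduct atoms)."""
    out = add_counts(neutral, ion.delta)
    bad = {e: n for e, n in out.items() if n < 0}
    if bad:
        raise ValueError(f"adduct {ion.label} leaves negative counts {bad}")
    return out


def ion_mz(neutral: ElementCounts, ion: IonSpec) -> float:
    """m/z of an adduct ion; electron mass included.

    m/z = (mass(M +/- adduct atoms) - z*m_e*sign) / z with sign +1 for
    positive ions.
    """
    f = ion_formula(neutral, ion)
    sign = 1 if ion.polarity == "pos" else -1
    return (monoisotopic_mass(f) - sign * ion.charge * ELECTRON_MASS) / ion.charge


def formula_ion_mz(ion_counts: ElementCounts, polarity: str, charge: int = 1) -> float:
    """m/z of an ion whose full elemental composition is ``ion_counts``."""
    sign = 1 if polarity == "pos" else -1
    return (monoisotopic_mass(ion_counts) - sign * charge * ELECTRON_MASS) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def rdbe(counts: ElementCounts) -> float:
    """Ring-plus-double-bond equivalents (rings + pi bonds) of a formula."""
    c = counts.get("C", 0)
    n = counts.get("N", 0) + counts.get("P", 0)
    h = (counts.get("H", 0) + counts.get("Cl", 0) + counts.get("Br", 0)
         + counts.get("F", 0) + counts.get("I", 0)
         + counts.get("Na", 0) + counts.get("K", 0))
    return c + 1 + (n - h) / 2.0


GAS_ADDUCTS: dict[str, ElementCounts] = {
    "none": {},
    "N2": {"N": 2},
    "O": {"O": 1},
    "N2O": {"N": 2, "O": 1},
}


@dataclass(frozen=True)
class FormulaCandidate:
    """One candidate ion formula for an observed fragment peak."""

    counts_key: tuple  # sorted (element, count) tuple, hashable
    mz: float
    ppm: float
    gas_adduct: str = "none"

    @property
    def counts(self) -> ElementCounts:
        return dict(self.counts_key)

    @property
    def formula(self) -> str:
        return format_formula(self.counts)


def _iter_subformulas(pool: list[tuple[str, int]], lo: float, hi: float) -> Iterator[tuple[ElementCounts, float]]:
    """DFS over the element-count lattice bounded by ``pool``, pruned by mass.

    Elements are visited heaviest-first so remaining-mass bounds prune early.
    Yields (counts, monoisotopic mass) for every subformula with mass in
    [lo, hi].
    """
    pool = sorted(pool, key=lambda p: -MONOISOTOPIC_MASS[p[0]])
    # max mass attainable from pool[i:]
    suffix_max = [0.0] * (len(pool) + 1)
    for i in range(len(pool) - 1, -1, -1):
        e, nmax = pool[i]
        suffix_max[i] = suffix_max[i + 1] + MONOISOTOPIC_MASS[e] * nmax

    counts: ElementCounts = {}

    def rec(i: int, mass: float) -> Iterator[tuple[ElementCounts, float]]:
        if mass > hi:
            return
        if i == len(pool):
            if mass >= lo:
                yield dict(counts), mass
            return
        if mass + suffix_max[i] < lo:
            return
        e, nmax = pool[i]
        me = MONOISOTOPIC_MASS[e]
        for n in range(nmax + 1):
            m2 = mass + me * n
            if m2 > hi:
                break
            if n:
                counts[e] = n
            yield from rec(i + 1, m2)
        counts.pop(e, None)

    yield from rec(0, 0.0)


_LATTICE_LIMIT = 2_000_000
_pool_tables: dict[tuple, tuple] = {}


def _pool_table(pool_key: tuple) -> tuple | None:
    """Precomputed (sorted masses, count matrix, elements) for a pool.

    The full subformula lattice of a precursor-ion pool is small enough to
    tabulate once (a few hundred thousand rows for a 1 kDa natural
    product); queries then reduce to a binary search. Pools beyond the size
    limit fall back to the pruned DFS.
    """
    if pool_key in _pool_tables:
        return _pool_tables[pool_key]
    size = 1
    for _, n in pool_key:
        size *= n + 1
    if size > _LATTICE_LIMIT:
        _pool_tables[pool_key] = None
        return None
    elements = [e for e, _ in pool_key]
    ranges = [range(n + 1) for _, n in pool_key]
    counts = np.array(list(itertools.product(*ranges)), dtype=np.int16)
    masses = counts @ np.array([MONOISOTOPIC_MASS[e] for e in elements])
    order = np.argsort(masses, kind="stable")
    table = (masses[order], counts[order], elements)
    if len(_pool_tables) > 32:
        _pool_tables.clear()
    _pool_tables[pool_key] = table
    return table


def enumerate_subformulas(
    precursor_ion: ElementCounts,
    observed_mz: float,
    tol_ppm: float,
    polarity: str,
    gas_adducts: bool = False,
    charge: int = 1,
    dbe_filter: bool = False,
) -> list[FormulaCandidate]:
    """All ion formulas drawn from the precursor-ion element pool that match
    ``observed_mz`` within ``tol_ppm``.

    With ``gas_adducts`` the pool is additionally extended by N2, O and N2O
    (collision-gas adduction); a candidate that needs the extension carries
    the corresponding flag. Results are sorted by |ppm error|; a formula
    reachable without gas addition is never flagged.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    sign = 1 if polarity == "pos" else -1
    target_mass = observed_mz * charge + sign * charge * ELECTRON_MASS
    half = target_mass * tol_ppm / 1e6
    found: dict[tuple, FormulaCandidate] = {}
    options = ["none", "N2", "O", "N2O"] if gas_adducts else ["none"]
    for gas in options:
        pool_counts = add_counts(precursor_ion, GAS_ADDUCTS[gas])
        pool = [(e, n) for e, n in pool_counts.items() if n > 0]
        pool_key = tuple(sorted(pool))
        table = _pool_table(pool_key)
        if table is not None:
            masses, count_mat, elements = table
            lo = int(np.searchsorted(masses, target_mass - half, side="left"))
            hi = int(np.searchsorted(masses, target_mass + half, side="right"))
            hits = (
                ({e: int(c) for e, c in zip(elements, count_mat[i]) if c}, float(masses[i]))
                for i in range(lo, hi)
            )
        else:
            hits = _iter_subformulas(pool, target_mass - half, target_mass + half)
        for counts, mass in hits:
            key = tuple(sorted(counts.items()))
            if key in found:  # reachable with less (or no) gas addition
                continue
            if gas != "none":
                # flag only formulas that genuinely exceed the precursor pool
                if all(counts.get(e, 0) <= precursor_ion.get(e, 0) for e in counts):
                    continue
            if dbe_filter and rdbe(counts) < -0.5:
                continue
            mz = (mass - sign * charge * ELECTRON_MASS) / charge
            found[key] = FormulaCandidate(
                counts_key=key, mz=mz, ppm=ppm_error(observed_mz, mz), gas_adduct=gas
            )
    return sorted(found.values(), key=lambda c: (abs(c.ppm), c.counts_key))
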