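"""Formula arithmetic, ion m/z and subformula enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscurate.chem import (
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    FormulaError,
    enumerate_subformulas,
    format_formula,
    formula_ion_mz,
    ion_formula,
    ion_mz,
    monoisotopic_mass,
    parse_adduct,
    parse_formula,
    ppm_error,
    rdbe,
)


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("C49H74N10O12", {"C": 49, "H": 74, "N": 10, "O": 12}),
            ("C2H3NO", {"C": 2, "H": 3, "N": 1, "O": 1}),
            ("H2O", {"H": 2, "O": 1}),
            ("C21H17BrCl2N2O12", {"C": 21, "H": 17, "Br": 1, "Cl": 2, "N": 2, "O": 12}),
        ],
    )
    def test_parses_hill_notation(self, text, expected):
        assert parse_formula(text) == expected

    @pytest.mark.parametrize("bad", ["", "   ", "Xx12", "C6H12O6!", "6CH12"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    @given(
        st.dictionaries(
            st.sampled_from(sorted(MONOISOTOPIC_MASS)),
            st.integers(min_value=1, max_value=99),
            min_size=1,
            max_size=6,
        )
    )
    @settings(derandomize=True, max_examples=60)
    def test_serialize_parse_identity(self, counts):
        assert parse_formula(format_formula(counts)) == counts


class TestMasses:
    def test_empty_formula_is_massless(self):
        assert monoisotopic_mass({}) == 0.0

    @pytest.mark.parametrize(
        "counts,mass",
        [({"H": 2, "O": 1}, 18.010565), ({"C": 6, "H": 12, "O": 6}, 180.063388)],
    )
    def test_monoisotopic_reference_values(self, counts, mass):
        assert monoisotopic_mass(counts) == pytest.approx(mass, abs=1e-6)

    def test_protonated_water(self):
        # electron mass included: (18.010565 + 1.007825 - 0.000549) / 1
        assert ion_mz({"H": 2, "O": 1}, parse_adduct("[M+H]+")) == pytest.approx(
            19.017841, abs=2e-6
        )

    def test_deprotonated_water(self):
        assert ion_mz({"H": 2, "O": 1}, parse_adduct("[M-H]-")) == pytest.approx(
            17.003289, abs=2e-6
        )

    def test_doubly_protonated_peptide(self):
        mz = ion_mz(parse_formula("C49H74N10O12"), parse_adduct("[M+2H]2+"))
        assert mz == pytest.approx(498.281676, abs=5e-5)

    def test_pos_neg_gap_is_two_protons_less_electrons(self):
        neutral = parse_formula("C6H12O6")
        gap = ion_mz(neutral, parse_adduct("[M+H]+")) - ion_mz(neutral, parse_adduct("[M-H]-"))
        expected = 2 * (MONOISOTOPIC_MASS["H"] - ELECTRON_MASS)
        assert gap == pytest.approx(expected, abs=1e-6)

    def test_adduct_polarity_consistency(self):
        ion = parse_adduct("[M+2H]2+")
        assert ion.charge == 2 and ion.polarity == "pos" and ion.delta == {"H": 2}
        with pytest.raises(ValueError):
            parse_adduct("[M*H]+")

    def test_adduct_subtraction_cannot_go_negative(self):
        with pytest.raises(ValueError):
            ion_formula({"C": 2}, parse_adduct("[M-H]-"))


class TestPpmError:
    def test_identity_is_zero(self):
        assert ppm_error(100.0, 100.0) == 0.0

    def test_signed_values(self):
        assert ppm_error(181.072100, 181.070665) == pytest.approx(7.93, abs=0.01)
        assert ppm_error(119.999, 120.0) == pytest.approx(-8.33, abs=0.01)

    def test_requires_positive_theoretical(self):
        with pytest.raises(ValueError):
            ppm_error(100.0, 0.0)


def brute_force_subformulas(precursor_ion, observed_mz, tol_ppm, polarity,
                            gas_adducts=False):
    """Independent oracle: exhaustive loop over the element-count lattice."""
    from mscurate.chem import GAS_ADDUCTS, add_counts

    sign = 1 if polarity == "pos" else -1
    results = {}
    options = ["none", "N2", "O", "N2O"] if gas_adducts else ["none"]
    for gas in options:
        pool = add_counts(precursor_ion, GAS_ADDUCTS[gas])
        elements = sorted(pool)
        for combo in itertools.product(*(range(pool[e] + 1) for e in elements)):
            counts = {e: c for e, c in zip(elements, combo) if c}
            mz = (monoisotopic_mass(counts) - sign * ELECTRON_MASS) / 1
            if mz <= 0:
                continue
            if abs(ppm_error(observed_mz, mz)) <= tol_ppm:
                key = tuple(sorted(counts.items()))
                results.setdefault(key, gas)
    return results


class TestEnumerateSubformulas:
    def test_precursor_self_match(self):
        pool = ion_formula(parse_formula("C6H12O6"), parse_adduct("[M+H]+"))
        mz = formula_ion_mz(pool, "pos")
        cands = enumerate_subformulas(pool, mz, 5.0, "pos")
        assert cands[0].counts == pool
        assert cands[0].ppm == pytest.approx(0.0, abs=1e-9)

    def test_methanol_fragment_unique(self):
        cands = enumerate_subformulas({"C": 2, "H": 7, "O": 1}, 31.017841, 5.0, "pos")
        assert [c.formula for c in cands] == ["CH3O"]

    @pytest.mark.parametrize("formula,adduct", [
        ("C10H14N2O4", "[M+H]+"),
        ("C9H14O7", "[M-H]-"),
        ("C8H10N4O2", "[M+H]+"),
    ])
    def test_matches_brute_force_lattice_scan(self, formula, adduct, rng):
        ion = parse_adduct(adduct)
        pool = ion_formula(parse_formula(formula), ion)
        assert sum(pool.values()) <= 40
        for _ in range(25):
            mz = float(rng.uniform(50, monoisotopic_mass(pool)))
            for gas in (False, True):
                got = enumerate_subformulas(pool, mz, 10.0, ion.polarity,
                                            gas_adducts=gas)
                oracle = brute_force_subformulas(pool, mz, 10.0, ion.polarity,
                                                 gas_adducts=gas)
                assert {c.counts_key for c in got} == set(oracle)
                for c in got:
                    assert c.gas_adduct == oracle[c.counts_key]

    def test_widening_tolerance_is_monotone(self, rng):
        pool = ion_formula(parse_formula("C10H14N2O4"), parse_adduct("[M+H]+"))
        for _ in range(20):
            mz = float(rng.uniform(60, 220))
            narrow = {c.counts_key for c in enumerate_subformulas(pool, mz, 5.0, "pos")}
            wide = {c.counts_key for c in enumerate_subformulas(pool, mz, 15.0, "pos")}
            assert narrow <= wide

    def test_sorted_by_abs_ppm(self, rng):
        pool = ion_formula(parse_formula("C20H30N4O6"), parse_adduct("[M+H]+"))
        for _ in range(10):
            cands = enumerate_subformulas(pool, float(rng.uniform(100, 400)), 15.0, "pos")
            ppms = [abs(c.ppm) for c in cands]
            assert ppms == sorted(ppms)

    def test_gas_adduct_flag_only_when_needed(self):
        # CH3O + N2 is only explicable with collision-gas addition
        pool = {"C": 2, "H": 7, "O": 1}
        target = formula_ion_mz({"C": 1, "H": 3, "O": 1, "N": 2}, "pos")
        cands = enumerate_subformulas(pool, target, 5.0, "pos", gas_adducts=True)
        flagged = [c for c in cands if c.counts == {"C": 1, "H": 3, "O": 1, "N": 2}]
        assert flagged and flagged[0].gas_adduct == "N2"
        assert not enumerate_subformulas(pool, target, 5.0, "pos", gas_adducts=False)

    def test_dbe_filter_removes_infeasible(self):
        pool = {"C": 2, "H": 9, "O": 1}  # H-saturated pool
        mz = formula_ion_mz({"H": 5, "O": 1}, "pos")
        unfiltered = enumerate_subformulas(pool, mz, 5.0, "pos")
        filtered = enumerate_subformulas(pool, mz, 5.0, "pos", dbe_filter=True)
        assert {c.counts_key for c in filtered} <= {c.counts_key for c in unfiltered}
        for c in filtered:
            assert rdbe(c.counts) >= -0.5
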