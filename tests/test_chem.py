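"""Sum-composition arithmetic, enumeration and isotope patterns."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidquery import chem
from lipidquery.chem import (
    FormulaError,
    SCConstraint,
    SumComposition,
    Tolerance,
    dbr,
    enumerate_compositions,
    isotope_pattern,
    monoisotopic_mz,
    parse_sc_constraint,
    parse_sum_composition,
)


class TestParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C5 H15 O4 N1 P1", {"C": 5, "H": 15, "O": 4, "N": 1, "P": 1}),
            ("H1", {"H": 1}),
            ("C44 H87 N1 O8 P1", {"C": 44, "H": 87, "N": 1, "O": 8, "P": 1}),
            ("CH4", {"C": 1, "H": 4}),  # omitted count means 1
        ],
    )
    def test_formula_counts(self, text, expected):
        assert parse_sum_composition(text).as_dict() == expected

    @pytest.mark.parametrize("bad", ["Xx5", "C5 Q1", "5C", "", "C5 1"])
    def test_malformed_formula_rejected(self, bad):
        with pytest.raises(FormulaError):
            parse_sum_composition(bad)

    def test_constraint_ranges(self):
        c = parse_sc_constraint(
            "C[30..48]H[30..200]N[1]O[8]P[1]", charge=1, dbr_range=(1.5, 7.5)
        )
        assert dict((el, (lo, hi)) for el, lo, hi in c.ranges) == {
            "C": (30, 48), "H": (30, 200), "N": (1, 1), "O": (8, 8), "P": (1, 1)
        }
        assert c.charge == 1 and c.dbr_range == (1.5, 7.5)

    def test_constraint_rejects_inverted_range(self):
        with pytest.raises(FormulaError):
            SCConstraint((("C", 5, 3),))

    def test_subtraction_below_zero_is_error(self):
        a = parse_sum_composition("C2 H4")
        b = parse_sum_composition("C3")
        with pytest.raises(FormulaError):
            a - b

    def test_canonical_string(self):
        sc = parse_sum_composition("P1 O8 N1 H87 C44")
        assert str(sc) == "C44 H87 N1 O8 P1"


class TestMass:
    def test_head_group_fragment_mz(self):
        sc = parse_sum_composition("C5 H15 O4 N1 P1", charge=+1)
        assert monoisotopic_mz(sc) == pytest.approx(184.0733, abs=5e-4)

    def test_proton_mass(self):
        sc = SumComposition.from_dict({"H": 1}, charge=+1)
        assert monoisotopic_mz(sc) == pytest.approx(1.00728, abs=1e-5)

    def test_ch4_vs_o_split(self):
        ch4 = parse_sum_composition("C1 H4")
        o = parse_sum_composition("O1")
        delta = abs(monoisotopic_mz(ch4) - monoisotopic_mz(o))
        assert delta * 1000 == pytest.approx(36.4, abs=0.05)

    def test_protonated_pc_36_1(self):
        sc = parse_sum_composition("C44 H87 N1 O8 P1", charge=+1)
        assert monoisotopic_mz(sc) == pytest.approx(788.6164, abs=5e-4)

    def test_electron_mass_matters(self):
        sc = parse_sum_composition("C5 H15 O4 N1 P1")
        cation = SumComposition(sc.counts, charge=+1)
        anion = SumComposition(sc.counts, charge=-1)
        assert monoisotopic_mz(anion) - monoisotopic_mz(cation) == pytest.approx(
            2 * chem.ELECTRON_MASS, abs=1e-9
        )

    def test_empty_composition_rejected(self):
        with pytest.raises(FormulaError):
            monoisotopic_mz(SumComposition((), 0))

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "P", "S"]),
            st.integers(0, 50),
            min_size=1,
        ).filter(lambda d: sum(d.values()) > 0),
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "P", "S"]),
            st.integers(0, 50),
            min_size=1,
        ).filter(lambda d: sum(d.values()) > 0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mass_additivity(self, a, b):
        sa = SumComposition.from_dict(a)
        sb = SumComposition.from_dict(b)
        assert monoisotopic_mz(sa + sb) == pytest.approx(
            monoisotopic_mz(sa) + monoisotopic_mz(sb), rel=1e-12
        )


class TestDbr:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C44 H87 N1 O8 P1", 2.5),  # protonated PC 36:1 as written
            ("C1 H4", 0.0),             # methane
            ("C6 H6", 4.0),             # benzene: 3 C=C + 1 ring
            ("C5 H15 O4 N1 P1", -0.5),  # protonated head-group fragment as written
        ],
    )
    def test_known_values(self, formula, expected):
        assert dbr(parse_sum_composition(formula)) == pytest.approx(expected)

    @given(
        st.dictionaries(st.sampled_from(["C", "H", "N", "O", "P"]),
                        st.integers(0, 30), min_size=1).filter(lambda d: d),
        st.dictionaries(st.sampled_from(["C", "H", "N", "O", "P"]),
                        st.integers(0, 30), min_size=1).filter(lambda d: d),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_dbr_additivity(self, a, b):
        # the constant "+1" ring term is counted once in a combined formula
        sa, sb = SumComposition.from_dict(a), SumComposition.from_dict(b)
        assert dbr(sa + sb) == pytest.approx(dbr(sa) + dbr(sb) - 1.0)


class TestEnumeration:
    def test_pc_constraint_contains_pc361(self):
        c = parse_sc_constraint(
            "C[30..48]H[30..200]N[1]O[8]P[1]", charge=1, dbr_range=(1.5, 7.5)
        )
        out = enumerate_compositions(c, 788.6164, Tolerance(5, "ppm"))
        assert [str(s) for s in out] == ["C44 H87 N1 O8 P1"]

    def test_below_lightest_mass_is_empty(self):
        c = parse_sc_constraint("C[30..48]H[30..200]N[1]O[8]P[1]", charge=1)
        assert enumerate_compositions(c, 10.0, Tolerance(1, "ppm")) == []

    def test_methane_unique(self):
        c = parse_sc_constraint("C[1..2]H[1..6]", charge=0, dbr_range=(-1, 5))
        target = monoisotopic_mz(parse_sum_composition("C1 H4"))
        out = enumerate_compositions(c, target, Tolerance(1, "ppm"))
        assert [s.as_dict() for s in out] == [{"C": 1, "H": 4}]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ranges = tuple(
            (el, int(lo), int(lo + span))
            for el, lo, span in [
                ("C", rng.integers(0, 20), rng.integers(1, 12)),
                ("H", rng.integers(0, 30), rng.integers(1, 25)),
                ("O", rng.integers(0, 4), rng.integers(1, 4)),
                ("N", 0, rng.integers(0, 2)),
            ]
        )
        c = SCConstraint(ranges, charge=int(rng.integers(-1, 2)))
        target = float(rng.uniform(50, 400))
        tol = Tolerance(float(rng.uniform(5, 500)), "ppm")
        fast = enumerate_compositions(c, target, tol)
        brute = chem._brute_force_enumerate(c, target, tol)
        assert [s.as_dict() for s in fast] == [s.as_dict() for s in brute]

    def test_sorted_by_mass_error(self):
        c = parse_sc_constraint("C[1..30]H[1..60]O[0..4]", charge=0)
        out = enumerate_compositions(c, 200.0, Tolerance(0.05, "da"))
        errs = [abs(monoisotopic_mz(s) - 200.0) for s in out]
        assert errs == sorted(errs)


def _enumerate_isotopologues(sc: SumComposition, n_peaks: int):
    """Exhaustive per-atom oracle for tiny molecules: every isotope choice."""
    atoms = [el for el, n in sc.counts for _ in range(n)]
    agg_ab: dict[int, float] = {}
    agg_m: dict[int, float] = {}
    choices = [list(chem.ISOTOPES[el].items()) for el in atoms]
    base = [min(ch, key=lambda kv: -kv[1][1])[0] for ch in choices]
    for combo in itertools.product(*choices):
        off = sum(nom - b for (nom, _), b in zip(combo, base))
        ab = float(np.prod([a for _, (_, a) in combo]))
        mass = sum(m for _, (m, _) in combo)
        agg_ab[off] = agg_ab.get(off, 0.0) + ab
        agg_m[off] = agg_m.get(off, 0.0) + ab * mass
    return {
        k: (agg_m[k] / agg_ab[k], agg_ab[k] / agg_ab[0])
        for k in sorted(agg_ab)[:n_peaks]
        if agg_ab[k] > 0
    }


class TestIsotopePattern:
    def test_single_carbon_ratio(self):
        pat = isotope_pattern(SumComposition.from_dict({"C": 1}), 2)
        table = chem.ISOTOPES["C"]
        assert pat.ratio(1) == pytest.approx(table[13][1] / table[12][1], rel=0.02)

    def test_h2_ratio_is_twice_deuterium(self):
        pat = isotope_pattern(SumComposition.from_dict({"H": 2}), 2)
        d, h = chem.ISOTOPES["H"][2][1], chem.ISOTOPES["H"][1][1]
        assert pat.ratio(1) == pytest.approx(2 * d / h, rel=0.01)

    def test_phosphorus_monoisotopic(self):
        pat = isotope_pattern(SumComposition.from_dict({"P": 1}), 3)
        assert pat.ratio(1) == 0.0 and pat.ratio(2) == 0.0

    def test_offset0_normalized_and_mz_increasing(self):
        sc = parse_sum_composition("C44 H87 N1 O8 P1", charge=+1)
        pat = isotope_pattern(sc, 4)
        assert pat.abundances[0] == 1.0
        assert all(b > a for a, b in zip(pat.mzs, pat.mzs[1:]))

    @pytest.mark.parametrize(
        "formula", ["C3 H5 O1", "C2 H2 S1", "C4 N1 H3", "O2 H2"]
    )
    def test_matches_exhaustive_oracle(self, formula):
        sc = parse_sum_composition(formula)
        pat = isotope_pattern(sc, 3)
        oracle = _enumerate_isotopologues(sc, 3)
        for k, (mass, ab) in oracle.items():
            assert pat.ratio(k) == pytest.approx(ab, abs=1e-9)
            if ab > 0:
                assert pat.mzs[k] == pytest.approx(mass, abs=1e-6)

    def test_large_composition_sums_to_binomial_total(self):
        # truncated pattern re-normalized to total 1 matches the closed-form
        # binomial for a pure-carbon chain
        n = 100
        pat = isotope_pattern(SumComposition.from_dict({"C": n}), 5)
        p13 = chem.ISOTOPES["C"][13][1]
        p12 = chem.ISOTOPES["C"][12][1]
        from math import comb
        for k in range(5):
            expected = comb(n, k) * (p13 / p12) ** k
            assert pat.ratio(k) == pytest.approx(expected, rel=1e-6)
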