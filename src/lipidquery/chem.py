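"""Elemental sum-composition arithmetic for shotgun lipidomics.

A *sum composition* is the elemental formula of an ion (e.g. the protonated
phosphorylcholine head-group fragment ``C5 H15 O4 N1 P1`` with charge +1).
This module provides monoisotopic mass/(m/z) arithmetic, the double-bond
equivalent (DBR), exhaustive enumeration of compositions under per-element
range constraints (sc-constraints such as ``C[30..48]H[30..200]N[1]O[8]P[1]``),
and isotope-pattern computation by polynomial convolution over natural
isotope abundances.

All masses are monoisotopic and in Da; the electron mass is accounted for in
m/z so that sub-ppm work at resolution 100,000 is meaningful.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "SumComposition",
    "SCConstraint",
    "IsotopePattern",
    "Tolerance",
    "parse_sum_composition",
    "parse_sc_constraint",
    "monoisotopic_mz",
    "dbr",
    "enumerate_compositions",
    "isotope_pattern",
]

ELECTRON_MASS = 0.000548579909  # Da, CODATA

# Fixed embedded isotope table (IUPAC 2013 atomic masses / representative
# abundances).  Each entry: nominal mass -> (exact mass, abundance).
# Embedding the table keeps results reproducible offline.
ISOTOPES: dict[str, dict[int, tuple[float, float]]] = {
    "H": {1: (1.0078250319, 0.999885), 2: (2.0141017781, 0.000115)},
    "C": {12: (12.0, 0.9893), 13: (13.0033548378, 0.0107)},
    "N": {14: (14.0030740052, 0.99636), 15: (15.0001088984, 0.00364)},
    "O": {
        16: (15.9949146221, 0.99757),
        17: (16.9991315000, 0.00038),
        18: (17.9991604000, 0.00205),
    },
    "P": {31: (30.9737615100, 1.0)},
    "S": {
        32: (31.9720706900, 0.9499),
        33: (32.9714585000, 0.0075),
        34: (33.9678668300, 0.0425),
        36: (35.9670808800, 0.0001),
    },
    "Na": {23: (22.9897692800, 1.0)},
    "K": {39: (38.9637064864, 0.932581), 40: (39.9639981660, 0.000117),
          41: (40.9618252579, 0.067302)},
    "Cl": {35: (34.9688526800, 0.7576), 37: (36.9659025900, 0.2424)},
    "F": {19: (18.9984031600, 1.0)},
    "Li": {6: (6.0151228874, 0.0759), 7: (7.0160034366, 0.9241)},
}

#: monoisotopic (= most abundant isotope) mass per element
MONOISOTOPIC_MASS: dict[str, float] = {
    el: max(isos.values(), key=lambda t: t[1])[0] for el, isos in ISOTOPES.items()
}

# Valences for the generalized double-bond-equivalent term
# DBR = 1 + sum n_i (v_i - 2) / 2.  Phosphorus is assigned valence 3 so that
# it contributes +1/2, which reproduces db = DBR - 1.5 = 1 for PC 36:1.
_VALENCE: dict[str, int] = {
    "H": 1, "C": 4, "N": 3, "O": 2, "P": 3, "S": 2,
    "F": 1, "Cl": 1, "Na": 1, "K": 1, "Li": 1,
}

# Canonical element print order: C, H first, remainder alphabetical.
def _element_sort_key(el: str) -> tuple[int, str]:
    return ({"C": 0, "H": 1}.get(el, 2), el)


class FormulaError(ValueError):
    """Malformed formula / constraint string or invalid composition."""


@dataclass(frozen=True)
class SumComposition:
    """Elemental formula with an ion charge state (0 = neutral).

    Element counts are non-negative integers; subtraction that would drive a
    count negative raises :class:`FormulaError` (a fragment cannot contain
    atoms absent from its precursor).
    """

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    @staticmethod
    def from_dict(counts: dict[str, int], charge: int = 0) -> "SumComposition":
        for el, n in counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {el}: {n}")
        items = tuple(
            (el, int(n))
            for el, n in sorted(counts.items(), key=lambda kv: _element_sort_key(kv[0]))
            if n > 0
        )
        return SumComposition(items, charge)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, element: str) -> float:
        if element == "db":
            return dbr(self)
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol: {element!r}")
        return dict(self.counts).get(element, 0)

    def __add__(self, other: "SumComposition") -> "SumComposition":
        merged = dict(self.counts)
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return SumComposition.from_dict(merged, self.charge + other.charge)

    def __sub__(self, other: "SumComposition") -> "SumComposition":
        merged = dict(self.counts)
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"subtraction yields negative count for {el}"
                )
        return SumComposition.from_dict(merged, self.charge - other.charge)

    @property
    def n_atoms(self) -> int:
        return sum(n for _, n in self.counts)

    @property
    def neutral_mass(self) -> float:
        """Monoisotopic mass of the formula as written, no electron term."""
        if not self.counts:
            raise FormulaError("empty composition has no mass")
        return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts)

    @property
    def mz(self) -> float:
        return monoisotopic_mz(self)

    def __str__(self) -> str:
        return " ".join(f"{el}{n}" for el, n in self.counts)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_sum_composition(text: str, charge: int = 0) -> SumComposition:
    """Parse a formula string like ``'C5 H15 O4 N1 P1'``.

    An omitted count means 1.  Unknown element symbols and malformed tokens
    are errors.
    """
    counts: dict[str, int] = {}
    pos = 0
    stripped = text.strip()
    if not stripped:
        raise FormulaError("empty formula string")
    while pos < len(stripped):
        if stripped[pos].isspace():
            pos += 1
            continue
        m = _FORMULA_TOKEN.match(stripped, pos)
        if not m or not m.group(1):
            raise FormulaError(f"malformed formula token at {stripped[pos:]!r}")
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol: {el!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    return SumComposition.from_dict(counts, charge)


@dataclass(frozen=True)
class SCConstraint:
    """Per-element closed count ranges plus charge and a DBR interval.

    Mirrors the query dialect ``C[30..48]H[30..200]N[1]O[8]P[1]``
    ``WITH CHG = +1, DBR = (1.5, 7.5)``.
    """

    ranges: tuple[tuple[str, int, int], ...]
    charge: int = 0
    dbr_range: tuple[float, float] = (-float("inf"), float("inf"))

    def __post_init__(self):
        for el, lo, hi in self.ranges:
            if el not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if lo > hi or lo < 0:
                raise FormulaError(f"bad range for {el}: [{lo}..{hi}]")
        if self.dbr_range[0] > self.dbr_range[1]:
            raise FormulaError(f"bad DBR range: {self.dbr_range}")

    def admits(self, sc: SumComposition) -> bool:
        counts = sc.as_dict()
        for el, lo, hi in self.ranges:
            if not lo <= counts.get(el, 0) <= hi:
                return False
        if set(counts) - {el for el, _, _ in self.ranges}:
            return False
        lo, hi = self.dbr_range
        return lo <= dbr(sc) <= hi


_RANGE_TOKEN = re.compile(r"([A-Z][a-z]?)\[(\d+)(?:\.\.(\d+))?\]")


def parse_sc_constraint(
    text: str,
    charge: int = 0,
    dbr_range: tuple[float, float] = (-float("inf"), float("inf")),
) -> SCConstraint:
    """Parse a bracketed range dialect string ``C[30..48]H[30..200]...``."""
    ranges = []
    pos = 0
    stripped = text.strip()
    if not stripped:
        raise FormulaError("empty constraint string")
    while pos < len(stripped):
        if stripped[pos].isspace():
            pos += 1
            continue
        m = _RANGE_TOKEN.match(stripped, pos)
        if not m:
            raise FormulaError(f"malformed constraint token at {stripped[pos:]!r}")
        el, lo, hi = m.group(1), int(m.group(2)), m.group(3)
        ranges.append((el, lo, int(hi) if hi is not None else lo))
        pos = m.end()
    return SCConstraint(tuple(ranges), charge, dbr_range)


def monoisotopic_mz(sc: SumComposition) -> float:
    """m/z of the ion; neutral monoisotopic mass when charge is 0.

    m/z = (sum of monoisotopic element masses - charge * m_e) / |charge|.
    """
    mass = sc.neutral_mass
    if sc.charge == 0:
        return mass
    return (mass - sc.charge * ELECTRON_MASS) / abs(sc.charge)


def dbr(sc: SumComposition) -> float:
    """Double-bond equivalents of the formula as written.

    Generalized valence form 1 + sum n_i (v_i - 2)/2; over C,H,N,O,P this is
    1 + C - H/2 + (N + P)/2.  Evaluated on the ion formula including any
    charge-carrying hydrogens.
    """
    return 1.0 + sum(
        n * (_VALENCE[el] - 2) for el, n in sc.counts if el in _VALENCE
    ) / 2.0


@dataclass(frozen=True)
class Tolerance:
    """Mass-match tolerance, either relative (ppm) or absolute (Da)."""

    value: float
    unit: str = "ppm"  # "ppm" | "da"

    def __post_init__(self):
        if self.unit not in ("ppm", "da"):
            raise ValueError(f"tolerance unit must be 'ppm' or 'da', got {self.unit!r}")
        if self.value < 0:
            raise ValueError("tolerance must be non-negative")

    @staticmethod
    def parse(text: str | float | int | "Tolerance") -> "Tolerance":
        if isinstance(text, Tolerance):
            return text
        if isinstance(text, (int, float)):
            return Tolerance(float(text), "ppm")
        s = str(text).strip().lower()
        if s.endswith("ppm"):
            return Tolerance(float(s[:-3]), "ppm")
        if s.endswith("mda"):
            return Tolerance(float(s[:-3]) * 1e-3, "da")
        if s.endswith("da"):
            return Tolerance(float(s[:-2]), "da")
        return Tolerance(float(s), "ppm")

    def window(self, mz: float) -> float:
        """Half-width of the acceptance window at the given m/z, in Da."""
        return mz * self.value * 1e-6 if self.unit == "ppm" else self.value

    def matches(self, observed: float, theoretical: float) -> bool:
        return abs(observed - theoretical) <= self.window(theoretical)


def enumerate_compositions(
    constraint: SCConstraint, target_mz: float, tol: Tolerance | str | float
) -> list[SumComposition]:
    """All compositions admitted by *constraint* within *tol* of *target_mz*.

    Exhaustive depth-first search over the element count ranges with
    residual-mass pruning; results are sorted by |mass error| ascending, ties
    broken by element counts, so output order is deterministic.
    """
    tol = Tolerance.parse(tol)
    if not constraint.ranges:
        return []
    for _, lo, hi in constraint.ranges:
        if hi - lo > 10**6:
            raise FormulaError("unbounded constraint range")
    half = tol.window(target_mz)
    charge = constraint.charge
    # target neutral-formula mass (mass of the formula as written)
    target_mass = (
        target_mz * abs(charge) + charge * ELECTRON_MASS if charge else target_mz
    )
    elements = [el for el, _, _ in constraint.ranges]
    los = [lo for _, lo, _ in constraint.ranges]
    his = [hi for _, _, hi in constraint.ranges]
    masses = [MONOISOTOPIC_MASS[el] for el in elements]
    # residual min/max mass attainable from elements i..end
    n = len(elements)
    min_rest = [0.0] * (n + 1)
    max_rest = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        min_rest[i] = min_rest[i + 1] + los[i] * masses[i]
        max_rest[i] = max_rest[i + 1] + his[i] * masses[i]

    out: list[SumComposition] = []
    counts = [0] * n

    def recurse(i: int, acc_mass: float) -> None:
        if i == n:
            if abs(acc_mass - target_mass) <= half:
                sc = SumComposition.from_dict(dict(zip(elements, counts)), charge)
                if not sc.counts:
                    return
                lo_d, hi_d = constraint.dbr_range
                if lo_d <= dbr(sc) <= hi_d:
                    out.append(sc)
            return
        for c in range(los[i], his[i] + 1):
            m = acc_mass + c * masses[i]
            if m + min_rest[i + 1] > target_mass + half:
                break
            if m + max_rest[i + 1] < target_mass - half:
                continue
            counts[i] = c
            recurse(i + 1, m)
        counts[i] = los[i]

    recurse(0, 0.0)
    out.sort(
        key=lambda sc: (abs(monoisotopic_mz(sc) - target_mz), sc.counts)
    )
    return out


@dataclass(frozen=True)
class IsotopePattern:
    """Isotopologue cluster aggregated by nominal mass offset.

    ``offsets[k]`` is the nominal offset (0, 1, 2, ...), ``mzs[k]`` the
    abundance-weighted exact m/z of that aggregate, ``abundances[k]`` its
    abundance relative to the monoisotopic peak (offset 0 = 1).
    """

    offsets: tuple[int, ...]
    mzs: tuple[float, ...]
    abundances: tuple[float, ...]

    def ratio(self, k: int) -> float:
        """Abundance of the M+k aggregate relative to M+0."""
        for off, ab in zip(self.offsets, self.abundances):
            if off == k:
                return ab
        return 0.0


def _element_distribution(el: str) -> tuple[np.ndarray, np.ndarray]:
    """Single-atom (abundance, abundance*mass) arrays over nominal offset."""
    isos = ISOTOPES[el]
    base = min(
        isos, key=lambda nom: -isos[nom][1]
    )  # most abundant nominal mass = monoisotopic reference
    max_off = max(nom - base for nom in isos)
    a = np.zeros(max_off + 1)
    s = np.zeros(max_off + 1)
    for nom, (mass, ab) in isos.items():
        off = nom - base
        if off < 0:
            # lighter-than-principal isotopes (6Li, ...) are not relevant for
            # lipidomics formulas; fold them into offset 0
            off = 0
        a[off] += ab
        s[off] += ab * mass
    return a, s


def isotope_pattern(sc: SumComposition, n_peaks: int = 3) -> IsotopePattern:
    """Expected isotopologue cluster of a composition.

    Polynomial convolution of per-element natural isotope distributions,
    aggregated by nominal mass offset; abundances normalized so the
    monoisotopic (offset-0) aggregate is 1.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if not sc.counts:
        raise FormulaError("empty composition has no isotope pattern")
    a = np.array([1.0])
    s = np.array([0.0])
    for el, count in sc.counts:
        ea, es = _element_distribution(el)
        for _ in range(count):
            new_a = np.convolve(a, ea)
            new_s = np.convolve(s, ea) + np.convolve(a, es)
            a, s = new_a[:n_peaks], new_s[:n_peaks]
    a0 = a[0]
    offsets, mzs, abundances = [], [], []
    charge = sc.charge
    for k in range(min(n_peaks, len(a))):
        if a[k] <= 0:
            offsets.append(k)
            mzs.append(monoisotopic_mz(sc) + k * 1.0033548378 / max(abs(charge), 1))
            abundances.append(0.0)
            continue
        mass_k = s[k] / a[k]
        mz_k = (mass_k - charge * ELECTRON_MASS) / abs(charge) if charge else mass_k
        offsets.append(k)
        mzs.append(mz_k)
        abundances.append(a[k] / a0)
    return IsotopePattern(tuple(offsets), tuple(mzs), tuple(abundances))


def _brute_force_enumerate(
    constraint: SCConstraint, target_mz: float, tol: Tolerance
) -> list[SumComposition]:
    """Nested-loop oracle for :func:`enumerate_compositions` (tests only)."""
    elements = [el for el, _, _ in constraint.ranges]
    out = []
    for combo in itertools.product(
        *(range(lo, hi + 1) for _, lo, hi in constraint.ranges)
    ):
        sc = SumComposition.from_dict(dict(zip(elements, combo)), constraint.charge)
        if not sc.counts:
            continue
        lo_d, hi_d = constraint.dbr_range
        if not lo_d <= dbr(sc) <= hi_d:
            continue
        if abs(monoisotopic_mz(sc) - target_mz) <= tol.window(target_mz):
            out.append(sc)
    out.sort(key=lambda sc: (abs(monoisotopic_mz(sc) - target_mz), sc.counts))
    return out
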