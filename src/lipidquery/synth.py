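"""Synthetic shotgun-lipidomics datasets with known ground truth.

Two families of generators:

* the *template-spectrum* experiment: a ladder of peaks spaced by exactly
  m/R_template (R = 500) over 500-945 Da, from which replicate spectra are
  drawn with per-peak Gaussian mass jitter sigma = m/(2 R_instrument); this
  is the controlled dataset used to validate the alignment algorithm, and
* full lipid mixtures: species with known sum compositions and molar
  amounts, complete isotope envelopes in MS1, and data-dependent MS2 scans
  whose fragment content reflects everything co-isolated within the
  precursor isolation window - including the isotopologues of lighter
  neighbours that make isotopic correction necessary.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .averaging import ResolutionModel, resolution_at
from .chem import SumComposition, isotope_pattern, parse_sum_composition
from .spectra_io import Acquisition, Scan

__all__ = [
    "make_template",
    "generate_template_spectra",
    "LipidSpecies",
    "LipidGroundTruth",
    "simulate_acquisitions",
    "fatty_acid_anion",
    "glycerophospholipid",
    "protonated",
    "deprotonated",
    "pa_mixture_truth",
    "pc_truth",
    "pe_truth",
]

C13_SHIFT = 1.0033548378  # 13C - 12C, dominant isotopologue spacing


def make_template(R_template: float = 500.0, lo: float = 500.0, hi: float = 945.0) -> np.ndarray:
    """Template peak ladder: m_{k+1} = m_k + m_k / R_template, from lo to hi."""
    if not lo < hi or R_template <= 0:
        raise ValueError("need lo < hi and positive template resolution")
    masses = [lo]
    while True:
        nxt = masses[-1] * (1.0 + 1.0 / R_template)
        if nxt > hi or nxt - masses[-1] < 1e-9:
            # the infinite-resolution limit degenerates to a single mass
            break
        masses.append(nxt)
    return np.array(masses)


def generate_template_spectra(
    template: np.ndarray,
    n_spectra: int = 256,
    R_instrument: float = 100000.0,
    seed: int | None = None,
) -> list[Scan]:
    """Replicate single-scan spectra with Gaussian mass jitter.

    Each spectrum carries one unit-intensity peak per template mass, drawn
    from N(m, m/(2 R_instrument)).  At the default parameters jittered peaks
    never cross template positions (spacing ~1.4 Da >> sigma ~4 mDa).
    """
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible generation")
    rng = np.random.default_rng(seed)
    template = np.asarray(template, dtype=float)
    sigma = template / (2.0 * R_instrument)
    scans = []
    for i in range(n_spectra):
        mz = rng.normal(template, sigma)
        scans.append(Scan(mz=mz, intensity=np.ones(template.size), ms_level=1,
                          polarity="+", index=i))
    return scans


# ---------------------------------------------------------------------------
# lipid formula builders

_HEADGROUPS = {
    # head alcohol condensed with glycerol-3-phosphate (one H2O removed)
    "PA": parse_sum_composition("C3 H9 O6 P1"),          # glycerophosphate
    "PC": parse_sum_composition("C8 H20 N1 O6 P1"),      # glycerophosphocholine
    "PE": parse_sum_composition("C5 H14 N1 O6 P1"),      # glycerophosphoethanolamine
    "PG": parse_sum_composition("C6 H15 O8 P1"),         # glycerophosphoglycerol
}
_H2O = parse_sum_composition("H2 O1")
_H = parse_sum_composition("H1")


def _fatty_acid(c: int, db: int) -> SumComposition:
    """Neutral fatty acid CnH(2n-2db)O2."""
    if c < 2 or db < 0 or 2 * c - 2 * db < 2:
        raise ValueError(f"implausible fatty acid {c}:{db}")
    return SumComposition.from_dict({"C": c, "H": 2 * c - 2 * db, "O": 2})


def fatty_acid_anion(c: int, db: int) -> SumComposition:
    """Acyl (carboxylate) anion CnH(2n-1-2db)O2-, the negative-mode reporter."""
    fa = _fatty_acid(c, db)
    return SumComposition(
        (fa - _H).counts, charge=-1
    )


def glycerophospholipid(cls: str, c: int, db: int, ether: bool = False) -> SumComposition:
    """Neutral diacyl (or 1-alkyl-2-acyl, *ether*) glycerophospholipid.

    *c*/*db* are totals over both moieties; the split between moieties does
    not change the sum composition.  Ether (PC-O / PE-O style) species
    replace one ester oxygen by CH2+H2 (a fatty alcohol in ether linkage),
    i.e. formula = diacyl(c-1, db) - O + CH4.
    """
    if cls not in _HEADGROUPS:
        raise ValueError(f"unknown lipid class {cls!r}")
    if ether:
        diacyl = glycerophospholipid(cls, c - 1, db, ether=False)
        return SumComposition.from_dict(
            {**diacyl.as_dict(),
             "C": diacyl["C"] + 1,
             "H": diacyl["H"] + 4,
             "O": diacyl["O"] - 1},
            diacyl.charge,
        )
    # two acyl moieties with c/db totals contribute C_c H_(2c-2db) O4; the
    # split between the moieties does not alter the sum composition
    acyls = SumComposition.from_dict({"C": c, "H": 2 * c - 2 * db, "O": 4})
    return _HEADGROUPS[cls] + acyls - _H2O - _H2O


def protonated(sc: SumComposition) -> SumComposition:
    return SumComposition((sc + _H).counts, charge=sc.charge + 1)


def deprotonated(sc: SumComposition) -> SumComposition:
    return SumComposition((sc - _H).counts, charge=sc.charge - 1)


# ---------------------------------------------------------------------------
# ground-truth mixtures

@dataclass(frozen=True)
class LipidSpecies:
    """One species: ionized precursor composition, molar amount, fragment rules.

    *fragments* are (label, ionized fragment composition) pairs; a moiety
    present twice (e.g. 18:1/18:1) is listed twice so its reporter channel
    carries twice the intensity.
    """

    name: str
    precursor: SumComposition
    amount: float
    fragments: tuple[tuple[str, SumComposition], ...] = ()

    def __post_init__(self):
        pmz = chem.monoisotopic_mz(self.precursor)
        for label, frag in self.fragments:
            if chem.monoisotopic_mz(frag) > pmz + 1e-9:
                raise ValueError(f"fragment {label} heavier than precursor {self.name}")


@dataclass(frozen=True)
class LipidGroundTruth:
    """Species list plus the acquisition-level noise model."""

    species: tuple[LipidSpecies, ...]
    polarity: str = "-"
    acquisition_multipliers: tuple[float, ...] = (1.0,)
    intensity_cv: float = 0.1        # per-peak log-normal spray noise
    msms_yield: float = 0.5          # fragment intensity per unit precursor
    base_intensity: float = 1e6      # MS1 intensity of one amount unit
    chemical_noise_density: float = 0.0   # noise peaks per Da in MS1
    chemical_noise_intensity: float = 0.0


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(-sigma**2 / 2.0, sigma, size)


def simulate_acquisitions(
    truth: LipidGroundTruth,
    n_acquisitions: int = 1,
    scans_per_spectrum: int = 3,
    resolution_ms1: ResolutionModel = ResolutionModel(100000.0),
    resolution_ms2: ResolutionModel | None = None,
    isolation_width: float = 1.0,
    seed: int | None = None,
    isotope_depth: int = 3,
    jitter_R_ms1: float | None = None,
    jitter_R_ms2: float | None = None,
) -> list[Acquisition]:
    """Simulate a multi-acquisition direct-infusion dataset.

    MS1 scans contain the full isotope envelope (offsets 0..*isotope_depth*)
    of every species; MS2 scans are generated per apparent precursor peak
    and contain the rule-defined fragments of every species isotopologue
    co-isolated within *isolation_width* - a fragment of an M+k precursor
    population appears at its own +k isotopologue position (the heavy label
    is retained on the charged fragment; first-order type-II model).

    Mass jitter is Gaussian with sigma = m/(2 R_jitter); by default the
    jitter resolution equals the binning resolution model, but on
    unit-resolution instruments the centroid precision is far better than
    the FWHM, so *jitter_R_ms1/2* can be set independently.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible generation")
    rng = np.random.default_rng(seed)
    resolution_ms2 = resolution_ms2 or resolution_ms1
    n_mult = len(truth.acquisition_multipliers)

    # expected isotopologue table: (species, offset) -> exact m/z, rel. abundance
    env: list[tuple[LipidSpecies, int, float, float]] = []
    for sp in truth.species:
        pat = isotope_pattern(sp.precursor, isotope_depth + 1)
        for off, mz_k, ab in zip(pat.offsets, pat.mzs, pat.abundances):
            if ab > 0:
                env.append((sp, off, mz_k, ab))
    env.sort(key=lambda t: t[2])

    # apparent precursor peaks: theoretical envelope merged at MS1 resolution
    targets: list[float] = []
    for _, _, mz_k, ab in env:
        w = mz_k / resolution_at(resolution_ms1, mz_k)
        if targets and mz_k - targets[-1] < w:
            continue
        targets.append(mz_k)

    # fragment isotopologue m/z per (species, fragment index, offset)
    frag_mz: dict[tuple[int, int, int], float] = {}
    for si, sp in enumerate(truth.species):
        for fi, (_, frag) in enumerate(sp.fragments):
            fpat = isotope_pattern(frag, isotope_depth + 1)
            for off, mz_k, _ in zip(fpat.offsets, fpat.mzs, fpat.abundances):
                frag_mz[(si, fi, off)] = mz_k

    acquisitions = []
    for a in range(n_acquisitions):
        mult = truth.acquisition_multipliers[a % n_mult]
        scans: list[Scan] = []
        idx = 0

        def jitter(mz: np.ndarray, model: ResolutionModel, R_override) -> np.ndarray:
            R = R_override if R_override else resolution_at(model, mz)
            return rng.normal(mz, mz / (2.0 * np.asarray(R, dtype=float)))

        ms1_mz = np.array([mz_k for _, _, mz_k, _ in env])
        ms1_base = np.array(
            [sp.amount * ab * truth.base_intensity for sp, _, _, ab in env]
        )
        for _ in range(scans_per_spectrum):
            inten = ms1_base * mult * _lognormal_factor(rng, truth.intensity_cv, ms1_base.size)
            mz = jitter(ms1_mz, resolution_ms1, jitter_R_ms1)
            if truth.chemical_noise_density > 0:
                span = (ms1_mz.min() - 5, ms1_mz.max() + 5)
                n_noise = rng.poisson(truth.chemical_noise_density * (span[1] - span[0]))
                mz = np.concatenate([mz, rng.uniform(*span, n_noise)])
                inten = np.concatenate(
                    [inten,
                     truth.chemical_noise_intensity
                     * _lognormal_factor(rng, 0.5, n_noise)]
                )
            scans.append(Scan(mz=mz, intensity=inten, ms_level=1,
                              polarity=truth.polarity, index=idx))
            idx += 1

        for t in targets:
            frag_peaks: dict[tuple[int, int, int], float] = {}
            for si, sp in enumerate(truth.species):
                pat = isotope_pattern(sp.precursor, isotope_depth + 1)
                for off, mz_k, ab in zip(pat.offsets, pat.mzs, pat.abundances):
                    if ab <= 0 or abs(mz_k - t) > isolation_width / 2.0:
                        continue
                    pop = sp.amount * ab * truth.base_intensity * truth.msms_yield
                    for fi in range(len(sp.fragments)):
                        key = (si, fi, off)
                        if key in frag_mz:
                            frag_peaks[key] = frag_peaks.get(key, 0.0) + pop
            if not frag_peaks:
                continue
            for _ in range(scans_per_spectrum):
                fmz = np.array([frag_mz[k] for k in sorted(frag_peaks)])
                fint = np.array([frag_peaks[k] for k in sorted(frag_peaks)])
                fint = fint * mult * _lognormal_factor(rng, truth.intensity_cv, fint.size)
                scans.append(
                    Scan(
                        mz=jitter(fmz, resolution_ms2, jitter_R_ms2),
                        intensity=fint,
                        ms_level=2,
                        polarity=truth.polarity,
                        precursor_mz=float(t),
                        index=idx,
                    )
                )
                idx += 1
        acquisitions.append(
            Acquisition(f"acq{a + 1}", scans, source="synthetic", polarity=truth.polarity)
        )
    return acquisitions


def pa_mixture_truth(
    ratios: tuple[float, float, float, float] = (1.0, 9.0, 1.0, 1.0),
    n_acquisitions: int = 4,
) -> LipidGroundTruth:
    """The four-standard phosphatidic-acid mixture (molar 1:9:1:1).

    PA 18:0/18:2 and PA 18:1/18:1 share the exact precursor mass, so the
    anticipated precursor-intensity pattern is 10:1:1 over PA 36:2 / 36:1 /
    36:0, while acyl-anion MS/MS quantification should recover 1:9:1:1.
    """
    def species(name, db_pairs, amount):
        total_c = 36
        total_db = sum(d for _, d in db_pairs)
        prec = deprotonated(glycerophospholipid("PA", total_c, total_db))
        frags = tuple(
            (f"FA {c}:{d}", fatty_acid_anion(c, d)) for c, d in db_pairs
        )
        return LipidSpecies(name, prec, amount, frags)

    sp = (
        species("PA 18:0/18:2", ((18, 0), (18, 2)), ratios[0]),
        species("PA 18:1/18:1", ((18, 1), (18, 1)), ratios[1]),
        species("PA 18:0/18:1", ((18, 0), (18, 1)), ratios[2]),
        species("PA 18:0/18:0", ((18, 0), (18, 0)), ratios[3]),
    )
    return LipidGroundTruth(
        species=sp,
        polarity="-",
        acquisition_multipliers=tuple(1.0 for _ in range(n_acquisitions)),
    )


def pc_truth(include_decoys: bool = True) -> LipidGroundTruth:
    """Protonated PC 36:1 plus non-PC decoy precursors (positive mode).

    The decoys are a triacylglycerol ammonium-adduct-like species and a
    sphingoid-style precursor: both fragment, but neither yields the
    phosphorylcholine head-group fragment at m/z 184.07.
    """
    pc36_1 = protonated(glycerophospholipid("PC", 36, 1))
    head = parse_sum_composition("C5 H15 O4 N1 P1")
    head_ion = SumComposition(head.counts, charge=+1)
    nl_ion = SumComposition((pc36_1 - head).counts, charge=+1)  # glyceride cation
    species = [
        LipidSpecies(
            "PC 36:1", pc36_1, 5.0,
            (("headPC", head_ion), ("NL head", nl_ion)),
        )
    ]
    if include_decoys:
        # decoy 1: same nominal region, no phosphorus (TAG-like cation)
        tag = SumComposition(
            parse_sum_composition("C49 H91 O6").counts, charge=+1
        )
        tag_frag = SumComposition(parse_sum_composition("C19 H35 O2").counts, charge=+1)
        # decoy 2: far precursor with an unrelated fragment near 184 (but
        # not within 5 ppm of 184.0733)
        dec = SumComposition(parse_sum_composition("C40 H81 N2 O3").counts, charge=+1)
        dec_frag = SumComposition(parse_sum_composition("C10 H18 N1 O2").counts, charge=+1)
        species += [
            LipidSpecies("TAG-like decoy", tag, 3.0, (("frag", tag_frag),)),
            LipidSpecies("amide decoy", dec, 2.0, (("frag", dec_frag),)),
        ]
    return LipidGroundTruth(
        species=tuple(species),
        polarity="+",
        acquisition_multipliers=(1.0, 0.9, 1.1),
    )


def pe_truth(
    pe_species: tuple[tuple[int, int], ...] = ((34, 1), (34, 2), (36, 1), (36, 2), (38, 4)),
    amount: float = 1.0,
) -> LipidGroundTruth:
    """Diacyl PE species only (negative mode) - no ether (PE-O) lipids.

    Used for the resolution-dependence experiment: any PE-O assignment made
    against this mixture is by construction a false positive, since the
    isobaric PE-O composition sits only 36.4 mDa away from each PE peak.
    """
    species = []
    for c, db in pe_species:
        prec = deprotonated(glycerophospholipid("PE", c, db))
        # split c:db into two equal-ish moieties for fragment rules
        c1, c2 = c // 2, c - c // 2
        d1, d2 = db // 2, db - db // 2
        frags = (
            (f"FA {c1}:{d1}", fatty_acid_anion(c1, d1)),
            (f"FA {c2}:{d2}", fatty_acid_anion(c2, d2)),
        )
        species.append(LipidSpecies(f"PE {c}:{db}", prec, amount, frags))
    return LipidGroundTruth(
        species=tuple(species),
        polarity="-",
        acquisition_multipliers=(1.0, 1.0, 1.0, 1.0),
    )
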