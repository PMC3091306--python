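"""Reproductions of the controlled validation experiments.

These routines wire the synthetic generators through the import/alignment/
correction machinery and measure the quantities the validation experiments
report: per-position occupancy and mass error of the template-spectrum
alignment, recovery of the PA-standard molar ratios under isotopic
correction, and the resolution dependence of PE vs PE-O (ether lipid)
assignment.  They are used by the acceptance checks and are convenient
entry points for exploring how the algorithms respond to parameters.
"""

from __future__ import annotations

import numpy as np

from . import chem, isocorrect, pipeline, synth
from .averaging import AveragedSpectrum, ResolutionModel
from .chem import Tolerance
from .masterscan import align_spectra

__all__ = [
    "template_alignment_stats",
    "pa_mixture_recovery",
    "pe_peo_false_positives",
]


def template_alignment_stats(
    seed: int,
    n_passes: int = 3,
    n_spectra: int = 256,
    R_instrument: float = 100000.0,
) -> dict[str, float]:
    """Align one simulated template dataset; measure Table-style statistics.

    Each of the 319 template positions is matched to the nearest aligned
    entry; returns the mean occupancy and mean absolute mass deviation
    (mDa and ppm) over the positions, plus the aligned entry count.
    """
    template = synth.make_template()
    scans = synth.generate_template_spectra(template, n_spectra, R_instrument, seed)
    spectra = [
        AveragedSpectrum(s.mz, s.intensity, np.ones(s.mz.size), np.ones(s.mz.size))
        for s in scans
    ]
    model = ResolutionModel(R_instrument, anchor=float(template[0]))
    entries = align_spectra(spectra, model, n_passes=n_passes)
    mzs = np.array([e.mz for e in entries])
    occs = np.array([e.occupancy for e in entries])
    nearest = np.abs(mzs[None, :] - template[:, None]).argmin(axis=1)
    dm = np.abs(mzs[nearest] - template)
    return {
        "n_entries": float(len(entries)),
        "mean_occupancy": float(occs[nearest].mean()),
        "mean_abs_error_mda": float(dm.mean() * 1e3),
        "mean_abs_error_ppm": float((dm / template).mean() * 1e6),
    }


_PA_CONSTRAINT = chem.parse_sc_constraint(
    "C[30..48]H[30..200]O[8]P[1]", charge=-1, dbr_range=(2.5, 8.5)
)


def pa_mixture_recovery(
    seed: int,
    n_acquisitions: int = 4,
    scans_per_spectrum: int = 12,
) -> dict[str, np.ndarray]:
    """Simulate and quantify the PA 1:9:1:1 standard mixture at unit resolution.

    Returns the precursor (MS) intensity pattern over PA 36:2/36:1/36:0
    normalized to 36:2 = 10, and the acyl-anion (MS/MS) pattern over the four
    standards normalized to PA 18:0/18:2 = 1, each before and after isotopic
    correction.  Anticipated: MS 10:1:1, MS/MS 1:9:1:1.
    """
    unit = ResolutionModel(800.0, anchor=400.0)
    truth = synth.pa_mixture_truth(n_acquisitions=n_acquisitions)
    acqs = synth.simulate_acquisitions(
        truth, n_acquisitions, scans_per_spectrum,
        resolution_ms1=unit, resolution_ms2=unit, isolation_width=1.0,
        seed=seed, jitter_R_ms1=7000.0, jitter_R_ms2=7000.0,
    )
    ms = pipeline.import_dataset(acqs, unit, unit, min_sn=0.0)

    # bind PA sum compositions (even-H anions) to precursor entries
    ident = []
    for e in ms.entries:
        scs = [
            s for s in chem.enumerate_compositions(_PA_CONSTRAINT, e.mz, "300ppm")
            if s["H"] % 2 == 0
        ]
        if scs:
            ident.append((e, scs[0]))

    def ms_pattern():
        by_nominal = {int(e.mz): e.intensities.mean() for e, _ in ident}
        base = by_nominal[699]
        return np.array([by_nominal[699], by_nominal[701], by_nominal[703]]) / base * 10

    ms_before = ms_pattern()
    isocorrect.correct_ms([(e.mz, e.intensities, sc) for e, sc in ident],
                          unit, depth=2)
    ms_after = ms_pattern()

    acyl = {f"18:{d}": synth.fatty_acid_anion(18, d) for d in (0, 1, 2)}
    blocks = []
    for e, sc in ident:
        frags = []
        for f in e.msms:
            match, label = None, f"{f.mz:.3f}"
            for name, a_sc in acyl.items():
                if abs(f.mz - chem.monoisotopic_mz(a_sc)) <= 0.1:
                    match, label = a_sc, name
            frags.append((f.mz, f.intensities, match, label))
        blocks.append((e.mz, sc, frags))

    def channel(nominal, name):
        for pmz, _, frags in blocks:
            if int(pmz) == nominal:
                for _, vec, _, lab in frags:
                    if lab == name:
                        return vec.mean()
        return 0.0

    def msms_pattern():
        raw = np.array([
            channel(699, "18:2"),              # PA 18:0/18:2 (one 18:2 / molecule)
            channel(699, "18:1") / 2,          # PA 18:1/18:1 (two 18:1)
            (channel(701, "18:0") + channel(701, "18:1")) / 2,  # PA 18:0/18:1
            channel(703, "18:0") / 2,          # PA 18:0/18:0 (two 18:0)
        ])
        return raw / raw[0]

    msms_before = msms_pattern()
    isocorrect.correct_msms(blocks, unit, depth=2, isolation_width=1.0)
    msms_after = msms_pattern()
    return {
        "ms_before": ms_before,
        "ms_after": ms_after,
        "msms_before": msms_before,
        "msms_after": msms_after,
    }


_PEO_CONSTRAINT = chem.parse_sc_constraint(
    "C[30..50]H[40..110]N[1]O[7]P[1]", charge=-1, dbr_range=(1.5, 7.5)
)


def pe_peo_false_positives(
    seed: int,
    ms1_resolution: float,
    ms2_tol: Tolerance | str,
    n_acquisitions: int = 4,
    scans_per_spectrum: int = 12,
) -> int:
    """Count PE-O assignments against a mixture containing only diacyl PE.

    A candidate assignment requires (a) a precursor entry matching an ether
    (O7) sum composition within the resolution-determined tolerance m/R(m)
    and (b) a block fragment interpretable as the candidate's acyl anion
    (12-22 carbons, 0-6 double bonds, chain lengths consistent with the
    precursor) within *ms2_tol*.  Every count is a false positive since the
    simulated mixture has no ether lipids; the diacyl isobar sits 36.4 mDa
    away from each candidate.
    """
    ms2_tol = Tolerance.parse(ms2_tol)
    model1 = ResolutionModel(ms1_resolution, anchor=400.0)
    model2 = ResolutionModel(800.0, anchor=400.0)
    truth = synth.pe_truth()
    acqs = synth.simulate_acquisitions(
        truth, n_acquisitions, scans_per_spectrum,
        resolution_ms1=model1, resolution_ms2=model2, isolation_width=1.0,
        seed=seed,
        jitter_R_ms1=None if ms1_resolution >= 20000 else 7000.0,
        jitter_R_ms2=7000.0,
    )
    ms = pipeline.import_dataset(acqs, model1, model2, min_sn=0.0,
                                 min_occupancy=0.5)
    count = 0
    for e in ms.entries:
        window = e.mz / ms1_resolution
        for sc in chem.enumerate_compositions(_PEO_CONSTRAINT, e.mz,
                                              Tolerance(window, "da")):
            c_total = int(sc["C"]) - 5  # minus glycerophosphoethanolamine carbons
            db_total = chem.dbr(sc) - 1.5
            confirmed = False
            for fc in range(12, 23):
                if not 12 <= c_total - fc:
                    continue
                for fd in range(0, 7):
                    if fd > db_total:
                        continue
                    target = chem.monoisotopic_mz(synth.fatty_acid_anion(fc, fd))
                    if any(
                        ms2_tol.matches(f.mz, target) for f in e.msms
                    ):
                        confirmed = True
                        break
                if confirmed:
                    break
            if confirmed:
                count += 1
    return count
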