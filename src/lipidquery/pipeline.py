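"""End-to-end import: acquisitions -> averaged spectra -> MasterScan."""

from __future__ import annotations

import logging

import numpy as np

from .averaging import AveragedSpectrum, ResolutionModel, average_scans
from .masterscan import MasterScan, associate_msms, build_masterscan, filter_entries, recalibrate
from .spectra_io import Acquisition

__all__ = ["import_dataset"]

log = logging.getLogger(__name__)


def _cluster_precursors(values: list[float], width: float) -> dict[float, float]:
    """Map each recorded precursor m/z to a cluster representative.

    Recorded precursor values of the same target vary slightly between
    acquisitions; a left-anchored sweep within *width* merges them.
    """
    mapping: dict[float, float] = {}
    for v in sorted(set(values)):
        anchor = None
        for rep in mapping.values():
            if abs(v - rep) <= width:
                anchor = rep
                break
        mapping[v] = anchor if anchor is not None else v
    return mapping


def import_dataset(
    acquisitions: list[Acquisition],
    resolution_ms1: ResolutionModel,
    resolution_ms2: ResolutionModel | None = None,
    n_passes: int = 3,
    min_sn: float = 3.0,
    isolation_width: float = 1.0,
    min_occupancy: float = 0.0,
    min_intensity_ms1: float = 0.0,
    min_intensity_ms2: float = 0.0,
    reference_masses: list[float] | None = None,
    recal_tol: float | str = 20.0,
    groups: dict[str, list[str]] | None = None,
) -> MasterScan:
    """Average, align and pre-filter a multi-acquisition dataset.

    Per acquisition, repeated MS1 scans are averaged into one representative
    spectrum and MS2 scans are grouped by recorded precursor m/z (clustered
    within half the isolation window) and averaged per group.  Averaged MS1
    spectra are aligned across acquisitions into precursor entries; averaged
    MS2 spectra are attached through the isolation window.  Optional
    reference-mass recalibration and occupancy/intensity pre-filters run
    last.
    """
    if not acquisitions:
        raise ValueError("no acquisitions to import")
    pols = {a.polarity for a in acquisitions}
    if len(pols) > 1:
        raise ValueError(f"acquisitions mix polarities {pols}; build one MasterScan per polarity")
    resolution_ms2 = resolution_ms2 or resolution_ms1

    ms1_spectra: list[AveragedSpectrum] = []
    all_prec: list[float] = []
    per_acq_msms: list[dict[float, list]] = []
    for acq in acquisitions:
        ms1 = acq.ms1_scans()
        if not ms1:
            raise ValueError(f"acquisition {acq.identifier!r} has no MS1 scans")
        ms1_spectra.append(average_scans(ms1, resolution_ms1, n_passes, min_sn))
        grouped: dict[float, list] = {}
        for scan in acq.ms2_scans():
            grouped.setdefault(float(scan.precursor_mz), []).append(scan)
        per_acq_msms.append(grouped)
        all_prec.extend(grouped)

    ms = build_masterscan(
        [a.identifier for a in acquisitions],
        ms1_spectra,
        resolution_ms1,
        polarity=acquisitions[0].polarity,
        n_passes=n_passes,
        groups=groups,
        resolution_ms2=resolution_ms2,
    )

    cluster = _cluster_precursors(all_prec, isolation_width / 2.0)
    msms_spectra: dict[float, list] = {}
    for acq_idx, grouped in enumerate(per_acq_msms):
        for prec, scans in grouped.items():
            spec = average_scans(scans, resolution_ms2, n_passes, min_sn)
            msms_spectra.setdefault(cluster[prec], []).append((acq_idx, spec))
    if msms_spectra:
        ms = associate_msms(ms, msms_spectra, isolation_width, n_passes)

    if reference_masses:
        ms = recalibrate(ms, reference_masses, recal_tol)
    if min_occupancy > 0 or min_intensity_ms1 > 0 or min_intensity_ms2 > 0:
        ms = filter_entries(ms, min_occupancy, min_intensity_ms1, min_intensity_ms2)
    log.info(
        "imported %d acquisitions into %d precursor entries (%d MS/MS blocks, %d orphans)",
        len(acquisitions), len(ms.entries),
        sum(1 for e in ms.entries if e.msms), len(ms.orphans),
    )
    return ms
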