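"""The MasterScan: a flat-file database of aligned shotgun spectra.

Averaged spectra from all acquisitions of an experiment are aligned into one
table of precursor entries.  Alignment uses the same resolution-dependent
sweep as scan averaging, except that representative masses are *unweighted*
means of member masses and every acquisition keeps its own intensity slot.
Each precursor entry can carry an aligned block of MS/MS fragment entries,
associated through the precursor isolation window.

Persistence is a versioned JSON text file with deterministic layout:
saving the same MasterScan twice is byte-identical, and load(save(x)) == x.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .averaging import AveragedSpectrum, ResolutionModel, resolution_at, _sweep_labels

__all__ = [
    "FragmentEntry",
    "PrecursorEntry",
    "MasterScan",
    "align_spectra",
    "build_masterscan",
    "associate_msms",
    "recalibrate",
    "filter_entries",
    "save",
    "load",
]

log = logging.getLogger(__name__)

FORMAT_VERSION = 1


@dataclass
class FragmentEntry:
    mz: float
    intensities: np.ndarray  # one slot per acquisition, 0 = absent

    @property
    def occupancy(self) -> float:
        return float(np.count_nonzero(self.intensities) / self.intensities.size)


@dataclass
class PrecursorEntry:
    mz: float
    intensities: np.ndarray
    msms: list[FragmentEntry] = field(default_factory=list)

    @property
    def occupancy(self) -> float:
        return float(np.count_nonzero(self.intensities) / self.intensities.size)

    def group_occupancy(self, indices: np.ndarray) -> float:
        sub = self.intensities[indices]
        return float(np.count_nonzero(sub) / sub.size)


@dataclass
class MasterScan:
    acquisition_ids: list[str]
    polarity: str
    entries: list[PrecursorEntry]
    groups: dict[str, list[str]] = field(default_factory=dict)
    resolution_ms1: ResolutionModel = field(default_factory=lambda: ResolutionModel(100000.0))
    resolution_ms2: ResolutionModel | None = None
    provenance: dict = field(default_factory=dict)
    orphans: list[tuple[float, int]] = field(default_factory=list)  # (precursor mz, n fragments)

    def __post_init__(self):
        n = len(self.acquisition_ids)
        for e in self.entries:
            if e.intensities.size != n:
                raise ValueError("intensity vector length != number of acquisitions")
        self.entries.sort(key=lambda e: e.mz)

    def group_indices(self, group: str | None) -> np.ndarray:
        if group is None:
            return np.arange(len(self.acquisition_ids))
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        idx = [self.acquisition_ids.index(a) for a in self.groups[group]]
        return np.array(idx, dtype=int)


def _align_peak_lists(
    mz_lists: list[np.ndarray],
    int_lists: list[np.ndarray],
    model: ResolutionModel,
    n_passes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Core unweighted alignment.

    Returns (representative m/z, intensity matrix of shape (n_entries,
    n_acquisitions)).  Representative masses are plain means over all member
    peak masses; multiple peaks of one acquisition falling into one bin have
    their intensities summed into that acquisition's slot.
    """
    n_acq = len(mz_lists)
    mz = np.concatenate(mz_lists) if mz_lists else np.empty(0)
    inten = np.concatenate(int_lists) if int_lists else np.empty(0)
    acq_idx = np.concatenate(
        [np.full(m.size, k, dtype=np.int64) for k, m in enumerate(mz_lists)]
    ) if mz_lists else np.empty(0, np.int64)
    if mz.size == 0:
        return np.empty(0), np.empty((0, n_acq))
    order = np.argsort(mz, kind="stable")
    mz, inten, acq_idx = mz[order], inten[order], acq_idx[order]

    # cluster state: sum of member masses + member count -> exact unweighted mean
    csum = mz.copy()
    ccnt = np.ones(mz.size)
    cm = mz.copy()
    orig_cluster = np.arange(mz.size, dtype=np.int64)
    for _ in range(max(1, n_passes)):
        labels = _sweep_labels(cm, model)
        nbins = int(labels[-1]) + 1
        csum = np.bincount(labels, weights=csum, minlength=nbins)
        ccnt = np.bincount(labels, weights=ccnt, minlength=nbins)
        cm = csum / ccnt
        orig_cluster = labels[orig_cluster]
        if labels.size == nbins:
            break

    matrix = np.zeros((cm.size, n_acq))
    np.add.at(matrix, (orig_cluster, acq_idx), inten)
    return cm, matrix


def align_spectra(
    spectra: list[AveragedSpectrum],
    model: ResolutionModel,
    n_passes: int = 3,
) -> list[PrecursorEntry]:
    """Align one averaged spectrum per acquisition into precursor entries."""
    if not spectra:
        raise ValueError("no spectra to align")
    if len({s.polarity for s in spectra}) > 1 or len({s.ms_level for s in spectra}) > 1:
        raise ValueError("spectra mix polarity or ms_level")
    cm, matrix = _align_peak_lists(
        [s.mz for s in spectra], [s.intensity for s in spectra], model, n_passes
    )
    return [PrecursorEntry(float(m), matrix[i]) for i, m in enumerate(cm)]


def build_masterscan(
    acquisition_ids: list[str],
    spectra: list[AveragedSpectrum],
    model: ResolutionModel,
    polarity: str = "+",
    n_passes: int = 3,
    groups: dict[str, list[str]] | None = None,
    resolution_ms2: ResolutionModel | None = None,
) -> MasterScan:
    entries = align_spectra(spectra, model, n_passes)
    return MasterScan(
        acquisition_ids=list(acquisition_ids),
        polarity=polarity,
        entries=entries,
        groups=groups or {},
        resolution_ms1=model,
        resolution_ms2=resolution_ms2,
        provenance={"n_passes": n_passes},
    )


def associate_msms(
    ms: MasterScan,
    msms_spectra: dict[float, list[tuple[int, AveragedSpectrum]]],
    isolation_width: float = 1.0,
    n_passes: int = 3,
) -> MasterScan:
    """Attach aligned MS/MS blocks to precursor entries.

    *msms_spectra* maps a recorded precursor m/z to the per-acquisition
    averaged MS/MS spectra fragmenting it, as (acquisition index, spectrum)
    pairs.  A spectrum is attached to every entry whose representative m/z
    lies within +-isolation_width/2 of the recorded precursor m/z, so with
    windows exceeding the peak spacing several entries legitimately share one
    MS/MS block.  Spectra matching no entry land in ``ms.orphans``.
    """
    if isolation_width <= 0:
        raise ValueError("isolation width must be positive")
    model2 = ms.resolution_ms2 or ms.resolution_ms1
    entry_mz = np.array([e.mz for e in ms.entries])
    n_acq = len(ms.acquisition_ids)
    per_entry: dict[int, list[tuple[int, AveragedSpectrum]]] = {}
    orphans: list[tuple[float, int]] = []
    for recorded, pairs in sorted(msms_spectra.items()):
        lo = np.searchsorted(entry_mz, recorded - isolation_width / 2, side="left")
        hi = np.searchsorted(entry_mz, recorded + isolation_width / 2, side="right")
        if lo == hi:
            orphans.append((float(recorded), sum(s.mz.size for _, s in pairs)))
            log.warning("MS/MS precursor %.4f matches no MasterScan entry", recorded)
            continue
        for i in range(lo, hi):
            per_entry.setdefault(int(i), []).extend(pairs)
    for i, pairs in per_entry.items():
        mz_lists = [np.empty(0)] * n_acq
        int_lists = [np.empty(0)] * n_acq
        grouped: dict[int, list[AveragedSpectrum]] = {}
        for acq, spec in pairs:
            grouped.setdefault(acq, []).append(spec)
        for acq, specs in grouped.items():
            mz_lists[acq] = np.concatenate([s.mz for s in specs])
            int_lists[acq] = np.concatenate([s.intensity for s in specs])
        # per-acquisition lists may be unsorted after concatenation; the
        # aligner sorts the pooled list itself
        cm, matrix = _align_peak_lists(mz_lists, int_lists, model2, n_passes)
        ms.entries[i].msms = [
            FragmentEntry(float(m), matrix[k]) for k, m in enumerate(cm)
        ]
    ms.orphans = orphans
    return ms


def recalibrate(
    ms: MasterScan,
    reference_masses: list[float],
    match_tol: "float | str" = 20.0,
    include_ms2: bool = False,
) -> MasterScan:
    """Linear mass recalibration against reference (lock) masses.

    Each reference is matched to the nearest precursor entry within
    *match_tol* (ppm by default).  With one matched reference a constant
    offset is removed; with two or more, the least-squares linear shift
    dm(m) = a*m + b is removed from all precursor masses (and fragment
    masses when *include_ms2*).
    """
    from .chem import Tolerance

    tol = Tolerance.parse(match_tol)
    entry_mz = np.array([e.mz for e in ms.entries])
    obs, ref = [], []
    for r in reference_masses:
        if entry_mz.size == 0:
            break
        i = int(np.argmin(np.abs(entry_mz - r)))
        if tol.matches(entry_mz[i], r):
            obs.append(entry_mz[i])
            ref.append(r)
    if not obs:
        raise ValueError("no reference mass matched within tolerance")
    obs_a, ref_a = np.array(obs), np.array(ref)
    err = obs_a - ref_a
    if len(obs) == 1:
        a, b = 0.0, float(err[0])
    else:
        a, b = np.polyfit(obs_a, err, 1)

    def corrected(m: np.ndarray | float):
        return m - (a * m + b)

    for e in ms.entries:
        e.mz = float(corrected(e.mz))
        if include_ms2:
            for f in e.msms:
                f.mz = float(corrected(f.mz))
    ms.entries.sort(key=lambda e: e.mz)
    ms.provenance["recalibration"] = {"slope": float(a), "offset": float(b),
                                      "n_references": len(obs)}
    return ms


def filter_entries(
    ms: MasterScan,
    min_occupancy: float = 0.0,
    min_intensity_ms1: float = 0.0,
    min_intensity_ms2: float = 0.0,
    scope: str | None = None,
) -> MasterScan:
    """Occupancy / intensity pre-filter.

    Intensities below the per-level threshold are zeroed first; occupancy is
    then computed over the *scope* group (default: all acquisitions) and
    entries (and fragments) below *min_occupancy* are dropped.
    """
    if min_occupancy < 0 or min_intensity_ms1 < 0 or min_intensity_ms2 < 0:
        raise ValueError("thresholds must be non-negative")
    idx = ms.group_indices(scope)
    kept: list[PrecursorEntry] = []
    for e in ms.entries:
        inten = np.where(e.intensities >= min_intensity_ms1, e.intensities, 0.0)
        sub = inten[idx]
        occ = np.count_nonzero(sub) / sub.size
        if occ < min_occupancy:
            continue
        frags = []
        for f in e.msms:
            fint = np.where(f.intensities >= min_intensity_ms2, f.intensities, 0.0)
            fsub = fint[idx]
            focc = np.count_nonzero(fsub) / fsub.size
            if focc >= min_occupancy:
                frags.append(FragmentEntry(f.mz, fint))
        kept.append(PrecursorEntry(e.mz, inten, frags))
    filtered = MasterScan(
        acquisition_ids=list(ms.acquisition_ids),
        polarity=ms.polarity,
        entries=kept,
        groups=dict(ms.groups),
        resolution_ms1=ms.resolution_ms1,
        resolution_ms2=ms.resolution_ms2,
        provenance=dict(ms.provenance),
    )
    filtered.provenance["filter"] = {
        "min_occupancy": min_occupancy,
        "min_intensity_ms1": min_intensity_ms1,
        "min_intensity_ms2": min_intensity_ms2,
        "scope": scope,
    }
    return filtered


# ---------------------------------------------------------------------------
# persistence: versioned JSON flat file (*.sc)

def _model_to_json(model: ResolutionModel | None):
    if model is None:
        return None
    return {"R0": model.R0, "anchor": model.anchor, "gradient": model.gradient}


def _model_from_json(obj) -> ResolutionModel | None:
    if obj is None:
        return None
    return ResolutionModel(obj["R0"], obj["anchor"], obj["gradient"])


def _pack(values) -> str:
    """Exact, compact text encoding of a float vector (network-order f8,
    base64) - the same convention mzXML uses for peak data."""
    import base64

    return base64.b64encode(
        np.asarray(values, dtype=">f8").tobytes()
    ).decode("ascii")


def _unpack(text: str) -> np.ndarray:
    import base64

    return np.frombuffer(base64.b64decode(text), dtype=">f8").astype(float)


def save(ms: MasterScan, path: str | Path) -> None:
    doc = {
        "format": "lipidquery-masterscan",
        "version": FORMAT_VERSION,
        "acquisitions": ms.acquisition_ids,
        "polarity": ms.polarity,
        "groups": ms.groups,
        "resolution_ms1": _model_to_json(ms.resolution_ms1),
        "resolution_ms2": _model_to_json(ms.resolution_ms2),
        "provenance": ms.provenance,
        "orphans": [[mz, n] for mz, n in ms.orphans],
        "entry_mz": _pack([e.mz for e in ms.entries]),
        "entry_intensities": _pack(
            np.concatenate([e.intensities for e in ms.entries])
            if ms.entries else []
        ),
        "msms": [
            {
                "entry": i,
                "mz": _pack([f.mz for f in e.msms]),
                "intensities": _pack(
                    np.concatenate([f.intensities for f in e.msms])
                ),
            }
            for i, e in enumerate(ms.entries)
            if e.msms
        ],
    }
    Path(path).write_text(
        json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n"
    )


def load(path: str | Path) -> MasterScan:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt MasterScan file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "lipidquery-masterscan":
        raise ValueError(f"{path} is not a lipidquery MasterScan file")
    if doc.get("version") != FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported MasterScan version {doc.get('version')}"
        )
    n_acq = len(doc["acquisitions"])
    entry_mz = _unpack(doc["entry_mz"])
    entry_int = _unpack(doc["entry_intensities"]).reshape(-1, max(n_acq, 1))
    entries = [
        PrecursorEntry(float(m), entry_int[i].copy())
        for i, m in enumerate(entry_mz)
    ]
    for block in doc["msms"]:
        e = entries[block["entry"]]
        frag_mz = _unpack(block["mz"])
        frag_int = _unpack(block["intensities"]).reshape(-1, max(n_acq, 1))
        e.msms = [
            FragmentEntry(float(m), frag_int[k].copy())
            for k, m in enumerate(frag_mz)
        ]
    return MasterScan(
        acquisition_ids=list(doc["acquisitions"]),
        polarity=doc["polarity"],
        entries=entries,
        groups={k: list(v) for k, v in doc["groups"].items()},
        resolution_ms1=_model_from_json(doc["resolution_ms1"]),
        resolution_ms2=_model_from_json(doc["resolution_ms2"]),
        provenance=doc["provenance"],
        orphans=[(mz, n) for mz, n in doc["orphans"]],
    )


def export_csv(ms: MasterScan, path: str | Path) -> None:
    """Precursor table as CSV: mz, occupancy, one column per acquisition."""
    import pandas as pd

    rows = [
        {"mz": e.mz, "occupancy": e.occupancy,
         **{aid: e.intensities[i] for i, aid in enumerate(ms.acquisition_ids)}}
        for e in ms.entries
    ]
    pd.DataFrame(rows, columns=["mz", "occupancy", *ms.acquisition_ids]).to_csv(
        path, index=False
    )
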