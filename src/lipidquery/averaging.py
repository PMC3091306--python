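"""Resolution-dependent scan averaging.

Repeated scans of one acquisition are merged into a single representative
spectrum.  Peak masses of the same ion are assumed Gaussian-distributed
across scans with sigma = m/(2 R(m)), where R(m) is the FWHM mass resolution
(linear in m).  All scans' peaks are pooled, sorted, and swept left to right:
each bin spans [m; m + m/R(m)) anchored at the lowest unconsumed mass, and
its members are replaced by their intensity-weighted mean mass.  Three
successive passes suffice to separate bins completely, i.e. no two adjacent
representative masses are closer than m/R(m).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import Scan

__all__ = ["ResolutionModel", "AveragedSpectrum", "resolution_at", "bin_pass", "average_scans"]


@dataclass(frozen=True)
class ResolutionModel:
    """Linear FWHM resolution model R(m) = R0 + gradient * (m - anchor)."""

    R0: float
    anchor: float = 400.0
    gradient: float = 0.0

    def __call__(self, m) -> np.ndarray | float:
        return resolution_at(self, m)


def resolution_at(model: ResolutionModel, m) -> np.ndarray | float:
    """Resolution at mass *m*; an error if the linear model goes non-positive."""
    r = model.R0 + model.gradient * (np.asarray(m, dtype=float) - model.anchor)
    if np.any(r <= 0):
        raise ValueError(
            f"resolution model {model} is non-positive at m={np.asarray(m)[np.asarray(r) <= 0]}"
        )
    return r if np.ndim(m) else float(r)


@dataclass
class AveragedSpectrum:
    """Representative spectrum of one acquisition.

    Per peak: representative m/z, mean intensity over contributing scans,
    member-peak count, and occupancy (fraction of scans contributing at
    least one member peak).
    """

    mz: np.ndarray
    intensity: np.ndarray
    members: np.ndarray
    occupancy: np.ndarray
    n_scans: int = 1
    ms_level: int = 1
    polarity: str = "+"
    precursor_mz: float | None = None


def _sweep_labels(mz: np.ndarray, model: ResolutionModel) -> np.ndarray:
    """Assign bin labels by the left-anchored sweep; mz must be sorted."""
    n = mz.size
    labels = np.empty(n, dtype=np.int64)
    i = 0
    label = 0
    while i < n:
        width = mz[i] / resolution_at(model, mz[i])
        j = int(np.searchsorted(mz, mz[i] + width, side="left"))
        j = max(j, i + 1)
        labels[i:j] = label
        label += 1
        i = j
    return labels


def bin_pass(
    mz: np.ndarray, intensity: np.ndarray, model: ResolutionModel
) -> tuple[np.ndarray, np.ndarray]:
    """One binning pass over a sorted peak list.

    Scanning from the lowest mass m, all masses in [m, m + m/R(m)) are
    replaced by a single peak at the intensity-weighted mean mass (Eq. of the
    scan-averaging algorithm; the I_max normalization cancels) whose
    intensity is the summed member intensity.  Returns (mz, intensity) of
    the binned list.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size == 0:
        return mz, intensity
    if np.any(np.diff(mz) < 0):
        raise ValueError("bin_pass requires an m/z-sorted peak list")
    labels = _sweep_labels(mz, model)
    nbins = int(labels[-1]) + 1
    wsum = np.bincount(labels, weights=intensity * mz, minlength=nbins)
    isum = np.bincount(labels, weights=intensity, minlength=nbins)
    counts = np.bincount(labels, minlength=nbins)
    # all-zero-intensity bins fall back to the unweighted mean
    msum = np.bincount(labels, weights=mz, minlength=nbins)
    rep = np.where(isum > 0, wsum / np.where(isum > 0, isum, 1.0), msum / counts)
    return rep, isum


def average_scans(
    scans: list[Scan],
    model: ResolutionModel,
    n_passes: int = 3,
    min_sn: float = 3.0,
) -> AveragedSpectrum:
    """Merge repeated scans into one representative spectrum.

    Peaks of all scans are pooled, noise-filtered at *min_sn* (signal-to-noise
    estimated per scan as the median intensity of the lower-intensity half of
    its peaks; scans with fewer than 20 peaks carry no estimable noise floor
    and are not filtered), then binned *n_passes* times.  The representative
    intensity of a peak is the mean of per-scan summed member intensities
    over contributing scans; occupancy is the fraction of scans contributing.
    """
    if not scans:
        raise ValueError("average_scans requires at least one scan")
    levels = {s.ms_level for s in scans}
    pols = {s.polarity for s in scans}
    if len(levels) > 1 or len(pols) > 1:
        raise ValueError("scans mix ms_level or polarity")
    n_scans = len(scans)

    mz_parts, int_parts, scan_parts = [], [], []
    for k, scan in enumerate(scans):
        mz, inten = scan.mz, scan.intensity
        if min_sn > 0 and mz.size >= 20:
            lower = np.sort(inten)[: mz.size // 2]
            noise = float(np.median(lower))
            if noise > 0:
                keep = inten >= min_sn * noise
                mz, inten = mz[keep], inten[keep]
        mz_parts.append(mz)
        int_parts.append(inten)
        scan_parts.append(np.full(mz.size, k, dtype=np.int64))
    mz = np.concatenate(mz_parts)
    inten = np.concatenate(int_parts)
    scan_idx = np.concatenate(scan_parts)
    order = np.argsort(mz, kind="stable")
    mz, inten, scan_idx = mz[order], inten[order], scan_idx[order]

    # cluster state: weighted-mass sums for exact multi-pass averaging
    wm = mz * inten  # sum of I*m per cluster
    wi = inten.copy()  # sum of I
    cm = mz.copy()  # representative mass
    # per-cluster, per-scan intensity bookkeeping survives merging via
    # member lists in (start, stop) ranges over the sorted original arrays?
    # Simpler: re-derive per-scan sums from an original->cluster mapping.
    orig_cluster = np.arange(mz.size, dtype=np.int64)

    for _ in range(max(1, n_passes)):
        if cm.size == 0:
            break
        labels = _sweep_labels(cm, model)
        nbins = int(labels[-1]) + 1
        new_wm = np.bincount(labels, weights=wm, minlength=nbins)
        new_wi = np.bincount(labels, weights=wi, minlength=nbins)
        counts = np.bincount(labels, minlength=nbins)
        mean_cm = np.bincount(labels, weights=cm, minlength=nbins) / counts
        new_cm = np.where(new_wi > 0, new_wm / np.where(new_wi > 0, new_wi, 1.0), mean_cm)
        orig_cluster = labels[orig_cluster]
        wm, wi, cm = new_wm, new_wi, new_cm
        if labels.size == nbins:  # converged: every cluster its own bin
            break

    # per-cluster occupancy and mean intensity over contributing scans
    nclusters = cm.size
    if nclusters:
        pair = orig_cluster * n_scans + scan_idx
        uniq = np.unique(pair)
        contrib = np.bincount(uniq // n_scans, minlength=nclusters)
        occupancy = contrib / n_scans
        total_int = np.bincount(orig_cluster, weights=inten, minlength=nclusters)
        mean_int = np.where(contrib > 0, total_int / np.maximum(contrib, 1), 0.0)
        members = np.bincount(orig_cluster, minlength=nclusters)
    else:
        occupancy = np.empty(0)
        mean_int = np.empty(0)
        members = np.empty(0, dtype=np.int64)

    prec = scans[0].precursor_mz if scans[0].ms_level >= 2 else None
    return AveragedSpectrum(
        mz=cm,
        intensity=mean_int,
        members=members,
        occupancy=occupancy,
        n_scans=n_scans,
        ms_level=scans[0].ms_level,
        polarity=scans[0].polarity,
        precursor_mz=prec,
    )
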