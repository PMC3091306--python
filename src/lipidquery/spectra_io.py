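"""Reading and writing shotgun direct-infusion acquisitions.

An *acquisition* is one complete set of MS and MS/MS scans from one infusion
of a sample.  Supported inputs are mzXML (a subset: 32/64-bit network-order
peaks, uncompressed or zlib) read through :mod:`pyteomics.mzxml`, and plain
two-column (m/z, intensity) peak-list text files.  A dataset manifest (flat
INI file) groups acquisitions into samples / blanks / replicates.

A minimal mzXML writer is provided so that synthetic datasets round-trip
through the same importer as real data.
"""

from __future__ import annotations

import base64
import configparser
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
from pyteomics import mzxml as _pyteomics_mzxml

__all__ = [
    "Scan",
    "Acquisition",
    "DatasetManifest",
    "read_mzxml",
    "read_peaklist",
    "write_mzxml",
    "load_manifest",
]


class SpectraIOError(ValueError):
    pass


@dataclass
class Scan:
    """One individual spectrum: centroided peaks plus acquisition metadata."""

    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    polarity: str = "+"
    precursor_mz: float | None = None
    index: int = 0

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise SpectraIOError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise SpectraIOError("negative intensity")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.ms_level >= 2 and self.precursor_mz is None:
            raise SpectraIOError("MS2 scan without precursor m/z")
        if self.polarity not in ("+", "-"):
            raise SpectraIOError(f"polarity must be '+' or '-', got {self.polarity!r}")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class Acquisition:
    """Ordered scans of one infusion; single polarity."""

    identifier: str
    scans: list[Scan]
    source: str = ""
    polarity: str = "+"

    def __post_init__(self):
        if not self.scans:
            raise SpectraIOError(f"acquisition {self.identifier!r} has no scans")

    def ms1_scans(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 1]

    def ms2_scans(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 2]


@dataclass
class DatasetManifest:
    """Acquisition file list plus named groups (sample/blank/replicate)."""

    acquisitions: list[Acquisition]
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        ids = [a.identifier for a in self.acquisitions]
        if len(set(ids)) != len(ids):
            raise SpectraIOError("duplicate acquisition identifier in manifest")
        if not self.groups:
            self.groups = {"all": list(ids)}
        for group, members in self.groups.items():
            unknown = set(members) - set(ids)
            if unknown:
                raise SpectraIOError(f"group {group!r} references unknown ids {unknown}")


def _split_by_polarity(identifier: str, source: str, scans: list[Scan]) -> list[Acquisition]:
    """One logical acquisition per polarity (some files interleave them)."""
    by_pol: dict[str, list[Scan]] = {}
    for s in scans:
        by_pol.setdefault(s.polarity, []).append(s)
    if len(by_pol) == 1:
        pol, sc = next(iter(by_pol.items()))
        return [Acquisition(identifier, sc, source, pol)]
    return [
        Acquisition(f"{identifier}{pol}", sc, source, pol)
        for pol, sc in sorted(by_pol.items())
    ]


def read_mzxml(path: str | Path) -> Acquisition:
    """Read an mzXML file into an :class:`Acquisition`.

    Scans are kept in file order; MS2 scans carry their recorded precursor
    m/z.  A file mixing polarities yields an error here; use
    :func:`read_mzxml_split` to split it into per-polarity acquisitions.
    """
    acqs = read_mzxml_split(path)
    if len(acqs) != 1:
        raise SpectraIOError(f"{path}: mixed polarities; use read_mzxml_split")
    return acqs[0]


def read_mzxml_split(path: str | Path) -> list[Acquisition]:
    path = Path(path)
    scans: list[Scan] = []
    with _pyteomics_mzxml.MzXML(str(path), use_index=False) as reader:
        for i, entry in enumerate(reader):
            if "msLevel" not in entry:
                raise SpectraIOError(f"{path}: scan without msLevel")
            level = int(entry["msLevel"])
            pol = entry.get("polarity", "+")
            prec = None
            if level >= 2:
                plist = entry.get("precursorMz")
                if not plist:
                    raise SpectraIOError(f"{path}: MS2 scan without precursorMz")
                prec = float(plist[0]["precursorMz"])
            scans.append(
                Scan(
                    mz=entry.get("m/z array", np.empty(0)),
                    intensity=entry.get("intensity array", np.empty(0)),
                    ms_level=level,
                    polarity=pol,
                    precursor_mz=prec,
                    index=i,
                )
            )
    if not scans:
        raise SpectraIOError(f"{path}: no scans")
    return _split_by_polarity(path.stem, str(path), scans)


def read_peaklist(
    path: str | Path,
    ms_level: int = 1,
    polarity: str = "+",
    precursor_mz: float | None = None,
) -> Scan:
    """Read a two-column (m/z, intensity) *.dta / *.csv peak list.

    Columns may be separated by whitespace, commas, tabs or semicolons;
    lines starting with ``#`` are comments.  Peaks are sorted by m/z.
    """
    mzs, intens = [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", " ").replace(";", " ").split() if p]
        if len(parts) < 2:
            raise SpectraIOError(f"{path}:{lineno}: expected two columns, got {raw!r}")
        try:
            mzs.append(float(parts[0]))
            intens.append(float(parts[1]))
        except ValueError as exc:
            raise SpectraIOError(f"{path}:{lineno}: non-numeric row {raw!r}") from exc
    return Scan(
        mz=np.array(mzs),
        intensity=np.array(intens),
        ms_level=ms_level,
        polarity=polarity,
        precursor_mz=precursor_mz,
    )


def _encode_peaks(mz: np.ndarray, intensity: np.ndarray, compress: bool) -> str:
    interleaved = np.empty(2 * mz.size, dtype=">f8")
    interleaved[0::2] = mz
    interleaved[1::2] = intensity
    raw = interleaved.tobytes()
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


def write_mzxml(path: str | Path, scans: list[Scan], compress: bool = False) -> None:
    """Write scans as a minimal centroided mzXML 3.2 file (64-bit peaks)."""
    if not scans:
        raise SpectraIOError("refusing to write an mzXML file with no scans")
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2"',
        '       xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance"',
        '       xsi:schemaLocation="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2 http://sashimi.sourceforge.net/schema_revision/mzXML_3.2/mzXML_idx_3.2.xsd">',
        f'  <msRun scanCount="{len(scans)}">',
    ]
    for num, scan in enumerate(scans, 1):
        lo = scan.mz.min() if scan.n_peaks else 0.0
        hi = scan.mz.max() if scan.n_peaks else 0.0
        lines.append(
            f'    <scan num="{num}" msLevel="{scan.ms_level}" peaksCount="{scan.n_peaks}"'
            f' polarity="{escape(scan.polarity)}" centroided="1"'
            f' lowMz="{lo:.6f}" highMz="{hi:.6f}">'
        )
        if scan.ms_level >= 2:
            lines.append(
                f'      <precursorMz precursorIntensity="0">{scan.precursor_mz:.6f}</precursorMz>'
            )
        comp = ' compressionType="zlib"' if compress else ' compressionType="none"'
        payload = _encode_peaks(scan.mz, scan.intensity, compress)
        lines.append(
            f'      <peaks precision="64" byteOrder="network"'
            f' contentType="m/z-int"{comp}>{payload}</peaks>'
        )
        lines.append("    </scan>")
    lines.append("  </msRun>")
    lines.append("</mzXML>")
    Path(path).write_text("\n".join(lines) + "\n")


def load_manifest(path: str | Path) -> DatasetManifest:
    """Load a dataset manifest (INI with [files] and optional [groups]).

    ``[files]`` maps acquisition id -> file path (mzXML or peak list);
    ``[groups]`` maps group name -> comma-separated acquisition ids.
    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keep identifier case
    read = cp.read(path)
    if not read:
        raise SpectraIOError(f"cannot read manifest {path}")
    if "files" not in cp:
        raise SpectraIOError(f"{path}: manifest needs a [files] section")
    acquisitions: list[Acquisition] = []
    seen: set[str] = set()
    for ident, fname in cp["files"].items():
        if ident in seen:
            raise SpectraIOError(f"{path}: duplicate identifier {ident!r}")
        seen.add(ident)
        fpath = Path(fname)
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        if not fpath.exists():
            raise SpectraIOError(f"{path}: missing file {fpath}")
        if fpath.suffix.lower() == ".mzxml":
            acq = read_mzxml(fpath)
            acq.identifier = ident
        else:
            scan = read_peaklist(fpath)
            acq = Acquisition(ident, [scan], str(fpath), scan.polarity)
        acquisitions.append(acq)
    groups: dict[str, list[str]] = {}
    if "groups" in cp:
        for gname, members in cp["groups"].items():
            groups[gname] = [m.strip() for m in members.split(",") if m.strip()]
    return DatasetManifest(acquisitions, groups)
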