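"""Centroided runs: reading/writing, XIC extraction, band detection, averaging.

A run is a retention-time-ordered list of centroided scans, interleaving MS1
full scans with all-ion-fragmentation (AIF) scans of one ESI polarity.  HILIC
separates phospholipids by head group, so one class elutes as one band; the
band is located from the XIC of its AIF diagnostic fragment and the MS1 scans
inside the band are averaged into a single class spectrum that is annotated
downstream.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .errors import BandNotFoundError, DataError
from .lipid_chem import IonSpecies

TSV_HEADER = ("rt_min", "polarity", "level", "mz", "intensity")

POLARITIES = ("positive", "negative")
LEVELS = ("full_scan", "AIF")


class CentroidPeak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Scan:
    """One centroided scan; peaks sorted ascending by m/z."""

    retention_time: float  # minutes
    polarity: str
    level: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.polarity not in POLARITIES:
            raise DataError(f"unknown polarity {self.polarity!r}")
        if self.level not in LEVELS:
            raise DataError(f"unknown scan level {self.level!r}")
        if self.mz.shape != self.intensity.shape:
            raise DataError("mz and intensity arrays differ in length")
        if self.mz.size:
            if np.any(self.mz <= 0) or np.any(self.intensity < 0):
                raise DataError("peaks require mz > 0 and intensity >= 0")
            if np.any(np.diff(self.mz) < 1e-6):
                raise DataError("scan peaks must be sorted and unique within 1e-6 m/z")

    @property
    def peaks(self) -> list[CentroidPeak]:
        return [CentroidPeak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]


@dataclass
class Chromatogram:
    """Extracted-ion chromatogram of one m/z window."""

    retention_time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.retention_time = np.asarray(self.retention_time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.retention_time.size > 1 and np.any(np.diff(self.retention_time) <= 0):
            raise DataError("chromatogram times must be strictly increasing")


@dataclass
class ClassSpectrum:
    """Averaged MS1 spectrum over one class band."""

    polarity: str
    rt_window: tuple[float, float]
    mz: np.ndarray
    intensity: np.ndarray
    lipid_class: object | None = None  # set by the pipeline once the band is assigned
    base_peak_intensity: float | None = None  # most intense endogenous candidate

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt_window[0] >= self.rt_window[1]:
            raise DataError("rt window start must precede end")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise DataError("averaged peaks must be sorted by m/z")


# --------------------------------------------------------------------------
# Run I/O — TSV scan dialect and centroided mzML
# --------------------------------------------------------------------------

def read_run(path: str | Path, format: str = "tsv") -> list[Scan]:
    """Read a centroided run; scans are returned ordered by retention time."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"run file not found: {path}")
    if format == "tsv":
        scans = _read_tsv(path)
    elif format == "mzml":
        scans = _read_mzml(path)
    else:
        raise DataError(f"unknown run format {format!r}")
    if not scans:
        raise DataError(f"no scans in {path}")
    scans.sort(key=lambda s: s.retention_time)
    return scans


def write_run(scans: Sequence[Scan], path: str | Path, format: str = "tsv") -> None:
    if format == "tsv":
        _write_tsv(scans, path)
    elif format == "mzml":
        _write_mzml(scans, path)
    else:
        raise DataError(f"unknown run format {format!r}")


def _read_tsv(path: Path) -> list[Scan]:
    lines = path.read_text(encoding="utf-8").splitlines()
    rows = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
    if not rows:
        raise DataError(f"empty run file: {path}")
    if tuple(rows[0].split("\t")) != TSV_HEADER:
        raise DataError(f"bad TSV header in {path}: expected {' '.join(TSV_HEADER)}")
    groups: dict[tuple[float, str, str], list[tuple[float, float]]] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        fields = row.split("\t")
        if len(fields) != 5:
            raise DataError(f"{path}:{lineno}: expected 5 tab-separated fields")
        try:
            rt = float(fields[0])
            mz = float(fields[3])
            inten = float(fields[4])
        except ValueError as exc:
            raise DataError(f"{path}:{lineno}: non-numeric value ({exc})") from None
        pol, level = fields[1], fields[2]
        if pol not in POLARITIES or level not in LEVELS:
            raise DataError(f"{path}:{lineno}: bad polarity/level {pol!r}/{level!r}")
        groups.setdefault((rt, pol, level), []).append((mz, inten))
    scans = []
    for (rt, pol, level), peaks in groups.items():
        peaks.sort()
        arr = np.array(peaks, dtype=float)
        scans.append(Scan(rt, pol, level, arr[:, 0], arr[:, 1]))
    return scans


def _write_tsv(scans: Sequence[Scan], path: str | Path) -> None:
    out = ["\t".join(TSV_HEADER)]
    for scan in sorted(scans, key=lambda s: (s.retention_time, s.polarity, s.level)):
        for m, i in zip(scan.mz, scan.intensity):
            out.append(f"{scan.retention_time:.6f}\t{scan.polarity}\t{scan.level}\t{m:.6f}\t{i:.6f}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# Minimal mzML support for centroided spectra, built directly on
# xml.etree: reading handles 32/64-bit, plain or zlib-compressed binary
# arrays; writing emits uncompressed 64-bit arrays.

_NS = "http://psi.hupo.org/ms/mzml"


def _decode_binary(bda: ET.Element) -> np.ndarray:
    accessions = {cv.get("accession") for cv in bda.iter() if cv.tag.endswith("cvParam")}
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    binary = bda.find(f"{{{_NS}}}binary")
    if binary is None:
        binary = bda.find("binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        import zlib

        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[Scan]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise DataError(f"{path}: not valid XML ({exc})") from exc
    root = tree.getroot()
    ns = f"{{{_NS}}}" if root.tag.startswith(f"{{{_NS}}}") else ""
    scans = []
    for spec in root.iter(f"{ns}spectrum"):
        params = {
            cv.get("accession"): cv for cv in spec.iter(f"{ns}cvParam")
        }
        if "MS:1000128" in params:
            raise DataError(
                f"{path}: profile-mode spectrum {spec.get('id')}; centroid the data first"
            )
        rt_param = next(
            (cv for cv in spec.iter(f"{ns}cvParam") if cv.get("accession") == "MS:1000016"),
            None,
        )
        if rt_param is None:
            raise DataError(f"{path}: spectrum {spec.get('id')} lacks a scan start time")
        rt = float(rt_param.get("value"))
        if rt_param.get("unitName") == "second":
            rt /= 60.0
        polarity = "negative" if "MS:1000129" in params else "positive"
        level = "full_scan" if params.get("MS:1000511") is None or \
            params["MS:1000511"].get("value") == "1" else "AIF"
        arrays = {}
        for bda in spec.iter(f"{ns}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
            if "MS:1000514" in accs:
                arrays["mz"] = _decode_binary(bda)
            elif "MS:1000515" in accs:
                arrays["intensity"] = _decode_binary(bda)
        if "mz" not in arrays or "intensity" not in arrays:
            raise DataError(f"{path}: spectrum {spec.get('id')} lacks m/z or intensity array")
        order = np.argsort(arrays["mz"])
        scans.append(Scan(rt, polarity, level, arrays["mz"][order], arrays["intensity"][order]))
    return scans


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{values.size}d", *values)).decode("ascii")


def _write_mzml(scans: Sequence[Scan], path: str | Path) -> None:
    def cv(parent, accession, name, value="", unit=()):
        el = ET.SubElement(parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value)
        if unit:
            el.set("unitCvRef", "UO")
            el.set("unitAccession", unit[0])
            el.set("unitName", unit[1])

    root = ET.Element("mzML", xmlns=_NS, version="1.1.0")
    cvlist = ET.SubElement(root, "cvList", count="2")
    ET.SubElement(cvlist, "cv", id="MS", fullName="PSI-MS", URI="")
    ET.SubElement(cvlist, "cv", id="UO", fullName="UO", URI="")
    run = ET.SubElement(root, "run", id="run")
    slist = ET.SubElement(run, "spectrumList", count=str(len(scans)))
    for idx, scan in enumerate(scans):
        spec = ET.SubElement(slist, "spectrum", index=str(idx),
                             id=f"scan={idx + 1}", defaultArrayLength=str(scan.mz.size))
        cv(spec, "MS:1000511", "ms level", "1" if scan.level == "full_scan" else "2")
        cv(spec, "MS:1000127", "centroid spectrum")
        if scan.polarity == "positive":
            cv(spec, "MS:1000130", "positive scan")
        else:
            cv(spec, "MS:1000129", "negative scan")
        sl = ET.SubElement(spec, "scanList", count="1")
        sc = ET.SubElement(sl, "scan")
        cv(sc, "MS:1000016", "scan start time", f"{scan.retention_time:.6f}",
           unit=("UO:0000031", "minute"))
        bl = ET.SubElement(spec, "binaryDataArrayList", count="2")
        for arr, acc, name in ((scan.mz, "MS:1000514", "m/z array"),
                               (scan.intensity, "MS:1000515", "intensity array")):
            encoded = _b64(arr)
            bda = ET.SubElement(bl, "binaryDataArray", encodedLength=str(len(encoded)))
            cv(bda, "MS:1000523", "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, acc, name)
            ET.SubElement(bda, "binary").text = encoded
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


# --------------------------------------------------------------------------
# XIC extraction and class-band detection
# --------------------------------------------------------------------------

def extract_xic(scans: Sequence[Scan], target_mz: float, tol_ppm: float = 5.0) -> Chromatogram:
    """Per-scan summed intensity within +/- tol_ppm of target_mz (0 when none)."""
    if tol_ppm <= 0:
        raise DataError("tol_ppm must be positive")
    tol = target_mz * tol_ppm * 1e-6
    rts, intens = [], []
    for scan in scans:
        lo = np.searchsorted(scan.mz, target_mz - tol, side="left")
        hi = np.searchsorted(scan.mz, target_mz + tol, side="right")
        rts.append(scan.retention_time)
        intens.append(float(scan.intensity[lo:hi].sum()))
    return Chromatogram(np.asarray(rts), np.asarray(intens))


def _moving_average(values: np.ndarray, width: int = 3) -> np.ndarray:
    if values.size < width:
        return values.copy()
    kernel = np.ones(width) / width
    smoothed = np.convolve(values, kernel, mode="same")
    # edges: shorter windows
    smoothed[0] = values[:2].mean()
    smoothed[-1] = values[-2:].mean()
    return smoothed


def detect_class_band(
    scans_aif: Sequence[Scan],
    diagnostic: IonSpecies,
    tol_ppm: float = 5.0,
    rel_threshold: float = 0.05,
) -> tuple[float, float]:
    """Contiguous RT interval around the global XIC apex of a diagnostic ion.

    The AIF XIC is smoothed with a 3-point moving average; the band is the
    contiguous interval around the most intense point where the smoothed trace
    stays at or above ``rel_threshold`` times the apex.
    """
    if not 0 < rel_threshold < 1:
        raise DataError("rel_threshold must lie in (0, 1)")
    xic = extract_xic(scans_aif, diagnostic.theoretical_mz, tol_ppm)
    if xic.intensity.size == 0 or xic.intensity.max() <= 0:
        raise BandNotFoundError(f"band not found for diagnostic ion {diagnostic.label}")
    smoothed = _moving_average(xic.intensity)
    apex = int(np.argmax(smoothed))
    floor = rel_threshold * smoothed[apex]
    lo = apex
    while lo > 0 and smoothed[lo - 1] >= floor:
        lo -= 1
    hi = apex
    while hi < smoothed.size - 1 and smoothed[hi + 1] >= floor:
        hi += 1
    return float(xic.retention_time[lo]), float(xic.retention_time[hi])


# --------------------------------------------------------------------------
# Retention-time spectral averaging
# --------------------------------------------------------------------------

def average_spectrum(
    scans_full: Sequence[Scan],
    rt_window: tuple[float, float],
    polarity: str,
    cluster_tol_ppm: float = 5.0,
) -> ClassSpectrum:
    """Average MS1 scans inside a closed RT window into one class spectrum.

    Peaks are clustered greedily in ascending m/z at ``cluster_tol_ppm``
    around the running intensity-weighted mean; a cluster's intensity is the
    sum over scans divided by the number of in-window scans, so a peak absent
    from some scans is zero-filled (true mean spectrum).
    """
    lo, hi = rt_window
    selected = [
        s for s in scans_full
        if s.polarity == polarity and s.level == "full_scan" and lo <= s.retention_time <= hi
    ]
    if not selected:
        raise DataError(f"no {polarity} full scans inside RT window [{lo:.3f}, {hi:.3f}] min")
    n_scans = len(selected)
    mz_all = np.concatenate([s.mz for s in selected])
    int_all = np.concatenate([s.intensity for s in selected])
    order = np.argsort(mz_all, kind="stable")
    mz_all, int_all = mz_all[order], int_all[order]

    out_mz, out_int = [], []
    i = 0
    n = mz_all.size
    while i < n:
        wsum = mz_all[i] * int_all[i]
        isum = int_all[i]
        mean = mz_all[i] if isum == 0 else wsum / isum
        j = i + 1
        while j < n and abs(mz_all[j] - mean) <= mean * cluster_tol_ppm * 1e-6:
            wsum += mz_all[j] * int_all[j]
            isum += int_all[j]
            if isum > 0:
                mean = wsum / isum
            j += 1
        out_mz.append(mean)
        out_int.append(isum / n_scans)
        i = j
    return ClassSpectrum(
        polarity=polarity,
        rt_window=(lo, hi),
        mz=np.asarray(out_mz),
        intensity=np.asarray(out_int),
    )
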