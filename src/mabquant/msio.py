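"""MS1 run model and mzML input/output.

A run is an ordered list of MS1 scans (retention time in minutes, ascending
m/z array, intensity array).  Both directions speak PSI-mzML 1.1.0 via lxml:
the reader handles 32/64-bit float arrays, optional zlib compression, and
second- or minute-valued scan start times; the writer emits centroid MS1
spectra as uncompressed 64-bit arrays.  Round trips are validated in the
test suite against an independent reader.

``average_spectrum`` sums scans over a half-open retention-time window
``[start, end)`` onto a resolution-aware m/z grid: bin width is the expected
peak width m/z / R oversampled 4x, i.e. constant relative width 1/(4R), with
each output m/z the intensity-weighted centroid of its bin.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

__all__ = ["Scan", "MsRun", "Spectrum", "read_run", "write_run", "average_spectrum"]

_NS = "http://psi.hupo.org/ms/mzml"
DEFAULT_RESOLUTION = 17500.0


@dataclass
class Scan:
    """One MS1 scan: retention time (minutes) plus centroid arrays."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz array must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")


@dataclass
class MsRun:
    """Ordered MS1 scans plus instrument/config metadata."""

    scans: list[Scan]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.scans:
            raise ValueError("a run needs at least one scan")
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be non-decreasing")

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    def scans_in_window(self, start: float, end: float) -> list[Scan]:
        """Scans with rt in the half-open window [start, end)."""
        return [s for s in self.scans if start <= s.rt < end]


@dataclass
class Spectrum:
    """A single or averaged spectrum without retention time."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")


_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"


def _decode_array(bda) -> np.ndarray:
    accessions = {cv.get("accession") for cv in bda.findall(f"{{{_NS}}}cvParam")}
    binary = bda.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_run(path: str) -> MsRun:
    """Read all MS1 scans of an mzML file; MS2+ spectra are skipped.

    Handles 32/64-bit float arrays with optional zlib compression.
    Retention times are converted to minutes.  Raises ``ValueError`` if the
    file contains no MS1 spectra.
    """
    tree = etree.parse(str(path))
    scans = []
    for spec in tree.iter(f"{{{_NS}}}spectrum"):
        ms_level = 1
        for cv in spec.findall(f"{{{_NS}}}cvParam"):
            if cv.get("accession") == _ACC_MS_LEVEL:
                ms_level = int(cv.get("value"))
        if ms_level != 1:
            continue
        rt_min = 0.0
        for cv in spec.iter(f"{{{_NS}}}cvParam"):
            if cv.get("accession") == _ACC_SCAN_START:
                rt_min = float(cv.get("value"))
                if cv.get("unitName", "minute") in ("second", "seconds"):
                    rt_min /= 60.0
        mz = intensity = None
        for bda in spec.iter(f"{{{_NS}}}binaryDataArray"):
            accessions = {cv.get("accession") for cv in bda.findall(f"{{{_NS}}}cvParam")}
            if _ACC_MZ_ARRAY in accessions:
                mz = _decode_array(bda)
            elif _ACC_INTENSITY_ARRAY in accessions:
                intensity = _decode_array(bda)
        if mz is None or intensity is None:
            raise ValueError(f"spectrum without m/z or intensity array in {path}")
        scans.append(Scan(rt=rt_min, mz=mz, intensity=intensity))
    if not scans:
        raise ValueError(f"no MS1 scans in {path}")
    metadata = {}
    for up in tree.findall(f".//{{{_NS}}}run/{{{_NS}}}userParam"):
        value = up.get("value", "")
        try:
            value = float(value) if "." in value or "e" in value.lower() else int(value)
        except ValueError:
            pass
        metadata[up.get("name")] = value
    return MsRun(scans=scans, metadata=metadata)


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _cv(parent, accession, name, value=None, **units):
    el = etree.SubElement(parent, "cvParam")
    el.set("cvRef", "MS")
    el.set("accession", accession)
    el.set("name", name)
    el.set("value", "" if value is None else str(value))
    for k, v in units.items():
        el.set(k, v)
    return el


def write_run(run: MsRun, path: str) -> None:
    """Write a run as PSI-mzML 1.1.0 (centroid MS1, 64-bit, uncompressed).

    Run-level metadata entries are persisted as userParams on the <run>
    element and restored by :func:`read_run`.
    """
    root = etree.Element("mzML", nsmap={None: _NS})
    root.set("version", "1.1.0")
    cvlist = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cvlist, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cvlist, "cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    soft_list = etree.SubElement(root, "softwareList", count="1")
    soft = etree.SubElement(soft_list, "software", id="mabquant", version="0.1.0")
    _cv(soft, "MS:1000799", "custom unreleased software tool", "mabquant")
    icl = etree.SubElement(root, "instrumentConfigurationList", count="1")
    ic = etree.SubElement(icl, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dpl = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dpl, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="mabquant")
    _cv(pm, "MS:1000544", "Conversion to mzML")
    run_el = etree.SubElement(root, "run", id="run1", defaultInstrumentConfigurationRef="IC1")
    for key, value in run.metadata.items():
        etree.SubElement(run_el, "userParam", name=str(key), value=str(value))
    slist = etree.SubElement(
        run_el, "spectrumList", count=str(len(run.scans)), defaultDataProcessingRef="DP1"
    )
    for i, scan in enumerate(run.scans):
        spec = etree.SubElement(
            slist, "spectrum", index=str(i), id=f"scan={i + 1}",
            defaultArrayLength=str(scan.mz.size),
        )
        _cv(spec, "MS:1000511", "ms level", scan.ms_level)
        _cv(spec, "MS:1000579", "MS1 spectrum")
        _cv(spec, "MS:1000127", "centroid spectrum")
        scan_list = etree.SubElement(spec, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan_el = etree.SubElement(scan_list, "scan")
        _cv(
            scan_el, "MS:1000016", "scan start time", repr(float(scan.rt)),
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute",
        )
        bdal = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
            (scan.mz, "MS:1000514", "m/z array", ("MS", "MS:1000040", "m/z")),
            (scan.intensity, "MS:1000515", "intensity array",
             ("MS", "MS:1000131", "number of detector counts")),
        ):
            payload = _b64(arr)
            bda = etree.SubElement(bdal, "binaryDataArray", encodedLength=str(len(payload)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name, unitCvRef=unit[0], unitAccession=unit[1], unitName=unit[2])
            etree.SubElement(bda, "binary").text = payload
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


def average_spectrum(
    run: MsRun, rt_window: tuple[float, float], resolution: float | None = None
) -> Spectrum:
    """Sum scan intensities over [start, end) onto a common m/z grid.

    Linear in intensities and invariant to scan order.  Raises ``ValueError``
    when the window covers no scan.
    """
    start, end = rt_window
    scans = run.scans_in_window(start, end)
    if not scans:
        raise ValueError(f"no scans in retention-time window [{start}, {end})")
    if resolution is None:
        resolution = float(run.metadata.get("resolution", DEFAULT_RESOLUTION))
    mz = np.concatenate([s.mz for s in scans])
    intensity = np.concatenate([s.intensity for s in scans])
    keep = intensity > 0
    mz, intensity = mz[keep], intensity[keep]
    if mz.size == 0:
        return Spectrum(np.empty(0), np.empty(0))
    # geometric bins of constant relative width 1/(4R), anchored at m/z 100
    log_ratio = np.log1p(1.0 / (4.0 * resolution))
    idx = np.floor(np.log(mz / 100.0) / log_ratio).astype(np.int64)
    order = np.argsort(idx, kind="stable")
    idx, mz, intensity = idx[order], mz[order], intensity[order]
    uniq, starts = np.unique(idx, return_index=True)
    sums = np.add.reduceat(intensity, starts)
    centroids = np.add.reduceat(mz * intensity, starts) / sums
    order = np.argsort(centroids)
    return Spectrum(centroids[order], sums[order])
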