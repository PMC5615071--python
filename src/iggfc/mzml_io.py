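"""Centroided MS1 run container and mzML I/O.

A run is held as RT-ordered scans of (m/z, intensity) centroid arrays.
A compact mzML writer and reader are provided (centroid MS1, 32/64-bit
float binary arrays, no compression or zlib), covering the subset of the
format this pipeline produces and consumes.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np


@dataclass
class Scan:
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative centroid intensity")


@dataclass
class RunSpectra:
    """RT-ordered centroided MS1 scans for one sample."""

    scans: list = field(default_factory=list)
    sample_id: str = ""

    def __post_init__(self):
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    def shifted(self, rt_shift: float) -> "RunSpectra":
        return RunSpectra(
            [Scan(s.rt + rt_shift, s.mz, s.intensity) for s in self.scans],
            self.sample_id)

    def with_mz_offset(self, offset: float) -> "RunSpectra":
        return RunSpectra(
            [Scan(s.rt, s.mz + offset, s.intensity) for s in self.scans],
            self.sample_id)


def _encode(array: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{array.size}d", *array)).decode()


def write_mzml(run: RunSpectra, path) -> None:
    """Write a centroid MS1 run to mzML."""
    sid = escape(run.sample_id or "run", {'"': "&quot;"})
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        f'<run id="{sid}">\n'
        f'<spectrumList count="{len(run.scans)}">\n'
    ]
    for i, scan in enumerate(run.scans):
        mz_b64 = _encode(scan.mz)
        int_b64 = _encode(scan.intensity)
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{scan.mz.size}">\n'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            '<scanList count="1">\n<scan>\n'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{scan.rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n'
            '</scan>\n</scanList>\n'
            '<binaryDataArrayList count="2">\n'
            f'<binaryDataArray encodedLength="{len(mz_b64)}">\n'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>\n'
            f'<binary>{mz_b64}</binary>\n</binaryDataArray>\n'
            f'<binaryDataArray encodedLength="{len(int_b64)}">\n'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>\n'
            f'<binary>{int_b64}</binary>\n</binaryDataArray>\n'
            '</binaryDataArrayList>\n</spectrum>\n'
        )
    parts.append('</spectrumList>\n</run>\n</mzML>\n')
    with open(path, "w") as fh:
        fh.write("".join(parts))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(elem) -> np.ndarray | None:
    """Decode one <binaryDataArray>; returns (kind, values)."""
    dtype, compression, kind, payload = "d", "none", None, ""
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000523":
                dtype = "d"
            elif acc == "MS:1000521":
                dtype = "f"
            elif acc == "MS:1000574":
                compression = "zlib"
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compression == "zlib":
        raw = zlib.decompress(raw)
    values = np.frombuffer(raw, dtype=np.dtype("<" + dtype)).astype(float)
    return kind, values


def _scan_start_time_seconds(spectrum) -> float:
    for child in spectrum.iter():
        if _local(child.tag) == "cvParam" and \
                child.get("accession") == "MS:1000016":
            rt = float(child.get("value"))
            if child.get("unitName", "second").startswith("minute"):
                rt *= 60.0
            return rt
    raise ValueError("spectrum without scan start time")


def read_mzml(path, sample_id: str = "") -> RunSpectra:
    """Read centroid MS1 scans from an mzML file."""
    scans = []
    for _, elem in ElementTree.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        ms_level = 1
        for child in elem.iter():
            if _local(child.tag) == "cvParam" and \
                    child.get("accession") == "MS:1000511":
                ms_level = int(child.get("value"))
        if ms_level != 1:
            elem.clear()
            continue
        rt = _scan_start_time_seconds(elem)
        arrays = {}
        for child in elem.iter():
            if _local(child.tag) == "binaryDataArray":
                kind, values = _decode_binary_array(child)
                if kind:
                    arrays[kind] = values
        scans.append(Scan(rt, arrays.get("mz", np.empty(0)),
                          arrays.get("intensity", np.empty(0))))
        elem.clear()
    scans.sort(key=lambda s: s.rt)
    return RunSpectra(scans, sample_id=sample_id)
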