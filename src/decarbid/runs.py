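"""In-memory containers for LC-MS acquisitions and their text serialization.

A :class:`Run` is an RT-ordered list of centroided scans from one injection.
Runs round-trip through a line-oriented text fixture format and can also be
read from (and written to, minimally) mzML.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "CentroidSpectrum",
    "Run",
    "MS2Spectrum",
    "MRMTrace",
    "read_run",
    "write_run",
    "read_mzml",
    "write_mzml",
    "read_ms2",
    "write_ms2",
]


@dataclass
class CentroidSpectrum:
    """One centroided MS1 scan: (m/z, intensity) pairs at a retention time."""

    retention_time: float  # minutes
    polarity: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities in centroid spectrum")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Run:
    """An RT-ordered scan list for one sample injection."""

    run_id: str
    polarity: str
    scans: list[CentroidSpectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.retention_time for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("scans are not RT-ordered")

    @property
    def scan_times(self) -> np.ndarray:
        return np.array([s.retention_time for s in self.scans])

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class MS2Spectrum:
    """A fragmentation spectrum tied to a precursor ion."""

    precursor_mz: float
    polarity: str
    mz: np.ndarray
    intensity: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative fragment intensities")


@dataclass
class MRMTrace:
    """A single Q1/Q3 transition chromatogram from one run."""

    analyte: str
    q1: float
    q3: float
    polarity: str
    rt: np.ndarray
    intensity: np.ndarray
    run_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.rt) < 0):
            raise ValueError("MRM trace points are not RT-ordered")


# ---------------------------------------------------------------------------
# Internal fixture format: plain text, one scan header then m/z-intensity
# pairs per line.
#
#   #RUN id=<run_id> polarity=<positive|negative>
#   SCAN rt=<minutes>
#   <mz> <intensity>
#   ...
# ---------------------------------------------------------------------------

def write_run(run: Run, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#RUN id={run.run_id} polarity={run.polarity}\n")
        for scan in run.scans:
            fh.write(f"SCAN rt={scan.retention_time:.6f}\n")
            for mz, inten in zip(scan.mz, scan.intensity):
                fh.write(f"{mz:.6f} {inten:.4f}\n")


def read_run(path: str | Path) -> Run:
    path = Path(path)
    run_id, polarity = path.stem, "positive"
    scans: list[CentroidSpectrum] = []
    cur_rt: float | None = None
    cur_mz: list[float] = []
    cur_int: list[float] = []

    def flush() -> None:
        if cur_rt is not None:
            scans.append(
                CentroidSpectrum(cur_rt, polarity, np.array(cur_mz), np.array(cur_int))
            )

    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#RUN"):
                for token in line.split()[1:]:
                    key, _, value = token.partition("=")
                    if key == "id":
                        run_id = value
                    elif key == "polarity":
                        polarity = value
            elif line.startswith("SCAN"):
                flush()
                cur_rt = float(line.split("rt=")[1])
                cur_mz, cur_int = [], []
            else:
                mz_s, int_s = line.split()
                cur_mz.append(float(mz_s))
                cur_int.append(float(int_s))
    flush()
    return Run(run_id, polarity, scans)


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

def _decode_binary(element, n_points: int) -> np.ndarray:
    accessions = {
        child.get("accession")
        for child in element
        if child.tag.endswith("cvParam")
    }
    binary = next(c for c in element if c.tag.endswith("binary"))
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "d" if "MS:1000523" in accessions else "f"
    return np.array(struct.unpack(f"<{n_points}{dtype}", raw))


def read_mzml(path: str | Path, run_id: str | None = None) -> Run:
    """Read centroided MS1 scans from an mzML file.

    A deliberately small reader for the subset of mzML this package writes
    (and instrument converters commonly emit): per-spectrum ms level,
    polarity and scan start time cvParams plus zlib/base64 m/z and
    intensity arrays in 32- or 64-bit floats.
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    scans: list[CentroidSpectrum] = []
    polarity = "positive"
    root = ET.parse(path).getroot()

    def findall(elem, tag):
        return [e for e in elem.iter() if e.tag.endswith(tag)]

    for spectrum in findall(root, "spectrum"):
        params = {
            p.get("accession"): p
            for p in findall(spectrum, "cvParam")
        }
        level = params.get("MS:1000511")
        if level is not None and level.get("value") not in ("", "1"):
            continue
        if "MS:1000129" in params:
            polarity = "negative"
        elif "MS:1000130" in params:
            polarity = "positive"
        rt_param = params.get("MS:1000016")
        if rt_param is None:
            raise ValueError(f"{path}: spectrum without a scan start time")
        rt = float(rt_param.get("value"))
        if rt_param.get("unitName") == "second":
            rt /= 60.0
        n = int(spectrum.get("defaultArrayLength"))
        arrays = {}
        for bda in findall(spectrum, "binaryDataArray"):
            accs = {p.get("accession") for p in findall(bda, "cvParam")}
            if "MS:1000514" in accs:
                arrays["mz"] = _decode_binary(bda, n)
            elif "MS:1000515" in accs:
                arrays["intensity"] = _decode_binary(bda, n)
        scans.append(CentroidSpectrum(rt, polarity, arrays["mz"], arrays["intensity"]))
    scans.sort(key=lambda s: s.retention_time)
    return Run(run_id or path.stem, polarity, scans)


def _encode_array(values: np.ndarray, dtype: str) -> str:
    packed = struct.pack(f"<{len(values)}{dtype}", *values)
    return base64.b64encode(zlib.compress(packed)).decode("ascii")


def write_mzml(run: Run, path: str | Path) -> None:
    """Write a minimal centroided mzML file readable by standard parsers."""
    pol_cv = (
        '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
        if run.polarity == "positive"
        else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>'
    )
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="1"><cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/></cvList>',
        '<fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
        "</fileContent></fileDescription>",
        '<softwareList count="1"><software id="decarbid" version="0"/></softwareList>',
        '<instrumentConfigurationList count="1"><instrumentConfiguration id="IC"/></instrumentConfigurationList>',
        '<dataProcessingList count="1"><dataProcessing id="dp">'
        '<processingMethod order="0" softwareRef="decarbid"/></dataProcessing></dataProcessingList>',
        f'<run id="{run.run_id}" defaultInstrumentConfigurationRef="IC">',
        f'<spectrumList count="{len(run.scans)}" defaultDataProcessingRef="dp">',
    ]
    for i, scan in enumerate(run.scans):
        mz_b64 = _encode_array(scan.mz, "d")
        int_b64 = _encode_array(scan.intensity, "f")
        lines.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(scan)}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            + pol_cv
            + '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{scan.retention_time:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>'
            "</scan></scanList>"
            '<binaryDataArrayList count="2">'
            f'<binaryDataArray encodedLength="{len(mz_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>'
            f"<binary>{mz_b64}</binary></binaryDataArray>"
            f'<binaryDataArray encodedLength="{len(int_b64)}">'
            '<cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression" value=""/>'
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>'
            f"<binary>{int_b64}</binary></binaryDataArray>"
            "</binaryDataArrayList></spectrum>"
        )
    lines += ["</spectrumList>", "</run>", "</mzML>"]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# MS2 spectra: MGF-style text blocks
# ---------------------------------------------------------------------------

def write_ms2(spectra: Iterable[MS2Spectrum], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            if spec.name:
                fh.write(f"TITLE={spec.name}\n")
            fh.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            fh.write(f"CHARGE=1{'+' if spec.polarity == 'positive' else '-'}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{mz:.5f} {inten:.4f}\n")
            fh.write("END IONS\n")


def read_ms2(path: str | Path) -> list[MS2Spectrum]:
    spectra: list[MS2Spectrum] = []
    name: str | None = None
    precursor = 0.0
    polarity = "positive"
    mzs: list[float] = []
    ints: list[float] = []
    in_block = False
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line == "BEGIN IONS":
                in_block, name, precursor = True, None, 0.0
                polarity, mzs, ints = "positive", [], []
            elif line == "END IONS":
                spectra.append(
                    MS2Spectrum(precursor, polarity, np.array(mzs), np.array(ints), name)
                )
                in_block = False
            elif in_block:
                if line.startswith("TITLE="):
                    name = line[6:]
                elif line.startswith("PEPMASS="):
                    precursor = float(line[8:].split()[0])
                elif line.startswith("CHARGE="):
                    polarity = "negative" if line.endswith("-") else "positive"
                elif line and line[0].isdigit():
                    mz_s, int_s = line.split()
                    mzs.append(float(mz_s))
                    ints.append(float(int_s))
    return spectra
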