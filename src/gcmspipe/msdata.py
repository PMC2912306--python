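"""Raw GC/MS data model, file readers/writers and chromatogram extraction.

The in-memory model targets unit-resolution GC-quadrupole data: every scan is
binned to nominal (integer) m/z on load, with intensities summed when two
profile points round to the same nominal mass.  Retention times are stored in
seconds throughout; readers convert from minutes where the source format uses
them.

Internally a :class:`RawRun` keeps a dense ``(n_scans, n_channels)`` intensity
matrix over the union of observed m/z channels, which makes EIC/TIC extraction
a column slice / row sum.  :class:`Scan` objects are materialised on demand.

Supported formats
-----------------
* mzML (minimal built-in reader and writer: the writer emits MS1 spectra as
  64-bit uncompressed float arrays; the reader also accepts 32-bit and
  zlib-compressed arrays),
* ANDI-MS netCDF (NetCDF-3 classic, via ``scipy.io.netcdf_file``),
* an internal tab-separated scan table: header ``rt_s`` followed by one
  column per nominal m/z, one row per scan.
"""

from __future__ import annotations

import base64
import math
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, InputError

#: Sentinel channel value for total-ion traces.
TIC_CHANNEL = -1

#: Default admissible nominal m/z range.
MZ_MIN, MZ_MAX = 10, 1000


def nominal_mz(mz: float) -> int:
    """Bin an m/z value to nominal mass (round half up)."""
    return int(math.floor(mz + 0.5))


@dataclass
class Scan:
    """One mass-spectral scan: retention time plus a nominal-m/z spectrum."""

    rt: float
    intensities: dict[int, float]

    def __post_init__(self):
        if self.rt < 0:
            raise DataError(f"scan retention time must be >= 0, got {self.rt}")
        for mz, inten in self.intensities.items():
            if not (MZ_MIN <= mz <= MZ_MAX):
                raise DataError(f"m/z {mz} outside [{MZ_MIN}, {MZ_MAX}]")
            if inten < 0:
                raise DataError(f"negative intensity {inten} at m/z {mz}")


@dataclass
class Trace:
    """A chromatogram: one m/z channel (or the TIC) against retention time."""

    channel: int
    rts: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.rts = np.asarray(self.rts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.rts.shape != self.intensities.shape:
            raise InputError("trace rt and intensity arrays differ in length")
        if self.rts.size >= 2 and not np.all(np.diff(self.rts) > 0):
            raise DataError("trace retention times must be strictly increasing")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.rts.tolist(), self.intensities.tolist()))

    def __len__(self) -> int:
        return self.rts.size


class RawRun:
    """Ordered MS scans for one GC/MS analysis.

    Parameters
    ----------
    run_id:
        Identifier, usually the source file stem.
    rts:
        Strictly increasing scan retention times in seconds.
    mzs:
        Sorted unique nominal m/z channels observed anywhere in the run.
    matrix:
        ``(n_scans, len(mzs))`` non-negative intensity matrix.
    metadata:
        Free-form acquisition metadata.
    """

    def __init__(self, run_id: str, rts: np.ndarray, mzs: np.ndarray,
                 matrix: np.ndarray, metadata: Mapping | None = None):
        rts = np.asarray(rts, dtype=float)
        mzs = np.asarray(mzs, dtype=int)
        matrix = np.asarray(matrix, dtype=float)
        if rts.ndim != 1 or rts.size < 2:
            raise DataError("a run needs at least 2 scans")
        diffs = np.diff(rts)
        bad = np.flatnonzero(diffs <= 0)
        if bad.size:
            raise DataError(
                f"scan retention times not strictly increasing: scan {bad[0] + 1} "
                f"(rt {rts[bad[0] + 1]:g} s after {rts[bad[0]]:g} s)")
        if matrix.shape != (rts.size, mzs.size):
            raise DataError("intensity matrix shape does not match scans/channels")
        if mzs.size and (np.any(np.diff(mzs) <= 0)):
            raise DataError("m/z channels must be sorted and unique")
        if np.any(matrix < 0):
            raise DataError("negative intensity in run")
        self.run_id = run_id
        self.rts = rts
        self.mzs = mzs
        self.matrix = matrix
        self.metadata = dict(metadata or {})
        self._mz_index = {int(m): i for i, m in enumerate(mzs)}

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_scans(cls, run_id: str, scans: Sequence[Scan],
                   metadata: Mapping | None = None) -> "RawRun":
        if len(scans) < 2:
            raise DataError("a run needs at least 2 scans")
        rts = np.array([s.rt for s in scans], dtype=float)
        all_mzs = sorted({mz for s in scans for mz in s.intensities})
        mzs = np.array(all_mzs, dtype=int)
        idx = {m: i for i, m in enumerate(all_mzs)}
        matrix = np.zeros((len(scans), len(all_mzs)))
        for i, s in enumerate(scans):
            for mz, inten in s.intensities.items():
                matrix[i, idx[mz]] = inten
        return cls(run_id, rts, mzs, matrix, metadata)

    # -- views -------------------------------------------------------------

    @property
    def n_scans(self) -> int:
        return self.rts.size

    @property
    def scan_interval(self) -> float:
        """Median spacing between consecutive scans, seconds."""
        return float(np.median(np.diff(self.rts)))

    def scan(self, i: int) -> Scan:
        row = self.matrix[i]
        nz = np.flatnonzero(row)
        return Scan(float(self.rts[i]),
                    {int(self.mzs[j]): float(row[j]) for j in nz})

    @property
    def scans(self) -> list[Scan]:
        return [self.scan(i) for i in range(self.n_scans)]


# ---------------------------------------------------------------------------
# chromatogram extraction
# ---------------------------------------------------------------------------

def extract_eic(run: RawRun, mz: int) -> Trace:
    """Extracted-ion chromatogram of one nominal m/z channel.

    A channel absent from every scan yields an all-zero trace of full length.
    """
    j = run._mz_index.get(int(mz))
    if j is None:
        inten = np.zeros(run.n_scans)
    else:
        inten = run.matrix[:, j].copy()
    return Trace(int(mz), run.rts.copy(), inten)


def extract_tic(run: RawRun) -> Trace:
    """Total-ion chromatogram: per-scan sum over all channels."""
    return Trace(TIC_CHANNEL, run.rts.copy(), run.matrix.sum(axis=1))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("mzml", "andi_netcdf", "tsv_scans")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    if suffix in (".cdf", ".nc"):
        return "andi_netcdf"
    if suffix in (".tsv", ".txt"):
        return "tsv_scans"
    raise FormatError(f"cannot infer raw format from extension {suffix!r}")


def load_run(path, format: str | None = None) -> RawRun:
    """Load a raw GC/MS run from mzML, ANDI-MS netCDF, or the internal TSV
    scan table.  Profile m/z values are binned to nominal mass with intensity
    summation on collisions."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "tsv_scans":
        return _load_tsv(path)
    if fmt == "mzml":
        return _load_mzml(path)
    return _load_andi(path)


def write_run(run: RawRun, path, format: str | None = None) -> None:
    """Write a run in the named format (inferred from extension by default)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv_scans":
        _write_tsv(run, path)
    elif fmt == "mzml":
        _write_mzml(run, path)
    elif fmt == "andi_netcdf":
        _write_andi(run, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


# -- internal TSV scan table -------------------------------------------------

def _load_tsv(path: Path) -> RawRun:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"{path}: not a readable TSV scan table ({exc})") from exc
    if df.columns[0] != "rt_s":
        raise FormatError(f"{path}: first column must be 'rt_s', got {df.columns[0]!r}")
    try:
        mzs = np.array([int(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer m/z column header ({exc})") from exc
    order = np.argsort(mzs)
    rts = df["rt_s"].to_numpy(dtype=float)
    matrix = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
    return RawRun(path.stem, rts, mzs[order], matrix)


def _write_tsv(run: RawRun, path: Path) -> None:
    df = pd.DataFrame(run.matrix, columns=[str(int(m)) for m in run.mzs])
    df.insert(0, "rt_s", run.rts)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


# -- mzML --------------------------------------------------------------------

def _bin_profile(mz_arr: np.ndarray, inten_arr: np.ndarray) -> dict[int, float]:
    out: dict[int, float] = {}
    nominal = np.floor(np.asarray(mz_arr, dtype=float) + 0.5).astype(int)
    for m, i in zip(nominal.tolist(), np.asarray(inten_arr, dtype=float).tolist()):
        if i != 0:
            out[m] = out.get(m, 0.0) + i
    return out


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(b64_text: str, accessions: set[str], n: int) -> np.ndarray:
    raw = base64.b64decode(b64_text.encode("ascii"))
    if "MS:1000574" in accessions:        # zlib compression
        import zlib
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    arr = np.frombuffer(raw, dtype=dtype)
    if arr.size != n:
        raise FormatError(f"binary array length {arr.size} != declared {n}")
    return arr.astype(float)


def _parse_spectrum_element(elem) -> Scan:
    """Extract rt and binned spectrum from one <spectrum> element."""
    import xml.etree.ElementTree as ET  # noqa: F401  (elem comes from ET)

    n = int(elem.attrib.get("defaultArrayLength", 0))
    rt_s = None
    arrays: dict[str, np.ndarray] = {}
    for scan_el in elem.iter():
        if _localname(scan_el.tag) == "cvParam" and \
                scan_el.attrib.get("accession") == "MS:1000016":
            value = float(scan_el.attrib["value"])
            unit = scan_el.attrib.get("unitName", "second")
            rt_s = value * 60.0 if unit in ("minute", "min") else value
    for bda in elem.iter():
        if _localname(bda.tag) != "binaryDataArray":
            continue
        accessions = set()
        kind = None
        b64 = ""
        for child in bda.iter():
            name = _localname(child.tag)
            if name == "cvParam":
                acc = child.attrib.get("accession", "")
                accessions.add(acc)
                if acc == "MS:1000514":
                    kind = "mz"
                elif acc == "MS:1000515":
                    kind = "intensity"
            elif name == "binary":
                b64 = child.text or ""
        if kind:
            arrays[kind] = _decode_binary(b64, accessions, n)
    if rt_s is None:
        raise FormatError("spectrum without scan start time")
    if "mz" not in arrays or "intensity" not in arrays:
        raise FormatError("spectrum missing m/z or intensity array")
    return Scan(rt_s, _bin_profile(arrays["mz"], arrays["intensity"]))


def _load_mzml(path: Path) -> RawRun:
    import xml.etree.ElementTree as ET

    scans: list[Scan] = []
    try:
        for _event, elem in ET.iterparse(str(path), events=("end",)):
            if _localname(elem.tag) == "spectrum":
                scans.append(_parse_spectrum_element(elem))
                elem.clear()
    except DataError:
        raise
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    except Exception as exc:
        raise FormatError(f"{path}: failed to parse mzML ({exc})") from exc
    if len(scans) < 2:
        raise FormatError(f"{path}: fewer than 2 spectra found")
    _check_monotonic(scans, path)
    return RawRun.from_scans(path.stem, scans)


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}" defaultDataProcessingRef="dp">
"""


def _b64_floats(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % len(values), *values)
    return base64.b64encode(raw).decode("ascii")


def _write_mzml(run: RawRun, path: Path) -> None:
    """Minimal mzML writer: MS1 spectra, 64-bit float arrays, no compression."""
    parts = [_MZML_HEADER.format(run_id=run.run_id, count=run.n_scans)]
    for i in range(run.n_scans):
        row = run.matrix[i]
        nz = np.flatnonzero(row)
        mz_arr = run.mzs[nz].astype(float)
        inten_arr = row[nz]
        n = len(mz_arr)
        mz_b64 = _b64_floats(mz_arr)
        in_b64 = _b64_floats(inten_arr)
        parts.append(f"""      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{run.rts[i]:.8f}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(in_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{in_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
""")
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    path.write_text("".join(parts))


# -- ANDI-MS netCDF ----------------------------------------------------------

def _load_andi(path: Path) -> RawRun:
    from scipy.io import netcdf_file

    try:
        with netcdf_file(str(path), "r", mmap=False) as nc:
            rt = np.array(nc.variables["scan_acquisition_time"][:], dtype=float)
            scan_index = np.array(nc.variables["scan_index"][:], dtype=int)
            mass = np.array(nc.variables["mass_values"][:], dtype=float)
            inten = np.array(nc.variables["intensity_values"][:], dtype=float)
    except DataError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: failed to parse ANDI-MS netCDF ({exc})") from exc
    scans = []
    bounds = list(scan_index) + [len(mass)]
    for i in range(len(rt)):
        lo, hi = bounds[i], bounds[i + 1]
        scans.append(Scan(float(rt[i]), _bin_profile(mass[lo:hi], inten[lo:hi])))
    _check_monotonic(scans, path)
    return RawRun.from_scans(path.stem, scans)


def _write_andi(run: RawRun, path: Path) -> None:
    from scipy.io import netcdf_file

    masses, intens, index = [], [], []
    pos = 0
    for i in range(run.n_scans):
        row = run.matrix[i]
        nz = np.flatnonzero(row)
        index.append(pos)
        masses.extend(run.mzs[nz].astype(float).tolist())
        intens.extend(row[nz].tolist())
        pos += nz.size
    with netcdf_file(str(path), "w") as nc:
        nc.createDimension("scan_number", run.n_scans)
        nc.createDimension("point_number", max(pos, 1))
        v = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        v[:] = run.rts
        v = nc.createVariable("scan_index", "i", ("scan_number",))
        v[:] = np.array(index, dtype=np.int32)
        v = nc.createVariable("mass_values", "d", ("point_number",))
        v[:] = np.array(masses or [0.0])
        v = nc.createVariable("intensity_values", "d", ("point_number",))
        v[:] = np.array(intens or [0.0])


def _check_monotonic(scans: list[Scan], path: Path) -> None:
    for i in range(1, len(scans)):
        if scans[i].rt <= scans[i - 1].rt:
            raise DataError(
                f"{path}: scans out of time order at scan index {i} "
                f"(rt {scans[i].rt:g} s after {scans[i - 1].rt:g} s)")
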