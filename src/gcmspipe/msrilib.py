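"""Mass-spectral / retention-index (MSRI) reference libraries.

A library entry pairs an analyte name with its retention index, a
unit-resolution mass spectrum (relative intensities scaled so the base peak is
999, the GC/MS library convention), an ordered list of quantifier ions, and
free-form annotations (chemical class, structure id, comment).

Two on-disk formats are supported:

* the native tab-delimited format with columns
  ``name  ri  quantifier_mzs  spectrum  class  structure_id  comment``
  where ``quantifier_mzs`` is semicolon-separated and ``spectrum`` is a
  space-separated list of ``mz:intensity`` pairs;
* AMDIS ``*.MSL`` import (``NAME:`` / ``RI:`` / ``NUM PEAKS:`` records with
  ``(mz intensity)`` pairs).  MSL records carry no quantifier field, so
  imported entries default their quantifier to the base peak, overridable via
  a sidecar name → quantifiers table; records without an RI are imported with
  a missing-RI flag and excluded from matching by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import FormatError, LibraryValidationError

BASE_PEAK = 999.0


@dataclass
class LibraryEntry:
    name: str
    ri: float | None
    spectrum: dict[int, float]
    quantifier_mzs: list[int]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.spectrum:
            raise LibraryValidationError(f"entry {self.name!r}: empty spectrum")
        peak_max = max(self.spectrum.values())
        if peak_max <= 0:
            raise LibraryValidationError(f"entry {self.name!r}: all-zero spectrum")
        if abs(peak_max - BASE_PEAK) > 1e-6:
            scale = BASE_PEAK / peak_max
            self.spectrum = {m: v * scale for m, v in self.spectrum.items()}
        if not self.quantifier_mzs:
            raise LibraryValidationError(f"entry {self.name!r}: no quantifier ions")
        for q in self.quantifier_mzs:
            if q not in self.spectrum:
                raise LibraryValidationError(
                    f"entry {self.name!r}: quantifier m/z {q} not in spectrum")
            if self.spectrum[q] <= 0:
                raise LibraryValidationError(
                    f"entry {self.name!r}: quantifier m/z {q} has zero intensity")

    @property
    def base_peak_mz(self) -> int:
        return max(self.spectrum, key=lambda m: (self.spectrum[m], -m))


class MsriLibrary:
    """A list of uniquely named library entries."""

    def __init__(self, entries: Sequence[LibraryEntry], provenance: str = ""):
        names = [e.name for e in entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise LibraryValidationError(f"duplicate entry names: {sorted(dupes)}")
        self.entries = list(entries)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, name: str) -> LibraryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]


# ---------------------------------------------------------------------------
# native TSV format
# ---------------------------------------------------------------------------

_COLUMNS = ["name", "ri", "quantifier_mzs", "spectrum",
            "class", "structure_id", "comment"]


def _format_spectrum(spec: dict[int, float]) -> str:
    return " ".join(f"{m}:{spec[m]:.6g}" for m in sorted(spec))


def _parse_spectrum(text: str, name: str) -> dict[int, float]:
    spec: dict[int, float] = {}
    for token in str(text).split():
        try:
            mz_s, in_s = token.split(":")
            spec[int(mz_s)] = float(in_s)
        except ValueError as exc:
            raise FormatError(
                f"entry {name!r}: bad spectrum token {token!r}") from exc
    return spec


def write_library(lib: MsriLibrary, path) -> None:
    rows = [{
        "name": e.name,
        "ri": "" if e.ri is None else f"{e.ri:.6g}",
        "quantifier_mzs": ";".join(str(q) for q in e.quantifier_mzs),
        "spectrum": _format_spectrum(e.spectrum),
        "class": e.annotations.get("class", ""),
        "structure_id": e.annotations.get("structure_id", ""),
        "comment": e.annotations.get("comment", ""),
    } for e in lib]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def parse_library(path) -> MsriLibrary:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such library file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable library TSV ({exc})") from exc
    if list(df.columns) != _COLUMNS:
        raise FormatError(f"{path}: expected columns {_COLUMNS}")
    entries = []
    for rec in df.to_dict("records"):
        name = rec["name"]
        annotations = {k: rec[k] for k in ("class", "structure_id", "comment")
                       if rec.get(k)}
        entries.append(LibraryEntry(
            name=name,
            ri=float(rec["ri"]) if rec["ri"] else None,
            spectrum=_parse_spectrum(rec["spectrum"], name),
            quantifier_mzs=[int(q) for q in str(rec["quantifier_mzs"]).split(";") if q],
            annotations=annotations))
    return MsriLibrary(entries, provenance=str(path))


# ---------------------------------------------------------------------------
# AMDIS .MSL import
# ---------------------------------------------------------------------------

_PAIR_RE = re.compile(r"\(\s*([0-9.]+)[ ,]+([0-9.]+)\s*\)")


def convert_msl(path, quantifier_sidecar=None) -> MsriLibrary:
    """Import an AMDIS-format ``*.MSL`` library.

    ``quantifier_sidecar`` is an optional TSV with columns ``name`` and
    ``quantifier_mzs`` (semicolon-separated) overriding the default
    base-peak quantifier for named entries.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such MSL file: {path}")
    overrides: dict[str, list[int]] = {}
    if quantifier_sidecar is not None:
        sc = pd.read_csv(quantifier_sidecar, sep="\t", dtype=str)
        for row in sc.itertuples():
            overrides[row.name] = [int(q) for q in row.quantifier_mzs.split(";")]

    entries: list[LibraryEntry] = []
    name = None
    ri: float | None = None
    num_peaks: int | None = None
    pair_text: list[str] = []

    def flush():
        nonlocal name, ri, num_peaks, pair_text
        if name is None:
            return
        pairs = _PAIR_RE.findall(" ".join(pair_text))
        if num_peaks is None or len(pairs) != num_peaks:
            raise FormatError(
                f"MSL record {name!r}: NUM PEAKS {num_peaks} but "
                f"{len(pairs)} (m/z, intensity) pairs listed")
        spectrum: dict[int, float] = {}
        for mz_s, in_s in pairs:
            mz = int(round(float(mz_s)))
            spectrum[mz] = spectrum.get(mz, 0.0) + float(in_s)
        base = max(spectrum, key=lambda m: (spectrum[m], -m))
        entries.append(LibraryEntry(name=name, ri=ri, spectrum=spectrum,
                                    quantifier_mzs=overrides.get(name, [base])))
        name, ri, num_peaks, pair_text = None, None, None, []

    for line in path.read_text().splitlines():
        stripped = line.strip()
        upper = stripped.upper()
        if upper.startswith("NAME:"):
            flush()
            name = stripped[5:].strip()
        elif upper.startswith("RI:"):
            ri = float(stripped[3:].strip())
        elif upper.startswith("NUM PEAKS:"):
            num_peaks = int(stripped[10:].strip())
        elif stripped and name is not None and not upper.startswith(
                ("FORMULA:", "MW:", "CASNO:", "RT:", "COMMENT:", "SYNONYM:")):
            pair_text.append(stripped)
    flush()
    return MsriLibrary(entries, provenance=str(path))
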