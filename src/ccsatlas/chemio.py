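"""Compound tables and MSP spectral libraries.

Compound tables are CSV/TSV with header columns
``id,name,smiles,inchikey,formula,mass,superclass,class,subclass`` (only
``id`` and ``smiles`` are mandatory; monoisotopic mass is computed from the
structure when absent).  SDF files are accepted and converted on ingest.
Spectra travel as MSP, the plain-text NIST library format of
``Name`` / ``PrecursorMZ`` / ``Num Peaks`` blocks.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Descriptors import ExactMolWt

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundEntry",
    "Spectrum",
    "SpectrumList",
    "mol_from_structure",
    "read_compound_table",
    "read_msp",
    "write_msp",
]

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

COMPOUND_COLUMNS = [
    "id", "name", "smiles", "inchikey", "formula", "mass",
    "superclass", "class", "subclass",
]


@dataclass
class CompoundEntry:
    """A neutral chemical structure with identifiers and optional class labels."""

    id: str
    name: str
    structure: str
    neutral_mass: float
    inchikey: str | None = None
    formula: str | None = None
    superclass: str | None = None
    klass: str | None = None
    subclass: str | None = None

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"{self.id}: neutral mass must be positive")
        if self.inchikey and not _INCHIKEY_RE.match(self.inchikey):
            raise ValueError(f"{self.id}: malformed InChIKey {self.inchikey!r}")


def mol_from_structure(structure: str):
    """Parse a SMILES (or InChI) line notation; returns None on failure."""
    if not isinstance(structure, str) or not structure.strip():
        return None
    s = structure.strip()
    if s.startswith("InChI="):
        return Chem.MolFromInchi(s)
    return Chem.MolFromSmiles(s)


def read_compound_table(path: str | Path) -> pd.DataFrame:
    """Read a compound table (CSV/TSV/SDF) into a normalized DataFrame.

    Missing masses are filled from the structure's monoisotopic weight.
    Rows whose structure does not parse keep NaN mass and are flagged in
    the boolean ``parsed`` column rather than silently dropped.
    """
    path = Path(path)
    if path.suffix.lower() == ".sdf":
        df = _read_sdf(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, dtype={"id": str})
    for col in COMPOUND_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["id"] = df["id"].astype(str)
    parsed, masses = [], []
    for _, row in df.iterrows():
        mol = mol_from_structure(row["smiles"])
        parsed.append(mol is not None)
        if pd.isna(row["mass"]) and mol is not None:
            masses.append(ExactMolWt(mol))
        else:
            masses.append(row["mass"])
    df["mass"] = masses
    df["parsed"] = parsed
    return df[COMPOUND_COLUMNS + ["parsed"]]


def _read_sdf(path: Path) -> pd.DataFrame:
    rows = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        props = mol.GetPropsAsDict()
        rows.append(
            {
                "id": str(props.get("id", props.get("ID", f"SDF{i:05d}"))),
                "name": props.get("name", props.get("NAME", mol.GetProp("_Name") if mol.HasProp("_Name") else "")),
                "smiles": Chem.MolToSmiles(mol),
                "mass": ExactMolWt(mol),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spectra / MSP
# ---------------------------------------------------------------------------


@dataclass
class Spectrum:
    """A fragment spectrum: (m/z, intensity) peaks plus free-form metadata."""

    peaks: np.ndarray  # shape (n, 2)
    precursor_mz: float | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=float).reshape(-1, 2)
        if len(self.peaks) == 0:
            raise ValueError("a spectrum needs at least one peak")
        if (self.peaks[:, 1] < 0).any():
            raise ValueError("peak intensities must be non-negative")

    @property
    def name(self) -> str:
        return self.metadata.get("NAME", "")

    def canonicalize(self) -> "Spectrum":
        """Sorted-by-m/z copy with uppercase metadata keys."""
        order = np.lexsort((self.peaks[:, 1], self.peaks[:, 0]))
        meta = {k.upper(): str(v) for k, v in self.metadata.items()}
        return Spectrum(self.peaks[order], self.precursor_mz, meta)


class SpectrumList(list):
    """A list of spectra; ``skipped`` records malformed MSP blocks."""

    def __init__(self, spectra=(), skipped=None):
        super().__init__(spectra)
        self.skipped: list[str] = list(skipped or [])


def read_msp(source) -> SpectrumList:
    """Parse an MSP stream or path.

    Tolerates lowercase keys and tab- or space-separated peak lines.  A
    block whose peak count disagrees with its ``Num Peaks`` header is
    skipped with a warning and counted in the result's ``skipped`` list.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_msp(fh)
    out = SpectrumList()
    block: list[str] = []
    for line in list(source) + [""]:
        if line.strip():
            block.append(line.rstrip("\n"))
        elif block:
            _parse_block(block, out)
            block = []
    return out


def _parse_block(lines: list[str], out: SpectrumList) -> None:
    meta: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    declared = None
    for line in lines:
        if ":" in line and not peaks:
            key, _, value = line.partition(":")
            key = key.strip().upper()
            value = value.strip()
            if key == "NUM PEAKS":
                declared = int(value)
            else:
                meta[key] = value
        else:
            parts = line.replace("\t", " ").split()
            if len(parts) >= 2:
                peaks.append((float(parts[0]), float(parts[1])))
    name = meta.get("NAME", "<unnamed>")
    if declared is None or declared != len(peaks) or not peaks:
        warnings.warn(f"MSP record {name!r}: declared {declared} peaks, found {len(peaks)}; skipped")
        out.skipped.append(name)
        return
    precursor = meta.get("PRECURSORMZ") or meta.get("PRECURSOR_MZ")
    out.append(
        Spectrum(
            np.array(peaks),
            precursor_mz=float(precursor) if precursor else None,
            metadata=meta,
        ).canonicalize()
    )


def write_msp(spectra, destination) -> None:
    """Write spectra as canonicalized MSP (uppercase keys, sorted peaks)."""
    if isinstance(destination, (str, Path)):
        with open(destination, "w", encoding="utf-8") as fh:
            write_msp(spectra, fh)
            return
    for spec in spectra:
        spec = spec.canonicalize()
        meta = dict(spec.metadata)
        destination.write(f"NAME: {meta.pop('NAME', '')}\n")
        if spec.precursor_mz is not None:
            meta.pop("PRECURSORMZ", None)
            destination.write(f"PRECURSORMZ: {spec.precursor_mz:.5f}\n")
        for key, value in meta.items():
            destination.write(f"{key}: {value}\n")
        destination.write(f"NUM PEAKS: {len(spec.peaks)}\n")
        for mz, inten in spec.peaks:
            destination.write(f"{mz:.5f}\t{inten:.1f}\n")
        destination.write("\n")


def msp_dumps(spectra) -> str:
    buf = io.StringIO()
    write_msp(spectra, buf)
    return buf.getvalue()
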