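"""MS/MS spectrum containers and MGF input/output.

A paired genome-metabolome dataset carries, for each sequenced sample, one or
more LC-MS/MS runs exported as Mascot Generic Format (MGF) files.  This module
reads and writes that format (through :mod:`pyteomics.mgf`), normalises the
peak lists, and merges the runs of one sample into a single metabolome, which
is the unit the fingerprinting step consumes.

MGF dialect
-----------
``PEPMASS``, ``CHARGE``, ``TITLE`` and ``SCANS`` are recognised
case-insensitively (GNPS exports vary).  The spectrum identifier is taken from
``TITLE`` if present, else ``SCANS``, else ``"<filename>:<block-index>"``.
Zero-intensity peaks are dropped at read time (they cannot contribute to a
cosine product); duplicate m/z values within one spectrum keep the
higher-intensity peak; peaks are stored sorted ascending by m/z.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _pyteomics_mgf

__all__ = [
    "Peak",
    "Spectrum",
    "Metabolome",
    "MgfError",
    "read_mgf",
    "write_mgf",
    "read_manifest",
    "merge_metabolomes",
]

MANIFEST_COLUMNS = ("sample_id", "mgf_path", "role")
ROLE_TRAINING = "training-metabolome"
ROLE_QUERY = "query"


class MgfError(ValueError):
    """Raised for malformed MGF content, naming the offending block."""


@dataclass(frozen=True)
class Peak:
    """One fragment peak: m/z in Da (> 0), intensity in arbitrary units (>= 0)."""

    mz: float
    intensity: float


class Spectrum:
    """One MS/MS fragmentation spectrum.

    Parameters
    ----------
    spectrum_id : str
        Identifier, unique within a dataset.
    precursor_mz : float
        Precursor ion m/z in Da, must be positive.
    peaks : iterable of (mz, intensity)
        Fragment peaks.  Cleaned on construction: zero-intensity peaks are
        dropped, duplicate m/z keep the higher intensity, and the list is
        sorted strictly ascending by m/z.
    charge : int
        Precursor charge; 0 means unknown.
    source_file : str
        Origin file, for provenance.
    """

    __slots__ = ("spectrum_id", "precursor_mz", "charge", "source_file", "mz", "intensity")

    def __init__(
        self,
        spectrum_id: str,
        precursor_mz: float,
        peaks: Iterable[tuple[float, float]] | np.ndarray,
        charge: int = 0,
        source_file: str = "",
    ) -> None:
        if not precursor_mz > 0:
            raise ValueError(f"precursor_mz must be positive, got {precursor_mz!r}")
        arr = np.asarray(list(peaks) if not isinstance(peaks, np.ndarray) else peaks, dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 2)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("peaks must be an iterable of (mz, intensity) pairs")
        if np.any(arr[:, 0] <= 0):
            raise ValueError(f"spectrum {spectrum_id!r}: all peak m/z must be positive")
        if np.any(arr[:, 1] < 0):
            raise ValueError(f"spectrum {spectrum_id!r}: peak intensities must be non-negative")
        arr = arr[arr[:, 1] > 0]
        if arr.shape[0]:
            # stable sort by (mz, intensity): for duplicate m/z the last row has
            # the highest intensity, which np.unique's "last index" keeps below
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            arr = arr[order]
            _, first = np.unique(arr[:, 0], return_index=True)
            counts = np.diff(np.append(first, arr.shape[0]))
            last = first + counts - 1
            arr = arr[last]
        self.spectrum_id = str(spectrum_id)
        self.precursor_mz = float(precursor_mz)
        self.charge = int(charge)
        self.source_file = str(source_file)
        self.mz = np.ascontiguousarray(arr[:, 0])
        self.intensity = np.ascontiguousarray(arr[:, 1])

    @property
    def peaks(self) -> np.ndarray:
        """Peak array of shape (n_peaks, 2): columns m/z, intensity."""
        return np.column_stack([self.mz, self.intensity])

    @property
    def n_peaks(self) -> int:
        return int(self.mz.shape[0])

    def with_id(self, spectrum_id: str) -> "Spectrum":
        """Copy of this spectrum under a different identifier."""
        s = Spectrum.__new__(Spectrum)
        s.spectrum_id = str(spectrum_id)
        s.precursor_mz = self.precursor_mz
        s.charge = self.charge
        s.source_file = self.source_file
        s.mz = self.mz
        s.intensity = self.intensity
        return s

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Spectrum({self.spectrum_id!r}, precursor_mz={self.precursor_mz:.4f}, "
            f"n_peaks={self.n_peaks})"
        )


@dataclass
class Metabolome:
    """All MS/MS spectra observed for one genome/sample."""

    sample_id: str
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.spectrum_id for s in self.spectra]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"metabolome {self.sample_id!r}: duplicate spectrum ids {dupes}"
            )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


def read_mgf(path: str | os.PathLike) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    One spectrum per ``BEGIN IONS``/``END IONS`` block.  The first token of
    ``PEPMASS`` is the precursor m/z; a missing ``CHARGE`` becomes 0.  An empty
    file yields an empty list; a malformed block raises :class:`MgfError`
    naming the block index.
    """
    path = Path(path)
    out: list[Spectrum] = []
    reader = _pyteomics_mgf.MGF(str(path), convert_arrays=1, read_charges=True)
    try:
        index = 0
        it = iter(reader)
        while True:
            try:
                entry = next(it)
            except StopIteration:
                break
            except Exception as exc:
                raise MgfError(f"{path.name}: malformed MGF block {index}: {exc}") from exc
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None:
                raise MgfError(f"{path.name}: MGF block {index} has no PEPMASS")
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge_val = params.get("charge")
            charge = int(charge_val[0]) if charge_val else 0
            sid = params.get("title") or params.get("scans") or f"{path.name}:{index}"
            try:
                spectrum = Spectrum(
                    spectrum_id=str(sid),
                    precursor_mz=precursor,
                    peaks=np.column_stack(
                        [entry["m/z array"], entry["intensity array"]]
                    )
                    if len(entry["m/z array"])
                    else np.empty((0, 2)),
                    charge=charge,
                    source_file=path.name,
                )
            except ValueError as exc:
                raise MgfError(f"{path.name}: MGF block {index}: {exc}") from exc
            out.append(spectrum)
            index += 1
    finally:
        reader.close()
    return out


def write_mgf(spectra: Sequence[Spectrum], path: str | os.PathLike) -> None:
    """Write spectra to ``path`` in MGF.

    Round-trips through :func:`read_mgf` reproduce spectrum ids, precursor
    masses and peak lists to six decimal places.  A charge of 0 (unknown) is
    written without a ``CHARGE`` line and reads back as 0.
    """
    entries = []
    for s in spectra:
        params: dict = {"title": s.spectrum_id, "pepmass": round(s.precursor_mz, 6)}
        if s.charge != 0:
            params["charge"] = s.charge
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    with open(path, "w") as fh:
        _pyteomics_mgf.write(entries, fh, fragment_format="{:.6f} {:.6f}")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read the 3-column sample manifest (sample_id, mgf_path, role)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path}: missing column(s) {missing}")
    bad_roles = sorted(set(df["role"]) - {ROLE_TRAINING, ROLE_QUERY})
    if bad_roles:
        raise ValueError(f"manifest {path}: unknown role(s) {bad_roles}")
    return df[list(MANIFEST_COLUMNS)]


def merge_metabolomes(
    manifest: pd.DataFrame,
    base_dir: str | os.PathLike | None = None,
    role: str = ROLE_TRAINING,
) -> dict[str, Metabolome]:
    """Merge every sample's MGF files into one metabolome per sample.

    Multiple LC-MS/MS files for the same genome (e.g. fractions or culture
    conditions) are unioned into a single set of experimental MS/MS spectra.
    Spectrum ids that occur in more than one file of a sample are
    disambiguated by suffixing the file index (``scan_1`` -> ``scan_1.0`` and
    ``scan_1.1``).

    Parameters
    ----------
    manifest : DataFrame
        As returned by :func:`read_manifest`.
    base_dir : path, optional
        Directory that relative ``mgf_path`` entries are resolved against.
    role : str
        Which manifest rows to merge (default: training metabolomes).
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    rows = manifest[manifest["role"] == role]
    out: dict[str, Metabolome] = {}
    for sample_id, group in rows.groupby("sample_id", sort=True):
        per_file: list[list[Spectrum]] = []
        errors: list[str] = []
        for p in group["mgf_path"]:
            fp = Path(p)
            if not fp.is_absolute():
                fp = base / fp
            try:
                per_file.append(read_mgf(fp))
            except OSError as exc:
                errors.append(f"{fp}: {exc}")
        if not per_file:
            raise ValueError(
                f"sample {sample_id!r} has zero readable MGF files: {errors}"
            )
        if errors:
            raise ValueError(f"sample {sample_id!r}: unreadable MGF file(s): {errors}")
        counts: dict[str, int] = {}
        for spectra in per_file:
            for s in spectra:
                counts[s.spectrum_id] = counts.get(s.spectrum_id, 0) + 1
        merged: list[Spectrum] = []
        for file_idx, spectra in enumerate(per_file):
            for s in spectra:
                if counts[s.spectrum_id] > 1:
                    merged.append(s.with_id(f"{s.spectrum_id}.{file_idx}"))
                else:
                    merged.append(s)
        out[str(sample_id)] = Metabolome(sample_id=str(sample_id), spectra=merged)
    return out
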