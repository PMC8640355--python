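"""Spectrum containers and plain-text spectrum/dataset I/O.

Two interchange dialects are supported, both plain text:

* ``two_column_txt`` — one file per spectrum, whitespace-separated
  ``wavenumber intensity`` rows, plus a ``metadata.csv`` sidecar per dataset
  directory (columns ``spectrum_id,sample_id,group,replicate,filename``).
* ``csv`` — for single spectra, a two-column CSV with header
  ``wavenumber,intensity``; for datasets, a wide matrix whose first column is
  the shared wavenumber axis and whose remaining columns are one spectrum
  each (column name = spectrum_id), with a ``<stem>_metadata.csv`` sidecar.

Vendor binary formats (e.g. WITec project files) are deliberately not
supported: plain text is the interchange format of this pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("ramanembryo")

#: Admissible group labels. ``medium`` marks the cell-free background
#: spectrum of the culture medium itself.
GROUPS = ("blastula", "non_blastula", "medium", "unknown")


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class RawSpectrum:
    """One Raman acquisition on its native (possibly irregular) axis.

    Parameters
    ----------
    wavenumbers:
        Strictly increasing Raman shifts in cm^-1.
    intensities:
        Scattering intensities (arbitrary units), same length as the axis.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    spectrum_id: str = ""
    sample_id: str = ""
    group: str = "unknown"
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        w, y = self.wavenumbers, self.intensities
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size:
            raise ValueError(
                f"spectrum '{self.spectrum_id}': axis and intensities must be "
                f"1-D of equal length (got {w.shape} vs {y.shape})"
            )
        if w.size < 2:
            raise ValueError(f"spectrum '{self.spectrum_id}': need at least 2 points")
        bad = np.where(np.diff(w) <= 0)[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"spectrum '{self.spectrum_id}': wavenumbers not strictly "
                f"increasing at index {i} ({w[i]} -> {w[i + 1]})"
            )
        if not np.all(np.isfinite(w)):
            raise ValueError(f"spectrum '{self.spectrum_id}': non-finite wavenumber")
        nf = np.where(~np.isfinite(y))[0]
        if nf.size:
            raise ValueError(
                f"spectrum '{self.spectrum_id}': non-finite intensity at index {int(nf[0])}"
            )
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}; expected one of {GROUPS}")
        if self.replicate is not None and int(self.replicate) < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass
class GridSpectrum:
    """A spectrum resampled onto the canonical integer 1 cm^-1 grid.

    The grid is ``grid_start, grid_start+1, ..., grid_end`` inclusive; the
    full-range grid used by normalization is [200, 2000] (1801 points) and
    the biological fingerprint grid is [600, 1800] (1201 points).
    """

    grid_start: int
    grid_end: int
    intensities: np.ndarray
    spectrum_id: str = ""
    sample_id: str = ""
    group: str = "unknown"
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.grid_start = int(self.grid_start)
        self.grid_end = int(self.grid_end)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.grid_end <= self.grid_start:
            raise ValueError("grid_end must exceed grid_start")
        n = self.grid_end - self.grid_start + 1
        if self.intensities.shape != (n,):
            raise ValueError(
                f"spectrum '{self.spectrum_id}': expected {n} intensities for grid "
                f"[{self.grid_start}, {self.grid_end}], got {self.intensities.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"spectrum '{self.spectrum_id}': non-finite intensity")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}; expected one of {GROUPS}")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_end + 1, dtype=float)


Spectrum = RawSpectrum | GridSpectrum


@dataclass
class SpectraDataset:
    """A collection of sample spectra plus one medium background spectrum."""

    spectra: list[Spectrum] = field(default_factory=list)
    medium: Spectrum | None = None
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.spectra)

    def validate(self) -> None:
        seen: set[str] = set()
        sample_group: dict[str, str] = {}
        for s in self.spectra:
            if not s.spectrum_id:
                raise ValueError("every spectrum needs a spectrum_id")
            if s.spectrum_id in seen:
                raise ValueError(f"duplicate spectrum_id {s.spectrum_id!r}")
            seen.add(s.spectrum_id)
            if s.group not in ("blastula", "non_blastula"):
                raise ValueError(
                    f"spectrum {s.spectrum_id!r}: dataset spectra must be labelled "
                    f"blastula/non_blastula, got {s.group!r}"
                )
            if not s.sample_id:
                raise ValueError(f"spectrum {s.spectrum_id!r} has no sample_id")
            prev = sample_group.setdefault(s.sample_id, s.group)
            if prev != s.group:
                raise ValueError(
                    f"sample {s.sample_id!r} has inconsistent group labels ({prev} vs {s.group})"
                )

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.spectra:
            counts[s.group] = counts.get(s.group, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# single-spectrum I/O


def write_spectrum(spectrum: Spectrum, path: str | Path, dialect: str = "two_column_txt") -> None:
    path = Path(path)
    w = np.asarray(spectrum.wavenumbers, dtype=float)
    y = np.asarray(spectrum.intensities, dtype=float)
    if dialect == "two_column_txt":
        np.savetxt(path, np.column_stack([w, y]), fmt="%.9f")
    elif dialect == "csv":
        pd.DataFrame({"wavenumber": w, "intensity": y}).to_csv(path, index=False, float_format="%.9f")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_spectrum(
    path: str | Path,
    dialect: str = "two_column_txt",
    *,
    spectrum_id: str = "",
    sample_id: str = "",
    group: str = "unknown",
    replicate: int | None = None,
) -> RawSpectrum:
    """Parse one spectrum file; invariant violations raise ``ValueError``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "two_column_txt":
        data = np.loadtxt(path, ndmin=2)
    elif dialect == "csv":
        frame = pd.read_csv(path)
        data = frame[["wavenumber", "intensity"]].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns, got {data.shape[1]}")
    return RawSpectrum(
        wavenumbers=data[:, 0],
        intensities=data[:, 1],
        spectrum_id=spectrum_id or path.stem,
        sample_id=sample_id,
        group=group,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# dataset I/O

_META_COLUMNS = ["spectrum_id", "sample_id", "group", "replicate", "filename"]


def write_dataset(dataset: SpectraDataset, out_dir: str | Path) -> Path:
    """Write a dataset as one two-column file per spectrum plus metadata.csv."""
    dataset.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    all_spectra = list(dataset.spectra)
    if dataset.medium is not None:
        all_spectra.append(dataset.medium)
    for s in all_spectra:
        fname = f"{s.spectrum_id or 'medium'}.txt"
        write_spectrum(s, out_dir / fname)
        rows.append(
            {
                "spectrum_id": s.spectrum_id or "medium",
                "sample_id": s.sample_id,
                "group": s.group,
                "replicate": "" if s.replicate is None else int(s.replicate),
                "filename": fname,
            }
        )
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(out_dir / "metadata.csv", index=False)
    if dataset.provenance:
        (out_dir / "provenance.json").write_text(dataset.provenance)
    log.info("write_dataset: %d spectra -> %s", len(all_spectra), out_dir)
    return out_dir


def read_dataset(path: str | Path) -> SpectraDataset:
    """Read a dataset directory (or wide-CSV matrix) back into memory.

    A missing medium spectrum is tolerated with a warning — background
    subtraction will fail later if attempted. Duplicate spectrum ids and an
    empty directory are errors. Spectra are returned in file order; the
    reader never reorders or deduplicates.
    """
    path = Path(path)
    if path.is_dir():
        meta_path = path / "metadata.csv"
        if not meta_path.exists():
            raise FileNotFoundError(f"no spectra found: {meta_path} missing")
        meta = pd.read_csv(meta_path, dtype={"spectrum_id": str, "sample_id": str})
        if meta.empty:
            raise ValueError(f"no spectra found in {path}")
        spectra: list[Spectrum] = []
        medium = None
        seen: set[str] = set()
        for row in meta.itertuples(index=False):
            sid = str(row.spectrum_id)
            if sid in seen:
                raise ValueError(f"duplicate spectrum_id {sid!r} in {meta_path}")
            seen.add(sid)
            rep = None if pd.isna(row.replicate) or row.replicate == "" else int(row.replicate)
            spec = read_spectrum(
                path / str(row.filename),
                spectrum_id=sid,
                sample_id="" if pd.isna(row.sample_id) else str(row.sample_id),
                group=str(row.group),
                replicate=rep,
            )
            if spec.group == "medium":
                medium = spec
            else:
                spectra.append(spec)
        prov_path = path / "provenance.json"
        provenance = prov_path.read_text() if prov_path.exists() else ""
    elif path.suffix == ".csv":
        spectra, medium, provenance = _read_wide_csv(path)
    else:
        raise FileNotFoundError(f"no spectra found at {path}")
    if not spectra:
        raise ValueError(f"no spectra found in {path}")
    if medium is None:
        log.warning("dataset at %s has no medium background spectrum", path)
    ds = SpectraDataset(spectra=spectra, medium=medium, provenance=provenance)
    ds.validate()
    log.info("read_dataset: %d spectra from %s", len(spectra), path)
    return ds


def write_dataset_wide(dataset: SpectraDataset, csv_path: str | Path) -> Path:
    """Write the wide-matrix dialect; requires a shared wavenumber axis."""
    dataset.validate()
    csv_path = Path(csv_path)
    all_spectra = list(dataset.spectra)
    if dataset.medium is not None:
        all_spectra.append(dataset.medium)
    axis = np.asarray(all_spectra[0].wavenumbers, dtype=float)
    cols = {"wavenumber": axis}
    rows = []
    for s in all_spectra:
        if not np.allclose(np.asarray(s.wavenumbers, float), axis, atol=1e-9):
            raise ValueError(
                "wide CSV dialect requires a shared wavenumber axis; "
                f"spectrum {s.spectrum_id!r} differs — use the directory dialect"
            )
        sid = s.spectrum_id or "medium"
        cols[sid] = np.asarray(s.intensities, dtype=float)
        rows.append(
            {
                "spectrum_id": sid,
                "sample_id": s.sample_id,
                "group": s.group,
                "replicate": "" if s.replicate is None else int(s.replicate),
                "filename": "",
            }
        )
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.9f")
    side = csv_path.with_name(csv_path.stem + "_metadata.csv")
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(side, index=False)
    return csv_path


def _read_wide_csv(csv_path: Path):
    frame = pd.read_csv(csv_path)
    side = csv_path.with_name(csv_path.stem + "_metadata.csv")
    if not side.exists():
        raise FileNotFoundError(f"wide CSV dataset needs metadata sidecar {side}")
    meta = pd.read_csv(side, dtype={"spectrum_id": str, "sample_id": str}).set_index("spectrum_id")
    axis = frame["wavenumber"].to_numpy(dtype=float)
    spectra: list[Spectrum] = []
    medium = None
    for sid in frame.columns[1:]:
        if sid in meta.index:
            row = meta.loc[sid]
            rep = None if pd.isna(row["replicate"]) or row["replicate"] == "" else int(row["replicate"])
            group = str(row["group"])
            sample_id = "" if pd.isna(row["sample_id"]) else str(row["sample_id"])
        else:
            rep, group, sample_id = None, "unknown", ""
        spec = RawSpectrum(
            wavenumbers=axis,
            intensities=frame[sid].to_numpy(dtype=float),
            spectrum_id=str(sid),
            sample_id=sample_id,
            group=group,
            replicate=rep,
        )
        if group == "medium":
            medium = spec
        else:
            spectra.append(spec)
    return spectra, medium, ""
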