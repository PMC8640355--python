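"""Raw spectra -> normalized fingerprint feature vectors.

Fixed stage order (each stage feeds only the next):

1. ``remove_baseline`` — asymmetric least squares (Whittaker smoother with
   asymmetry weights) fluorescence removal.
2. ``resample_to_grid`` — cubic B-spline (not-a-knot) interpolation onto the
   integer 1 cm^-1 grid [200, 2000].
3. ``vector_normalize`` — divide by the Euclidean norm over the full grid.
4. ``subtract_background`` — pointwise subtraction of the identically
   processed medium spectrum (negative values retained).
5. ``extract_fingerprint`` — restriction to the biological fingerprint
   region [600, 1800] (1201 points).

``preprocess_dataset`` applies the chain to every spectrum and stacks the
result into a :class:`FeatureMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.linalg import solveh_banded

from .spectra_io import GridSpectrum, RawSpectrum, SpectraDataset, Spectrum, config_hash

log = logging.getLogger("ramanembryo")

__all__ = [
    "PreprocessParams",
    "FeatureMatrix",
    "remove_baseline",
    "resample_to_grid",
    "vector_normalize",
    "subtract_background",
    "extract_fingerprint",
    "preprocess_dataset",
]


@dataclass
class PreprocessParams:
    """Knobs of the preprocessing chain (all exposed in the YAML config).

    ``lam`` (smoothness) and ``p`` (asymmetry) are the two ALS parameters;
    ``normalize_before_subtraction`` switches the order of stages 3 and 4.
    """

    lam: float = 1e5
    p: float = 0.01
    max_iter: int = 10
    grid_start: int = 200
    grid_end: int = 2000
    fp_start: int = 600
    fp_end: int = 1800
    normalize_before_subtraction: bool = True
    subtract_medium: bool = True

    def to_dict(self) -> dict:
        return self.__dict__.copy()


# cache of the banded upper form of D2'D2 (second-difference penalty), per n
_PENALTY_CACHE: dict[int, np.ndarray] = {}


def _penalty_banded(n: int) -> np.ndarray:
    """Upper banded form (3, n) of D'D for the second-difference matrix D."""
    ab = _PENALTY_CACHE.get(n)
    if ab is None:
        ab = np.zeros((3, n))
        ab[0, 2:] = 1.0
        ab[1, 1:] = -4.0
        ab[1, 1] = ab[1, -1] = -2.0
        ab[2, :] = 6.0
        ab[2, 0] = ab[2, -1] = 1.0
        ab[2, 1] = ab[2, -2] = 5.0
        _PENALTY_CACHE[n] = ab
    return ab


def remove_baseline(
    spectrum: RawSpectrum, lam: float = 1e5, p: float = 0.01, max_iter: int = 10
) -> RawSpectrum:
    """Subtract a smooth fluorescence baseline estimated by asymmetric least squares.

    Minimises ``sum_i w_i (y_i - z_i)^2 + lam * sum_i (d2 z)_i^2`` with the
    classic asymmetry reweighting ``w_i = p`` where ``y_i > z_i`` (points
    above the baseline are presumed Raman signal) and ``1 - p`` below.
    Larger ``lam`` yields a stiffer baseline.
    """
    if lam <= 0:
        raise ValueError("smoothness lam must be > 0")
    if not 0.0 < p < 1.0:
        raise ValueError("asymmetry p must lie in (0, 1)")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    y = spectrum.intensities
    n = y.size
    penalty = lam * _penalty_banded(n)
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        ab = penalty.copy()
        ab[2] += w
        z = solveh_banded(ab, w * y, lower=False)
        w = np.where(y > z, p, 1.0 - p)
    return replace(spectrum, wavenumbers=spectrum.wavenumbers.copy(), intensities=y - z)


def resample_to_grid(
    spectrum: RawSpectrum, grid_start: int = 200, grid_end: int = 2000
) -> GridSpectrum:
    """Interpolate onto the integer wavenumber grid with a not-a-knot cubic spline.

    The interpolant passes through every observed point exactly; evaluation
    outside the observed axis is refused (no extrapolation).
    """
    w, y = spectrum.wavenumbers, spectrum.intensities
    eps = 1e-9
    if w[0] > grid_start + eps or w[-1] < grid_end - eps:
        raise ValueError(
            f"spectrum '{spectrum.spectrum_id}': axis [{w[0]:.3f}, {w[-1]:.3f}] does not "
            f"cover the grid [{grid_start}, {grid_end}]; refusing to extrapolate"
        )
    spline = CubicSpline(w, y, bc_type="not-a-knot")
    grid = np.arange(grid_start, grid_end + 1, dtype=float)
    return GridSpectrum(
        grid_start=grid_start,
        grid_end=grid_end,
        intensities=spline(grid),
        spectrum_id=spectrum.spectrum_id,
        sample_id=spectrum.sample_id,
        group=spectrum.group,
        replicate=spectrum.replicate,
    )


def vector_normalize(spectrum: GridSpectrum) -> GridSpectrum:
    """Scale so the Euclidean norm of the intensities over the grid equals 1."""
    norm = float(np.linalg.norm(spectrum.intensities))
    if not np.isfinite(norm) or norm <= 0.0:
        raise ValueError(
            f"spectrum '{spectrum.spectrum_id}': zero-norm spectrum cannot be vector-normalized"
        )
    return replace(spectrum, intensities=spectrum.intensities / norm)


def subtract_background(sample: GridSpectrum, medium: GridSpectrum) -> GridSpectrum:
    """Pointwise ``sample - medium``; negative differences are retained."""
    if (sample.grid_start, sample.grid_end) != (medium.grid_start, medium.grid_end):
        raise ValueError(
            f"grid mismatch: sample [{sample.grid_start}, {sample.grid_end}] vs "
            f"medium [{medium.grid_start}, {medium.grid_end}]"
        )
    return replace(sample, intensities=sample.intensities - medium.intensities)


def extract_fingerprint(
    spectrum: GridSpectrum, fp_start: int = 600, fp_end: int = 1800
) -> GridSpectrum:
    """Restrict to the biological fingerprint grid [600, 1800] inclusive."""
    if spectrum.grid_start > fp_start or spectrum.grid_end < fp_end:
        raise ValueError(
            f"spectrum '{spectrum.spectrum_id}': grid [{spectrum.grid_start}, "
            f"{spectrum.grid_end}] does not cover the fingerprint range [{fp_start}, {fp_end}]"
        )
    lo = fp_start - spectrum.grid_start
    hi = fp_end - spectrum.grid_start + 1
    return replace(
        spectrum,
        grid_start=fp_start,
        grid_end=fp_end,
        intensities=spectrum.intensities[lo:hi].copy(),
    )


@dataclass
class FeatureMatrix:
    """Preprocessed spectra stacked row-wise over the fingerprint grid.

    Row order equals dataset order. ``medium_fingerprint`` carries the
    identically processed (but unsubtracted) medium spectrum on the same
    grid, so exploratory analyses can reconstruct absolute band positions.
    """

    X: np.ndarray
    wavenumbers: np.ndarray
    spectrum_ids: np.ndarray
    sample_ids: np.ndarray
    groups: np.ndarray
    replicates: np.ndarray
    medium_fingerprint: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        for name in ("spectrum_ids", "sample_ids", "groups", "replicates"):
            setattr(self, name, np.asarray(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        n, p = self.X.shape
        if self.wavenumbers.shape != (p,):
            raise ValueError("wavenumber header length must match feature columns")
        for name in ("spectrum_ids", "sample_ids", "groups", "replicates"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per row")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]

    def rows_for_samples(self, sample_ids) -> np.ndarray:
        wanted = set(sample_ids)
        return np.array([sid in wanted for sid in self.sample_ids])

    def to_csv(self, path) -> None:
        meta = pd.DataFrame(
            {
                "spectrum_id": self.spectrum_ids,
                "sample_id": self.sample_ids,
                "group": self.groups,
                "replicate": self.replicates,
            }
        )
        data = pd.DataFrame(self.X, columns=[f"{w:g}" for w in self.wavenumbers])
        pd.concat([meta, data], axis=1).to_csv(path, index=False)
        if self.medium_fingerprint is not None:
            side = pd.DataFrame(
                {"wavenumber": self.wavenumbers, "intensity": self.medium_fingerprint}
            )
            import pathlib

            p = pathlib.Path(path)
            side.to_csv(p.with_name(p.stem + "_medium.csv"), index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        frame = pd.read_csv(path, dtype={"spectrum_id": str, "sample_id": str})
        meta_cols = ["spectrum_id", "sample_id", "group", "replicate"]
        feat_cols = [c for c in frame.columns if c not in meta_cols]
        import pathlib

        p = pathlib.Path(path)
        med_path = p.with_name(p.stem + "_medium.csv")
        medium = None
        if med_path.exists():
            medium = pd.read_csv(med_path)["intensity"].to_numpy(dtype=float)
        return cls(
            X=frame[feat_cols].to_numpy(dtype=float),
            wavenumbers=np.array([float(c) for c in feat_cols]),
            spectrum_ids=frame["spectrum_id"].to_numpy(),
            sample_ids=frame["sample_id"].to_numpy(),
            groups=frame["group"].to_numpy(),
            replicates=frame["replicate"].to_numpy(),
            medium_fingerprint=medium,
        )


def _process_one(spectrum: RawSpectrum, params: PreprocessParams) -> GridSpectrum:
    corrected = remove_baseline(spectrum, params.lam, params.p, params.max_iter)
    gridded = resample_to_grid(corrected, params.grid_start, params.grid_end)
    if params.normalize_before_subtraction:
        gridded = vector_normalize(gridded)
    return gridded


def preprocess_dataset(
    dataset: SpectraDataset, params: PreprocessParams | None = None
) -> FeatureMatrix:
    """Run the full chain over a dataset and stack fingerprint vectors.

    The medium spectrum is passed through the same baseline removal,
    regridding and normalization before being subtracted from every sample
    spectrum. Raises if subtraction is requested but the dataset has no
    medium spectrum; per-spectrum failures are re-raised annotated with the
    offending spectrum_id.
    """
    params = params or PreprocessParams()
    dataset.validate()
    if params.subtract_medium and dataset.medium is None:
        raise ValueError("dataset has no medium background spectrum; cannot subtract background")

    medium_grid = None
    medium_fp = None
    if dataset.medium is not None:
        medium_grid = _process_one(dataset.medium, params)
        medium_fp = extract_fingerprint(medium_grid, params.fp_start, params.fp_end).intensities

    rows, sids, samps, grps, reps = [], [], [], [], []
    for spec in dataset.spectra:
        try:
            g = _process_one(spec, params)
            if params.subtract_medium:
                g = subtract_background(g, medium_grid)
            if not params.normalize_before_subtraction:
                g = vector_normalize(g)
            fp = extract_fingerprint(g, params.fp_start, params.fp_end)
        except Exception as exc:
            raise type(exc)(f"while preprocessing spectrum {spec.spectrum_id!r}: {exc}") from exc
        rows.append(fp.intensities)
        sids.append(spec.spectrum_id)
        samps.append(spec.sample_id)
        grps.append(spec.group)
        reps.append(0 if spec.replicate is None else int(spec.replicate))

    fm = FeatureMatrix(
        X=np.vstack(rows),
        wavenumbers=np.arange(params.fp_start, params.fp_end + 1, dtype=float),
        spectrum_ids=np.array(sids),
        sample_ids=np.array(samps),
        groups=np.array(grps),
        replicates=np.array(reps, dtype=int),
        medium_fingerprint=medium_fp,
    )
    log.info(
        "preprocess_dataset: %d spectra -> %d x %d features (config %s)",
        len(dataset.spectra),
        fm.X.shape[0],
        fm.X.shape[1],
        config_hash(params.to_dict()),
    )
    return fm
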