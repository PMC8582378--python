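"""m/z binning and dynamic-range reduction.

Different acquisitions of the same mass range never share an identical m/z
axis: point counts and the exact global extremes drift slightly between TMAs.
Learning across datasets therefore needs a common feature grid. The approach
here is coarse uniform binning: fix a bin width (3 Da by default, matching the
spacing of singly charged tryptic peptides well enough), span the global m/z
range observed over *all* datasets with B equally spaced bin centers, assign
every original m/z point to its nearest center, and sum intensities within
each bin. A square-root transform then compresses the dynamic range, which is
dominated by the much higher mean intensities at low m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .msi_io import RawSpectrum, TissueGroup

DEFAULT_BIN_WIDTH = 3.0


@dataclass(frozen=True)
class BinSpec:
    """The shared m/z bin grid harmonizing all datasets of a cohort.

    ``n_bins`` equals ``round((global_max - global_min) / width)`` and the
    centers are linearly spaced over ``[global_min, global_max]`` inclusive,
    so nearest-center assignment is equivalent to midpoint bin boundaries.
    """

    width: float
    global_min: float
    global_max: float
    n_bins: int

    @property
    def centers(self) -> np.ndarray:
        if self.n_bins == 1:
            return np.array([(self.global_min + self.global_max) / 2.0])
        return np.linspace(self.global_min, self.global_max, self.n_bins)

    @property
    def step(self) -> float:
        if self.n_bins == 1:
            return self.global_max - self.global_min
        return (self.global_max - self.global_min) / (self.n_bins - 1)


@dataclass
class FeatureVector:
    """One binned spectrum; ``transformed`` marks the sqrt stage as applied."""

    values: np.ndarray
    transformed: bool = False


@dataclass
class FeatureMatrix:
    """Per-spectrum feature rows plus the bookkeeping needed for safe CV."""

    X: np.ndarray                 # (n_spectra, n_bins)
    labels: np.ndarray            # (n_spectra,) int {0,1}
    group_ids: np.ndarray         # (n_spectra,) str
    patient_ids: np.ndarray       # (n_spectra,) str
    tma_ids: np.ndarray           # (n_spectra,) str
    bin_spec: BinSpec | None = None
    transformed: bool = False

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        for name in ("labels", "group_ids", "patient_ids", "tma_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has length {len(getattr(self, name))}, expected {n}")

    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def rows_for_groups(self, group_ids: Iterable[str]) -> np.ndarray:
        """Boolean row mask selecting the spectra of the given groups."""
        wanted = set(map(str, group_ids))
        return np.array([g in wanted for g in self.group_ids], dtype=bool)

    def save(self, path: str | Path) -> None:
        """Persist as ``<path>.npz`` plus a ``<path>.meta.csv`` sidecar."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            X=self.X,
            width=np.array([self.bin_spec.width if self.bin_spec else np.nan]),
            global_min=np.array([self.bin_spec.global_min if self.bin_spec else np.nan]),
            global_max=np.array([self.bin_spec.global_max if self.bin_spec else np.nan]),
            transformed=np.array([self.transformed]),
        )
        pd.DataFrame(
            dict(label=self.labels, group_id=self.group_ids,
                 patient_id=self.patient_ids, tma_id=self.tma_ids)
        ).to_csv(path.with_suffix(".meta.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            X = z["X"]
            width = float(z["width"][0])
            gmin, gmax = float(z["global_min"][0]), float(z["global_max"][0])
            transformed = bool(z["transformed"][0])
        meta = pd.read_csv(path.with_suffix(".meta.csv"),
                           dtype={"group_id": str, "patient_id": str, "tma_id": str})
        spec = None
        if np.isfinite(width):
            spec = BinSpec(width=width, global_min=gmin, global_max=gmax,
                           n_bins=X.shape[1])
        return cls(X=X, labels=meta["label"].to_numpy(),
                   group_ids=meta["group_id"].to_numpy(),
                   patient_ids=meta["patient_id"].to_numpy(),
                   tma_ids=meta["tma_id"].to_numpy(),
                   bin_spec=spec, transformed=transformed)


def compute_bin_spec(
    dataset_extremes: Sequence[tuple[float, float]],
    width: float = DEFAULT_BIN_WIDTH,
) -> BinSpec:
    """Build the shared bin grid from per-dataset (min m/z, max m/z) pairs.

    The bin count is the nearest integer of (global range / width), never
    below 1; with the extremes and 3 Da width typical of a tryptic-peptide
    acquisition over 800-4500 Da this yields a grid of ~1200 bins.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if not dataset_extremes:
        raise ValueError("need extremes from at least one dataset")
    global_min = min(lo for lo, _ in dataset_extremes)
    global_max = max(hi for _, hi in dataset_extremes)
    if global_max <= global_min:
        raise ValueError(
            f"degenerate m/z range [{global_min}, {global_max}]"
        )
    n_bins = max(1, int(round((global_max - global_min) / width)))
    return BinSpec(width=float(width), global_min=float(global_min),
                   global_max=float(global_max), n_bins=n_bins)


def dataset_extremes(spectra: Iterable[RawSpectrum]) -> dict[str, tuple[float, float]]:
    """Per-dataset (min, max) m/z over all points of all spectra."""
    out: dict[str, tuple[float, float]] = {}
    for s in spectra:
        lo, hi = float(s.mz[0]), float(s.mz[-1])
        cur = out.get(s.tma_id)
        if cur is None:
            out[s.tma_id] = (lo, hi)
        else:
            out[s.tma_id] = (min(cur[0], lo), max(cur[1], hi))
    return out


def _bin_indices(mz: np.ndarray, spec: BinSpec) -> np.ndarray:
    if spec.n_bins == 1:
        return np.zeros(len(mz), dtype=np.intp)
    t = (mz - spec.global_min) / spec.step
    # nearest center; exact halfway ties go to the lower-index bin
    idx = np.ceil(t - 0.5).astype(np.intp)
    return np.clip(idx, 0, spec.n_bins - 1)


def bin_spectrum(s: RawSpectrum, spec: BinSpec) -> FeatureVector:
    """Sum a spectrum's intensities into the nearest bin center of ``spec``.

    Points beyond the global range (possible when one dataset's axis juts out
    past the recorded extremes by less than a bin) clamp to the end bins, so
    total intensity is always conserved.
    """
    idx = _bin_indices(s.mz, spec)
    values = np.bincount(idx, weights=s.intensity, minlength=spec.n_bins)
    return FeatureVector(values=values, transformed=False)


def sqrt_transform(v: FeatureVector) -> FeatureVector:
    """Elementwise square root, compressing the low-m/z-dominated range."""
    if np.any(v.values < 0):
        raise ValueError("negative bin value; upstream invariant violated")
    return FeatureVector(values=np.sqrt(v.values), transformed=True)


def build_feature_matrix(
    groups: Sequence[TissueGroup],
    spec: BinSpec,
    apply_sqrt: bool = True,
) -> FeatureMatrix:
    """Bin every spectrum of every group into one aligned feature matrix.

    Rows appear in group order then each group's spectrum order; each row
    carries its group's class label and the patient/TMA bookkeeping needed by
    the cross-validation designs.
    """
    if not groups:
        raise ValueError("no tissue groups supplied")
    rows, labels, gids, pids, tids = [], [], [], [], []
    for g in groups:
        for s in g.spectra:
            fv = bin_spectrum(s, spec)
            if apply_sqrt:
                fv = sqrt_transform(fv)
            rows.append(fv.values)
            labels.append(g.label)
            gids.append(g.group_id)
            pids.append(g.patient_id)
            tids.append(s.tma_id)
    return FeatureMatrix(
        X=np.asarray(rows, dtype=np.float64),
        labels=np.asarray(labels, dtype=np.int64),
        group_ids=np.asarray(gids, dtype=object),
        patient_ids=np.asarray(pids, dtype=object),
        tma_ids=np.asarray(tids, dtype=object),
        bin_spec=spec,
        transformed=apply_sqrt,
    )
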