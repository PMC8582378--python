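"""Seeded synthetic MALDI-MSI tissue-microarray cohorts.

The generator emulates the statistical shape of a real tryptic-peptide imaging
cohort without modelling the chemistry: each spectrum is a sum of shared
Gaussian peaks whose base amplitudes decay with m/z (mean intensity is much
higher at low m/z), with per-patient and per-pixel log-normal variation, a
small non-negative additive baseline, and per-TMA jitter of the m/z axis
extremes so that datasets must be harmonized by binning. A configurable subset
of peaks carries a class effect: positive-class tissue scales them by a fold
change.

Two cohort layouts are supported. The *paired* design mirrors a tumour/normal
microarray study: most patients contribute one group per class (with separate
core counts per class) and some patients only one class. The *single* design
mirrors a per-patient binary outcome (e.g. nodal metastasis) with class
imbalance: one group per patient.

Everything is driven by one seed; the same configuration always reproduces the
cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .msi_io import RawSpectrum, read_annotations, read_imzml

_TMA_GRID_WIDTH = 256   # pixels per coordinate row when laying out spectra


@dataclass(frozen=True)
class SimConfig:
    """Cohort layout, spectrum model, and noise parameters.

    Defaults describe a small but realistic desk-scale cohort: 3 TMAs of 8
    patients with both tissue classes, 2 normal + 4 tumour cores per patient,
    10-40 spectra per core, 2000-point axes over 800-1400 Da with +-0.5 Da
    per-TMA extreme jitter, 60 peptide-like peaks of width 1 Da kept at least
    4 Da apart whose base amplitude decays with m/z (scale 250 Da), 10 of
    them scaled 3-fold in the positive class, log-normal pixel noise
    (sigma 0.3) and patient effects (sigma 0.2), and a half-normal baseline
    at 1% of the unit peak height.
    """

    n_tmas: int = 3
    design: str = "paired"              # "paired" | "single"
    # paired design: patient counts over the whole cohort
    n_patients_both: int = 24
    n_patients_pos_only: int = 0
    n_patients_neg_only: int = 0
    # single design: one group per patient
    n_patients_pos: int = 8
    n_patients_neg: int = 40
    cores_neg: int = 2
    cores_pos: int = 4
    spectra_per_core: tuple[int, int] = (10, 40)
    axis_points: int = 2000
    mz_min: float = 800.0
    mz_max: float = 1400.0
    axis_jitter: float = 0.5
    n_peaks: int = 60
    peak_sigma: float = 1.0
    min_peak_separation: float = 4.0
    amp_decay: float = 250.0
    amp_sigma: float = 0.5
    n_effect_peaks: int = 10
    fold_change: float = 3.0
    noise_sigma: float = 0.3
    patient_sigma: float = 0.2
    baseline_scale: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_tmas, self.axis_points, self.n_peaks) < 1:
            raise ValueError("counts must be positive")
        if self.design not in ("paired", "single"):
            raise ValueError(f"unknown design {self.design!r}")
        if not 0 <= self.n_effect_peaks <= self.n_peaks:
            raise ValueError("n_effect_peaks must lie in [0, n_peaks]")
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")
        lo, hi = self.spectra_per_core
        if lo < 1 or hi < lo:
            raise ValueError("spectra_per_core must be a valid positive range")
        margin = 3.0 * self.peak_sigma + self.axis_jitter
        if self.mz_min + margin >= self.mz_max - margin:
            raise ValueError(
                "m/z range too narrow: discriminating peaks would fall outside it"
            )
        usable = (self.mz_max - margin) - (self.mz_min + margin)
        if (self.n_peaks - 1) * self.min_peak_separation >= usable:
            raise ValueError(
                f"{self.n_peaks} peaks at separation >= {self.min_peak_separation}"
                f" Da do not fit into {usable:.1f} usable Da"
            )


@dataclass
class SimCohort:
    """A generated cohort plus its ground truth."""

    config: SimConfig
    spectra: list[RawSpectrum]
    annotations: pd.DataFrame
    axes: dict[str, np.ndarray]
    peak_centers: np.ndarray
    base_amplitudes: np.ndarray
    effect_indices: np.ndarray

    def expected_mean_spectrum(self, label: int, tma_id: str) -> np.ndarray:
        """Noise-free class-mean spectrum on one TMA's axis (up to a constant
        log-normal scale factor common to all peaks)."""
        amps = self.base_amplitudes.copy()
        if label == 1:
            amps[self.effect_indices] *= self.config.fold_change
        return amps @ _peak_profiles(self.axes[tma_id], self.peak_centers,
                                     self.config.peak_sigma)


def _peak_profiles(axis: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    """Unit-height Gaussian profile of every peak on an axis: (n_peaks, n_points)."""
    d = axis[None, :] - centers[:, None]
    return np.exp(-0.5 * (d / sigma) ** 2)


def _patient_roster(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[str, str, tuple[int, ...]]]:
    """(patient_id, tma_id, classes) triples, patients spread round-robin."""
    entries: list[tuple[int, ...]] = []
    if cfg.design == "paired":
        entries += [(0, 1)] * cfg.n_patients_both
        entries += [(1,)] * cfg.n_patients_pos_only
        entries += [(0,)] * cfg.n_patients_neg_only
    else:
        labels = np.array([1] * cfg.n_patients_pos + [0] * cfg.n_patients_neg)
        rng.shuffle(labels)
        entries += [(int(l),) for l in labels]
    if not entries:
        raise ValueError("configuration yields no patients")
    roster = []
    for i, classes in enumerate(entries):
        tma = f"tma{i % cfg.n_tmas:02d}"
        roster.append((f"p{i:04d}", tma, classes))
    return roster


def generate_cohort(cfg: SimConfig) -> SimCohort:
    """Generate a cohort deterministically from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # peak centers uniform over the usable range but kept min_peak_separation
    # apart, so every peak is a resolved local maximum of the mean spectrum
    margin = 3.0 * cfg.peak_sigma + cfg.axis_jitter
    lo_mz, hi_mz = cfg.mz_min + margin, cfg.mz_max - margin
    slack = (hi_mz - lo_mz) - (cfg.n_peaks - 1) * cfg.min_peak_separation
    offsets = np.sort(rng.uniform(0.0, slack, cfg.n_peaks))
    centers = lo_mz + offsets + cfg.min_peak_separation * np.arange(cfg.n_peaks)
    base_amp = (
        np.exp(-(centers - cfg.mz_min) / cfg.amp_decay)
        * rng.lognormal(0.0, cfg.amp_sigma, cfg.n_peaks)
    )
    effect_idx = np.sort(rng.choice(cfg.n_peaks, cfg.n_effect_peaks, replace=False))

    axes: dict[str, np.ndarray] = {}
    profiles: dict[str, np.ndarray] = {}
    for t in range(cfg.n_tmas):
        tma = f"tma{t:02d}"
        lo = cfg.mz_min + rng.uniform(-cfg.axis_jitter, cfg.axis_jitter)
        hi = cfg.mz_max + rng.uniform(-cfg.axis_jitter, cfg.axis_jitter)
        axes[tma] = np.linspace(lo, hi, cfg.axis_points)
        profiles[tma] = _peak_profiles(axes[tma], centers, cfg.peak_sigma)

    roster = _patient_roster(cfg, rng)
    lo_n, hi_n = cfg.spectra_per_core
    effect_mask = np.isin(np.arange(cfg.n_peaks), effect_idx)

    spectra: list[RawSpectrum] = []
    ann_rows = []
    pixel_counter: dict[str, int] = {t: 0 for t in axes}
    for patient_id, tma, classes in roster:
        pfac = np.exp(cfg.patient_sigma * rng.standard_normal(cfg.n_peaks))
        for label in classes:
            group_id = f"{patient_id}_c{label}"
            amps_group = base_amp * pfac
            if label == 1:
                amps_group = amps_group * np.where(effect_mask, cfg.fold_change, 1.0)
            n_cores = cfg.cores_pos if label == 1 else cfg.cores_neg
            for _core in range(n_cores):
                n_spec = int(rng.integers(lo_n, hi_n + 1))
                noise = np.exp(cfg.noise_sigma
                               * rng.standard_normal((n_spec, cfg.n_peaks)))
                inten = (amps_group[None, :] * noise) @ profiles[tma]
                inten += np.abs(
                    cfg.baseline_scale * rng.standard_normal(inten.shape)
                )
                for row in inten:
                    i = pixel_counter[tma]
                    pixel_counter[tma] += 1
                    coords = (1 + i % _TMA_GRID_WIDTH, 1 + i // _TMA_GRID_WIDTH)
                    spectra.append(RawSpectrum(coords=coords, mz=axes[tma],
                                               intensity=row, tma_id=tma))
                    ann_rows.append(dict(tma_id=tma, x=coords[0], y=coords[1],
                                         patient_id=patient_id,
                                         group_id=group_id, label=label))
    annotations = pd.DataFrame(ann_rows)
    return SimCohort(config=cfg, spectra=spectra, annotations=annotations,
                     axes=axes, peak_centers=centers, base_amplitudes=base_amp,
                     effect_indices=effect_idx)


def write_imzml(
    cohort: SimCohort, directory: str | Path, per_class_files: bool = False
) -> list[Path]:
    """Write the cohort as continuous-mode imzML/ibd pairs + annotations.csv.

    One file pair per TMA by default; with ``per_class_files`` one pair per
    TMA x class (the layout where class identity is carried by the file),
    named ``<tma>__c<label>.imzML``. Spectra round-trip exactly (float64
    m/z and intensities).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    label_of = {
        (r.tma_id, r.x, r.y): r.label
        for r in cohort.annotations.itertuples(index=False)
    }

    buckets: dict[str, list[RawSpectrum]] = {}
    for s in cohort.spectra:
        key = s.tma_id
        if per_class_files:
            key = f"{s.tma_id}__c{label_of[(s.tma_id, *s.coords)]}"
        buckets.setdefault(key, []).append(s)

    paths = []
    for key in sorted(buckets):
        path = directory / f"{key}.imzML"
        with ImzMLWriter(str(path), mz_dtype=np.float64,
                         intensity_dtype=np.float64, mode="continuous",
                         spec_type="profile") as w:
            for s in buckets[key]:
                w.addSpectrum(s.mz, s.intensity, (s.coords[0], s.coords[1], 1))
        paths.append(path)
    cohort.annotations.to_csv(directory / "annotations.csv", index=False)
    return paths


def read_cohort(directory: str | Path) -> tuple[list[RawSpectrum], pd.DataFrame]:
    """Read back a written cohort: all spectra plus the annotation table.

    File stems of the per-class layout (``tma03__c1``) collapse to the
    physical TMA id so downstream joins and leave-one-TMA-out splits see the
    true array identity.
    """
    directory = Path(directory)
    ann = read_annotations(directory / "annotations.csv")
    spectra: list[RawSpectrum] = []
    for path in sorted(directory.glob("*.imzML")):
        tma_id = path.stem.split("__")[0]
        spectra.extend(read_imzml(path, tma_id=tma_id))
    return spectra, ann
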