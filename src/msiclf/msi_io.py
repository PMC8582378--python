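"""Reading imzML imaging data and assembling labelled patient tissue groups.

A MALDI-MSI acquisition yields one mass spectrum per spatial pixel. The unit of
classification downstream is not the pixel but the *tissue group*: all spectra
of one tissue type (e.g. tumour) from one patient, possibly pooled over several
tissue-microarray cores. This module reads imzML/ibd pairs into
:class:`RawSpectrum` records, optionally rescales each spectrum to a fixed
total ion count, and joins spectra against a per-pixel annotation table to
produce :class:`TissueGroup` objects.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("tma_id", "x", "y", "patient_id", "group_id", "label")


class SpectrumValidationError(ValueError):
    """A spectrum violates a structural invariant (lengths, monotone m/z...)."""


class AnnotationError(ValueError):
    """The annotation table is internally inconsistent."""


class EmptySpectrumError(ValueError):
    """Raised when normalizing a spectrum whose total ion count is zero."""


@dataclass
class RawSpectrum:
    """One pixel's spectrum: an m/z axis, intensities, and provenance.

    Parameters
    ----------
    coords
        1-based pixel position ``(x, y)`` following the imzML convention.
    mz
        Strictly increasing m/z values in Da.
    intensity
        Non-negative ion counts, one per m/z value.
    tma_id
        Identifier of the source dataset (one TMA, or one TMA x class file).
    """

    coords: tuple[int, int]
    mz: np.ndarray
    intensity: np.ndarray
    tma_id: str

    def validate(self) -> None:
        if len(self.mz) != len(self.intensity):
            raise SpectrumValidationError(
                f"pixel {self.coords} of {self.tma_id}: m/z axis has "
                f"{len(self.mz)} points but {len(self.intensity)} intensities"
            )
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise SpectrumValidationError(
                f"pixel {self.coords} of {self.tma_id}: m/z axis not strictly increasing"
            )
        if np.any(self.intensity < 0):
            raise SpectrumValidationError(
                f"pixel {self.coords} of {self.tma_id}: negative intensity"
            )

    @property
    def tic(self) -> float:
        """Total ion count (sum of intensities)."""
        return float(np.sum(self.intensity))


@dataclass
class TissueGroup:
    """All spectra of one tissue type from one patient — the sample unit."""

    group_id: str
    patient_id: str
    label: int
    spectra: list[RawSpectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"group {self.group_id}: label must be 0 or 1")

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    @property
    def tma_id(self) -> str:
        """The TMA the group sits on; groups never straddle TMAs."""
        tmas = {s.tma_id for s in self.spectra}
        if len(tmas) != 1:
            raise ValueError(f"group {self.group_id} spans TMAs {sorted(tmas)}")
        return next(iter(tmas))


def _count_spectrum_elements(path: Path) -> int:
    # cheap scan; imzML spectrum lists are flat
    text = path.read_text(errors="replace")
    return len(re.findall(r"<spectrum[ >]", text))


def read_imzml(path: str | Path, tma_id: str | None = None) -> list[RawSpectrum]:
    """Read a continuous-mode imzML/ibd pair into per-pixel spectra.

    Parameters
    ----------
    path
        Path to the ``.imzML`` XML file; the binary ``.ibd`` companion must sit
        next to it.
    tma_id
        Dataset identity recorded on every spectrum; defaults to the file stem.

    Returns
    -------
    list of RawSpectrum
        One record per pixel in the file's pixel order, coordinates preserved.

    Raises
    ------
    FileNotFoundError
        Missing imzML or ibd file.
    SpectrumValidationError
        A pixel whose intensity and m/z arrays disagree in length or whose
        m/z axis is not strictly increasing; the message names the pixel.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"imzML file not found: {path}")
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FileNotFoundError(f"binary companion not found: {ibd}")
    if tma_id is None:
        tma_id = path.stem

    try:
        parser = ImzMLParser(str(path))
    except Exception:
        # pyimzml cannot index a file with zero pixels; a truly empty file is
        # a legal degenerate input and yields an empty collection.
        if _count_spectrum_elements(path) == 0:
            logger.warning("imzML file %s contains no spectra", path)
            return []
        raise

    spectra: list[RawSpectrum] = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        s = RawSpectrum(
            coords=(int(x), int(y)),
            mz=np.asarray(mz, dtype=np.float64),
            intensity=np.asarray(inten, dtype=np.float64),
            tma_id=tma_id,
        )
        try:
            s.validate()
        except SpectrumValidationError as err:
            raise SpectrumValidationError(f"pixel {i + 1}: {err}") from err
        spectra.append(s)
    return spectra


def tic_normalize(s: RawSpectrum, target: float = 1.0) -> RawSpectrum:
    """Rescale a spectrum so its total ion count equals ``target``.

    The m/z axis is untouched. Data exported from vendor pipelines is often
    already TIC-normalized, in which case this stage can simply be skipped.

    Raises
    ------
    EmptySpectrumError
        If the spectrum's total intensity is zero (tissue-void pixel).
    """
    total = s.tic
    if total <= 0:
        raise EmptySpectrumError(
            f"pixel {s.coords} of {s.tma_id}: zero total ion count"
        )
    return RawSpectrum(
        coords=s.coords,
        mz=s.mz,
        intensity=s.intensity * (target / total),
        tma_id=s.tma_id,
    )


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-pixel annotation table (CSV/TSV, sniffed by extension).

    Expected header columns: ``tma_id, x, y, patient_id, group_id, label``
    with label in {0, 1}. Validates the table with :func:`validate_annotations`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    ann = pd.read_csv(path, sep=sep, dtype={"tma_id": str, "patient_id": str, "group_id": str})
    validate_annotations(ann)
    return ann


def validate_annotations(ann: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise AnnotationError(f"annotation table missing columns: {missing}")
    if not ann["label"].isin([0, 1]).all():
        raise AnnotationError("labels must be 0 (negative) or 1 (positive)")
    dup = ann.duplicated(subset=["tma_id", "x", "y"], keep=False)
    if dup.any():
        clash = ann.loc[dup, ["tma_id", "x", "y"]].drop_duplicates().head(3)
        raise AnnotationError(
            f"coordinates claimed by more than one group: {clash.to_dict('records')}"
        )
    per_group = ann.groupby("group_id").agg(
        n_patients=("patient_id", "nunique"), n_labels=("label", "nunique")
    )
    bad = per_group[(per_group.n_patients > 1) | (per_group.n_labels > 1)]
    if len(bad):
        raise AnnotationError(
            f"groups with conflicting patient or label: {list(bad.index[:5])}"
        )


def expand_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Expand a rectangular-region shorthand table into per-pixel rows.

    Input columns: ``tma_id, x_min, x_max, y_min, y_max, patient_id, group_id,
    label`` with inclusive bounds; output is a standard annotation table.
    """
    rows = []
    for r in regions.itertuples(index=False):
        for y in range(int(r.y_min), int(r.y_max) + 1):
            for x in range(int(r.x_min), int(r.x_max) + 1):
                rows.append(
                    dict(tma_id=r.tma_id, x=x, y=y, patient_id=r.patient_id,
                         group_id=r.group_id, label=r.label)
                )
    ann = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    validate_annotations(ann)
    return ann


def assign_groups(
    spectra: Iterable[RawSpectrum],
    ann: pd.DataFrame,
    tma_labels: Mapping[str, int] | None = None,
) -> list[TissueGroup]:
    """Join spectra against the annotation table into labelled tissue groups.

    Each annotated spectrum lands in exactly one group; spectra at coordinates
    the table does not cover are dropped (their count is logged). Groups that
    end up with zero spectra are not emitted.

    Parameters
    ----------
    spectra
        Pixel spectra, typically pooled over every dataset of a cohort.
    ann
        Per-pixel annotation table; its ``label`` column may be absent when
        ``tma_labels`` supplies class labels by file identity instead (the
        layout where each dataset holds a single class).
    tma_labels
        Optional mapping ``tma_id -> label`` overriding per-pixel labels.
    """
    ann = ann.copy()
    if tma_labels is not None:
        ann["label"] = ann["tma_id"].map(tma_labels)
        if ann["label"].isna().any():
            missing = sorted(set(ann.loc[ann["label"].isna(), "tma_id"]))
            raise AnnotationError(f"no label provided for TMA(s) {missing}")
        ann["label"] = ann["label"].astype(int)
    validate_annotations(ann)

    index: dict[tuple[str, int, int], tuple[str, str, int]] = {}
    for r in ann.itertuples(index=False):
        index[(str(r.tma_id), int(r.x), int(r.y))] = (
            str(r.group_id), str(r.patient_id), int(r.label)
        )

    groups: dict[str, TissueGroup] = {}
    n_excluded = 0
    n_total = 0
    for s in spectra:
        n_total += 1
        key = (s.tma_id, s.coords[0], s.coords[1])
        hit = index.get(key)
        if hit is None:
            n_excluded += 1
            continue
        group_id, patient_id, label = hit
        g = groups.get(group_id)
        if g is None:
            g = TissueGroup(group_id=group_id, patient_id=patient_id, label=label)
            groups[group_id] = g
        g.spectra.append(s)

    logger.info(
        "assigned %d/%d spectra to %d tissue groups (%d unannotated spectra dropped)",
        n_total - n_excluded, n_total, len(groups), n_excluded,
    )
    if not groups:
        warnings.warn("annotation table matched no spectrum coordinates", stacklevel=2)
    return list(groups.values())


def drop_empty_spectra(spectra: Sequence[RawSpectrum]) -> list[RawSpectrum]:
    """Remove zero-TIC pixels (tissue voids), logging how many were dropped."""
    kept = [s for s in spectra if s.tic > 0]
    n_dropped = len(spectra) - len(kept)
    if n_dropped:
        logger.info("dropped %d spectra with zero total ion count", n_dropped)
    return kept
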