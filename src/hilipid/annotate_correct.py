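"""Sum-composition annotation and isotopic interference corrections.

An averaged class spectrum is matched against the theoretical target list at
an absolute m/z tolerance (0.05 by default), low-abundance species are removed
relative to the endogenous base peak (1% by default), and two isotopic
corrections are applied:

* type-II — within a class, species that differ by exactly one C=C bond are
  2 Da apart, so the M+2 isotopologue of the more unsaturated species overlaps
  the M+0 of the less unsaturated one after band averaging.  Processing each
  (subclass, C) group in order of decreasing D, the interference
  ``corrected_M0(D) * f2(D)/f0(D)`` is subtracted from the M+0 of the D-1
  member.
* type-I — the interference-free M+0 is rescaled to the whole isotope pattern
  by dividing by the monoisotopic fraction f0 of the species' formula.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .lipid_chem import (
    IonSpecies,
    IsotopePattern,
    SumComposition,
    isotope_pattern,
)
from .spectra import ClassSpectrum

log = logging.getLogger(__name__)


@dataclass
class AnnotatedSpecies:
    """A matched species and its raw / corrected intensities."""

    ion: IonSpecies
    experimental_mz: float
    raw_m0_intensity: float
    type2_corrected_m0_intensity: float | None = None
    type1_corrected_total_intensity: float | None = None

    @property
    def species(self) -> SumComposition:
        assert isinstance(self.ion.species, SumComposition)
        return self.ion.species

    @property
    def is_internal_standard(self) -> bool:
        return self.ion.is_internal_standard

    @property
    def delta_mz(self) -> float:
        return self.experimental_mz - self.ion.theoretical_mz

    @property
    def pattern(self) -> IsotopePattern:
        return isotope_pattern(self.ion.formula)


def match_targets(
    spectrum: ClassSpectrum,
    targets: Sequence[IonSpecies],
    tol_mz: float = 0.05,
) -> list[AnnotatedSpecies]:
    """Match targets to spectrum peaks within an absolute m/z tolerance.

    Each target takes its nearest in-tolerance peak and each peak serves at
    most one target; conflicts resolve by smaller |Δm/z|, ties toward the
    lower theoretical m/z.  Unmatched targets are omitted.
    """
    if tol_mz <= 0:
        raise DataError("tol_mz must be positive")
    mz = spectrum.mz
    candidates = []  # (|dmz|, theoretical mz, target index, peak index)
    for ti, target in enumerate(targets):
        lo = np.searchsorted(mz, target.theoretical_mz - tol_mz, side="left")
        hi = np.searchsorted(mz, target.theoretical_mz + tol_mz, side="right")
        for pi in range(lo, hi):
            candidates.append(
                (abs(mz[pi] - target.theoretical_mz), target.theoretical_mz, ti, pi)
            )
    candidates.sort()
    used_targets: set[int] = set()
    used_peaks: set[int] = set()
    matches: list[AnnotatedSpecies] = []
    for _, _, ti, pi in candidates:
        if ti in used_targets or pi in used_peaks:
            continue
        used_targets.add(ti)
        used_peaks.add(pi)
        matches.append(AnnotatedSpecies(
            ion=targets[ti],
            experimental_mz=float(mz[pi]),
            raw_m0_intensity=float(spectrum.intensity[pi]),
        ))
    matches.sort(key=lambda a: a.ion.theoretical_mz)
    return matches


def filter_by_intensity(
    annotations: Sequence[AnnotatedSpecies],
    threshold_fraction: float = 0.01,
) -> list[AnnotatedSpecies]:
    """Keep endogenous species above a fraction of the endogenous base peak.

    Internal standards are always retained and never define the base peak.
    """
    endogenous = [a for a in annotations if not a.is_internal_standard]
    if not endogenous:
        raise DataError("no endogenous annotations to define the base peak")
    base = max(a.raw_m0_intensity for a in endogenous)
    return [
        a for a in annotations
        if a.is_internal_standard or a.raw_m0_intensity > threshold_fraction * base
    ]


def _type2_group_key(a: AnnotatedSpecies) -> tuple:
    sc = a.species
    # subclass tag keeps ether and diacyl apart; deuterated standards are
    # chemically distinct and form their own groups
    return (sc.lipid_class, sc.carbons, a.is_internal_standard, a.ion.formula.d)


def correct_type2(
    annotations: Sequence[AnnotatedSpecies],
    overlap_fraction: float = 1.0,
) -> list[AnnotatedSpecies]:
    """Remove same-class ΔD=1 M+2 interference from each M+0 intensity.

    Groups share (subclass, total carbons); within a group members are
    processed in descending D.  The most unsaturated member is interference
    free; every member whose D+1 neighbour exists has
    ``corrected_M0(D+1) * f2/f0`` subtracted (clamped at zero).  Members with
    no ΔD=1 neighbour are untouched.
    """
    if not 0 <= overlap_fraction <= 1:
        raise DataError("overlap_fraction must lie in [0, 1]")
    groups: dict[tuple, list[AnnotatedSpecies]] = {}
    for a in annotations:
        groups.setdefault(_type2_group_key(a), []).append(a)
    for key, members in groups.items():
        d_seen = [m.species.double_bonds for m in members]
        if len(set(d_seen)) != len(d_seen):
            raise DataError(f"duplicate (class, C, D) annotation in type-II group {key}")
        members.sort(key=lambda m: -m.species.double_bonds)
        corrected: dict[int, AnnotatedSpecies] = {}
        for m in members:
            d = m.species.double_bonds
            value = m.raw_m0_intensity
            upper = corrected.get(d + 1)
            if upper is not None:
                pattern = upper.pattern
                interference = (
                    upper.type2_corrected_m0_intensity * pattern.m2_over_m0 * overlap_fraction
                )
                value -= interference
                if value < 0:
                    log.warning(
                        "type-II correction drove %s below zero (%.3g); clamping",
                        m.species.label, value,
                    )
                    value = 0.0
            m.type2_corrected_m0_intensity = value
            corrected[d] = m
    return list(annotations)


def correct_type1(annotations: Sequence[AnnotatedSpecies]) -> list[AnnotatedSpecies]:
    """Rescale each interference-free M+0 to the whole-pattern intensity."""
    for a in annotations:
        if a.type2_corrected_m0_intensity is None:
            raise DataError(
                f"type-II correction missing for {a.species.label}; apply it first"
            )
        f0 = a.pattern.f0
        if f0 <= 0:
            raise DataError(f"non-positive monoisotopic fraction for {a.ion.formula.hill()}")
        a.type1_corrected_total_intensity = a.type2_corrected_m0_intensity / f0
    return list(annotations)


def annotate_and_correct(
    spectrum: ClassSpectrum,
    targets: Sequence[IonSpecies],
    tol_mz: float = 0.05,
    threshold_fraction: float = 0.01,
    overlap_fraction: float = 1.0,
) -> list[AnnotatedSpecies]:
    """match -> 1% filter -> type-II -> type-I, in the workflow order."""
    annotations = match_targets(spectrum, targets, tol_mz)
    if not annotations:
        return []
    annotations = filter_by_intensity(annotations, threshold_fraction)
    endogenous = [a for a in annotations if not a.is_internal_standard]
    if endogenous:
        spectrum.base_peak_intensity = max(a.raw_m0_intensity for a in endogenous)
    correct_type2(annotations, overlap_fraction)
    correct_type1(annotations)
    return annotations


ANNOTATION_COLUMNS = (
    "subclass", "species", "C", "D", "theoretical_mz", "experimental_mz",
    "delta_mz", "raw_m0", "corrected_m0", "corrected_total", "is_standard",
)


def annotations_to_frame(annotations: Sequence[AnnotatedSpecies]) -> pd.DataFrame:
    """Tidy table of an annotation list (one row per matched species)."""
    rows = []
    for a in annotations:
        sc = a.species
        rows.append({
            "subclass": sc.lipid_class.value,
            "species": sc.label + (f" d{a.ion.formula.d}" if a.ion.formula.d else ""),
            "C": sc.carbons,
            "D": sc.double_bonds,
            "theoretical_mz": a.ion.theoretical_mz,
            "experimental_mz": a.experimental_mz,
            "delta_mz": a.delta_mz,
            "raw_m0": a.raw_m0_intensity,
            "corrected_m0": a.type2_corrected_m0_intensity,
            "corrected_total": a.type1_corrected_total_intensity,
            "is_standard": a.is_internal_standard,
        })
    return pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
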