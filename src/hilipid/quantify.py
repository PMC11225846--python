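"""Relative abundances, replicate aggregation, concentrations and class ratios.

Quantification uses one internal standard (IS) per class, spiked at a known
concentration into every extract: because HILIC co-elutes a whole class in one
narrow band, all its species ionize under near-identical conditions and share
an ionization yield with the IS, so

    conc(species) = corrected_total(species) / corrected_total(IS) * spike.

Relative abundances (per-class fractions of corrected intensities) feed the
chemometrics; species whose relative abundance varies by more than 20% RSD
across the extraction replicates of any pellet are excluded from chemometrics
globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate_correct import AnnotatedSpecies
from .errors import DataError
from .lipid_chem import LipidClass, SumComposition

log = logging.getLogger(__name__)

DEFAULT_SPIKE_UG_ML = 3.0  # IS concentration in the final extract
DEFAULT_RSD_CUTOFF = 0.20

RATIO_NAMES = ("PE/PC", "PI/PC", "CL/PC", "PC O/PC", "PE O/PE")


class CellLine(Enum):
    WT = "WT"
    OPA1_KO = "OPA1_KO"
    MFN12_KO = "MFN12_KO"


@dataclass(frozen=True)
class SampleRecord:
    """One analyzed run: cell line x biological x extraction replicate."""

    cell_line: CellLine
    biological_replicate: int
    extraction_replicate: int

    @property
    def sort_key(self) -> tuple:
        lines = list(CellLine)
        return (lines.index(self.cell_line), self.biological_replicate,
                self.extraction_replicate)

    def __post_init__(self) -> None:
        if not 1 <= self.biological_replicate:
            raise DataError("biological replicate index must be >= 1")
        if not 1 <= self.extraction_replicate:
            raise DataError("extraction replicate index must be >= 1")

    @property
    def sample_id(self) -> str:
        return f"{self.cell_line.value}_b{self.biological_replicate}_e{self.extraction_replicate}"

    @property
    def pellet_id(self) -> str:
        return f"{self.cell_line.value}_b{self.biological_replicate}"


def full_design(n_biological: int = 3, n_extraction: int = 3) -> list[SampleRecord]:
    """The three-line design (3 lines x n_bio x n_ext samples)."""
    return [
        SampleRecord(line, b, e)
        for line in CellLine
        for b in range(1, n_biological + 1)
        for e in range(1, n_extraction + 1)
    ]


@dataclass
class ClassProfile:
    """Relative abundances of one class family in one sample."""

    family: LipidClass
    fractions: dict[str, float]  # species label -> fraction
    total_intensity: float


def relative_abundances(annotations: Sequence[AnnotatedSpecies]) -> ClassProfile:
    """Fractions of type-I-corrected totals over the endogenous species of a class."""
    endo = [a for a in annotations if not a.is_internal_standard]
    if not endo:
        raise DataError("no endogenous annotations")
    families = {a.species.lipid_class.family for a in endo}
    if len(families) != 1:
        raise DataError(f"annotations span multiple class families: {families}")
    totals = {}
    for a in endo:
        if a.type1_corrected_total_intensity is None:
            raise DataError(f"type-I corrected total missing for {a.species.label}")
        totals[a.species.label] = a.type1_corrected_total_intensity
    grand = sum(totals.values())
    if grand <= 0:
        raise DataError("zero class total; cannot form relative abundances")
    return ClassProfile(
        family=families.pop(),
        fractions={k: v / grand for k, v in totals.items()},
        total_intensity=grand,
    )


@dataclass
class QuantTable:
    """Per-sample species concentrations (μg/ml of extract) and class totals."""

    sample: SampleRecord
    concentrations: dict[SumComposition, float]
    subclass_totals: dict[LipidClass, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": self.sample.sample_id,
                "cell_line": self.sample.cell_line.value,
                "biological_replicate": self.sample.biological_replicate,
                "extraction_replicate": self.sample.extraction_replicate,
                "subclass": sc.lipid_class.value,
                "species": sc.label,
                "concentration": conc,
            }
            for sc, conc in sorted(self.concentrations.items(), key=lambda kv: kv[0].label)
        ]
        return pd.DataFrame(rows)


def estimate_concentrations(
    annotations: Sequence[AnnotatedSpecies],
    sample: SampleRecord,
    spike_ug_ml: float = DEFAULT_SPIKE_UG_ML,
) -> QuantTable:
    """Single-IS concentration estimates for one sample's annotations."""
    if spike_ug_ml <= 0:
        raise DataError("spike concentration must be positive")
    by_family: dict[LipidClass, list[AnnotatedSpecies]] = {}
    for a in annotations:
        by_family.setdefault(a.species.lipid_class.family, []).append(a)
    concentrations: dict[SumComposition, float] = {}
    subclass_totals: dict[LipidClass, float] = {}
    for family, members in by_family.items():
        standards = [a for a in members if a.is_internal_standard]
        if not standards:
            raise DataError(f"no internal standard matched for class {family.value}")
        is_total = sum(a.type1_corrected_total_intensity or 0.0 for a in standards)
        if is_total <= 0:
            raise DataError(f"zero-intensity internal standard for class {family.value}")
        for a in members:
            if a.is_internal_standard:
                continue
            if a.type1_corrected_total_intensity is None:
                raise DataError(f"uncorrected annotation {a.species.label}")
            conc = a.type1_corrected_total_intensity / is_total * spike_ug_ml
            concentrations[a.species] = conc
            sub = a.species.lipid_class
            subclass_totals[sub] = subclass_totals.get(sub, 0.0) + conc
    return QuantTable(sample=sample, concentrations=concentrations,
                      subclass_totals=subclass_totals)


def class_ratios(
    quant: QuantTable | Mapping[LipidClass, float],
    combined_denominators: bool = False,
) -> dict[str, float]:
    """The five class/subclass concentration ratios of one sample.

    By default the diacyl subclass total is the reference: PE/PC, PI/PC and
    CL/PC are relative to diacyl PC, PC O/PC to diacyl PC and PE O/PE to
    diacyl PE.  With ``combined_denominators`` the PC (PE) denominator is the
    diacyl + ether family total.
    """
    totals = quant.subclass_totals if isinstance(quant, QuantTable) else dict(quant)
    get = lambda cls: float(totals.get(cls, 0.0))
    pc_den = get(LipidClass.PC)
    pe_den = get(LipidClass.PE)
    if combined_denominators:
        pc_den += get(LipidClass.PC_O)
        pe_den += get(LipidClass.PE_O)
    if pc_den <= 0:
        raise DataError("zero PC denominator for class ratios")
    if pe_den <= 0:
        raise DataError("zero PE denominator for PE O/PE ratio")
    return {
        "PE/PC": get(LipidClass.PE) / pc_den,
        "PI/PC": get(LipidClass.PI) / pc_den,
        "CL/PC": get(LipidClass.CL) / pc_den,
        "PC O/PC": get(LipidClass.PC_O) / pc_den,
        "PE O/PE": get(LipidClass.PE_O) / pe_den,
    }


@dataclass
class AggregationResult:
    """Replicate aggregation of one class family's relative abundances."""

    family: LipidClass
    sample_table: pd.DataFrame        # samples x species fractions
    pellet_means: pd.DataFrame        # (line, bio) x species
    pellet_rsd: pd.DataFrame          # (line, bio) x species
    line_means: pd.DataFrame          # line x species
    excluded_species: tuple[str, ...]  # RSD > cutoff in at least one pellet
    chemometrics_matrix: pd.DataFrame  # pellet means, retained species only
    cell_lines: pd.Series             # cell line label per chemometrics row


def aggregate_replicates(
    profiles: Mapping[SampleRecord, ClassProfile],
    rsd_cutoff: float = DEFAULT_RSD_CUTOFF,
) -> AggregationResult:
    """Mean/RSD across extraction replicates; global RSD-based exclusion.

    A species is excluded from the chemometrics input as soon as its relative
    abundance RSD exceeds the cutoff within any single pellet.  The
    chemometrics matrix holds per-pellet (biological replicate) means of the
    never-excluded species.
    """
    if len(profiles) < 2:
        raise DataError("replicate aggregation needs at least two samples")
    families = {p.family for p in profiles.values()}
    if len(families) != 1:
        raise DataError("profiles span multiple class families")
    family = families.pop()

    all_species = sorted({sp for p in profiles.values() for sp in p.fractions})
    inconsistent = any(set(p.fractions) != set(all_species) for p in profiles.values())
    if inconsistent:
        log.warning(
            "inconsistent %s species sets across replicates; zero-filling the union",
            family.value,
        )
    records = sorted(profiles, key=lambda r: r.sort_key)
    rows = {
        rec.sample_id: [profiles[rec].fractions.get(sp, 0.0) for sp in all_species]
        for rec in records
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=all_species)
    meta = pd.DataFrame(
        [
            {"sample": rec.sample_id, "pellet": rec.pellet_id, "line": rec.cell_line.value}
            for rec in records
        ]
    ).set_index("sample")

    grouped = table.groupby(meta["pellet"], sort=True)
    pellet_means = grouped.mean()
    pellet_sd = grouped.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = pellet_sd / pellet_means
    rsd = rsd.where(~((pellet_means == 0) & (pellet_sd == 0)), 0.0)
    rsd = rsd.where(~((pellet_means == 0) & (pellet_sd > 0)), np.inf)

    excluded = tuple(sp for sp in all_species if (rsd[sp] > rsd_cutoff).any())
    retained = [sp for sp in all_species if sp not in excluded]

    pellet_line = meta.drop_duplicates("pellet").set_index("pellet")["line"]
    line_means = pellet_means.groupby(pellet_line).mean()

    return AggregationResult(
        family=family,
        sample_table=table,
        pellet_means=pellet_means,
        pellet_rsd=rsd,
        line_means=line_means,
        excluded_species=excluded,
        chemometrics_matrix=pellet_means[retained],
        cell_lines=pellet_line.loc[pellet_means.index],
    )
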