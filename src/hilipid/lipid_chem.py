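"""Elemental formulas, exact ion masses and isotope patterns for glycerophospholipids.

Species are handled at the sum-composition level ("PC 34:1"): a lipid class
tag plus the total number of side-chain carbons C and side-chain C=C double
bonds D, without resolving individual acyl/alk(en)yl chains.  Each class maps
to an exact elemental formula by fixed glycerophospholipid stoichiometry, from
which monoisotopic ion m/z values and aggregated isotope patterns (M+0 ... M+n)
are computed.  The module also generates the theoretical target list used for
annotation, including deuterated internal standards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Pinned physical constants (monoisotopic masses in u, IUPAC representative
# isotopic abundances).  All mass arithmetic in the package goes through this
# table so that results are bit-stable.
# --------------------------------------------------------------------------

ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "D": 2.01410178,  # heavy-hydrogen label of internal standards
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
}

PROTON_MASS = 1.00727646
ELECTRON_MASS = ATOMIC_MASS["H"] - PROTON_MASS  # 0.00054857, keeps bookkeeping closed

#: mass gap between consecutive aggregated isotopologues (13C - 12C)
NEUTRON_GAIN = 13.00335484 - 12.0

#: per-element abundance of the isotope that is k nucleons heavier than the
#: principal one; index = nucleon shift.  Deuterium label sites are treated as
#: monoisotopic (no further exchange).
ISOTOPE_ABUNDANCE = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "D": (1.0,),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
}


class LipidClass(Enum):
    """The six annotated glycerophospholipid (sub)classes.

    PC_O / PE_O are the ether-linked (alk(en)yl/acyl) subclasses; the vinyl
    ether double bond of plasmenyl species counts inside D, so one "O"
    stoichiometry per sum composition suffices.
    """

    PC = "PC"
    PC_O = "PC O"
    PE = "PE"
    PE_O = "PE O"
    PI = "PI"
    CL = "CL"

    @property
    def is_ether(self) -> bool:
        return self in (LipidClass.PC_O, LipidClass.PE_O)

    @property
    def family(self) -> "LipidClass":
        """Diacyl parent class whose HILIC band/spectrum the species shares."""
        return {LipidClass.PC_O: LipidClass.PC, LipidClass.PE_O: LipidClass.PE}.get(self, self)

    @property
    def polarity(self) -> str:
        return "positive" if self.family is LipidClass.PC else "negative"


class Adduct(Enum):
    PLUS_H = "+H"
    MINUS_H = "-H"
    MINUS_2H = "-2H"
    # the formula already is the ion (diagnostic fragments); only the electron
    # is added/removed
    CATION = "cation"
    ANION = "anion"


#: ionization assumed per class: PC as [M+H]+, PE/PI as [M-H]-, CL as [M-2H]2-
CLASS_ADDUCT = {
    LipidClass.PC: (Adduct.PLUS_H, 1),
    LipidClass.PC_O: (Adduct.PLUS_H, 1),
    LipidClass.PE: (Adduct.MINUS_H, 1),
    LipidClass.PE_O: (Adduct.MINUS_H, 1),
    LipidClass.PI: (Adduct.MINUS_H, 1),
    LipidClass.CL: (Adduct.MINUS_2H, 2),
}


@dataclass(frozen=True, order=True)
class SumComposition:
    """A lipid species identity: class + total side-chain carbons and C=C bonds."""

    lipid_class: LipidClass
    carbons: int
    double_bonds: int

    def __post_init__(self) -> None:
        if not isinstance(self.lipid_class, LipidClass):
            raise ValueError(f"unknown lipid class: {self.lipid_class!r}")
        if self.carbons <= 0:
            raise ValueError(f"carbons must be positive, got {self.carbons}")
        if self.double_bonds < 0 or self.double_bonds > self.carbons / 2:
            raise ValueError(
                f"double bonds must satisfy 0 <= D <= C/2, got {self.double_bonds} for C={self.carbons}"
            )

    @property
    def label(self) -> str:
        return f"{self.lipid_class.value} {self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass(frozen=True)
class ElementalFormula:
    """Element counts; D is the deuterium label count of internal standards."""

    c: int = 0
    h: int = 0
    d: int = 0
    n: int = 0
    o: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts().values()):
            raise ValueError(f"negative element count in {self}")

    def counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "D": self.d, "N": self.n, "O": self.o, "P": self.p}

    @property
    def n_atoms(self) -> int:
        return sum(self.counts().values())

    def monoisotopic_mass(self) -> float:
        return sum(ATOMIC_MASS[el] * cnt for el, cnt in self.counts().items())

    def hill(self) -> str:
        """Hill-order formula string; deuterium rendered as a D count after H."""
        parts = []
        for el in ("C", "H", "D", "N", "O", "P"):
            cnt = self.counts()[el]
            if cnt == 0:
                continue
            parts.append(el + (str(cnt) if cnt > 1 else ""))
        return "".join(parts)

    @classmethod
    def from_hill(cls, text: str) -> "ElementalFormula":
        import re

        counts = {"C": 0, "H": 0, "D": 0, "N": 0, "O": 0, "P": 0}
        pos = 0
        for m in re.finditer(r"([A-Z][a-z]?)(\d*)", text):
            if not m.group(0):
                continue
            el, num = m.group(1), m.group(2)
            if el not in counts:
                raise ValueError(f"unsupported element {el!r} in formula {text!r}")
            counts[el] += int(num) if num else 1
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"could not parse formula {text!r}")
        return cls(
            c=counts["C"], h=counts["H"], d=counts["D"],
            n=counts["N"], o=counts["O"], p=counts["P"],
        )


# (extra C beyond side chains, H offset in 2C - 2D + offset, N, O, P)
_FORMULA_RULES = {
    LipidClass.PC: (8, 16, 1, 8, 1),
    LipidClass.PC_O: (8, 18, 1, 7, 1),
    LipidClass.PE: (5, 10, 1, 8, 1),
    LipidClass.PE_O: (5, 12, 1, 7, 1),
    LipidClass.PI: (9, 15, 0, 13, 1),
    # triglycerol backbone (9 C) with two phosphodiester bridges: verified
    # against independent assembly from glycerols + phosphates + acyls
    LipidClass.CL: (9, 14, 0, 17, 2),
}


def formula_from_sum_composition(species: SumComposition, deuterium: int = 0) -> ElementalFormula:
    """Neutral elemental formula of a sum composition.

    ``deuterium`` replaces that many hydrogens with heavy-label sites, as in
    the d7 internal standards.
    """
    try:
        extra_c, h_off, n, o, p = _FORMULA_RULES[species.lipid_class]
    except KeyError:  # pragma: no cover - SumComposition already validates
        raise ValueError(f"no formula rule for class {species.lipid_class!r}") from None
    h = 2 * species.carbons - 2 * species.double_bonds + h_off
    if deuterium < 0 or deuterium > h:
        raise ValueError(f"deuterium count {deuterium} out of range for {species.label}")
    return ElementalFormula(c=species.carbons + extra_c, h=h - deuterium, d=deuterium, n=n, o=o, p=p)


def ion_mz(formula: ElementalFormula, adduct: Adduct, charge_magnitude: int = 1) -> float:
    """Monoisotopic m/z of an ion formed from ``formula``.

    For PLUS_H / MINUS_H / MINUS_2H the formula is the neutral molecule and
    protons are added/removed (proton bookkeeping keeps electron masses
    implicit).  For CATION / ANION the formula is already the ion's and only
    one electron is removed/added.
    """
    if formula.n_atoms == 0:
        raise ValueError("empty formula")
    m = formula.monoisotopic_mass()
    if adduct is Adduct.PLUS_H:
        mz = m + charge_magnitude * PROTON_MASS
    elif adduct is Adduct.MINUS_H:
        if charge_magnitude != 1:
            raise ValueError("[M-H]- is singly charged")
        mz = m - PROTON_MASS
    elif adduct is Adduct.MINUS_2H:
        if charge_magnitude != 2:
            raise ValueError("[M-2H]2- requires charge magnitude 2")
        mz = m - 2 * PROTON_MASS
    elif adduct is Adduct.CATION:
        mz = m - charge_magnitude * ELECTRON_MASS
    elif adduct is Adduct.ANION:
        mz = m + charge_magnitude * ELECTRON_MASS
    else:  # pragma: no cover
        raise ValueError(f"unsupported adduct {adduct!r}")
    mz /= charge_magnitude
    if mz <= 0:
        raise ValueError(f"non-positive m/z for {formula.hill()} {adduct.value}")
    return mz


@dataclass(frozen=True)
class IonSpecies:
    """A target-list entry: one ionized species with its theoretical m/z."""

    formula: ElementalFormula
    adduct: Adduct
    charge_magnitude: int
    theoretical_mz: float
    species: SumComposition | str
    is_internal_standard: bool = False

    def __post_init__(self) -> None:
        if self.charge_magnitude == 2 and self.adduct is not Adduct.MINUS_2H:
            raise ValueError("doubly charged ions are [M-2H]2- (cardiolipins) only")
        if self.theoretical_mz <= 0:
            raise ValueError("theoretical m/z must be positive")

    @property
    def label(self) -> str:
        return self.species.label if isinstance(self.species, SumComposition) else str(self.species)

    @property
    def lipid_class(self) -> LipidClass | None:
        return self.species.lipid_class if isinstance(self.species, SumComposition) else None


# --------------------------------------------------------------------------
# Isotope patterns
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotopologue abundances f_0 ... f_n (by nucleon shift).

    f_0 is the monoisotopic fraction consumed by the type-I correction;
    f_2/f_0 is the M+2/M+0 interference factor of the type-II correction.
    """

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.fractions):
            raise ValueError("negative isotopologue fraction")

    @property
    def f0(self) -> float:
        return self.fractions[0]

    def f(self, k: int) -> float:
        return self.fractions[k] if k < len(self.fractions) else 0.0

    @property
    def m2_over_m0(self) -> float:
        return self.f(2) / self.f0


def _convolve_truncated(a: np.ndarray, b: np.ndarray, n_max: int) -> np.ndarray:
    return np.convolve(a, b)[: n_max + 1]


def _element_pattern(dist: Sequence[float], count: int, n_max: int) -> np.ndarray:
    """Distribution of the total nucleon shift of ``count`` i.i.d. atoms."""
    result = np.zeros(n_max + 1)
    result[0] = 1.0
    base = np.asarray(dist, dtype=float)[: n_max + 1]
    k = count
    while k:  # exponentiation by squaring with truncation
        if k & 1:
            result = _convolve_truncated(result, base, n_max)
        k >>= 1
        if k:
            base = _convolve_truncated(base, base, n_max)
    return result


def isotope_pattern(formula: ElementalFormula, n_max: int = 5) -> IsotopePattern:
    """Aggregated isotope pattern of a formula by per-element convolution."""
    if formula.n_atoms == 0:
        raise ValueError("empty formula")
    if n_max < 2:
        raise ValueError("n_max must be >= 2 (type-II correction needs f_2)")
    acc = np.zeros(n_max + 1)
    acc[0] = 1.0
    for el, cnt in formula.counts().items():
        if cnt:
            acc = _convolve_truncated(acc, _element_pattern(ISOTOPE_ABUNDANCE[el], cnt, n_max), n_max)
    return IsotopePattern(tuple(float(f) for f in acc))


def isotopologue_mz(ion: IonSpecies, k: int) -> float:
    """m/z of the aggregated M+k isotopologue of a target ion."""
    return ion.theoretical_mz + k * NEUTRON_GAIN / ion.charge_magnitude


# --------------------------------------------------------------------------
# Diagnostic product ions (AIF class markers)
# --------------------------------------------------------------------------

#: class-diagnostic head-group fragments observed in all-ion fragmentation:
#: phosphocholine cation for PC, deprotonated dehydro-glycerophosphoethanolamine
#: for PE, deprotonated phospho-dehydroinositol for PI, dehydroglycerophosphate
#: anion for CL.  Formulas are the ion formulas.
DIAGNOSTIC_IONS: dict[LipidClass, IonSpecies] = {}


def _make_diagnostic(cls: LipidClass, hill: str, adduct: Adduct, label: str) -> None:
    f = ElementalFormula.from_hill(hill)
    DIAGNOSTIC_IONS[cls] = IonSpecies(
        formula=f, adduct=adduct, charge_magnitude=1,
        theoretical_mz=ion_mz(f, adduct, 1), species=label,
    )


_make_diagnostic(LipidClass.PC, "C5H15NO4P", Adduct.CATION, "phosphocholine")
_make_diagnostic(LipidClass.PE, "C5H11NO5P", Adduct.ANION, "dehydro-glycerophosphoethanolamine")
_make_diagnostic(LipidClass.PI, "C6H10O8P", Adduct.ANION, "phospho-dehydroinositol")
_make_diagnostic(LipidClass.CL, "C3H6O5P", Adduct.ANION, "dehydroglycerophosphate")


# --------------------------------------------------------------------------
# Target list generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassEnumeration:
    """Enumeration range of one class for target-list generation."""

    lipid_class: LipidClass
    c_min: int
    c_max: int
    d_min: int = 0
    d_max: int = 8
    include_odd_c: bool = False

    def carbons(self) -> list[int]:
        step = 1 if self.include_odd_c else 2
        start = self.c_min
        if not self.include_odd_c and start % 2:
            start += 1
        return list(range(start, self.c_max + 1, step))


#: observed sum-composition spans of the four mitochondrial classes; PI and CL
#: additionally carry odd-carbon species.
DEFAULT_ENUMERATIONS = (
    ClassEnumeration(LipidClass.PC, 30, 40, 0, 8),
    ClassEnumeration(LipidClass.PC_O, 30, 40, 0, 8),
    ClassEnumeration(LipidClass.PE, 32, 42, 0, 8),
    ClassEnumeration(LipidClass.PE_O, 32, 42, 0, 8),
    ClassEnumeration(LipidClass.PI, 32, 40, 0, 8, include_odd_c=True),
    ClassEnumeration(LipidClass.CL, 64, 72, 0, 9, include_odd_c=True),
)


@dataclass(frozen=True)
class InternalStandard:
    """A spiked exogenous species quantifying one lipid class."""

    species: SumComposition
    deuterium: int = 0

    @property
    def label(self) -> str:
        lbl = self.species.label
        return f"{lbl} d{self.deuterium}" if self.deuterium else lbl


#: deuterated internal standards per class plus the exogenous CL 56:0
DEFAULT_INTERNAL_STANDARDS = (
    InternalStandard(SumComposition(LipidClass.PC, 33, 1), deuterium=7),
    InternalStandard(SumComposition(LipidClass.PE, 33, 1), deuterium=7),
    InternalStandard(SumComposition(LipidClass.PI, 33, 1), deuterium=7),
    InternalStandard(SumComposition(LipidClass.CL, 56, 0), deuterium=0),
)


def target_for(species: SumComposition, deuterium: int = 0,
               is_internal_standard: bool = False) -> IonSpecies:
    """Build the target-list entry for one species with its class adduct."""
    adduct, z = CLASS_ADDUCT[species.lipid_class]
    formula = formula_from_sum_composition(species, deuterium=deuterium)
    return IonSpecies(
        formula=formula, adduct=adduct, charge_magnitude=z,
        theoretical_mz=ion_mz(formula, adduct, z), species=species,
        is_internal_standard=is_internal_standard,
    )


def generate_target_list(
    enumerations: Iterable[ClassEnumeration] = DEFAULT_ENUMERATIONS,
    internal_standards: Iterable[InternalStandard] = DEFAULT_INTERNAL_STANDARDS,
    ambiguity_tol_mz: float = 0.05,
) -> list[IonSpecies]:
    """Enumerate one target per (class, C, D) plus internal-standard entries.

    Within a class, theoretical m/z values closer than the matching tolerance
    are logged as ambiguous but both targets are retained.
    """
    enumerations = list(enumerations)
    if not enumerations:
        raise ValueError("no class enumerations supplied")
    targets: list[IonSpecies] = []
    for enum_cfg in enumerations:
        if enum_cfg.c_min > enum_cfg.c_max or enum_cfg.d_min > enum_cfg.d_max:
            raise ValueError(f"empty enumeration range for {enum_cfg.lipid_class.value}")
        for c in enum_cfg.carbons():
            for d in range(enum_cfg.d_min, enum_cfg.d_max + 1):
                if d > c / 2:
                    continue
                targets.append(target_for(SumComposition(enum_cfg.lipid_class, c, d)))
    for is_cfg in internal_standards:
        targets.append(target_for(is_cfg.species, deuterium=is_cfg.deuterium,
                                  is_internal_standard=True))
    # flag near-isobaric targets inside each class
    by_class: dict[LipidClass, list[IonSpecies]] = {}
    for t in targets:
        by_class.setdefault(t.species.lipid_class, []).append(t)
    for cls, group in by_class.items():
        mzs = sorted(group, key=lambda t: t.theoretical_mz)
        for a, b in zip(mzs, mzs[1:]):
            if b.theoretical_mz - a.theoretical_mz < ambiguity_tol_mz:
                log.warning(
                    "ambiguous %s targets %s / %s separated by %.4f m/z",
                    cls.value, a.label, b.label, b.theoretical_mz - a.theoretical_mz,
                )
    return targets


# --------------------------------------------------------------------------
# Target-list TSV export/import
# --------------------------------------------------------------------------

_TARGET_COLUMNS = ("class", "C", "D", "adduct", "charge", "formula", "mz", "is_standard")


def write_target_list(targets: Sequence[IonSpecies], path: str | Path) -> None:
    lines = ["\t".join(_TARGET_COLUMNS)]
    for t in targets:
        sc = t.species
        if not isinstance(sc, SumComposition):
            raise ValueError("only sum-composition targets are exportable")
        lines.append("\t".join([
            sc.lipid_class.value, str(sc.carbons), str(sc.double_bonds),
            t.adduct.value, str(t.charge_magnitude), t.formula.hill(),
            f"{t.theoretical_mz:.6f}", "1" if t.is_internal_standard else "0",
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_target_list(path: str | Path) -> list[IonSpecies]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or tuple(lines[0].split("\t")) != _TARGET_COLUMNS:
        raise ValueError(f"not a target-list file: {path}")
    targets = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_TARGET_COLUMNS):
            raise ValueError(f"malformed target-list row at line {i}")
        cls, c, d, adduct, z, hill, mz, is_std = fields
        targets.append(IonSpecies(
            formula=ElementalFormula.from_hill(hill),
            adduct=Adduct(adduct), charge_magnitude=int(z),
            theoretical_mz=float(mz),
            species=SumComposition(LipidClass(cls), int(c), int(d)),
            is_internal_standard=is_std == "1",
        ))
    return targets
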