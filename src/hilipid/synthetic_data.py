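"""Forward model: ground-truth mitochondrial lipidomes rendered as HILIC runs.

``simulate_lipidome`` builds per-sample ground truth for a three-line design
(WT, OPA1-null, Mfn1/2-null; 3 biological x 3 extraction replicates): each
line has a template abundance surface per subclass (Gaussian in total carbons
and in double bonds) modulated by planted effects — ether-subclass incidence,
a shift of the mean unsaturation, loss of the longest cardiolipins — and each
sample multiplies the template by log-normal biological and extraction noise.

``simulate_run`` renders a sample into centroided full-scan + AIF scans: each
species contributes its aggregated isotopologue peaks scaled by a Gaussian
chromatographic band profile, with ppm mass error and multiplicative
intensity noise; peaks closer than the resolving-power-dependent FWHM merge
into one centroid, which is what creates the M+0/M+2 type-II interference
between species one double bond apart.  Deuterated internal standards are
rendered at the same effective spike level in every run.

The effect sizes are configuration choices reproducing the qualitative
directions of the study design; they are not measured values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .lipid_chem import (
    DEFAULT_ENUMERATIONS,
    DEFAULT_INTERNAL_STANDARDS,
    DIAGNOSTIC_IONS,
    ClassEnumeration,
    InternalStandard,
    IonSpecies,
    LipidClass,
    NEUTRON_GAIN,
    SumComposition,
    isotope_pattern,
    target_for,
)
from .quantify import CellLine, SampleRecord, class_ratios, full_design
from .spectra import Scan

log = logging.getLogger(__name__)

_LINE_INDEX = {line: i for i, line in enumerate(CellLine)}


# --------------------------------------------------------------------------
# Planted effects and abundance templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectConfig:
    """Per-line planted effects and class-ratio targets (configuration values).

    ``unsaturation_shift`` moves the mean double-bond count of every class;
    PI gets its own shifts so the two knockouts stay distinguishable there
    (the study design has WT < Mfn1/2-null < OPA1-null PI unsaturation).
    ``cl_c72_occupancy`` scales the abundance of 72-carbon cardiolipins,
    which are exclusive to WT by default.
    """

    pc_ether_ratio: Mapping[CellLine, float] = field(
        default_factory=lambda: {CellLine.WT: 0.50, CellLine.OPA1_KO: 0.40, CellLine.MFN12_KO: 0.25})
    pe_ether_ratio: Mapping[CellLine, float] = field(
        default_factory=lambda: {CellLine.WT: 0.90, CellLine.OPA1_KO: 0.60, CellLine.MFN12_KO: 0.35})
    unsaturation_shift: Mapping[CellLine, float] = field(
        default_factory=lambda: {CellLine.WT: 0.0, CellLine.OPA1_KO: 0.5, CellLine.MFN12_KO: 0.5})
    pi_unsaturation_shift: Mapping[CellLine, float] = field(
        default_factory=lambda: {CellLine.WT: 0.0, CellLine.OPA1_KO: 0.7, CellLine.MFN12_KO: 0.35})
    cl_c72_occupancy: Mapping[CellLine, float] = field(
        default_factory=lambda: {CellLine.WT: 1.0, CellLine.OPA1_KO: 0.0, CellLine.MFN12_KO: 0.0})
    pe_to_pc: float = 0.80
    pi_to_pc: float = 0.15
    cl_to_pc: Mapping[CellLine, float] = field(
        default_factory=lambda: {CellLine.WT: 0.30, CellLine.OPA1_KO: 0.27, CellLine.MFN12_KO: 0.23})
    pc_total_ug_ml: float = 30.0

    def __post_init__(self) -> None:
        for name in ("pc_ether_ratio", "pe_ether_ratio", "cl_c72_occupancy", "cl_to_pc"):
            values = getattr(self, name)
            if any(v < 0 for v in values.values()):
                raise ConfigError(f"negative multiplier in {name}")
        if self.pc_total_ug_ml <= 0 or self.pe_to_pc < 0 or self.pi_to_pc < 0:
            raise ConfigError("class totals and ratios must be non-negative")

    def subclass_totals(self, line: CellLine) -> dict[LipidClass, float]:
        pc = self.pc_total_ug_ml
        pe = self.pe_to_pc * pc
        return {
            LipidClass.PC: pc,
            LipidClass.PC_O: self.pc_ether_ratio[line] * pc,
            LipidClass.PE: pe,
            LipidClass.PE_O: self.pe_ether_ratio[line] * pe,
            LipidClass.PI: self.pi_to_pc * pc,
            LipidClass.CL: self.cl_to_pc[line] * pc,
        }


@dataclass(frozen=True)
class ClassShape:
    """Gaussian abundance surface of one subclass over (C, D)."""

    mu_c: float
    sigma_c: float
    mu_d: float
    sigma_d: float
    odd_c_weight: float = 0.05  # odd-carbon species are real but minor


#: typical sum-composition centers of the mitochondrial classes
DEFAULT_SHAPES: dict[LipidClass, ClassShape] = {
    LipidClass.PC: ClassShape(34.0, 2.0, 1.8, 1.3),
    LipidClass.PC_O: ClassShape(34.0, 2.0, 2.5, 1.5),
    LipidClass.PE: ClassShape(38.0, 2.0, 4.0, 1.6),
    LipidClass.PE_O: ClassShape(38.0, 2.0, 4.5, 1.6),
    LipidClass.PI: ClassShape(37.0, 1.6, 3.0, 1.4),
    LipidClass.CL: ClassShape(68.0, 2.0, 4.0, 1.8),
}


def line_template(
    line: CellLine,
    effects: EffectConfig = EffectConfig(),
    shapes: Mapping[LipidClass, ClassShape] = DEFAULT_SHAPES,
    enumerations: Iterable[ClassEnumeration] = DEFAULT_ENUMERATIONS,
    prune_fraction: float = 0.02,
) -> dict[SumComposition, float]:
    """Noise-free species concentrations (μg/ml) of one cell line.

    Species whose template weight falls below ``prune_fraction`` of the
    subclass maximum are dropped: real class spectra only yield species above
    a detectability floor relative to the base peak, and the default keeps
    the per-family species counts near those typically annotated in
    mitochondrial extracts (~60 PC, ~55 PE, ~20 PI, ~30 CL).
    """
    totals = effects.subclass_totals(line)
    template: dict[SumComposition, float] = {}
    for enum_cfg in enumerations:
        cls = enum_cfg.lipid_class
        shape = shapes[cls]
        if cls is LipidClass.PI:
            shift = effects.pi_unsaturation_shift[line]
        else:
            shift = effects.unsaturation_shift[line]
        mu_d = shape.mu_d + shift
        weights: dict[SumComposition, float] = {}
        for c in enum_cfg.carbons():
            for d in range(enum_cfg.d_min, enum_cfg.d_max + 1):
                if d > c / 2:
                    continue
                w = math.exp(-((c - shape.mu_c) ** 2) / (2 * shape.sigma_c ** 2))
                w *= math.exp(-((d - mu_d) ** 2) / (2 * shape.sigma_d ** 2))
                if c % 2:
                    w *= shape.odd_c_weight
                if cls is LipidClass.CL and c == 72:
                    w *= effects.cl_c72_occupancy[line]
                if w > 0:
                    weights[SumComposition(cls, c, d)] = w
        if not weights:
            continue
        peak = max(weights.values())
        weights = {sp: w for sp, w in weights.items() if w >= prune_fraction * peak}
        total_w = sum(weights.values())
        for sp, w in weights.items():
            template[sp] = w / total_w * totals[cls]
    return template


# --------------------------------------------------------------------------
# Ground-truth lipidomes per sample
# --------------------------------------------------------------------------

@dataclass
class GroundTruthLipidome:
    """True per-species concentrations of one sample."""

    sample: SampleRecord
    concentrations: dict[SumComposition, float]

    def subclass_totals(self) -> dict[LipidClass, float]:
        totals: dict[LipidClass, float] = {}
        for sp, conc in self.concentrations.items():
            totals[sp.lipid_class] = totals.get(sp.lipid_class, 0.0) + conc
        return totals

    def ratios(self, combined_denominators: bool = False) -> dict[str, float]:
        return class_ratios(self.subclass_totals(), combined_denominators)

    def family_fractions(self, family: LipidClass) -> dict[str, float]:
        members = {sp: c for sp, c in self.concentrations.items()
                   if sp.lipid_class.family is family}
        total = sum(members.values())
        if total <= 0:
            raise DataError(f"empty family {family.value} in ground truth")
        return {sp.label: c / total for sp, c in members.items()}


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size) - sigma * sigma / 2)


def simulate_lipidome(
    design: Sequence[SampleRecord] | None = None,
    effects: EffectConfig = EffectConfig(),
    cv_biological: float = 0.10,
    cv_extraction: float = 0.05,
    scale_cv: float = 0.10,
    seed: int = 0,
    shapes: Mapping[LipidClass, ClassShape] = DEFAULT_SHAPES,
    enumerations: Iterable[ClassEnumeration] = DEFAULT_ENUMERATIONS,
) -> dict[SampleRecord, GroundTruthLipidome]:
    """Ground-truth lipidomes for every sample of a design.

    Noise is applied per species: a biological factor shared by the extraction
    replicates of a pellet, an extraction factor per sample, and one shared
    pellet scale factor (overall mitochondrial yield) that cancels in every
    ratio and fraction.  Seeding is per (line, pellet, extract), so any subset
    design reproduces the corresponding samples of the full design.
    """
    if design is None:
        design = full_design()
    if any(cv < 0 for cv in (cv_biological, cv_extraction, scale_cv)):
        raise ConfigError("noise CVs must be non-negative")
    templates: dict[CellLine, dict[SumComposition, float]] = {}
    out: dict[SampleRecord, GroundTruthLipidome] = {}
    for rec in design:
        if rec.cell_line not in templates:
            templates[rec.cell_line] = line_template(
                rec.cell_line, effects, shapes, enumerations)
        template = templates[rec.cell_line]
        species = list(template)
        base = np.array([template[sp] for sp in species])
        li = _LINE_INDEX[rec.cell_line]
        rng_bio = np.random.default_rng(
            np.random.SeedSequence([seed, li, rec.biological_replicate, 0]))
        bio = _lognormal_factors(rng_bio, cv_biological, len(species))
        scale = float(_lognormal_factors(rng_bio, scale_cv, 1)[0])
        rng_ext = np.random.default_rng(
            np.random.SeedSequence([seed, li, rec.biological_replicate,
                                    rec.extraction_replicate]))
        ext = _lognormal_factors(rng_ext, cv_extraction, len(species))
        conc = base * bio * ext * scale
        out[rec] = GroundTruthLipidome(rec, dict(zip(species, conc)))
    return out


# --------------------------------------------------------------------------
# Instrument model and run rendering
# --------------------------------------------------------------------------

#: class elution apexes in minutes, following the head-group elution order
#: (PI < CL < PE < PC); ether subclasses trail their diacyl parent slightly.
DEFAULT_APEX_RT: dict[LipidClass, float] = {
    LipidClass.PI: 7.0,
    LipidClass.CL: 8.5,
    LipidClass.PE: 10.0,
    LipidClass.PE_O: 10.35,
    LipidClass.PC: 12.5,
    LipidClass.PC_O: 12.85,
}


@dataclass(frozen=True)
class InstrumentModel:
    """Acquisition and noise parameters of the rendered runs."""

    apex_rt: Mapping[LipidClass, float] = field(default_factory=lambda: dict(DEFAULT_APEX_RT))
    band_sigma_min: float = 0.10
    full_scan_interval_min: float = 0.10
    # mass error decomposes into a systematic per-run calibration offset,
    # slow scan-to-scan drift, and uncorrelated per-centroid jitter; the sum
    # stays inside the instrument's stated 5 ppm accuracy envelope
    run_calibration_ppm: float = 1.5
    scan_drift_ppm: float = 0.3
    centroid_jitter_ppm: float = 0.5
    intensity_cv: float = 0.03
    resolving_power: float = 140_000.0   # at m/z 200, sqrt(m/z) scaling
    # two peaks yield separate centroids only when parted by ~1.5 FWHM
    # (spectral resolution criterion); closer pairs merge into one centroid,
    # which makes the delta-D=1 M+0/M+2 interference systematic across the
    # precursor m/z range, as observed
    merge_fwhm_factor: float = 1.5
    n_isotopologues: int = 5
    aif_yield: float = 0.5
    response_per_ug_ml: Mapping[LipidClass, float] = field(default_factory=lambda: {
        LipidClass.PC: 1.0e6, LipidClass.PE: 8.0e5,
        LipidClass.PI: 6.0e5, LipidClass.CL: 5.0e5,
    })
    rt_range: Mapping[str, tuple[float, float]] = field(default_factory=lambda: {
        "negative": (6.2, 11.4), "positive": (11.8, 13.6),
    })
    spike_ug_ml: float = 3.0
    internal_standards: tuple[InternalStandard, ...] = DEFAULT_INTERNAL_STANDARDS

    def __post_init__(self) -> None:
        order = [self.apex_rt[c] for c in
                 (LipidClass.PI, LipidClass.CL, LipidClass.PE, LipidClass.PC)]
        if sorted(order) != order:
            raise ConfigError("class apexes must follow the PI < CL < PE < PC elution order")
        if self.run_calibration_ppm + self.scan_drift_ppm + self.centroid_jitter_ppm > 5:
            raise ConfigError("mass-error scale exceeds the 5 ppm accuracy envelope")
        if self.band_sigma_min <= 0 or self.full_scan_interval_min <= 0:
            raise ConfigError("band width and scan interval must be positive")

    def fwhm(self, mz: float | np.ndarray) -> float | np.ndarray:
        """Peak width at the resolving power R(mz) = R0 * sqrt(200 / mz)."""
        return mz ** 1.5 / (self.resolving_power * math.sqrt(200.0))


def _merge_centroids(mz: np.ndarray, intensity: np.ndarray,
                     instrument: InstrumentModel) -> tuple[np.ndarray, np.ndarray]:
    """Merge peaks closer than the local FWHM into intensity-weighted centroids."""
    if mz.size == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    out_mz, out_int = [], []
    wsum, isum = mz[0] * intensity[0], intensity[0]
    mean = mz[0]
    for m, i in zip(mz[1:], intensity[1:]):
        if m - mean <= instrument.merge_fwhm_factor * instrument.fwhm(mean):
            wsum += m * i
            isum += i
            mean = wsum / isum if isum > 0 else m
        else:
            out_mz.append(mean)
            out_int.append(isum)
            wsum, isum, mean = m * i, i, m
    out_mz.append(mean)
    out_int.append(isum)
    return np.asarray(out_mz), np.asarray(out_int)


def simulate_run(
    truth: GroundTruthLipidome,
    instrument: InstrumentModel = InstrumentModel(),
    polarity: str = "negative",
    seed: int | np.random.SeedSequence = 0,
) -> list[Scan]:
    """Render one sample into centroided full-scan + AIF scans of one polarity."""
    rng = np.random.default_rng(seed)
    sigma = instrument.band_sigma_min

    # species rendered in this polarity: endogenous + spiked internal standards
    rendered: list[tuple[SumComposition, float, IonSpecies]] = []
    for sp, conc in truth.concentrations.items():
        if sp.lipid_class.polarity == polarity and conc > 0:
            rendered.append((sp, conc, target_for(sp)))
    for is_cfg in instrument.internal_standards:
        if is_cfg.species.lipid_class.polarity == polarity:
            rendered.append((
                is_cfg.species, instrument.spike_ug_ml,
                target_for(is_cfg.species, deuterium=is_cfg.deuterium,
                           is_internal_standard=True),
            ))
    if not rendered:
        raise DataError(f"no species to render in {polarity} polarity")

    n_iso = instrument.n_isotopologues
    apexes = np.array([instrument.apex_rt[sp.lipid_class] for sp, _, _ in rendered])
    heights = np.array([
        conc * instrument.response_per_ug_ml[sp.lipid_class.family]
        for sp, conc, _ in rendered
    ])
    iso_mz = np.array([
        [ion.theoretical_mz + k * NEUTRON_GAIN / ion.charge_magnitude
         for k in range(n_iso + 1)]
        for _, _, ion in rendered
    ])
    iso_frac = np.array([
        isotope_pattern(ion.formula, n_iso).fractions for _, _, ion in rendered
    ])
    families = [sp.lipid_class.family for sp, _, _ in rendered]

    lo, hi = instrument.rt_range[polarity]
    times = np.arange(lo, hi + 1e-9, instrument.full_scan_interval_min)
    # calibration offsets are bounded in practice ("accuracy always better
    # than 5 ppm"): truncate the draw at 2 sigma
    cal = instrument.run_calibration_ppm * 1e-6
    run_offset = float(np.clip(rng.normal(0.0, cal), -2 * cal, 2 * cal))
    scans: list[Scan] = []
    for t in times:
        gauss = np.exp(-((t - apexes) ** 2) / (2 * sigma * sigma))
        active = np.nonzero(gauss > 1e-3)[0]

        # ---- MS1 full scan
        mz_list, int_list = [], []
        drift = 1.0 + run_offset + rng.normal(0.0, instrument.scan_drift_ppm * 1e-6)
        for si in active:
            base = heights[si] * gauss[si] * iso_frac[si]
            keep = base > 0
            if not keep.any():
                continue
            noise = _lognormal_factors(rng, instrument.intensity_cv, int(keep.sum()))
            jitter = 1.0 + rng.normal(0.0, instrument.centroid_jitter_ppm * 1e-6,
                                      int(keep.sum()))
            mz_list.append(iso_mz[si][keep] * drift * jitter)
            int_list.append(base[keep] * noise)
        if mz_list:
            mz, inten = _merge_centroids(np.concatenate(mz_list),
                                         np.concatenate(int_list), instrument)
        else:
            mz, inten = np.empty(0), np.empty(0)
        scans.append(Scan(float(t), polarity, "full_scan", mz, inten))

        # ---- AIF scan (diagnostic head-group fragments)
        t_aif = t + instrument.full_scan_interval_min / 2
        fam_signal: dict[LipidClass, float] = {}
        gauss_aif = np.exp(-((t_aif - apexes) ** 2) / (2 * sigma * sigma))
        for si in np.nonzero(gauss_aif > 1e-3)[0]:
            fam = families[si]
            fam_signal[fam] = fam_signal.get(fam, 0.0) + heights[si] * gauss_aif[si]
        frag_mz, frag_int = [], []
        drift = 1.0 + run_offset + rng.normal(0.0, instrument.scan_drift_ppm * 1e-6)
        for fam, signal in sorted(fam_signal.items(), key=lambda kv: kv[0].value):
            diag = DIAGNOSTIC_IONS[fam]
            noise = float(_lognormal_factors(rng, instrument.intensity_cv, 1)[0])
            frag_mz.append(diag.theoretical_mz * drift
                           * (1.0 + rng.normal(0.0, instrument.centroid_jitter_ppm * 1e-6)))
            frag_int.append(instrument.aif_yield * signal * noise)
        order = np.argsort(frag_mz)
        scans.append(Scan(
            float(t_aif), polarity, "AIF",
            np.asarray(frag_mz)[order], np.asarray(frag_int)[order],
        ))
    return scans


def simulate_cohort_runs(
    lipidomes: Mapping[SampleRecord, GroundTruthLipidome],
    instrument: InstrumentModel = InstrumentModel(),
    seed: int = 0,
) -> dict[SampleRecord, dict[str, list[Scan]]]:
    """Render both polarities for every sample, deterministically sub-seeded."""
    runs: dict[SampleRecord, dict[str, list[Scan]]] = {}
    for rec in sorted(lipidomes, key=lambda r: r.sort_key):
        li = _LINE_INDEX[rec.cell_line]
        runs[rec] = {
            pol: simulate_run(
                lipidomes[rec], instrument, pol,
                np.random.SeedSequence([seed, li, rec.biological_replicate,
                                        rec.extraction_replicate, pi]),
            )
            for pi, pol in enumerate(("positive", "negative"))
        }
    return runs
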