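"""Pipeline orchestration: simulate -> detect -> annotate -> quantify -> stats.

Each stage reads the previous stage's files from the output directory and
writes its own, so any stage can be re-run in isolation and ``run_pipeline``
chains the stages through those same files; ``analyze_cohort`` offers a
file-free path for repeated-cohort statistics.  Every CSV carries a
provenance header line (config hash + seed) as a ``#`` comment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .annotate_correct import (
    AnnotatedSpecies,
    annotate_and_correct,
    annotations_to_frame,
)
from .errors import ConfigError, DataError
from .lipid_chem import (
    DIAGNOSTIC_IONS,
    IonSpecies,
    LipidClass,
    SumComposition,
    generate_target_list,
    write_target_list,
)
from .quantify import (
    RATIO_NAMES,
    AggregationResult,
    CellLine,
    ClassProfile,
    SampleRecord,
    aggregate_replicates,
    class_ratios,
    estimate_concentrations,
    relative_abundances,
)
from .spectra import ClassSpectrum, Scan, average_spectrum, detect_class_band, read_run, write_run
from .stats_chemometrics import autoscale, run_hca, run_pca, tukey_hsd, heatmap_frame, export_heatmap_png
from .synthetic_data import (
    EffectConfig,
    GroundTruthLipidome,
    InstrumentModel,
    simulate_cohort_runs,
    simulate_lipidome,
)

log = logging.getLogger(__name__)

FAMILIES = (LipidClass.PC, LipidClass.PE, LipidClass.PI, LipidClass.CL)

_LINE_NAMES = {line.value: line for line in CellLine}


@dataclass(frozen=True)
class PipelineConfig:
    """All tolerances, thresholds and design parameters of one analysis."""

    outdir: str = "hilipid_out"
    seed: int = 0
    lines: tuple[str, ...] = tuple(line.value for line in CellLine)
    n_biological: int = 3
    n_extraction: int = 3
    match_tol_mz: float = 0.05
    xic_tol_ppm: float = 5.0
    cluster_tol_ppm: float = 5.0
    intensity_threshold: float = 0.01
    rsd_cutoff: float = 0.20
    band_rel_threshold: float = 0.05
    spike_ug_ml: float = 3.0
    overlap_fraction: float = 1.0
    combined_denominators: bool = False
    cv_biological: float = 0.10
    cv_extraction: float = 0.05
    scale_cv: float = 0.10
    write_heatmap_png: bool = False
    effects: EffectConfig = field(default_factory=EffectConfig)
    instrument: InstrumentModel = field(default_factory=InstrumentModel)

    def __post_init__(self) -> None:
        for name in ("match_tol_mz", "xic_tol_ppm", "cluster_tol_ppm", "spike_ug_ml"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("intensity_threshold", "rsd_cutoff", "band_rel_threshold"):
            if not 0 < getattr(self, name) < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")
        unknown = [l for l in self.lines if l not in _LINE_NAMES]
        if unknown:
            raise ConfigError(f"unknown cell line(s) {unknown}; expected {list(_LINE_NAMES)}")
        if self.n_biological < 1 or self.n_extraction < 1:
            raise ConfigError("replicate counts must be >= 1")

    # -- construction / provenance ------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        if "effects" in raw:
            kwargs["effects"] = _effects_from_dict(raw.pop("effects"))
        if "instrument" in raw:
            kwargs["instrument"] = _instrument_from_dict(raw.pop("instrument"))
        if "lines" in raw:
            raw["lines"] = tuple(raw["lines"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**raw, **kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                # the output location is not an analysis parameter
                return {f.name: encode(getattr(obj, f.name))
                        for f in dataclasses.fields(obj) if f.name != "outdir"}
            if isinstance(obj, Mapping):
                return {str(getattr(k, "value", k)): encode(v) for k, v in sorted(
                    obj.items(), key=lambda kv: str(getattr(kv[0], "value", kv[0])))}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            return getattr(obj, "value", obj)

        blob = json.dumps(encode(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def design(self) -> list[SampleRecord]:
        return [
            SampleRecord(_LINE_NAMES[line], b, e)
            for line in self.lines
            for b in range(1, self.n_biological + 1)
            for e in range(1, self.n_extraction + 1)
        ]


def _effects_from_dict(raw: Mapping) -> EffectConfig:
    raw = dict(raw)
    kwargs = {}
    per_line = {"pc_ether_ratio", "pe_ether_ratio", "unsaturation_shift",
                "pi_unsaturation_shift", "cl_c72_occupancy", "cl_to_pc"}
    for key, value in raw.items():
        if key in per_line:
            try:
                kwargs[key] = {_LINE_NAMES[k]: float(v) for k, v in value.items()}
            except KeyError as exc:
                raise ConfigError(f"unknown cell line in effects.{key}: {exc}") from exc
        else:
            kwargs[key] = value
    try:
        return EffectConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad effects config: {exc}") from exc


def _instrument_from_dict(raw: Mapping) -> InstrumentModel:
    raw = dict(raw)
    if "apex_rt" in raw:
        raw["apex_rt"] = {LipidClass(k): float(v) for k, v in raw["apex_rt"].items()}
    if "response_per_ug_ml" in raw:
        raw["response_per_ug_ml"] = {
            LipidClass(k): float(v) for k, v in raw["response_per_ug_ml"].items()}
    if "rt_range" in raw:
        raw["rt_range"] = {k: tuple(v) for k, v in raw["rt_range"].items()}
    try:
        return InstrumentModel(**raw)
    except TypeError as exc:
        raise ConfigError(f"bad instrument config: {exc}") from exc


# --------------------------------------------------------------------------
# Provenance-stamped CSV I/O
# --------------------------------------------------------------------------

def _write_csv(frame: pd.DataFrame, path: Path, cfg: PipelineConfig, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# hilipid config={cfg.config_hash()} seed={cfg.seed}\n")
        frame.to_csv(fh, index=index)


def _read_csv(path: Path, **kwargs) -> pd.DataFrame:
    if not path.exists():
        raise DataError(f"missing stage output {path}; run the preceding stage first")
    return pd.read_csv(path, comment="#", **kwargs)


def _sample_from_id(sample_id: str) -> SampleRecord:
    try:
        line, b, e = sample_id.rsplit("_", 2)
        return SampleRecord(_LINE_NAMES[line], int(b[1:]), int(e[1:]))
    except (ValueError, KeyError) as exc:
        raise DataError(f"cannot parse sample id {sample_id!r}") from exc


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> dict[SampleRecord, dict[str, list[Scan]]]:
    """Generate ground-truth lipidomes and rendered runs; write both."""
    out = Path(cfg.outdir)
    design = cfg.design()
    lipidomes = simulate_lipidome(
        design, cfg.effects, cfg.cv_biological, cfg.cv_extraction,
        cfg.scale_cv, seed=cfg.seed,
    )
    instrument = replace(cfg.instrument, spike_ug_ml=cfg.spike_ug_ml)
    runs = simulate_cohort_runs(lipidomes, instrument, seed=cfg.seed)

    truth_rows, ratio_rows = [], []
    for rec in design:
        truth = lipidomes[rec]
        for sp, conc in sorted(truth.concentrations.items(), key=lambda kv: kv[0].label):
            truth_rows.append({
                "sample": rec.sample_id, "cell_line": rec.cell_line.value,
                "subclass": sp.lipid_class.value, "species": sp.label,
                "C": sp.carbons, "D": sp.double_bonds, "concentration": conc,
            })
        ratio_rows.append({"sample": rec.sample_id, "cell_line": rec.cell_line.value,
                           **truth.ratios(cfg.combined_denominators)})
        for pol, tag in (("positive", "pos"), ("negative", "neg")):
            path = out / "runs" / f"{rec.sample_id}_{tag}.tsv"
            path.parent.mkdir(parents=True, exist_ok=True)
            write_run(runs[rec][pol], path)
    _write_csv(pd.DataFrame(truth_rows), out / "truth" / "lipidome.csv", cfg)
    _write_csv(pd.DataFrame(ratio_rows), out / "truth" / "ratios.csv", cfg)
    write_target_list(generate_target_list(), out / "target_list.tsv")
    return runs


def _load_runs(cfg: PipelineConfig) -> dict[SampleRecord, dict[str, list[Scan]]]:
    out = Path(cfg.outdir)
    runs = {}
    for rec in cfg.design():
        runs[rec] = {
            pol: read_run(out / "runs" / f"{rec.sample_id}_{tag}.tsv")
            for pol, tag in (("positive", "pos"), ("negative", "neg"))
        }
    return runs


def detect_sample_bands(
    runs: Mapping[str, list[Scan]], cfg: PipelineConfig
) -> dict[LipidClass, ClassSpectrum]:
    """Band detection + spectral averaging for one sample's two runs."""
    spectra = {}
    for family in FAMILIES:
        pol = family.polarity
        scans = runs[pol]
        aif = [s for s in scans if s.level == "AIF"]
        window = detect_class_band(
            aif, DIAGNOSTIC_IONS[family],
            tol_ppm=cfg.xic_tol_ppm, rel_threshold=cfg.band_rel_threshold,
        )
        spectrum = average_spectrum(scans, window, pol, cfg.cluster_tol_ppm)
        spectrum.lipid_class = family
        spectra[family] = spectrum
    return spectra


def stage_detect(
    cfg: PipelineConfig,
    runs: Mapping[SampleRecord, Mapping[str, list[Scan]]] | None = None,
) -> dict[SampleRecord, dict[LipidClass, ClassSpectrum]]:
    """Detect class bands and write averaged class spectra per sample."""
    out = Path(cfg.outdir)
    if runs is None:
        runs = _load_runs(cfg)
    all_spectra = {}
    band_rows = []
    for rec, sample_runs in runs.items():
        try:
            spectra = detect_sample_bands(sample_runs, cfg)
        except DataError as exc:
            raise DataError(f"detect stage failed for sample {rec.sample_id}: {exc}") from exc
        all_spectra[rec] = spectra
        for family, spectrum in spectra.items():
            band_rows.append({
                "sample": rec.sample_id, "family": family.value,
                "polarity": spectrum.polarity,
                "rt_start": spectrum.rt_window[0], "rt_end": spectrum.rt_window[1],
            })
            frame = pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity})
            name = f"{rec.sample_id}_{family.value.replace(' ', '')}.csv"
            _write_csv(frame, out / "spectra" / name, cfg)
    _write_csv(pd.DataFrame(band_rows), out / "bands.csv", cfg)
    return all_spectra


def stage_annotate(
    cfg: PipelineConfig,
    spectra: Mapping[SampleRecord, Mapping[LipidClass, ClassSpectrum]] | None = None,
    targets: Sequence[IonSpecies] | None = None,
) -> pd.DataFrame:
    """Match, filter and isotope-correct every class spectrum; write one table."""
    out = Path(cfg.outdir)
    if targets is None:
        targets = generate_target_list(ambiguity_tol_mz=cfg.match_tol_mz)
    if spectra is None:
        spectra = _load_spectra(cfg)
    by_family = {
        family: [t for t in targets if t.species.lipid_class.family is family]
        for family in FAMILIES
    }
    frames = []
    for rec, sample_spectra in spectra.items():
        for family, spectrum in sample_spectra.items():
            try:
                annotations = annotate_and_correct(
                    spectrum, by_family[family],
                    tol_mz=cfg.match_tol_mz,
                    threshold_fraction=cfg.intensity_threshold,
                    overlap_fraction=cfg.overlap_fraction,
                )
            except DataError as exc:
                raise DataError(
                    f"annotate stage failed for sample {rec.sample_id}, "
                    f"class {family.value}: {exc}"
                ) from exc
            frame = annotations_to_frame(annotations)
            frame.insert(0, "sample", rec.sample_id)
            frame.insert(1, "family", family.value)
            frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    _write_csv(table, out / "annotations.csv", cfg)
    return table


def _load_spectra(cfg: PipelineConfig) -> dict[SampleRecord, dict[LipidClass, ClassSpectrum]]:
    out = Path(cfg.outdir)
    bands = _read_csv(out / "bands.csv")
    spectra: dict[SampleRecord, dict[LipidClass, ClassSpectrum]] = {}
    for _, row in bands.iterrows():
        rec = _sample_from_id(row["sample"])
        family = LipidClass(row["family"])
        name = f"{row['sample']}_{family.value.replace(' ', '')}.csv"
        frame = _read_csv(out / "spectra" / name)
        spectrum = ClassSpectrum(
            polarity=row["polarity"],
            rt_window=(float(row["rt_start"]), float(row["rt_end"])),
            mz=frame["mz"].to_numpy(), intensity=frame["intensity"].to_numpy(),
            lipid_class=family,
        )
        spectra.setdefault(rec, {})[family] = spectrum
    return spectra


def _annotations_from_frame(frame: pd.DataFrame, cfg: PipelineConfig) -> list[AnnotatedSpecies]:
    """Rebuild annotation objects from the tidy table (for stage isolation)."""
    from .lipid_chem import DEFAULT_INTERNAL_STANDARDS, target_for

    is_by_subclass = {
        (s.species.lipid_class, s.species.carbons, s.species.double_bonds): s
        for s in DEFAULT_INTERNAL_STANDARDS
    }
    annotations = []
    for _, row in frame.iterrows():
        sc = SumComposition(LipidClass(row["subclass"]), int(row["C"]), int(row["D"]))
        if bool(row["is_standard"]):
            std = is_by_subclass.get((sc.lipid_class, sc.carbons, sc.double_bonds))
            if std is None:
                raise DataError(f"unknown internal standard {row['species']!r}")
            ion = target_for(sc, deuterium=std.deuterium, is_internal_standard=True)
        else:
            ion = target_for(sc)
        annotations.append(AnnotatedSpecies(
            ion=ion,
            experimental_mz=float(row["experimental_mz"]),
            raw_m0_intensity=float(row["raw_m0"]),
            type2_corrected_m0_intensity=float(row["corrected_m0"]),
            type1_corrected_total_intensity=float(row["corrected_total"]),
        ))
    return annotations


@dataclass
class QuantResult:
    quant: pd.DataFrame                  # per sample/species concentrations
    class_totals: pd.DataFrame           # per sample/subclass totals
    ratios: pd.DataFrame                 # per sample, the five ratios
    profiles: dict[LipidClass, AggregationResult]


def quantify_cohort(
    annotations_by_sample: Mapping[SampleRecord, Sequence[AnnotatedSpecies]],
    cfg: PipelineConfig,
) -> QuantResult:
    """Concentrations, ratios and RSD-aggregated profiles for a whole cohort."""
    quant_frames, totals_rows, ratio_rows = [], [], []
    profiles: dict[LipidClass, dict[SampleRecord, ClassProfile]] = {f: {} for f in FAMILIES}
    for rec in sorted(annotations_by_sample, key=lambda r: r.sample_id):
        anns = annotations_by_sample[rec]
        try:
            table = estimate_concentrations(anns, rec, cfg.spike_ug_ml)
            ratios = class_ratios(table, cfg.combined_denominators)
        except DataError as exc:
            raise DataError(f"quantify stage failed for sample {rec.sample_id}: {exc}") from exc
        quant_frames.append(table.to_frame())
        for sub, total in sorted(table.subclass_totals.items(), key=lambda kv: kv[0].value):
            totals_rows.append({"sample": rec.sample_id, "cell_line": rec.cell_line.value,
                                "subclass": sub.value, "total_concentration": total})
        ratio_rows.append({"sample": rec.sample_id, "cell_line": rec.cell_line.value,
                           "biological_replicate": rec.biological_replicate, **ratios})
        for family in FAMILIES:
            fam_anns = [a for a in anns if a.species.lipid_class.family is family]
            profiles[family][rec] = relative_abundances(fam_anns)

    aggregated = {
        family: aggregate_replicates(profiles[family], cfg.rsd_cutoff)
        for family in FAMILIES
    }
    return QuantResult(
        quant=pd.concat(quant_frames, ignore_index=True),
        class_totals=pd.DataFrame(totals_rows),
        ratios=pd.DataFrame(ratio_rows),
        profiles=aggregated,
    )


def stage_quantify(
    cfg: PipelineConfig, annotations: pd.DataFrame | None = None
) -> QuantResult:
    """Concentrations, class ratios, relative abundances and RSD aggregation."""
    out = Path(cfg.outdir)
    if annotations is None:
        annotations = _read_csv(out / "annotations.csv")
    by_sample = {
        _sample_from_id(sample_id): _annotations_from_frame(frame, cfg)
        for sample_id, frame in annotations.groupby("sample", sort=True)
    }
    result = quantify_cohort(by_sample, cfg)
    _write_csv(result.quant, out / "quant.csv", cfg)
    _write_csv(result.class_totals, out / "class_totals.csv", cfg)
    _write_csv(result.ratios, out / "ratios.csv", cfg)
    for family, agg in result.profiles.items():
        tag = family.value.replace(" ", "")
        _write_csv(agg.sample_table, out / f"profiles_{tag}.csv", cfg, index=True)
        excl = pd.DataFrame({"species": list(agg.excluded_species)})
        _write_csv(excl, out / f"excluded_{tag}.csv", cfg)
        matrix = agg.chemometrics_matrix.copy()
        matrix.insert(0, "cell_line", agg.cell_lines.values)
        _write_csv(matrix, out / f"chemometrics_{tag}.csv", cfg, index=True)
    return result


@dataclass
class StatsResult:
    tukey: pd.DataFrame
    pca: dict[LipidClass, object]
    hca: dict[LipidClass, object]


def stage_stats(cfg: PipelineConfig, quant: QuantResult | None = None) -> StatsResult:
    """Tukey HSD on the class ratios; PCA/HCA per intraclass profile."""
    out = Path(cfg.outdir)
    if quant is not None:
        ratios = quant.ratios
        matrices = {
            family: (agg.chemometrics_matrix, agg.cell_lines)
            for family, agg in quant.profiles.items()
        }
    else:
        ratios = _read_csv(out / "ratios.csv")
        matrices = {}
        for family in FAMILIES:
            tag = family.value.replace(" ", "")
            frame = _read_csv(out / f"chemometrics_{tag}.csv", index_col=0)
            matrices[family] = (frame.drop(columns="cell_line"), frame["cell_line"])

    # ratios per biological replicate (mean over extraction replicates), then Tukey
    tukey_rows = []
    bio_means = ratios.groupby(["cell_line", "biological_replicate"], sort=True)[
        list(RATIO_NAMES)].mean().reset_index()
    for ratio_name in RATIO_NAMES:
        groups = {
            line: bio_means.loc[bio_means["cell_line"] == line, ratio_name].to_numpy()
            for line in sorted(bio_means["cell_line"].unique())
        }
        groups = {k: v for k, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            log.warning("skipping Tukey for %s: fewer than two groups", ratio_name)
            continue
        table = tukey_hsd(groups)
        table.insert(0, "ratio", ratio_name)
        tukey_rows.append(table)
    tukey = pd.concat(tukey_rows, ignore_index=True) if tukey_rows else pd.DataFrame()
    _write_csv(tukey, out / "tukey.csv", cfg)

    pca_results, hca_results = {}, {}
    for family, (matrix, lines) in matrices.items():
        tag = family.value.replace(" ", "")
        scaled = autoscale(matrix)
        pca = run_pca(scaled, groups=pd.Series(lines.values, index=scaled.index))
        samples_hca = run_hca(scaled, axis="samples")
        variables_hca = run_hca(scaled, axis="variables")
        pca_results[family] = pca
        hca_results[family] = samples_hca
        _write_csv(pca.scores, out / f"pca_{tag}_scores.csv", cfg, index=True)
        _write_csv(pca.loadings, out / f"pca_{tag}_loadings.csv", cfg, index=True)
        _write_csv(pd.DataFrame({
            "component": [f"PC{i+1}" for i in range(pca.variance_fractions.size)],
            "variance_fraction": pca.variance_fractions,
        }), out / f"pca_{tag}_variance.csv", cfg)
        merges = pd.DataFrame(samples_hca.linkage,
                              columns=["left", "right", "height", "size"])
        _write_csv(merges, out / f"hca_{tag}_merges.csv", cfg)
        (out / f"hca_{tag}.nwk").write_text(samples_hca.newick() + "\n", encoding="utf-8")
        ordered = heatmap_frame(scaled, samples_hca, variables_hca)
        _write_csv(ordered, out / f"heatmap_{tag}.csv", cfg, index=True)
        if cfg.write_heatmap_png:
            export_heatmap_png(ordered, out / f"heatmap_{tag}.png")
    return StatsResult(tukey=tukey, pca=pca_results, hca=hca_results)


@dataclass
class PipelineResult:
    config: PipelineConfig
    annotations: pd.DataFrame
    quant: QuantResult
    stats: StatsResult


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """All stages chained through their files, so every stage sees exactly
    what a later isolated re-run would read; deterministic given the seed."""
    stage_simulate(cfg)
    stage_detect(cfg)
    annotations = stage_annotate(cfg)
    quant = stage_quantify(cfg, annotations)
    stats = stage_stats(cfg, quant)
    return PipelineResult(config=cfg, annotations=annotations, quant=quant, stats=stats)


def analyze_cohort(
    cfg: PipelineConfig, targets: Sequence[IonSpecies] | None = None
) -> tuple[dict[SampleRecord, GroundTruthLipidome], QuantResult]:
    """Simulate and analyze one cohort fully in memory (no files written).

    Returns the ground-truth lipidomes alongside the recovered quantification,
    for recovery scoring and repeated-cohort statistics.
    """
    design = cfg.design()
    lipidomes = simulate_lipidome(
        design, cfg.effects, cfg.cv_biological, cfg.cv_extraction,
        cfg.scale_cv, seed=cfg.seed,
    )
    instrument = replace(cfg.instrument, spike_ug_ml=cfg.spike_ug_ml)
    runs = simulate_cohort_runs(lipidomes, instrument, seed=cfg.seed)
    if targets is None:
        targets = generate_target_list(ambiguity_tol_mz=cfg.match_tol_mz)
    by_family = {
        family: [t for t in targets if t.species.lipid_class.family is family]
        for family in FAMILIES
    }
    annotations_by_sample: dict[SampleRecord, list[AnnotatedSpecies]] = {}
    for rec, sample_runs in runs.items():
        spectra = detect_sample_bands(sample_runs, cfg)
        anns: list[AnnotatedSpecies] = []
        for family, spectrum in spectra.items():
            anns.extend(annotate_and_correct(
                spectrum, by_family[family],
                tol_mz=cfg.match_tol_mz,
                threshold_fraction=cfg.intensity_threshold,
                overlap_fraction=cfg.overlap_fraction,
            ))
        annotations_by_sample[rec] = anns
    return lipidomes, quantify_cohort(annotations_by_sample, cfg)
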