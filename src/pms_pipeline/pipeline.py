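"""End-to-end orchestration: simulate -> map -> characterize -> statistics.

A run takes a single TOML config (one table per stage), flows one top-level
seed through every stochastic component, writes each stage's outputs under
the output directory with fixed file names, and consolidates everything into
a deterministic ``report.json`` carrying provenance (seed, config hash) and
a truth-vs-called comparison when simulated ground truth is available.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from .breakpoints import (
    NoJunctionError,
    assemble_junction,
    locate_breakpoints_from_pairs,
    merge_evidence,
    normalize_depth,
    segment_depth,
)
from .datatypes import Region, RegionSet, SchemaError
from .mendel import build_error_profile, call_candidate_regions, hemizygosity_consistency
from .simulate import SIRE_ID, CohortBundle, SimulationConfig, simulate_cohort
from .stats import LethalityConfig, inheritance_report

log = logging.getLogger("pms_pipeline")

__version__ = "0.1.0"


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: Path = Path("out")
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # mendel-scan parameters
    min_affected_errors: int = 2
    max_gap_bp: int = 1_000_000
    min_cluster_size: int = 5
    het_penalty: float = 1.0
    # breakpoint parameters
    insert_z: float = 4.0
    min_support: int = 3
    lethality: LethalityConfig = field(default_factory=LethalityConfig)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "simulation": dataclasses.asdict(self.simulation),
                "mendel": [
                    self.min_affected_errors,
                    self.max_gap_bp,
                    self.min_cluster_size,
                    self.het_penalty,
                ],
                "breakpoint": [self.insert_z, self.min_support],
                "lethality": dataclasses.asdict(self.lethality),
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_RATE_FIELDS = {
    "germline_mosaicism",
    "male_lethality",
    "genotyping_error_rate",
    "hemizygote_nocall_rate",
}


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as e:
            raise ConfigError(f"{path}: {e}") from None
    if "seed" not in raw:
        raise ConfigError("missing required key 'seed'")
    cfg = RunConfig(seed=int(raw["seed"]))
    if "out_dir" in raw:
        cfg.out_dir = Path(raw["out_dir"])
    sim_raw = raw.get("simulation", {})
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key, value in sim_raw.items():
        if key not in sim_fields:
            raise ConfigError(f"unknown simulation key {key!r}")
        if key in _RATE_FIELDS and not 0.0 <= float(value) <= 1.0:
            raise ConfigError(f"simulation.{key} out of range [0, 1]: {value}")
        setattr(cfg.simulation, key, value)
    cfg.simulation.seed = cfg.seed
    for section, keys in {
        "mendel": ["min_affected_errors", "max_gap_bp", "min_cluster_size", "het_penalty"],
        "breakpoint": ["insert_z", "min_support"],
    }.items():
        for key, value in raw.get(section, {}).items():
            if key not in keys:
                raise ConfigError(f"unknown {section} key {key!r}")
            setattr(cfg, key, value)
    if "lethality" in raw:
        try:
            cfg.lethality = LethalityConfig(**raw["lethality"])
        except (TypeError, ValueError) as e:
            raise ConfigError(f"lethality section: {e}") from None
    try:
        cfg.simulation.validate()
    except ValueError as e:
        raise ConfigError(str(e)) from None
    return cfg


@dataclass
class RunReport:
    data: dict

    def write(self, path: str | Path) -> None:
        pio.write_json(self.data, path)


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: RunConfig, write_outputs: bool = True) -> RunReport:
    """Run simulate -> mendel scan -> depth/breakpoint -> stats end to end."""
    out = Path(cfg.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    log.info("[simulate] seed=%d", cfg.seed)
    try:
        bundle = simulate_cohort(cfg.simulation)
    except Exception as e:  # pragma: no cover - config pre-validated
        raise StageFailure("simulate", e) from e
    if write_outputs:
        write_bundle(bundle, out)

    log.info("[mendelscan] %d markers", len(bundle.marker_map))
    try:
        profile = build_error_profile(bundle.genotypes, bundle.pedigree, SIRE_ID)
        regions = call_candidate_regions(
            profile,
            bundle.marker_map,
            min_affected_errors=cfg.min_affected_errors,
            max_gap_bp=cfg.max_gap_bp,
            min_cluster_size=cfg.min_cluster_size,
            het_penalty=cfg.het_penalty,
        )
        hemi_fraction = None
        if regions:
            hemi_fraction = hemizygosity_consistency(
                regions[0].as_region(),
                bundle.genotypes,
                bundle.pedigree,
                bundle.truth.carrier_ids,
                bundle.marker_map,
            )
    except Exception as e:
        raise StageFailure("mendelscan", e) from e
    if write_outputs and regions:
        pio.write_bed(
            RegionSet([r.as_region() for r in regions]), out / "regions.bed"
        )

    log.info("[depthscan]")
    try:
        ratio = normalize_depth(bundle.depth_carrier)
        segments = segment_depth(ratio)
    except Exception as e:
        raise StageFailure("depthscan", e) from e

    log.info("[breakpoint] %d evidence records", len(bundle.pairs))
    junction = None
    try:
        try:
            bracket = locate_breakpoints_from_pairs(
                bundle.pairs,
                bundle.config.insert_mean,
                bundle.config.insert_sd,
                z=cfg.insert_z,
            )
            junction = assemble_junction(
                bundle.pairs,
                bundle.reference.fetch,
                bracket,
                min_support=cfg.min_support,
            )
        except NoJunctionError as e:
            log.info("[breakpoint] no junction: %s", e)
        call = merge_evidence(segments, junction)
    except Exception as e:
        raise StageFailure("breakpoint", e) from e
    if write_outputs:
        pio.write_json(_call_dict(call), out / "deletion_call.json")

    log.info("[stats]")
    try:
        report = inheritance_report(
            birth=bundle.counts["birth"],
            sperm=bundle.counts["sperm"],
            blastocyst=bundle.counts["blastocyst"],
            sperm_experiments=bundle.sperm_experiments,
            ai_records=bundle.ai_records,
            lethality_cfg=cfg.lethality,
        )
    except Exception as e:
        raise StageFailure("stats", e) from e

    truth = bundle.truth
    truth_region = truth.deleted_interval
    top_region = regions[0].as_region() if regions else None
    recovery = {
        "region_overlaps_truth": bool(top_region and top_region.overlaps(truth_region)),
        "junction_exact": bool(
            junction
            and junction.left_flank == truth.left_flank
            and junction.right_flank == truth.right_flank
            and junction.inserted_seq == truth.inserted_seq
        ),
        "mosaicism_truth": truth.germline_mosaicism,
        "lethality_truth": truth.male_lethality,
    }
    concordant = bool(top_region and top_region.overlaps(call.interval))

    data = {
        "provenance": {
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "version": __version__,
        },
        "candidate_regions": [dataclasses.asdict(r) for r in regions],
        "hemizygosity_consistency": hemi_fraction,
        "deletion_call": _call_dict(call),
        "evidence_concordant": concordant,
        "inheritance": report.to_dict(),
        "truth_recovery": recovery,
    }
    run_report = RunReport(data)
    if write_outputs:
        run_report.write(out / "report.json")
    return run_report


def _call_dict(call) -> dict:
    d = {
        "chrom": call.chrom,
        "start": call.interval.start,
        "end": call.interval.end,
        "length_bp": call.length_bp,
        "flags": call.flags,
    }
    if call.junction is not None:
        d.update(
            left_flank=call.junction.left_flank,
            right_flank=call.junction.right_flank,
            inserted_seq=call.junction.inserted_seq,
            support=call.junction.support,
        )
    return d


def write_bundle(bundle: CohortBundle, out: Path) -> None:
    """Write every simulated component in its on-disk format, plus truth."""
    out.mkdir(parents=True, exist_ok=True)
    pio.write_pedigree(bundle.pedigree, out / "pedigree.tsv")
    pio.write_marker_map(bundle.marker_map, out / "markers.tsv")
    pio.write_genotypes(bundle.genotypes, out / "genotypes.tsv")
    pio.write_depth(bundle.depth_carrier, out / "depth_carrier.tsv")
    pio.write_depth(bundle.depth_control, out / "depth_control.tsv")
    pio.write_pairs(bundle.pairs, out / "pairs.tsv")
    pio.write_counts(bundle.counts, out / "counts.tsv")
    pio.write_ai_records(bundle.ai_records, out / "ai_records.csv")
    truth = bundle.truth.to_dict()
    truth["sperm_experiments"] = bundle.sperm_experiments
    pio.write_json(truth, out / "truth.json")
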