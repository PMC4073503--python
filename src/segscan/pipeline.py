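"""End-to-end pipeline: simulate -> ferment -> popstats -> bsa.

A single :class:`PipelineConfig` (YAML round-trippable) drives the whole
chain.  One global seed fans out into named per-stage substreams via
``numpy.random.SeedSequence`` spawn keys, so each stage can be rerun
independently yet reproducibly, and two runs with the same config produce
byte-identical outputs and manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, bsa, ferment, io, popstats, simulate
from .errors import ConfigError

log = logging.getLogger("segscan")

STAGES = ("cross", "phenotype", "curves", "signals")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named, reproducible substream of the global seed for one stage."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(STAGES.index(stage),))
    )


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_markers: int = 6318
    genetic_rate: float = 0.35
    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    model: simulate.QTLEffectModel = field(
        default_factory=simulate.QTLEffectModel.default_model
    )
    scan: bsa.ScanParameters = field(default_factory=bsa.ScanParameters)
    checkpoint_h: float = 89.0
    volume_L: float = 1.2
    duration_h: float = 120.0
    curve_noise_sd: float = 0.01

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"]["loci"] = [dataclasses.asdict(l) for l in self.model.loci]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = simulate.SimulationConfig(**d["sim"])
        if "model" in d:
            m = dict(d["model"])
            m["loci"] = tuple(simulate.QTLLocus(**l) for l in m.get("loci", ()))
            d["model"] = simulate.QTLEffectModel(**m)
        if "scan" in d:
            d["scan"] = bsa.ScanParameters(**d["scan"])
        return cls(**d)

    def to_yaml(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def parameter_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, str]:
    """Execute the full chain, writing every artifact under ``outdir``.

    Stages: synthetic cross -> planted phenotypes -> fermentation curves ->
    checkpoint phenotype extraction -> heritability/transgression report ->
    bulk selection -> pooled signals -> QTL scan.  Returns a name -> path
    mapping of the written artifacts.  Errors from any stage abort the run
    with the failing stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    marker_map = _stage(
        "map", lambda: simulate.MarkerMap.default_map(config.n_markers, config.genetic_rate)
    )
    io.write_marker_map(marker_map, outdir / "marker_map.tsv")
    paths["marker_map"] = str(outdir / "marker_map.tsv")

    population = _stage(
        "cross",
        lambda: simulate.make_f2_population(marker_map, config.sim, stage_rng(config.seed, "cross")),
    )
    io.write_genotypes(population, marker_map, outdir / "genotypes.tsv")
    paths["genotypes"] = str(outdir / "genotypes.tsv")

    planted = _stage(
        "phenotype",
        lambda: simulate.assign_phenotypes(
            population, config.model, config.sim, marker_map, stage_rng(config.seed, "phenotype")
        ),
    )

    def _curves():
        rng = stage_rng(config.seed, "curves")
        curves = {
            row.strain: simulate.simulate_fermentation_curve(
                row.co2_at_checkpoint,
                duration_h=config.duration_h,
                rng=rng,
                noise_sd=config.curve_noise_sd,
                checkpoint_h=config.checkpoint_h,
            )
            for row in planted.itertuples()
        }
        measured = planted.copy()
        measured["co2_at_checkpoint"] = [
            ferment.phenotype_at(curves[s], config.checkpoint_h) for s in measured["strain"]
        ]
        return curves, measured

    curves, phenotypes = _stage("curves", _curves)
    io.write_curves(curves, outdir / "curves.csv")
    io.write_phenotypes(phenotypes, outdir / "phenotypes.csv")
    paths["curves"] = str(outdir / "curves.csv")
    paths["phenotypes"] = str(outdir / "phenotypes.csv")

    def _stats():
        seg = phenotypes.loc[phenotypes["group"] == "segregant", "co2_at_checkpoint"]
        pa = phenotypes.loc[phenotypes["group"] == "parentA", "co2_at_checkpoint"]
        pb = phenotypes.loc[phenotypes["group"] == "parentB", "co2_at_checkpoint"]
        h2 = popstats.heritability(seg, pa, pb)
        tr = popstats.transgression(seg, pa, pb)
        return {
            "n_segregants": int(len(seg)),
            "heritability_percent": h2.H2_percent,
            "var_seg": h2.var_seg,
            "var_env": h2.var_env,
            "negative_estimate": h2.negative_estimate,
            "transgression": {
                "n_high": tr.n_high,
                "n_low": tr.n_low,
                "percent": tr.percent,
                "sigma": tr.sigma,
                "low_cut": tr.thresholds[0],
                "high_cut": tr.thresholds[1],
            },
        }

    stats = _stage("stats", _stats)
    (outdir / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))
    paths["stats"] = str(outdir / "stats.json")

    low, high = _stage(
        "bulks", lambda: popstats.select_bulks(phenotypes, k=config.sim.bulk_size)
    )
    (outdir / "bulks.json").write_text(
        json.dumps({"bulk_low": low, "bulk_high": high}, indent=2)
    )
    paths["bulks"] = str(outdir / "bulks.json")

    signals = _stage(
        "signals",
        lambda: simulate.simulate_signal_table(
            population, low, high, marker_map, config.sim, stage_rng(config.seed, "signals")
        ),
    )
    io.write_signals(signals, outdir / "signals.tsv")
    paths["signals"] = str(outdir / "signals.tsv")

    probes, scan, regions = _stage("bsa", lambda: bsa.scan_table(signals, config.scan))
    io.write_windows(scan.windows, outdir / "windows.tsv")
    io.write_regions_tsv(regions, outdir / "regions.tsv")
    io.write_regions_bed(regions, outdir / "regions.bed")
    paths["windows"] = str(outdir / "windows.tsv")
    paths["regions_tsv"] = str(outdir / "regions.tsv")
    paths["regions_bed"] = str(outdir / "regions.bed")

    manifest = {
        "segscan_version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "artifacts": sorted(Path(p).name for p in paths.values()),
        "n_informative_probes": int(probes["selected"].sum()),
        "n_regions": len(regions),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = str(outdir / "manifest.json")
    return paths
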