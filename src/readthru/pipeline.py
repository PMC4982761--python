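"""End-to-end orchestration: simulate/load -> quantify -> classify -> profile -> test.

A single YAML config drives the run; every stage writes a TSV intermediate
and the final JSON report carries the resolved config, per-stage row
counts, the classification summary, KS results, and a sha256 manifest of
every written file. Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations_io import (
    StrandedCoverage,
    load_stranded_tags,
    read_gene_models,
    write_gene_models_bed12,
    write_tags_bed6,
)
from .classify import ClassifierConfig, classify_all
from .metagene import ProfileSpec, average_profile, scaled_metagene
from .quantify import condition_means, quantify_all
from .stats import ks_two_sample
from .synthetic_data import SimulationConfig, simulate_annotation, simulate_library

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 in the CLI)."""


@dataclass
class TagFileSpec:
    condition: str
    replicate: int
    path: str


@dataclass
class PipelineConfig:
    seed: int = 0
    window_bp: int = 5000
    control: str = "control"
    treatment: str = "perturbed"
    simulation: SimulationConfig | None = None
    annotation: str | None = None
    annotation_dialect: str = "bed12"
    chrom_length: int | None = None
    tag_files: list[TagFileSpec] = field(default_factory=list)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    profiles: dict[str, ProfileSpec] = field(default_factory=dict)
    ks_mode: str = "profile"  # 'profile', 'per_gene', or 'both'

    def resolved_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "window_bp": self.window_bp,
            "conditions": {"control": self.control, "treatment": self.treatment},
            "classifier": dataclasses.asdict(self.classifier),
            "profiles": {
                name: dataclasses.asdict(spec) for name, spec in self.profiles.items()
            },
            "stats": {"ks_mode": self.ks_mode},
            "version": __version__,
        }
        d["classifier"]["tier_bounds"] = list(self.classifier.tier_bounds)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        else:
            d["inputs"] = {
                "annotation": self.annotation,
                "annotation_dialect": self.annotation_dialect,
                "chrom_length": self.chrom_length,
                "tags": [dataclasses.asdict(t) for t in self.tag_files],
            }
        return d


_TOP_KEYS = {
    "seed", "window_bp", "conditions", "simulation", "inputs",
    "classifier", "profiles", "stats",
}

_DEFAULT_PROFILES = {
    "tts_fixed": {"anchor": "tts", "upstream_bp": 1000, "downstream_bp": 5000, "bin_bp": 50},
    "scaled_body": {
        "anchor": "scaled", "upstream_bp": 3000, "downstream_bp": 3000,
        "bin_bp": 50, "body_bins": 60,
    },
}


def validate_config(source: str | dict) -> PipelineConfig:
    """Parse and validate a pipeline config; fill and record all defaults.

    Unknown keys are rejected at every level (typo safety). Exactly one of
    a ``simulation`` block or an ``inputs`` block must be present.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("pipeline config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if ("simulation" in raw) == ("inputs" in raw):
        raise ConfigError("exactly one of 'simulation' or 'inputs' must be given")

    try:
        cfg = PipelineConfig()
        cfg.seed = int(raw.get("seed", 0))
        cfg.window_bp = int(raw.get("window_bp", 5000))
        if cfg.window_bp <= 0:
            raise ConfigError("window_bp must be > 0")

        cond = raw.get("conditions", {})
        if not isinstance(cond, dict) or set(cond) - {"control", "treatment"}:
            raise ConfigError("conditions block accepts only 'control' and 'treatment'")

        cls_block = dict(raw.get("classifier", {}))
        known_cls = {f.name for f in dataclasses.fields(ClassifierConfig)}
        bad = set(cls_block) - known_cls
        if bad:
            raise ConfigError(f"unknown classifier keys: {sorted(bad)}")
        if "tier_bounds" in cls_block:
            cls_block["tier_bounds"] = tuple(cls_block["tier_bounds"])
        cls_block.setdefault("window_bp", cfg.window_bp)
        cfg.classifier = ClassifierConfig(**cls_block)

        prof_block = raw.get("profiles", None)
        if prof_block is None:
            prof_block = _DEFAULT_PROFILES
        if not isinstance(prof_block, dict):
            raise ConfigError("profiles must be a mapping of name -> spec")
        known_prof = {f.name for f in dataclasses.fields(ProfileSpec)}
        for name, spec in prof_block.items():
            bad = set(spec) - known_prof
            if bad:
                raise ConfigError(f"profile {name!r}: unknown keys {sorted(bad)}")
            cfg.profiles[name] = ProfileSpec(**spec)

        stats_block = dict(raw.get("stats", {}))
        if set(stats_block) - {"ks_mode"}:
            raise ConfigError("stats block accepts only 'ks_mode'")
        cfg.ks_mode = stats_block.get("ks_mode", "profile")
        if cfg.ks_mode not in ("profile", "per_gene", "both"):
            raise ConfigError("ks_mode must be 'profile', 'per_gene' or 'both'")

        if "simulation" in raw:
            sim_block = dict(raw["simulation"] or {})
            sim_block.setdefault("seed", cfg.seed)
            cfg.simulation = SimulationConfig.from_dict(sim_block)
            cfg.control = cond.get("control", cfg.simulation.conditions[0])
            cfg.treatment = cond.get("treatment", cfg.simulation.conditions[1])
            if {cfg.control, cfg.treatment} != set(cfg.simulation.conditions):
                raise ConfigError(
                    f"conditions {cfg.control!r}/{cfg.treatment!r} do not match "
                    f"simulated conditions {cfg.simulation.conditions}"
                )
            cfg.chrom_length = cfg.simulation.chrom_length
        else:
            inp = dict(raw["inputs"] or {})
            bad = set(inp) - {"annotation", "annotation_dialect", "chrom_length", "tags"}
            if bad:
                raise ConfigError(f"unknown inputs keys: {sorted(bad)}")
            if "annotation" not in inp or "tags" not in inp:
                raise ConfigError("inputs block needs 'annotation' and 'tags'")
            cfg.annotation = inp["annotation"]
            cfg.annotation_dialect = inp.get("annotation_dialect", "bed12")
            cfg.chrom_length = inp.get("chrom_length")
            cfg.tag_files = [
                TagFileSpec(str(t["condition"]), int(t["replicate"]), str(t["path"]))
                for t in inp["tags"]
            ]
            labels = {t.condition for t in cfg.tag_files}
            if "control" not in cond or "treatment" not in cond:
                raise ConfigError("inputs mode requires explicit conditions block")
            cfg.control, cfg.treatment = cond["control"], cond["treatment"]
            for label in (cfg.control, cfg.treatment):
                if label not in labels:
                    raise ConfigError(f"condition {label!r} has no tag files")
    except (ValueError, TypeError, KeyError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
    return cfg


@dataclass
class RunReport:
    version: str
    config: dict
    row_counts: dict
    call_summary: dict
    ks_results: dict
    manifest: dict  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_profile_tsv(path: str, profile, values: np.ndarray) -> None:
    df = pd.DataFrame(
        {
            "bin_index": np.arange(values.size),
            "offset": profile.offsets_bp(),
            "mean": values,
            "n_genes": profile.n_genes,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir: str) -> RunReport:
    """Run every stage in fixed order, writing intermediates under ``outdir``.

    A ``.partial`` marker is present while the run is incomplete; it is
    removed only after the report has been written.
    """
    os.makedirs(outdir, exist_ok=True)
    marker = os.path.join(outdir, ".partial")
    with open(marker, "w") as fh:
        fh.write("run in progress or failed\n")

    manifest_files: list[str] = []
    row_counts: dict = {}

    def out(name: str) -> str:
        manifest_files.append(name)
        return os.path.join(outdir, name)

    try:
        # --- stage 1: inputs -------------------------------------------------
        if config.simulation is not None:
            sim = config.simulation
            logger.info("[simulate] %d genes, seed %d", sim.n_genes, sim.seed)
            models, truth = simulate_annotation(sim)
            libraries = []
            for condition in sim.conditions:
                for rep in range(1, sim.n_replicates + 1):
                    cov = simulate_library(models, truth, condition, rep, sim)
                    libraries.append(cov)
                    write_tags_bed6(cov, out(f"{condition}_{rep}.bed6"))
            write_gene_models_bed12(models, out("genes.bed12"))
            truth.to_csv(out("truth.tsv"), sep="\t", index=False, float_format="%.10g")
            with open(out("config_resolved.yaml"), "w") as fh:
                yaml.safe_dump(config.resolved_dict(), fh, sort_keys=True)
        else:
            logger.info("[load] annotation %s", config.annotation)
            models = read_gene_models(config.annotation, config.annotation_dialect)
            libraries = [
                load_stranded_tags(t.path, t.condition, t.replicate)
                for t in config.tag_files
            ]
        row_counts["genes"] = len(models)
        row_counts["libraries"] = len(libraries)

        # --- stage 2: quantify ----------------------------------------------
        logger.info("[quantify] window %d bp", config.window_bp)
        quants = quantify_all(
            models, libraries, window_bp=config.window_bp,
            chrom_length=config.chrom_length,
        )
        quants.to_csv(out("quant.tsv"), sep="\t", index=False, float_format="%.10g")
        row_counts["quant_rows"] = len(quants)

        # --- stage 3: classify ----------------------------------------------
        logger.info("[classify] %s vs %s", config.treatment, config.control)
        calls = classify_all(
            models, quants, config.control, config.treatment,
            config.classifier, chrom_length=config.chrom_length,
        )
        calls.to_csv(out("calls.tsv"), sep="\t", index=False, float_format="%.10g")
        summary = calls["call"].value_counts().to_dict()
        call_summary = {k: int(summary.get(k, 0)) for k in
                        ("up", "down", "unchanged", "excluded_overlap", "excluded_low")}
        row_counts["call_rows"] = len(calls)

        # --- stage 4: profiles ----------------------------------------------
        by_condition: dict[str, list[StrandedCoverage]] = {}
        for cov in libraries:
            by_condition.setdefault(cov.condition, []).append(cov)
        profile_values: dict[str, dict[str, np.ndarray]] = {}
        for name, spec in config.profiles.items():
            profile_values[name] = {}
            for condition in (config.control, config.treatment):
                per_lib = []
                prof = None
                for cov in by_condition[condition]:
                    fn = scaled_metagene if spec.anchor == "scaled" else average_profile
                    prof = fn(models, cov, spec, chrom_length=config.chrom_length)
                    per_lib.append(prof.values)
                vals = np.nanmean(np.vstack(per_lib), axis=0)
                profile_values[name][condition] = vals
                _write_profile_tsv(out(f"profile_{name}_{condition}.tsv"), prof, vals)
        row_counts["profiles"] = len(config.profiles)

        # --- stage 5: stats --------------------------------------------------
        ks_results: dict = {}
        if config.ks_mode in ("profile", "both"):
            for name, per_cond in profile_values.items():
                a = per_cond[config.control]
                b = per_cond[config.treatment]
                mask = ~(np.isnan(a) | np.isnan(b))
                res = ks_two_sample(a[mask], b[mask])
                ks_results[f"profile:{name}"] = {
                    "D": res.statistic, "p": res.p_value,
                    "n1": res.n1, "n2": res.n2, "mode": "per-bin average profile",
                }
        if config.ks_mode in ("per_gene", "both"):
            means = condition_means(quants)
            piv = means.pivot(index="gene_id", columns="condition", values="rt_fpkm")
            res = ks_two_sample(
                piv[config.control].to_numpy(), piv[config.treatment].to_numpy()
            )
            ks_results["per_gene:rt_fpkm"] = {
                "D": res.statistic, "p": res.p_value,
                "n1": res.n1, "n2": res.n2, "mode": "per-gene read-through FPKM",
            }

        # --- report -----------------------------------------------------------
        manifest = {name: _sha256(os.path.join(outdir, name)) for name in manifest_files}
        report = RunReport(
            version=__version__,
            config=config.resolved_dict(),
            row_counts=row_counts,
            call_summary=call_summary,
            ks_results=ks_results,
            manifest=manifest,
        )
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            fh.write(report.to_json() + "\n")
    except Exception:
        logger.error("pipeline failed; partial-run marker left in %s", outdir)
        raise
    os.remove(marker)
    return report
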