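"""Pipeline orchestration with plain-file handoff and provenance manifest.

Stages (prefix-closed chain): simulate -> count -> qc -> test -> call-hits;
interactome runs independently. Every stage reads and writes plain TSV/FASTQ
under the run's output directory, and the run writes a manifest recording the
seed, a hash of the configuration, package versions and a checksum of every
artifact, so a rerun with identical inputs and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .deconvolve import CountMatrix, count_samples, representation_stats
from .hits import (
    HitRuleConfig,
    call_genes_screen,
    consolidate_screens,
    flag_table,
    median_fold_change,
    per_mouse_fold_changes,
)
from .library import (
    ShrnaLibrary,
    load_library,
    load_sample_sheet,
    make_dub_library,
    write_library,
    write_sample_sheet,
)
from .simulate import EffectModel, ScreenSimParams, simulate_screen, write_screen_fastq
from .stats import differential_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

STAGES = ("simulate", "count", "qc", "test", "call-hits")
_DEPENDS = {
    "simulate": None,
    "count": "simulate",
    "qc": "count",
    "test": "count",
    "call-hits": "test",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Run configuration: paths, per-stage parameter blocks, global seed."""

    outdir: Path
    seed: int = 0
    library: str | None = None  # path, or None for the packaged synthetic library
    screens: list = field(default_factory=lambda: ["primary", "secondary"])
    sim: dict = field(default_factory=dict)  # ScreenSimParams overrides + effects
    emit_fastq: bool = False
    tissue: str = "BM"
    hits: dict = field(default_factory=dict)  # HitRuleConfig overrides
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys {sorted(unknown)}")
        raw["outdir"] = Path(raw.get("outdir", "dubscreen-run"))
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()

    def load_library(self) -> ShrnaLibrary:
        if self.library:
            if not Path(self.library).exists():
                raise PipelineError(f"library file not found: {self.library}")
            return load_library(self.library)
        return make_dub_library()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _effects_from_config(lib: ShrnaLibrary, sim_cfg: dict) -> EffectModel:
    effects = EffectModel.neutral(lib)
    for spec in sim_cfg.get("effects", []):
        effects = effects.with_gene(
            lib, spec["gene"], float(spec["fitness"]), spec.get("efficacies")
        )
    return effects


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages and write the provenance manifest.

    ``stages`` must be a dependency-closed subset (each stage's predecessor
    either requested or already materialized under outdir). Returns the
    manifest dict.
    """
    stages = list(stages)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise PipelineError(f"unknown stages {bad}")
    stages.sort(key=STAGES.index)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def _require(path: Path, producer: str):
        if not path.exists():
            raise PipelineError(
                f"missing artifact {path.name!r}: run the {producer!r} stage first"
            )
        return path

    lib = config.load_library()
    lib_path = out / "library.tsv"
    write_library(lib, lib_path)
    artifacts["library"] = lib_path

    sim_cfg = dict(config.sim)
    params_kwargs = {
        k: v for k, v in sim_cfg.items() if k in ScreenSimParams.__dataclass_fields__
    }

    if "simulate" in stages:
        effects = _effects_from_config(lib, sim_cfg)
        for i, screen in enumerate(config.screens):
            params = ScreenSimParams(**{**params_kwargs, "seed": config.seed + i})
            result = simulate_screen(lib, params, effects, screen_id=screen)
            result.counts.write_tsv(out / f"counts_{screen}.tsv")
            write_sample_sheet(result.sheet, out / f"samples_{screen}.tsv")
            result.truth.gene_truth.to_csv(out / f"truth_{screen}.tsv", sep="\t")
            artifacts[f"counts_{screen}"] = out / f"counts_{screen}.tsv"
            artifacts[f"samples_{screen}"] = out / f"samples_{screen}.tsv"
            artifacts[f"truth_{screen}"] = out / f"truth_{screen}.tsv"
            if config.emit_fastq:
                paths = write_screen_fastq(
                    result, lib, out / f"fastq_{screen}", seed=config.seed + i
                )
                for sid, p in paths.items():
                    artifacts[f"fastq_{screen}_{sid}"] = p

    for screen in config.screens:
        if "count" in stages and config.emit_fastq:
            sheet = load_sample_sheet(
                _require(out / f"samples_{screen}.tsv", "simulate")
            )
            fq_dir = out / f"fastq_{screen}"
            _require(fq_dir, "simulate")
            found = {p.stem: p for p in fq_dir.glob("*.fastq")}
            paths = {s: found[s] for s in sheet.sample_ids if s in found}
            cm = count_samples(paths, lib, sheet)
            cm.write_tsv(out / f"counts_{screen}.tsv")
            artifacts[f"counts_{screen}"] = out / f"counts_{screen}.tsv"

    def _load_counts(screen: str) -> CountMatrix:
        sheet = load_sample_sheet(_require(out / f"samples_{screen}.tsv", "simulate"))
        return CountMatrix.read_tsv(
            _require(out / f"counts_{screen}.tsv", "count"), sheet
        )

    if "qc" in stages:
        for screen in config.screens:
            cm = _load_counts(screen)
            t0 = cm.sheet.reference_sample(screen)
            pairs = [("plasmid", t0)] if "plasmid" in cm.sample_ids else []
            pairs += [(t0, s) for s in cm.sheet.samples(screen, config.tissue)]
            rep = representation_stats(cm, pairs)
            rep.write_tsv(out / f"qc_{screen}.tsv")
            artifacts[f"qc_{screen}"] = out / f"qc_{screen}.tsv"

    if "test" in stages:
        for screen in config.screens:
            cm = _load_counts(screen)
            table, flagged = differential_table(
                cm, screen, tissue=config.tissue, gene_of=lib.gene_of
            )
            table.to_csv(out / f"diff_{screen}.tsv", sep="\t")
            artifacts[f"diff_{screen}"] = out / f"diff_{screen}.tsv"
            if flagged:
                (out / f"outliers_{screen}.txt").write_text("\n".join(flagged) + "\n")

    if "call-hits" in stages:
        cfg = HitRuleConfig(**config.hits)
        per_screen = {}
        for screen in config.screens:
            diff = pd.read_csv(
                _require(out / f"diff_{screen}.tsv", "test"),
                sep="\t", index_col="hairpin_id",
            )
            cm = _load_counts(screen)
            flagged_file = out / f"outliers_{screen}.txt"
            dropped = (
                flagged_file.read_text().split() if flagged_file.exists() else []
            )
            samples = [
                s for s in cm.sheet.samples(screen, config.tissue) if s not in dropped
            ]
            fc = per_mouse_fold_changes(cm, screen, config.tissue, samples=samples)
            med = fc.apply(median_fold_change, axis=1)
            flags = flag_table(diff, cfg)
            per_screen[screen], _ev = call_genes_screen(
                flags, med, lib.gene_of, cfg, all_genes=lib.genes()
            )
        calls, overlap = consolidate_screens(per_screen, cfg)
        calls.to_csv(out / "hits.tsv", sep="\t")
        overlap.to_csv(out / "overlap.tsv", sep="\t", index=False)
        artifacts["hits"] = out / "hits.tsv"
        artifacts["overlap"] = out / "overlap.tsv"

    manifest = {
        "package": "dubscreen",
        "version": __version__,
        "seed": config.seed,
        "stages": stages,
        "config_hash": config.config_hash(),
        "artifacts": {k: {"path": str(p), "sha256": _sha256(p)}
                      for k, p in sorted(artifacts.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def verify_manifest(outdir) -> list:
    """Recompute artifact checksums against the manifest; returns the names
    of tampered or missing artifacts (empty list = intact)."""
    out = Path(outdir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    bad = []
    for name, meta in manifest["artifacts"].items():
        p = Path(meta["path"])
        if not p.exists() or _sha256(p) != meta["sha256"]:
            bad.append(name)
    return bad
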