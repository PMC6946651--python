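"""Config-driven orchestration of the full analysis chain.

Stages (in dependency order): simulate (or ingest an existing VCF+popmap) →
filter → prune → stats (pi, theta, windowed Fst) → scan (windowed f_d with
jackknife Z) → mask (drop significant windows) → restat (Fst after masking) →
tree (NJ + window bootstrap, masked and unmasked) → compare.  Every
intermediate artifact is a standard text format (VCF/BED/TSV/newick/JSON) and
every stage's randomness derives from the manifest seed through a per-stage
substream, so deleting later outputs and re-running reproduces them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import admixscan, phylo, popstats, simpop, variants
from .popmap import PopulationMap

log = logging.getLogger("camelscan")

_STAGES = ["simulate", "filter", "prune", "stats", "scan", "mask", "restat", "tree", "compare"]
_DEPS = {
    "mask": ["scan"],
    "restat": ["mask"],
    "compare": ["restat", "tree"],
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Either ``scenario`` (parameters forwarded to
    :func:`simpop.make_camel_scenario`) or ``input_vcf`` + ``input_popmap``
    must be given.  ``stages`` toggles stages on/off; ``params`` carries
    per-stage keyword overrides (defaults follow the library defaults).
    """

    outdir: str
    seed: int = 0
    scenario: dict | None = None
    input_vcf: str | None = None
    input_popmap: str | None = None
    stages: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        enabled = self.enabled_stages()
        if "simulate" in enabled and self.input_vcf:
            raise ConfigError("give either a scenario or an input VCF, not both")
        if "simulate" not in enabled and not (self.input_vcf and self.input_popmap):
            raise ConfigError("without the simulate stage, input_vcf and input_popmap are required")
        for stage, deps in _DEPS.items():
            if stage in enabled:
                missing = [d for d in deps if d not in enabled]
                if missing:
                    raise ConfigError(f"stage {stage!r} requires {missing} to be enabled")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")

    def enabled_stages(self) -> list[str]:
        defaults = {s: True for s in _STAGES}
        if self.input_vcf:
            defaults["simulate"] = False
        defaults.update(self.stages)
        return [s for s in _STAGES if defaults.get(s, False)]

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) ^ zlib.crc32(stage.encode())) % (2**31)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir, "seed": self.seed, "scenario": self.scenario,
            "input_vcf": self.input_vcf, "input_popmap": self.input_popmap,
            "stages": dict(self.stages), "params": dict(self.params),
            "log_level": self.log_level,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> {outputs: {path: sha}, seconds}

    def record(self, stage: str, outputs: list[Path], seconds: float) -> None:
        self.stages[stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "seconds": round(seconds, 3),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed, "stages": self.stages}, fh, indent=2)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the enabled stages in dependency order; returns the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = config.enabled_stages()
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    params = config.params

    matrix: variants.GenotypeMatrix
    popmap: PopulationMap
    truth_windows: list = []
    scan_df = None
    masked_matrix = None
    fst_before = fst_after = None
    tree_unmasked = tree_masked = None
    removed: list = []

    def _stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    if "simulate" in enabled:
        t0 = _stage("simulate")
        scen = dict(config.scenario or {})
        scen.setdefault("seed", config.stage_seed("simulate"))
        cfg = simpop.make_camel_scenario(**scen)
        matrix, popmap, truth, _ = simpop.simulate(cfg)
        truth_windows = truth.introgressed_windows
        paths = simpop.write_outputs(matrix, popmap, truth, str(outdir / "simulated"),
                                     contig_lengths=cfg.chromosome_lengths)
        manifest.record("simulate", [Path(p) for p in paths.values()], time.perf_counter() - t0)
    else:
        matrix, _ = variants.read_vcf(config.input_vcf)
        popmap = PopulationMap.read_tsv(config.input_popmap)

    if "filter" in enabled:
        t0 = _stage("filter")
        thr = variants.FilterThresholds(**params.get("filter", {}))
        matrix, report = variants.filter_variants(matrix, thr)
        rp = outdir / "filter_report.json"
        rp.write_text(json.dumps(report.to_dict(), indent=2))
        fv = outdir / "filtered.vcf"
        variants.write_vcf(matrix, fv)
        manifest.record("filter", [rp, fv], time.perf_counter() - t0)

    if "prune" in enabled:
        t0 = _stage("prune")
        kept = variants.ld_prune(matrix, **params.get("prune", {}))
        bed = outdir / "ld_pruned.bed"
        variants.write_bed(
            [(str(matrix.chrom[i]), int(matrix.pos[i]) - 1, int(matrix.pos[i])) for i in kept], bed
        )
        manifest.record("prune", [bed], time.perf_counter() - t0)

    window_size = int(params.get("stats", {}).get("window_size", 10_000))
    windows = popstats.windows_from_matrix(matrix, window_size)

    if "stats" in enabled:
        t0 = _stage("stats")
        frames = []
        for pop in popmap.populations:
            frames.append(popstats.nucleotide_diversity(matrix, popmap, pop, windows).assign(population=pop))
            frames.append(popstats.watterson_theta(matrix, popmap, pop, windows).assign(population=pop))
        sp = outdir / "diversity.tsv"
        pd.concat(frames).to_csv(sp, sep="\t", index=False)
        fst_before = phylo.fst_distance_matrix(matrix, popmap, windows)
        fp = outdir / "fst_matrix.tsv"
        pd.DataFrame(fst_before.values, index=fst_before.labels, columns=fst_before.labels).to_csv(fp, sep="\t")
        manifest.record("stats", [sp, fp], time.perf_counter() - t0)

    if "scan" in enabled:
        t0 = _stage("scan")
        sp = params.get("scan", {})
        quartet = admixscan.QuartetConfig(*sp.get("quartet", ("east_asian", "central_asian", "wild_bactrian", "dromedary")))
        scan_df = admixscan.introgression_scan(
            matrix, popmap, quartet,
            window_size=int(sp.get("window_size", 100_000)),
            block_size=int(sp.get("block_size", 10_000)),
            z_threshold=float(sp.get("z_threshold", 2.0)),
        )
        path = outdir / "scan.tsv"
        scan_df.to_csv(path, sep="\t", index=False)
        manifest.record("scan", [path], time.perf_counter() - t0)

    if "mask" in enabled:
        t0 = _stage("mask")
        masked_matrix, removed = admixscan.mask_introgressed(
            matrix, scan_df, z_threshold=float(params.get("scan", {}).get("z_threshold", 2.0))
        )
        bed = outdir / "removed_windows.bed"
        variants.write_bed(removed, bed)
        mv = outdir / "masked.vcf"
        variants.write_vcf(masked_matrix, mv)
        manifest.record("mask", [bed, mv], time.perf_counter() - t0)

    if "restat" in enabled:
        t0 = _stage("restat")
        mwindows = popstats.windows_from_matrix(masked_matrix, window_size)
        fst_after = phylo.fst_distance_matrix(masked_matrix, popmap, mwindows)
        fp = outdir / "fst_matrix_masked.tsv"
        pd.DataFrame(fst_after.values, index=fst_after.labels, columns=fst_after.labels).to_csv(fp, sep="\t")
        manifest.record("restat", [fp], time.perf_counter() - t0)

    if "tree" in enabled:
        t0 = _stage("tree")
        tp = params.get("tree", {})
        kw = dict(
            n_windows=int(tp.get("n_windows", 200)),
            window=int(tp.get("window", 10_000)),
            min_spacing=int(tp.get("min_spacing", 10_000)),
            replicates=int(tp.get("replicates", 100)),
            seed=config.stage_seed("tree"),
        )
        outputs = []
        tree_unmasked, _ = phylo.bootstrap_support(matrix, popmap, **kw)
        p1 = outdir / "nj_unmasked.nwk"
        phylo.write_newick(tree_unmasked, p1)
        outputs.append(p1)
        if masked_matrix is not None:
            tree_masked, _ = phylo.bootstrap_support(masked_matrix, popmap, **kw)
            p2 = outdir / "nj_masked.nwk"
            phylo.write_newick(tree_masked, p2)
            outputs.append(p2)
        manifest.record("tree", outputs, time.perf_counter() - t0)

    if "compare" in enabled:
        t0 = _stage("compare")
        report = compare_masked_unmasked(
            fst_before, fst_after, scan_df, removed, tree_unmasked, tree_masked
        )
        rp = outdir / "compare.json"
        rp.write_text(json.dumps(report, indent=2))
        manifest.record("compare", [rp], time.perf_counter() - t0)

    mp = outdir / "manifest.json"
    manifest.write(mp)
    return manifest


def compare_masked_unmasked(
    fst_before: popstats.DistanceMatrix,
    fst_after: popstats.DistanceMatrix,
    scan_df: pd.DataFrame,
    removed: list,
    tree_unmasked: phylo.PhyloTree | None = None,
    tree_masked: phylo.PhyloTree | None = None,
) -> dict:
    """Per-pair Fst deltas, removed-window bookkeeping, and tree distance."""
    if fst_before is None or fst_after is None:
        raise ValueError("both masked and unmasked Fst matrices are required")
    if fst_before.labels != fst_after.labels:
        raise ValueError("Fst matrices are over different populations")
    deltas = {}
    labels = fst_before.labels
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            deltas[f"{a}|{b}"] = float(fst_after.values[i, j] - fst_before.values[i, j])
    by_class = scan_df["classification"].value_counts().to_dict() if scan_df is not None else {}
    report = {
        "fst_delta": deltas,
        "removed_window_count": len(removed),
        "windows_by_classification": {str(k): int(v) for k, v in by_class.items()},
    }
    if tree_unmasked is not None and tree_masked is not None:
        report["robinson_foulds_masked_vs_unmasked"] = tree_unmasked.robinson_foulds(tree_masked)
    return report
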