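"""Run configuration, stage orchestration and reproducibility manifests."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as _io
from .callers import call_sites, extract_start_signals, pfm_around_sites, replicate_correlation
from .dmr import dmr_test, volcano_table
from .genome import RegionSet
from .regions import count_regions, enrichment_score, metagene, sliding_window_correlation
from .simulate import SimParams, build_dmnminus_library, build_dmnplus_library

PIPELINES = ("simulate_plus", "simulate_minus", "call_sites", "quantify",
             "metagene", "corr", "dmr")


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


@dataclass
class RunConfig:
    """One pipeline invocation: stage name, parameters, paths, seed.

    Unknown keys are rejected so a typo cannot silently fall back to a
    default.  Every threshold is echoed into the output manifest.
    """

    pipeline: str
    outdir: str
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)       # SimParams overrides
    min_intensity: int = 5
    offset: int = 1
    prefix_k: int = 3
    flank: int = 2000
    n_bins: int = 100
    window: int = 2000
    min_depth: int = 5
    anchor: str = "tss"
    overlap_rule: str = "any_overlap"
    pseudocount: float = 1.0
    paired: bool = False
    dedup: bool = False

    def __post_init__(self):
        if self.pipeline not in PIPELINES:
            raise ConfigError(f"unknown pipeline {self.pipeline!r}; choose from {PIPELINES}")
        valid_sim = {f.name for f in dataclasses.fields(SimParams)}
        bad = set(self.sim) - valid_sim
        if bad:
            raise ConfigError(f"unknown simulation parameters {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - valid
        if bad:
            raise ConfigError(f"{path}: unknown config keys {sorted(bad)}")
        try:
            return cls(**data)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def sim_params(self) -> SimParams:
        kwargs = dict(self.sim)
        kwargs.setdefault("seed", self.seed)
        if "size_select" in kwargs:
            kwargs["size_select"] = tuple(kwargs["size_select"])
        return SimParams(**kwargs)


def _load_genome(cfg: RunConfig):
    path = cfg.inputs.get("genome")
    if not path or not Path(path).exists():
        raise ConfigError(f"missing genome FASTA input: {path!r}")
    return _io.read_fasta(path)


def _load_truth(path) -> pd.DataFrame:
    if not path or not Path(path).exists():
        raise ConfigError(f"missing placements input: {path!r}")
    if str(path).endswith(".sam"):
        return _io.read_sam_starts(path)
    return _io.read_tsv(path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute one stage; returns (and writes) the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        outputs[name] = _io.sha256_file(path)

    if cfg.pipeline == "simulate_plus":
        genome = _load_genome(cfg)
        methylome = _io.read_methylome_tsv(cfg.inputs["methylome"])
        methylome.validate_against(genome)
        lib = build_dmnplus_library(genome, methylome, cfg.sim_params())
        _emit("truth.tsv", lib.write_truth)
        _emit("reads.sam", lib.write_sam)
        _emit("reads_R1.fastq", lambda p: lib.write_fastq(p, outdir / "reads_R2.fastq"))
        outputs["reads_R2.fastq"] = _io.sha256_file(outdir / "reads_R2.fastq")

    elif cfg.pipeline == "simulate_minus":
        genome = _load_genome(cfg)
        methylome = _io.read_methylome_tsv(cfg.inputs["methylome"])
        methylome.validate_against(genome)
        params = cfg.sim_params()
        treated = build_dmnminus_library(genome, methylome, params, treated=True)
        untreated = build_dmnminus_library(genome, methylome, params, treated=False)
        _emit("treated_truth.tsv", treated.write_truth)
        _emit("input_truth.tsv", untreated.write_truth)

    elif cfg.pipeline == "call_sites":
        genome = _load_genome(cfg)
        truth = _load_truth(cfg.inputs.get("placements"))
        signals = extract_start_signals(truth, offset=cfg.offset, dedup=cfg.dedup)
        called = call_sites(signals, genome, min_intensity=cfg.min_intensity)
        report = called.copy()
        report["pos"] = report["pos"] + 1  # user-facing tables are 1-based
        _emit("called_sites.tsv", lambda p: _io.write_tsv(report, p))
        if len(called):
            pfm, _ = pfm_around_sites(genome, called, flank=5)
            _emit("pfm.tsv", lambda p: pfm.to_csv(p, sep="\t"))

    elif cfg.pipeline == "quantify":
        regions = RegionSet.from_bed(cfg.inputs["regions"])
        truth = _load_truth(cfg.inputs.get("placements"))
        frags = truth[truth["read_id"].notna() & (truth["read_id"] != "")]
        frags = frags.rename(columns={"frag_start": "start", "frag_end": "end"})
        counts = count_regions(frags[["contig", "start", "end"]], regions,
                               overlap_rule=cfg.overlap_rule)
        if "input_placements" in cfg.inputs:
            inp = _load_truth(cfg.inputs["input_placements"])
            inp = inp[inp["read_id"].notna() & (inp["read_id"] != "")]
            inp = inp.rename(columns={"frag_start": "start", "frag_end": "end"})
            icounts = count_regions(inp[["contig", "start", "end"]], regions,
                                    overlap_rule=cfg.overlap_rule)
            counts = enrichment_score(counts, icounts, pseudocount=cfg.pseudocount)
        _emit("region_counts.tsv", lambda p: _io.write_tsv(counts, p))

    elif cfg.pipeline == "metagene":
        genome = _load_genome(cfg)
        genes = RegionSet.from_bed(cfg.inputs["genes"])
        truth = _load_truth(cfg.inputs.get("placements"))
        frags = truth[truth["read_id"].notna() & (truth["read_id"] != "")]
        frags = frags.rename(columns={"frag_start": "start", "frag_end": "end"})
        prof = metagene(frags[["contig", "start", "end"]], genome, genes,
                        flank=cfg.flank, n_bins=cfg.n_bins, anchor=cfg.anchor)
        df = pd.DataFrame({"bin": range(prof.n_bins), "value": prof.bins})
        _emit("metagene.tsv", lambda p: _io.write_tsv(df, p))

    elif cfg.pipeline == "corr":
        a = _load_truth(cfg.inputs.get("placements_a"))
        b = _load_truth(cfg.inputs.get("placements_b"))
        if cfg.inputs.get("genome"):
            genome = _load_genome(cfg)
            fa = a.rename(columns={"frag_start": "start", "frag_end": "end"})
            fb = b.rename(columns={"frag_start": "start", "frag_end": "end"})
            r = sliding_window_correlation(fa, fb, genome, window=cfg.window,
                                           min_depth=cfg.min_depth)
        else:
            sa = extract_start_signals(a, offset=cfg.offset)
            sb = extract_start_signals(b, offset=cfg.offset)
            r = replicate_correlation(sa, sb)
        _emit("correlation.json",
              lambda p: Path(p).write_text(json.dumps({"pearson_r": r}, indent=1)))

    elif cfg.pipeline == "dmr":
        counts_a = _io.read_tsv(cfg.inputs["group_a"]).set_index("region")
        counts_b = _io.read_tsv(cfg.inputs["group_b"]).set_index("region")
        res = dmr_test(counts_a, counts_b, paired=cfg.paired,
                       pseudocount=cfg.pseudocount)
        _emit("dmr.tsv", lambda p: _io.write_tsv(res, p))
        _emit("volcano.tsv", lambda p: _io.write_tsv(volcano_table(res), p))

    manifest = {
        "pipeline": cfg.pipeline,
        "seed": cfg.seed,
        "parameters": {k: v for k, v in dataclasses.asdict(cfg).items()
                       if k not in ("inputs", "outdir")},
        "inputs": {k: _io.sha256_file(v) for k, v in cfg.inputs.items()
                   if isinstance(v, str) and Path(v).exists()},
        "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
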