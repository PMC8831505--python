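"""Run configuration and end-to-end pipeline orchestration.

A run is described by a nested YAML/dict config (library, simulator,
extraction, statistics, power sections) with schema-validated defaults;
unknown keys are rejected so typos fail loudly.  One master seed fans
out to per-stage seeds through a counter-based SeedSequence scheme, so
any stage can be rerun in isolation and reproduce its output exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import library as lib_mod
from . import power as power_mod
from . import quant, simulate, stats

log = logging.getLogger("tfhscreen")

__all__ = ["RunConfig", "load_config", "run_end_to_end", "ConfigError"]


class ConfigError(ValueError):
    """Raised on schema violations in a run configuration."""


@dataclass
class LibrarySection:
    n_genes: int = 20
    guides_per_gene: int = 4
    n_controls: int = 20
    gene_prefix: str = "Gene"


@dataclass
class SimulatorSection:
    plasmid_sigma: float = 0.5
    culture_doublings: float = 6.0
    transfer_pool_size: int = 1_000_000
    engraftment_rate: float = 0.10
    invivo_doublings: float = 6.0
    baseline_tfh_logit: float = 0.0
    gc_tfh_fraction: float = 0.4
    sort_coverage: int = 750
    seq_depth: int = 300
    sort_purity: float = 0.95
    pcr_shape: float = 10.0
    n_mice: int = 5
    n_experiments: int = 2
    pooled_sort: bool = False
    # planted effects for the demonstration run
    n_tfh_genes: int = 2
    tfh_effect: float = -2.0
    emit_fastq: bool = True
    read_length: int = 100
    error_rate: float = 0.001


@dataclass
class ExtractionSection:
    anchor_up: str = "CCTTGTTTG"
    anchor_down: str = "GTTTTA"
    anchor_mismatches: int = 0
    spacer_mismatches: int = 1


@dataclass
class StatisticsSection:
    comparison: str = "Tfh_vs_Th1"
    pseudocount: float = 0.5
    fdr_alpha: float = 0.25
    n_perm: int = 10_000
    zscore_reference: str = "controls"


@dataclass
class PowerSection:
    enabled: bool = True
    spike_frequencies: list = field(
        default_factory=lambda: [1 / 100, 1 / 300, 1 / 1000, 1 / 3000]
    )
    effect_sizes: list = field(default_factory=lambda: [-3.0])
    coverages: list = field(default_factory=lambda: [750])
    n_reps: int = 10
    z_threshold: float = 2.0


@dataclass
class RunConfig:
    library: LibrarySection = field(default_factory=LibrarySection)
    simulator: SimulatorSection = field(default_factory=SimulatorSection)
    extraction: ExtractionSection = field(default_factory=ExtractionSection)
    statistics: StatisticsSection = field(default_factory=StatisticsSection)
    power: PowerSection = field(default_factory=PowerSection)
    seed: int = 0
    output_dir: str = "tfhscreen_run"


_SECTIONS = {
    "library": LibrarySection,
    "simulator": SimulatorSection,
    "extraction": ExtractionSection,
    "statistics": StatisticsSection,
    "power": PowerSection,
}


def _build_section(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {path}: {sorted(unknown)}")
    return cls(**data)


def load_config(source: str | Path | dict | None) -> RunConfig:
    """Build a validated RunConfig from a YAML path, a dict, or None
    (all defaults).  Unknown keys raise :class:`ConfigError` naming the
    offending section."""
    if source is None:
        return RunConfig()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_known = set(_SECTIONS) | {"seed", "output_dir"}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    return RunConfig(seed=int(data.get("seed", 0)),
                     output_dir=str(data.get("output_dir", "tfhscreen_run")),
                     **kwargs)


def _stage_seed(master: int, stage: int) -> int:
    """Counter-based per-stage seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(stage,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_end_to_end(config: RunConfig | dict | str | None = None,
                   output_dir: str | Path | None = None) -> dict:
    """Full demonstration pipeline: build library, simulate the screen,
    emit/count FASTQ, analyze, and (optionally) run the titration power
    grid.  Writes every artifact plus a manifest of file hashes; returns
    a result bundle with the in-memory objects.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # --- library -------------------------------------------------
        stage = "library"
        genes = [f"{cfg.library.gene_prefix}{i:03d}"
                 for i in range(1, cfg.library.n_genes + 1)]
        library = lib_mod.build_library(
            genes, cfg.library.guides_per_gene, cfg.library.n_controls,
            seed=_stage_seed(cfg.seed, 0),
        )
        lib_mod.write_library(library, out / "library.csv")
        lib_mod.write_spacer_fasta(library, out / "library.fasta")
        log.info("library: %d guides (%d genes + %d controls)", len(library),
                 cfg.library.n_genes, cfg.library.n_controls)

        # --- simulate ------------------------------------------------
        stage = "simulate"
        sim = cfg.simulator
        truth = simulate.ScreenTruth.neutral(library)
        for g in genes[: sim.n_tfh_genes]:
            truth.tfh_logit_shift[g] = sim.tfh_effect
        sim_fields = {f.name for f in dataclasses.fields(simulate.ScreenConfig)}
        screen_cfg = simulate.ScreenConfig(
            **{k: v for k, v in dataclasses.asdict(sim).items()
               if k in sim_fields and k != "seed"},
            seed=_stage_seed(cfg.seed, 1),
        )
        table = simulate.simulate_screen(library, truth, screen_cfg)
        truth.to_frame().to_csv(out / "truth.csv", index=False)
        table.write(out / "sim_counts.tsv", out / "samples.csv")

        # --- FASTQ round trip ---------------------------------------
        stage = "count"
        if sim.emit_fastq:
            fastq_dir = out / "fastq"
            fastq_dir.mkdir(exist_ok=True)
            rng = np.random.default_rng(_stage_seed(cfg.seed, 2))
            paths = {}
            for sid in table.counts.columns:
                p = fastq_dir / f"{sid}.fastq"
                simulate.emit_fastq(table.counts[sid], library, p,
                                    read_length=sim.read_length,
                                    error_rate=sim.error_rate, rng=rng)
                paths[sid] = str(p)
            policy = quant.ExtractionPolicy(
                anchor_up=cfg.extraction.anchor_up,
                anchor_down=cfg.extraction.anchor_down,
                anchor_mismatches=cfg.extraction.anchor_mismatches,
                spacer_mismatches=cfg.extraction.spacer_mismatches,
            )
            counted, mapstats = quant.count_samples(paths, library,
                                                    table.samples, policy)
            counted.counts.to_csv(out / "counts.tsv", sep="\t")
            mapstats.to_csv(out / "mapping_stats.tsv", sep="\t")
        else:
            counted = table
            counted.counts.to_csv(out / "counts.tsv", sep="\t")

        # --- analyze -------------------------------------------------
        stage = "analyze"
        st = cfg.statistics
        genes_df = stats.analyze_screen(
            counted, library, comparison=st.comparison,
            pseudocount=st.pseudocount, zscore_reference=st.zscore_reference,
            alpha=st.fdr_alpha, n_perm=st.n_perm,
            seed=_stage_seed(cfg.seed, 3),
        )
        genes_df.to_csv(out / "gene_results.tsv", sep="\t")
        n_hits = int((genes_df["fdr"] < st.fdr_alpha).sum())
        log.info("analyze: %d genes, %d at FDR < %.2f", len(genes_df),
                 n_hits, st.fdr_alpha)

        # --- power ---------------------------------------------------
        stage = "power"
        power_df = None
        if cfg.power.enabled:
            grid = power_mod.PowerGrid(
                spike_frequencies=tuple(cfg.power.spike_frequencies),
                effect_sizes=tuple(cfg.power.effect_sizes),
                coverages=tuple(int(c) for c in cfg.power.coverages),
                n_reps=cfg.power.n_reps,
                z_threshold=cfg.power.z_threshold,
            )
            power_df = power_mod.titration_power(
                library, grid, screen_cfg, seed=_stage_seed(cfg.seed, 4)
            )
            power_df.to_csv(out / "power.tsv", sep="\t", index=False)

        # --- manifest ------------------------------------------------
        stage = "manifest"
        files = sorted(p for p in out.rglob("*") if p.is_file()
                       and p.name != "manifest.json")
        manifest = {
            "seed": cfg.seed,
            "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    return {
        "library": library,
        "truth": truth,
        "counts": counted,
        "gene_results": genes_df,
        "power": power_df,
        "manifest": manifest,
        "output_dir": out,
    }
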