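"""End-to-end orchestration: simulate/load -> profile -> peaks/DMRs ->
repeats -> enrichment, with plain-file handoff and a machine-readable
manifest.

Every stage writes its outputs as BED/TSV before the next stage runs, so
each stage is independently re-runnable and testable; a stage failure raises
:class:`PipelineError` naming the stage, with upstream outputs retained.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import load_annotation
from .dmr import (
    assign_to_genes,
    call_dmrs,
    count_in_regions,
    methylated_gene_set,
    scan_peaks,
    union_regions,
)
from .enrichment import TermUniverse, enrich
from .exceptions import PipelineError, ValidationError
from .io import ensure_dir, sha256_of, write_bed, write_tsv
from .profiles import (
    FragmentSet,
    compare_levels,
    filter_unique,
    metagene,
    tile_and_count,
    unique_mapping_rate,
)
from .repeats import repeat_summary
from .synthetic import SyntheticConfig, simulate_experiment

logger = logging.getLogger("medipdiff")


@dataclass
class RunConfig:
    """One pipeline run: inputs (or simulation), thresholds, seed, outdir."""

    outdir: str = "medipdiff_out"
    seed: int = 0
    # simulation settings; ignored when explicit input paths are given
    simulate: dict = field(default_factory=dict)
    # explicit inputs (all-or-nothing): fasta, gff3, repeats, fragments {cond: bed}
    inputs: dict = field(default_factory=dict)
    fc_min: float = 2.0
    p_max: float = 0.05
    q_max: float = 0.05
    peak_alpha: float = 1e-4
    window_width: int = 1000
    repeat_window: int = 10_000
    merge_gap: int = 1000
    enrichment_q_max: float = 0.05

    def __post_init__(self):
        for name in ("fc_min", "p_max", "q_max", "peak_alpha"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        if self.window_width <= 0 or self.repeat_window <= 0:
            raise ValidationError("window widths must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s: done", name)
            return result

        return inner

    return wrap


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a manifest dict (also written).

    Outputs (all under ``config.outdir``): mapping_summary.tsv,
    windows_{S,F}.tsv, peaks_{S,F}.bed, dmrs.bed, dmr_tests.tsv,
    dmg_table.tsv, methylated_genes.tsv, repeat_summary_{S,F}.tsv,
    enrichment_{hyper,hypo}.tsv, metagene_{S,F}.tsv, level_tests.tsv and
    manifest.json (versions, seed, thresholds, checksums).
    """
    out = ensure_dir(config.outdir)
    outputs: dict[str, str] = {}

    annotation, fragments, term_map = _load_inputs(config, out)
    chrom_sizes = annotation.chrom_sizes
    conditions = sorted(fragments)

    # --- mapping summary (Table-1 shape) -----------------------------------
    @_stage("mapping_summary")
    def _mapping():
        rows = []
        for cond in conditions:
            fs = fragments[cond]
            rows.append(
                {
                    "sample": cond,
                    "total_reads": fs.total_reads,
                    "unique_mapped_reads": fs.unique_reads,
                    "unique_rate_percent": unique_mapping_rate(
                        fs.unique_reads, fs.total_reads
                    )
                    if fs.total_reads
                    else 0.0,
                }
            )
        df = pd.DataFrame(rows)
        write_tsv(df, out / "mapping_summary.tsv")
        outputs["mapping_summary"] = "mapping_summary.tsv"
        return df

    _mapping()

    # --- unique filtering + windows ----------------------------------------
    @_stage("windows")
    def _windows():
        unique_sets, windows = {}, {}
        for cond in conditions:
            ufs = filter_unique(fragments[cond])
            unique_sets[cond] = ufs
            wc = tile_and_count(ufs, chrom_sizes, config.window_width)
            windows[cond] = wc
            path = out / f"windows_{cond}.tsv"
            write_tsv(wc.windows, path)
            outputs[f"windows_{cond}"] = path.name
        return unique_sets, windows

    unique_sets, windows = _windows()

    # --- metagene profiles + level tests -----------------------------------
    @_stage("profiles")
    def _profiles():
        bodies = annotation.gene_bodies()
        for cond in conditions:
            prof = metagene(unique_sets[cond], bodies)
            df = pd.DataFrame(
                {
                    "bin": np.arange(len(prof.values)),
                    "segment": ["upstream"] * 20 + ["body"] * 40 + ["downstream"] * 20,
                    "normalized_depth": prof.values,
                }
            )
            path = out / f"metagene_{cond}.tsv"
            write_tsv(df, path)
            outputs[f"metagene_{cond}"] = path.name
        if len(conditions) == 2:
            a, b = conditions
            tests = compare_levels(windows[a], windows[b], annotation)
            write_tsv(tests, out / "level_tests.tsv")
            outputs["level_tests"] = "level_tests.tsv"

    _profiles()

    # --- peaks + DMRs -------------------------------------------------------
    @_stage("dmr")
    def _dmr():
        peaks = {}
        for cond in conditions:
            pk = scan_peaks(windows[cond], merge_gap=config.merge_gap,
                            alpha=config.peak_alpha)
            peaks[cond] = pk
            path = out / f"peaks_{cond}.bed"
            pk_bed = pk.assign(name=[f"peak{i}" for i in range(len(pk))],
                               score=pk["count"], strand=".")
            write_bed(pk_bed, path)
            outputs[f"peaks_{cond}"] = path.name
        if len(conditions) != 2:
            return peaks, pd.DataFrame(), pd.DataFrame()
        s_cond, f_cond = "S", "F"
        if set(conditions) != {"S", "F"}:
            s_cond, f_cond = conditions
        regions = union_regions(peaks[s_cond], peaks[f_cond])
        counts_s = count_in_regions(unique_sets[s_cond], regions)
        counts_f = count_in_regions(unique_sets[f_cond], regions)
        dmrs = call_dmrs(
            regions, counts_s, counts_f,
            unique_sets[s_cond].total_reads, unique_sets[f_cond].total_reads,
            fc_min=config.fc_min, p_max=config.p_max, q_max=config.q_max,
        )
        dmr_bed = dmrs.assign(
            name=[f"dmr{i}" for i in range(len(dmrs))], score=0, strand="."
        )
        write_bed(dmr_bed, out / "dmrs.bed",
                  extra_columns=["count_s", "count_f", "fold", "p", "q", "direction"])
        outputs["dmrs"] = "dmrs.bed"
        return peaks, regions, dmrs

    peaks, regions, dmrs = _dmr()

    # --- gene assignment ----------------------------------------------------
    @_stage("genes")
    def _genes():
        annotated, dmg = assign_to_genes(dmrs, annotation)
        write_tsv(annotated, out / "dmr_gene_overlaps.tsv")
        write_tsv(dmg, out / "dmg_table.tsv")
        outputs["dmr_gene_overlaps"] = "dmr_gene_overlaps.tsv"
        outputs["dmg_table"] = "dmg_table.tsv"
        rows = []
        for cond in sorted(peaks):
            genes = methylated_gene_set(peaks[cond], annotation)
            rows += [{"sample": cond, "gene_id": g} for g in sorted(genes)]
        write_tsv(pd.DataFrame(rows, columns=["sample", "gene_id"]),
                  out / "methylated_genes.tsv")
        outputs["methylated_genes"] = "methylated_genes.tsv"
        return annotated

    annotated = _genes()

    # --- repeats ------------------------------------------------------------
    @_stage("repeats")
    def _repeats():
        for cond in conditions:
            summ = repeat_summary(
                unique_sets[cond], annotation.repeats, chrom_sizes,
                width=config.repeat_window,
            )
            path = out / f"repeat_summary_{cond}.tsv"
            write_tsv(summ, path)
            outputs[f"repeat_summary_{cond}"] = path.name

    _repeats()

    # --- enrichment ---------------------------------------------------------
    @_stage("enrichment")
    def _enrich():
        if term_map is None or len(term_map) == 0:
            logger.info("no gene->term map supplied; enrichment skipped")
            return
        universe = TermUniverse.from_frame(term_map)
        for direction in ("hyper", "hypo"):
            genes = set(
                annotated.loc[annotated["direction"] == direction, "gene_id"]
            ) & universe.genes
            result = (
                enrich(genes, universe, q_max=config.enrichment_q_max)
                if genes
                else pd.DataFrame(
                    columns=["term", "m", "n", "M", "N", "p", "q", "significant"]
                )
            )
            path = out / f"enrichment_{direction}.tsv"
            write_tsv(result, path)
            outputs[f"enrichment_{direction}"] = path.name

    _enrich()

    # --- manifest -----------------------------------------------------------
    manifest = {
        "package": "medipdiff",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "thresholds": {
            "fc_min": config.fc_min,
            "p_max": config.p_max,
            "q_max": config.q_max,
            "peak_alpha": config.peak_alpha,
            "window_width": config.window_width,
            "repeat_window": config.repeat_window,
            "merge_gap": config.merge_gap,
        },
        "outputs": outputs,
        "checksums": {
            name: sha256_of(out / rel) for name, rel in sorted(outputs.items())
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


@_stage("inputs")
def _load_inputs(config: RunConfig, out: Path):
    """Simulate (default) or load explicit inputs."""
    if config.inputs:
        required = {"fasta", "gff3", "fragments"}
        missing = required - set(config.inputs)
        if missing:
            raise ValidationError(f"input config missing keys: {sorted(missing)}")
        annotation = load_annotation(
            config.inputs["gff3"],
            config.inputs["fasta"],
            config.inputs.get("repeats"),
        )
        fragments = {
            cond: FragmentSet.from_bed(path, cond)
            for cond, path in config.inputs["fragments"].items()
        }
        term_map = None
        if config.inputs.get("term_map"):
            term_map = pd.read_csv(
                config.inputs["term_map"], sep="\t", header=None,
                names=["gene", "term"],
            )
        return annotation, fragments, term_map

    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", config.seed)
    sim_config = SyntheticConfig(**sim_kwargs)
    exp = simulate_experiment(sim_config)
    from .synthetic import write_experiment

    write_experiment(exp, Path(out) / "simulated_inputs")
    return exp.annotation, exp.fragments, exp.term_map
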