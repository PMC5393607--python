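"""End-to-end orchestration: simulate -> call marks -> screen -> report.

The functions here are the programmatic face of the command line: each takes
a config (YAML path or object), runs the corresponding stage of the screen,
writes its output files, and returns a machine-readable summary. Stage gene
counts reported in the summary are, by construction, the row counts of the
TSVs written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from . import io as bio
from .calling import (
    DEFAULT_EFFECTIVE_GENOME_SIZE,
    LibraryStats,
    call_marks,
)
from .core import IntervalIndex, make_promoter_window
from .screen import (
    CONDITIONS,
    MARKS,
    annotate_expression,
    intersect_tf,
    screen_transitions,
)
from .simulate import SimConfig, simulate_scenario

__all__ = [
    "PipelineConfig",
    "run_simulate",
    "run_screen",
    "run_report",
    "screen_simulated",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and screen parameters for one run of the screen."""

    annotation: str
    reads_h3k4me3_pre: str
    reads_h3k4me3_post: str
    reads_h3k27me3_pre: str
    reads_h3k27me3_post: str
    tf_peaks: str
    out_dir: str = "."
    counts_pre: str | None = None
    counts_post: str | None = None
    annotation_format: str = "gtf"
    flank: int = 5000
    alpha: float = 0.05
    min_fold: float = 2.0
    effective_genome_size: float = DEFAULT_EFFECTIVE_GENOME_SIZE
    pseudocount: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        missing = {"annotation", "tf_peaks"} | {
            f"reads_{m.lower()}_{c}" for m in MARKS for c in CONDITIONS
        }
        missing -= set(raw)
        if missing:
            raise ValueError(f"missing required config key(s): {sorted(missing)}")
        return cls(**raw)

    def read_paths(self) -> dict[tuple[str, str], str]:
        return {
            (mark, condition): getattr(self, f"reads_{mark.lower()}_{condition}")
            for mark in MARKS
            for condition in CONDITIONS
        }

    def validate_paths(self) -> None:
        required = [self.annotation, self.tf_peaks, *self.read_paths().values()]
        if self.counts_pre or self.counts_post:
            required += [self.counts_pre, self.counts_post]
        for p in required:
            if p is None or not Path(p).is_file():
                raise FileNotFoundError(f"missing input file: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_simulate(config: SimConfig | str, out_dir) -> dict:
    """Generate a full synthetic scenario plus manifest and a ready screen config.

    Returns {"files": name->path, "manifest": path, "screen_config": path}.
    """
    if not isinstance(config, SimConfig):
        config = SimConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = simulate_scenario(config, out)

    screen_cfg = {
        "annotation": files["annotation"],
        "tf_peaks": files["tf_peaks"],
        "counts_pre": files["counts_pre"],
        "counts_post": files["counts_post"],
        "out_dir": str(out),
        "flank": config.flank,
        "effective_genome_size": float(config.genome_size),
    }
    for mark in MARKS:
        for condition in CONDITIONS:
            screen_cfg[f"reads_{mark.lower()}_{condition}"] = files[
                f"reads_{mark}_{condition}"
            ]
    screen_config_path = out / "screen_config.yaml"
    with open(screen_config_path, "w") as fh:
        yaml.safe_dump(screen_cfg, fh, sort_keys=True)

    manifest_path = out / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("file\tsha256\tbytes\n")
        for name in sorted(files):
            p = Path(files[name])
            fh.write(f"{p.name}\t{_sha256(p)}\t{p.stat().st_size}\n")
    return {
        "files": files,
        "manifest": str(manifest_path),
        "screen_config": str(screen_config_path),
    }


def run_screen(config: PipelineConfig | str) -> dict:
    """Run the full screen; writes mark_calls/transitions/candidates TSVs.

    Returns a summary dict (also written to summary.json) whose stage counts
    equal the row counts of the written tables.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = bio.read_annotation(config.annotation, format=config.annotation_format)
    windows = [make_promoter_window(g, flank=config.flank) for g in genes]
    window_by_gene = {w.gene_id: w for w in windows}
    symbols = {g.gene_id: g.symbol for g in genes}
    logger.info("annotated_genes=%d", len(genes))

    indexes = {}
    stats = {}
    for (mark, condition), path in config.read_paths().items():
        reads = bio.read_intervals_bed(path)
        indexes[(mark, condition)] = IntervalIndex(reads)
        stats[(mark, condition)] = LibraryStats(
            mark=mark,
            condition=condition,
            total_reads=len(reads),
            effective_genome_size=config.effective_genome_size,
        )
        logger.info("library %s/%s: %d reads", mark, condition, len(reads))

    calls = call_marks(
        windows, indexes, stats, alpha=config.alpha, min_fold=config.min_fold
    )
    mark_calls_path = out / "mark_calls.tsv"
    with open(mark_calls_path, "w") as fh:
        fh.write("gene_id\tmark\tcondition\tcount\tlambda_bg\tfold\tp_value\tq_value\tpresent\n")
        for c in calls:
            fh.write(
                f"{c.gene_id}\t{c.mark}\t{c.condition}\t{c.count}\t{c.lambda_bg!r}\t"
                f"{c.fold!r}\t{c.p_value!r}\t{c.q_value!r}\t{str(c.present).lower()}\n"
            )

    transitions = screen_transitions(calls)
    transitions_path = out / "transitions.tsv"
    with open(transitions_path, "w") as fh:
        fh.write("gene_id\tstate_pre\tstate_post\tis_switch\n")
        for t in transitions:
            fh.write(
                f"{t.gene_id}\t{t.state_pre.value}\t{t.state_post.value}\t"
                f"{str(t.is_switch).lower()}\n"
            )

    switch = [t for t in transitions if t.is_switch]
    logger.info("switch_genes=%d", len(switch))

    tf_peaks = bio.read_intervals_bed(config.tf_peaks)
    records = intersect_tf(switch, window_by_gene, tf_peaks, symbols=symbols)
    candidates = [r for r in records if r.tf_bound]
    logger.info("tf_bound=%d", len(candidates))

    if config.counts_pre and config.counts_post:
        counts_pre = bio.read_counts_tsv(config.counts_pre)
        counts_post = bio.read_counts_tsv(config.counts_post)
        candidates = annotate_expression(
            candidates,
            counts_pre.iloc[:, 0],
            counts_post.iloc[:, 0],
            pseudocount=config.pseudocount,
        )

    candidates_path = out / "candidates.tsv"
    bio.write_candidate_report(candidates, candidates_path)

    summary = {
        "annotated_genes": len(genes),
        "switch_genes": len(switch),
        "tf_bound": len(candidates),
        "candidate_symbols": sorted(r.symbol for r in candidates),
        "outputs": {
            "mark_calls": str(mark_calls_path),
            "transitions": str(transitions_path),
            "candidates": str(candidates_path),
        },
        "parameters": {
            "flank": config.flank,
            "alpha": config.alpha,
            "min_fold": config.min_fold,
            "effective_genome_size": config.effective_genome_size,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def screen_simulated(config: SimConfig) -> dict:
    """Simulate a scenario and run the screen fully in memory.

    Same statistical pipeline as :func:`run_screen` (library stats from the
    full simulated read sets) without the file round trip; used for seed
    sweeps. Returns the recovered and planted gene sets plus the truth table.
    """
    from .simulate import generate_annotation, generate_truth, simulate_reads, simulate_tf_peaks

    truth = generate_truth(config)
    genes = generate_annotation(config, truth)
    libraries = simulate_reads(truth, genes, config)
    windows = [make_promoter_window(g, flank=config.flank) for g in genes]
    window_by_gene = {w.gene_id: w for w in windows}
    symbols = {g.gene_id: g.symbol for g in genes}
    indexes = {key: lib.index() for key, lib in libraries.items()}
    stats = {key: lib.stats for key, lib in libraries.items()}
    calls = call_marks(windows, indexes, stats)
    transitions = screen_transitions(calls)
    switch = [t for t in transitions if t.is_switch]
    tf_peaks = simulate_tf_peaks(truth, genes, config)
    records = intersect_tf(switch, window_by_gene, tf_peaks, symbols=symbols)
    candidates = [r for r in records if r.tf_bound]
    planted_switch = set(
        truth.loc[
            (truth["state_pre"] == "bivalent")
            & (truth["state_post"] == "k4_monovalent"),
            "gene_id",
        ]
    )
    return {
        "truth": truth,
        "mark_calls": calls,
        "transitions": transitions,
        "switch_ids": {t.gene_id for t in switch},
        "planted_switch_ids": planted_switch,
        "candidate_symbols": {r.symbol for r in candidates},
        "planted_tf_symbols": set(truth.loc[truth["tf_peak_planted"], "symbol"]),
        "candidates": candidates,
    }


def run_report(
    candidates_path, counts_pre_path, counts_post_path, out_path, pseudocount: float = 0.5
) -> int:
    """Annotate an existing candidate report with expression log2FC; returns row count."""
    records = bio.read_candidate_report(candidates_path)
    counts_pre = bio.read_counts_tsv(counts_pre_path)
    counts_post = bio.read_counts_tsv(counts_post_path)
    annotated = annotate_expression(
        records, counts_pre.iloc[:, 0], counts_post.iloc[:, 0], pseudocount=pseudocount
    )
    bio.write_candidate_report(annotated, out_path)
    return len(annotated)
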