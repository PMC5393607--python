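"""Synthetic two-mark, two-condition ChIP-seq data with planted ground truth.

The generator emulates the data behind a promoter bivalency screen of
osteoclast differentiation: H3K4me3 and H3K27me3 read sets for a precursor
("pre", BMM-like) and a differentiated ("post", osteoclast-like) condition,
NFATc1-style TF peak calls, a gene annotation, and expression counts — all
derived deterministically from a seed, with the planted per-gene chromatin
states recorded in a truth table.

The packaged ``osteoclast`` scenario plants 49 bivalent -> K4-monovalent
switch genes among 2,000, gives 33 of them a TF peak at the TSS, and assigns
those 33 the symbols of the known osteoclast candidate set (*Cadm1*,
*Nfatc1*, *Car2*, ...), so the full screen has an exact expected answer.

Model choices: background reads are a homogeneous Poisson process over the
genome, tuned so a promoter window collects ``lambda_bg_per_window`` expected
background reads; a planted-present mark adds uniformly placed reads inside
the window until its expectation is ``enrichment_fold`` times background (no
peak shape — the caller integrates over the window); expression counts are
negative binomial with a planted log2 fold change on switch genes.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calling import LibraryStats
from .core import GeneRecord, GenomicInterval
from .screen import ChromatinState

__all__ = [
    "CANDIDATE_SYMBOLS",
    "SimConfig",
    "SimulatedLibrary",
    "generate_truth",
    "generate_annotation",
    "simulate_reads",
    "simulate_tf_peaks",
    "simulate_counts",
    "simulate_scenario",
]

#: The 33 osteoclast switch genes with TF promoter binding that the
#: ``osteoclast`` scenario plants (alphabetical).
CANDIDATE_SYMBOLS = (
    "4930506M07Rik", "Adcy3", "Arhgef12", "Atrnl1", "Bahd1", "Cadm1",
    "Car2", "Cd109", "Cd97", "Cdyl2", "Cgnl1", "D10Bwg1379e",
    "Edil3", "Fbxo32", "Lgals3", "Met", "Msi2", "Myo1d",
    "Nfatc1", "Plxna2", "Plxnd1", "Ppap2a", "Rab34", "Rab38",
    "Rnd1", "Rps6ka2", "Rusc2", "Sdc1", "Sh3bgrl2", "Tmcc3",
    "Tspan17", "Vegfa", "Zfp462",
)

# state-pair keys usable in proportions: name -> (state_pre, state_post)
STATE_PAIRS = {
    "switch": (ChromatinState.BIVALENT, ChromatinState.K4_MONOVALENT),
    "biv_biv": (ChromatinState.BIVALENT, ChromatinState.BIVALENT),
    "k4_k4": (ChromatinState.K4_MONOVALENT, ChromatinState.K4_MONOVALENT),
    "biv_unmarked": (ChromatinState.BIVALENT, ChromatinState.UNMARKED),
    "k27_k27": (ChromatinState.K27_MONOVALENT, ChromatinState.K27_MONOVALENT),
    "unmarked_k4": (ChromatinState.UNMARKED, ChromatinState.K4_MONOVALENT),
    "unmarked": (ChromatinState.UNMARKED, ChromatinState.UNMARKED),
}

MARKS = ("H3K4me3", "H3K27me3")
CONDITIONS = ("pre", "post")


@dataclass(frozen=True)
class SimConfig:
    """All tunables of the simulator; a pure function of this + seed.

    ``chrom_length`` is per chromosome; the genome totals
    ``n_chroms * chrom_length`` bp (2e8 at defaults, over 5 chromosomes).
    """

    n_genes: int = 2000
    n_chroms: int = 5
    chrom_length: int = 40_000_000
    flank: int = 5000
    lambda_bg_per_window: float = 10.0
    enrichment_fold: float = 8.0
    read_length: int = 36
    tf_peak_width: int = 400
    tf_offtarget_rate: float = 0.0  # expected stray peaks genome-wide
    seed: int = 42
    scenario: str = "osteoclast"
    n_switch: int = 49
    n_tf_bound: int = 33
    # distractor state proportions (fraction of n_genes); remainder unmarked
    frac_biv_biv: float = 0.10
    frac_k4_k4: float = 0.20
    frac_biv_unmarked: float = 0.05
    # proportions for the "random" scenario; None reproduces the defaults above
    random_proportions: dict | None = None
    # expression model
    depth: float = 1e6  # expected library total per condition
    switch_lfc: float = 3.0  # planted log2FC on switch genes
    base_expression_sigma: float = 1.0  # lognormal spread of baseline means
    nb_size: float = 50.0  # NB shape r (dispersion 1/r)

    def __post_init__(self) -> None:
        positive = (
            "n_chroms", "chrom_length", "flank", "enrichment_fold",
            "read_length", "tf_peak_width", "depth", "nb_size",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.lambda_bg_per_window < 0:
            raise ValueError("lambda_bg_per_window must be >= 0")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.scenario not in ("osteoclast", "random", "custom"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "osteoclast" and 0 < self.n_genes < self.n_switch:
            raise ValueError(
                f"osteoclast scenario needs n_genes >= {self.n_switch}, got {self.n_genes}"
            )
        if not 0 <= self.n_tf_bound <= self.n_switch:
            raise ValueError("need 0 <= n_tf_bound <= n_switch")

    @property
    def genome_size(self) -> int:
        return self.n_chroms * self.chrom_length

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass(frozen=True)
class SimulatedLibrary:
    """One simulated read set plus its bookkeeping.

    Reads are kept as parallel (chrom number, start) arrays; ``index()``
    builds an overlap-count index without materializing interval objects.
    """

    stats: LibraryStats
    n_background: int
    n_enriched: int
    read_length: int
    chrom_nums: np.ndarray = field(repr=False, default=None)
    starts: np.ndarray = field(repr=False, default=None)
    path: str | None = None

    def index(self):
        from .core import IntervalIndex

        chroms = np.char.add("chr", self.chrom_nums.astype(str))
        return IntervalIndex.from_arrays(
            chroms, self.starts, self.starts + self.read_length
        )


def _rngs(config: SimConfig) -> dict[str, np.random.Generator]:
    """Named, independent RNG streams so each stage is reproducible alone."""
    root = np.random.SeedSequence(config.seed)
    names = (
        "truth", "annotation",
        "reads_H3K4me3_pre", "reads_H3K4me3_post",
        "reads_H3K27me3_pre", "reads_H3K27me3_post",
        "tf", "counts",
    )
    children = root.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


# ---------------------------------------------------------------------------
# truth table


def _osteoclast_pairs(config: SimConfig, rng: np.random.Generator) -> list[str]:
    """Per-gene state-pair names with the fixed osteoclast-scenario counts."""
    n = config.n_genes
    if n == 0:
        return []
    counts = {
        "switch": config.n_switch,
        "biv_biv": round(config.frac_biv_biv * n),
        "k4_k4": round(config.frac_k4_k4 * n),
        "biv_unmarked": round(config.frac_biv_unmarked * n),
    }
    if sum(counts.values()) > n:
        raise ValueError("state proportions exceed n_genes")
    counts["unmarked"] = n - sum(counts.values())
    labels = np.repeat(
        list(counts.keys()), list(counts.values())
    )
    return list(rng.permutation(labels))


def _random_pairs(config: SimConfig, rng: np.random.Generator) -> list[str]:
    props = config.random_proportions
    if props is None:
        n = max(config.n_genes, 1)
        props = {
            "switch": config.n_switch / n,
            "biv_biv": config.frac_biv_biv,
            "k4_k4": config.frac_k4_k4,
            "biv_unmarked": config.frac_biv_unmarked,
        }
        props["unmarked"] = max(0.0, 1.0 - sum(props.values()))
    unknown = set(props) - set(STATE_PAIRS)
    if unknown:
        raise ValueError(f"unknown state pair(s) in proportions: {sorted(unknown)}")
    names = sorted(props)
    weights = np.array([props[k] for k in names], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("proportions must sum to a positive value")
    weights = weights / weights.sum()
    return list(rng.choice(names, size=config.n_genes, p=weights))


def generate_truth(config: SimConfig) -> pd.DataFrame:
    """Planted per-gene ground truth.

    Columns: gene_id, symbol, state_pre, state_post, tf_peak_planted,
    expression_lfc_planted. In the osteoclast scenario exactly ``n_switch``
    genes switch bivalent -> K4-monovalent and exactly ``n_tf_bound`` of them
    carry a planted TF peak and one of the known candidate symbols.
    """
    rng = _rngs(config)["truth"]
    if config.scenario == "random":
        pairs = _random_pairs(config, rng)
    else:
        pairs = _osteoclast_pairs(config, rng)

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    symbols = [f"Sim{i:05d}" for i in range(config.n_genes)]
    tf_planted = np.zeros(config.n_genes, dtype=bool)
    lfc = np.zeros(config.n_genes, dtype=float)

    switch_idx = [i for i, p in enumerate(pairs) if p == "switch"]
    lfc[switch_idx] = config.switch_lfc
    if config.scenario != "random" and switch_idx:
        # TF peaks (and the named candidate symbols) go to a random subset of
        # the switch genes; symbols are assigned in positional order so the
        # mapping is deterministic given the seed.
        chosen = sorted(
            rng.choice(len(switch_idx), size=config.n_tf_bound, replace=False)
        )
        for sym, j in zip(CANDIDATE_SYMBOLS, chosen):
            gi = switch_idx[j]
            tf_planted[gi] = True
            symbols[gi] = sym
    else:
        tf_planted[switch_idx] = True

    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": symbols,
            "state_pre": [STATE_PAIRS[p][0].value for p in pairs],
            "state_post": [STATE_PAIRS[p][1].value for p in pairs],
            "tf_peak_planted": tf_planted,
            "expression_lfc_planted": lfc,
        }
    )


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    config: SimConfig,
    truth: pd.DataFrame | None = None,
    path=None,
) -> list[GeneRecord]:
    """Place genes with non-overlapping promoter windows; optionally write GTF.

    Genes are laid out round-robin over the chromosomes at even spacing (with
    >= 2*flank between TSSs, so +/-flank windows never overlap or clip);
    strands are random.
    """
    if truth is None:
        truth = generate_truth(config)
    rng = _rngs(config)["annotation"]
    n = config.n_genes
    if n == 0:
        if path is not None:
            with open(path, "w") as fh:
                fh.write(f"# seed={config.seed}\n")
        return []
    per_chrom = [n // config.n_chroms + (c < n % config.n_chroms) for c in range(config.n_chroms)]
    for n_c in per_chrom:
        if n_c and (config.chrom_length - 2 * config.flank) / n_c < 2 * config.flank:
            raise ValueError(
                f"cannot fit {n_c} genes on a {config.chrom_length} bp chromosome "
                f"with >= {2 * config.flank} bp TSS spacing"
            )
    strands = rng.choice(["+", "-"], size=n)
    genes: list[GeneRecord] = []
    i = 0
    for c, n_c in enumerate(per_chrom):
        usable = config.chrom_length - 2 * config.flank
        for j in range(n_c):
            tss = config.flank + int((j + 0.5) * usable / n_c)
            genes.append(
                GeneRecord(
                    gene_id=truth["gene_id"].iloc[i],
                    symbol=truth["symbol"].iloc[i],
                    chrom=f"chr{c + 1}",
                    tss=tss,
                    strand=str(strands[i]),
                )
            )
            i += 1
    if path is not None:
        _write_gtf(genes, config, path)
    return genes


def _write_gtf(genes: Sequence[GeneRecord], config: SimConfig, path) -> None:
    body = 10_000  # nominal gene-body length for the GTF span
    with open(path, "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        for g in genes:
            if g.strand == "+":
                start0, end0 = g.tss, min(g.tss + body, config.chrom_length)
            else:
                start0, end0 = max(0, g.tss + 1 - body), g.tss + 1
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tbivalscreen\tgene\t{start0 + 1}\t{end0}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# reads


def _planted_present(truth: pd.DataFrame, mark: str, condition: str) -> np.ndarray:
    states = truth[f"state_{condition}"].to_numpy()
    if mark == "H3K4me3":
        return (states == "bivalent") | (states == "k4_monovalent")
    return (states == "bivalent") | (states == "k27_monovalent")


def simulate_reads(
    truth: pd.DataFrame,
    genes: Sequence[GeneRecord],
    config: SimConfig,
    out_dir=None,
) -> dict[tuple[str, str], SimulatedLibrary]:
    """Simulate the four mark x condition libraries; optionally write BEDs.

    The per-start background rate is lambda_bg / (2*flank + read_length - 1),
    which makes the expected number of background reads overlapping an
    interior promoter window exactly ``lambda_bg_per_window``. Each
    planted-present window gets Poisson((fold - 1) * lambda_bg) extra reads
    placed uniformly inside it, bringing its expectation to fold * lambda_bg.
    """
    rngs = _rngs(config)
    window_span = 2 * config.flank + config.read_length - 1
    rate = config.lambda_bg_per_window / window_span
    n_starts = config.chrom_length - config.read_length + 1
    libraries: dict[tuple[str, str], SimulatedLibrary] = {}
    for mark in MARKS:
        for condition in CONDITIONS:
            rng = rngs[f"reads_{mark}_{condition}"]
            chroms: list[np.ndarray] = []
            starts: list[np.ndarray] = []
            n_bg = 0
            for c in range(config.n_chroms):
                k = rng.poisson(rate * n_starts)
                chroms.append(np.full(k, c + 1, dtype=np.int32))
                starts.append(rng.integers(0, n_starts, size=k))
                n_bg += int(k)
            n_enr = 0
            present = _planted_present(truth, mark, condition)
            extra_rate = (config.enrichment_fold - 1.0) * config.lambda_bg_per_window
            if extra_rate > 0:
                for gi in np.flatnonzero(present):
                    g = genes[gi]
                    lo = max(0, g.tss - config.flank)
                    hi = min(config.chrom_length, g.tss + config.flank) - config.read_length
                    k = rng.poisson(extra_rate)
                    chroms.append(np.full(k, int(g.chrom[3:]), dtype=np.int32))
                    starts.append(rng.integers(lo, hi + 1, size=k))
                    n_enr += int(k)
            chrom_arr = np.concatenate(chroms) if chroms else np.empty(0, dtype=np.int32)
            start_arr = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
            stats = LibraryStats(
                mark=mark,
                condition=condition,
                total_reads=n_bg + n_enr,
                effective_genome_size=float(config.genome_size),
            )
            path = None
            if out_dir is not None:
                path = str(Path(out_dir) / f"reads_{mark}_{condition}.bed")
                _write_reads_bed(chrom_arr, start_arr, config, path)
            libraries[(mark, condition)] = SimulatedLibrary(
                stats=stats,
                n_background=n_bg,
                n_enriched=n_enr,
                read_length=config.read_length,
                chrom_nums=chrom_arr,
                starts=start_arr,
                path=path,
            )
    return libraries


def _write_reads_bed(chrom_arr, start_arr, config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        rl = config.read_length
        for c, s in zip(chrom_arr.tolist(), start_arr.tolist()):
            fh.write(f"chr{c}\t{s}\t{s + rl}\n")


# ---------------------------------------------------------------------------
# TF peaks


def simulate_tf_peaks(
    truth: pd.DataFrame,
    genes: Sequence[GeneRecord],
    config: SimConfig,
    path=None,
) -> list[GenomicInterval]:
    """One peak centered on the TSS of each tf_peak_planted gene.

    ``tf_offtarget_rate`` adds Poisson-many stray peaks uniformly over the
    genome (default 0).
    """
    rng = _rngs(config)["tf"]
    half = config.tf_peak_width // 2
    peaks = []
    for gi in np.flatnonzero(truth["tf_peak_planted"].to_numpy()):
        g = genes[gi]
        start = max(0, g.tss - half)
        end = min(config.chrom_length, g.tss - half + config.tf_peak_width)
        peaks.append(GenomicInterval(g.chrom, start, end))
    n_off = rng.poisson(config.tf_offtarget_rate)
    for _ in range(n_off):
        c = int(rng.integers(1, config.n_chroms + 1))
        start = int(rng.integers(0, config.chrom_length - config.tf_peak_width))
        peaks.append(GenomicInterval(f"chr{c}", start, start + config.tf_peak_width))
    if path is not None:
        with open(path, "w") as fh:
            fh.write(f"# seed={config.seed}\n")
            for p in peaks:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
    return peaks


# ---------------------------------------------------------------------------
# expression counts


def simulate_counts(
    truth: pd.DataFrame, config: SimConfig, out_dir=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts for both conditions (one single-column table each).

    Baseline gene abundances are lognormal; the post-condition mean is shifted
    by the planted log2FC; per-condition means are scaled so each library's
    expected total equals ``depth``. Counts are NB with shape ``nb_size``.
    """
    rng = _rngs(config)["counts"]
    n = config.n_genes
    base = rng.lognormal(mean=0.0, sigma=config.base_expression_sigma, size=n)
    lfc = truth["expression_lfc_planted"].to_numpy()
    mu_pre = base / base.sum() * config.depth if n else base
    w_post = base * np.exp2(lfc)
    mu_post = w_post / w_post.sum() * config.depth if n else w_post
    r = config.nb_size

    def draw(mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = r / (r + mu)
        return rng.negative_binomial(r, p) if mu.size else np.empty(0, dtype=int)

    idx = pd.Index(truth["gene_id"], name="gene_id")
    pre = pd.DataFrame({"pre": draw(mu_pre)}, index=idx)
    post = pd.DataFrame({"post": draw(mu_post)}, index=idx)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        for name, df in (("counts_pre.tsv", pre), ("counts_post.tsv", post)):
            p = Path(out_dir) / name
            with open(p, "w") as fh:
                fh.write(f"# seed={config.seed}\n")
                df.to_csv(fh, sep="\t", index=True, index_label="gene_id")
    return pre, post


# ---------------------------------------------------------------------------
# one-call orchestration


def simulate_scenario(config: SimConfig, out_dir) -> dict[str, str]:
    """Generate the full scenario into ``out_dir``; returns name -> path.

    Writes: annotation.gtf, 4x reads_<mark>_<condition>.bed, tf_peaks.bed,
    counts_pre.tsv, counts_post.tsv, truth.tsv, config.yaml.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)
    genes = generate_annotation(config, truth, path=out / "annotation.gtf")
    libraries = simulate_reads(truth, genes, config, out_dir=out)
    simulate_tf_peaks(truth, genes, config, path=out / "tf_peaks.bed")
    simulate_counts(truth, config, out_dir=out)
    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(f"# seed={config.seed}\n")
        truth.to_csv(fh, sep="\t", index=False)
    config.to_yaml(out / "config.yaml")
    files = {
        "annotation": str(out / "annotation.gtf"),
        "tf_peaks": str(out / "tf_peaks.bed"),
        "counts_pre": str(out / "counts_pre.tsv"),
        "counts_post": str(out / "counts_post.tsv"),
        "truth": str(truth_path),
        "config": str(out / "config.yaml"),
    }
    for (mark, condition), lib in libraries.items():
        files[f"reads_{mark}_{condition}"] = lib.path
    return files


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
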