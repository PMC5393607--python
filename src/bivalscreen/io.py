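"""Readers and writers for the interchange formats the screen touches.

Conventions: BED is 0-based half-open and kept bit-exact; GTF is 1-based
inclusive and converted on read; all writers emit byte-deterministic output
for identical inputs. Readers reject malformed input with the offending line
number — nothing is silently repaired.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from .core import GeneRecord, GenomicInterval
from .screen import CandidateRecord, ChromatinState

__all__ = [
    "ParseError",
    "read_annotation",
    "read_intervals_bed",
    "write_intervals_bed",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_candidate_report",
    "read_candidate_report",
    "write_bedgraph",
]

REPORT_COLUMNS = (
    "gene_id",
    "symbol",
    "state_pre",
    "state_post",
    "is_switch",
    "tf_bound",
    "log2fc_expression",
)


class ParseError(ValueError):
    """Malformed input file; message carries file and line number."""


def _fail(path, lineno: int, msg: str):
    raise ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# gene annotation

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_annotation(path, format: str = "gtf") -> list[GeneRecord]:
    """Read a gene annotation and collapse it to one canonical TSS per gene.

    Supported dialects: ``gtf`` (any feature lines; attributes must carry
    gene_id, with gene_name as optional symbol), ``bed12`` (one transcript per
    line, name column = gene id), and ``tss_tsv`` (explicit columns gene_id,
    symbol, chrom, tss, strand). The canonical TSS of a multi-transcript gene
    is the 5'-most start site on the gene's strand.
    """
    readers = {"gtf": _read_gtf, "bed12": _read_bed12, "tss_tsv": _read_tss_tsv}
    if format not in readers:
        raise ValueError(f"unknown annotation format {format!r}")
    genes = readers[format](path)
    if not genes:
        raise ValueError(f"{path}: annotation contains zero genes")
    return genes


def _collapse(spans, path) -> list[GeneRecord]:
    """spans: gene_id -> (symbol, chrom, strand, [candidate 0-based starts/ends])."""
    genes = []
    for gene_id in sorted(spans):
        symbol, chrom, strand, starts, ends = spans[gene_id]
        tss = min(starts) if strand == "+" else max(ends) - 1
        genes.append(GeneRecord(gene_id, symbol, chrom, tss, strand))
    return genes


def _read_gtf(path) -> list[GeneRecord]:
    spans: dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                _fail(path, lineno, f"expected 9 tab-separated GTF fields, got {len(fields)}")
            chrom, _src, _feat, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            if start1 < 1 or end1 < start1:
                _fail(path, lineno, f"invalid 1-based span {start1}-{end1}")
            if strand not in ("+", "-"):
                _fail(path, lineno, f"gene strand must be + or -, got {strand!r}")
            attr = dict(_GTF_ATTR.findall(attrs))
            if "gene_id" not in attr:
                _fail(path, lineno, "missing gene_id attribute")
            gene_id = attr["gene_id"]
            symbol = attr.get("gene_name", gene_id)
            start0, end0 = start1 - 1, end1  # GTF is 1-based inclusive
            if gene_id not in spans:
                spans[gene_id] = (symbol, chrom, strand, [start0], [end0])
            else:
                prev = spans[gene_id]
                if prev[1] != chrom or prev[2] != strand:
                    _fail(path, lineno, f"gene {gene_id!r} spans multiple chroms/strands")
                prev[3].append(start0)
                prev[4].append(end0)
    return _collapse(spans, path)


def _read_bed12(path) -> list[GeneRecord]:
    spans: dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                _fail(path, lineno, f"BED12 needs >= 6 fields, got {len(fields)}")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            if start < 0 or end <= start:
                _fail(path, lineno, f"invalid span [{start}, {end})")
            if strand not in ("+", "-"):
                _fail(path, lineno, f"gene strand must be + or -, got {strand!r}")
            if name not in spans:
                spans[name] = (name, chrom, strand, [start], [end])
            else:
                prev = spans[name]
                if prev[1] != chrom or prev[2] != strand:
                    _fail(path, lineno, f"gene {name!r} spans multiple chroms/strands")
                prev[3].append(start)
                prev[4].append(end)
    return _collapse(spans, path)


def _read_tss_tsv(path) -> list[GeneRecord]:
    genes = []
    seen = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene_id", "symbol", "chrom", "tss", "strand"]
        if header != expected:
            _fail(path, 1, f"expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                _fail(path, lineno, f"expected 5 fields, got {len(fields)}")
            gene_id, symbol, chrom, tss_s, strand = fields
            if gene_id in seen:
                _fail(path, lineno, f"duplicated gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                tss = int(tss_s)
            except ValueError:
                _fail(path, lineno, "non-integer tss")
            try:
                genes.append(GeneRecord(gene_id, symbol, chrom, tss, strand))
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return genes


# ---------------------------------------------------------------------------
# intervals (reads, peaks)


def read_intervals_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file into GenomicIntervals, preserving file order."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                _fail(path, lineno, f"BED needs >= 3 fields, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, "non-integer coordinates")
            if start < 0 or end <= start:
                _fail(path, lineno, f"invalid span [{start}, {end})")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


def write_intervals_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED6 (name '.', score 0) in the given order."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_bedgraph(
    intervals: Iterable[tuple[str, int, int, float]], path, track_name: str = "coverage"
) -> None:
    """Write (chrom, start, end, value) tuples as a bedGraph track."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# expression counts


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a gene_id x condition table of non-negative integer counts."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: counts table needs gene_id plus >= 1 condition column")
    if df.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        first = df["gene_id"][dup].iloc[0]
        raise ParseError(f"{path}: duplicated gene_id {first!r}")
    counts = df.set_index("gene_id")
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or (vals % 1 != 0).any():
            raise ParseError(f"{path}: column {col!r} has negative or non-integer counts")
        counts[col] = vals.astype(int)
    return counts


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=True, index_label="gene_id")


# ---------------------------------------------------------------------------
# candidate report


def _fmt_lfc(value: float | None) -> str:
    return "NA" if value is None else repr(float(value))


def write_candidate_report(records: Sequence[CandidateRecord], path) -> None:
    """Write the candidate report TSV, sorted by symbol (byte-deterministic)."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for rec in sorted(records, key=lambda r: (r.symbol, r.gene_id)):
            fh.write(
                "\t".join(
                    (
                        rec.gene_id,
                        rec.symbol,
                        rec.state_pre.value,
                        rec.state_post.value,
                        str(rec.is_switch).lower(),
                        str(rec.tf_bound).lower(),
                        _fmt_lfc(rec.log2fc_expression),
                    )
                )
                + "\n"
            )


def read_candidate_report(path) -> list[CandidateRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(REPORT_COLUMNS):
            _fail(path, 1, f"expected header {list(REPORT_COLUMNS)}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(REPORT_COLUMNS):
                _fail(path, lineno, f"expected {len(REPORT_COLUMNS)} fields, got {len(fields)}")
            gene_id, symbol, pre_s, post_s, switch_s, bound_s, lfc_s = fields
            try:
                records.append(
                    CandidateRecord(
                        gene_id=gene_id,
                        symbol=symbol,
                        state_pre=ChromatinState(pre_s),
                        state_post=ChromatinState(post_s),
                        is_switch=switch_s == "true",
                        tf_bound=bound_s == "true",
                        log2fc_expression=None if lfc_s == "NA" else float(lfc_s),
                    )
                )
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return records
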