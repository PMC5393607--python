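"""Per-promoter histone-mark presence calls.

Model: reads of a ChIP library fall on the genome as a homogeneous Poisson
process, so the background expectation for a window of length L is

    lambda = total_reads * L / effective_genome_size

(a global, MACS-style lambda; no input track, no local background). A mark is
called present in a window when the observed read count is both sufficiently
enriched (count / lambda >= min_fold) and significant under the Poisson
upper tail after Benjamini-Hochberg correction across all promoters of the
same (mark, condition) stratum (q < alpha).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, IntervalIndex, PromoterWindow

__all__ = [
    "LibraryStats",
    "MarkCall",
    "background_rate",
    "poisson_upper_tail",
    "bh_adjust",
    "call_marks",
]

#: mappable mouse genome, the organism the screen was designed for
DEFAULT_EFFECTIVE_GENOME_SIZE = 1.87e9


@dataclass(frozen=True, slots=True)
class LibraryStats:
    """Size and genome context of one sequenced ChIP library."""

    mark: str
    condition: str
    total_reads: int
    effective_genome_size: float

    def __post_init__(self) -> None:
        if self.total_reads < 0:
            raise ValueError("total_reads must be >= 0")
        if self.effective_genome_size <= 0:
            raise ValueError("effective_genome_size must be > 0")


@dataclass(frozen=True, slots=True)
class MarkCall:
    """Evidence and verdict for one promoter x mark x condition cell."""

    gene_id: str
    mark: str
    condition: str
    count: int
    lambda_bg: float
    fold: float
    p_value: float
    q_value: float
    present: bool


def background_rate(stats: LibraryStats, window_length: int) -> float:
    """Expected background read count in a window: total * L / genome."""
    if window_length <= 0:
        raise ValueError(f"window_length must be positive, got {window_length}")
    if stats.total_reads == 0:
        raise ValueError(
            f"degenerate library ({stats.mark}/{stats.condition}): zero total reads"
        )
    return stats.total_reads * window_length / stats.effective_genome_size


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam); exactly 1 for k <= 0."""
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if k == 0:
        return 1.0
    # sf is the complemented CDF, computed in a numerically stable way
    # (log-space internally), so extreme tails do not underflow to garbage.
    return float(poisson.sf(k - 1, lam))


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_marks(
    windows: Sequence[PromoterWindow],
    reads_by_mark_condition: Mapping[
        tuple[str, str], Sequence[GenomicInterval] | IntervalIndex
    ],
    stats: Mapping[tuple[str, str], LibraryStats],
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> list[MarkCall]:
    """Call mark presence for every window x (mark, condition) stratum.

    BH correction is applied within each stratum across all windows, so the
    FDR target refers to promoters, the unit the screen selects on. A missing
    read set or LibraryStats for a declared stratum is a configuration error.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if min_fold < 1:
        raise ValueError(f"min_fold must be >= 1, got {min_fold}")
    for key in reads_by_mark_condition:
        if key not in stats:
            raise KeyError(f"no LibraryStats for stratum {key}")

    calls: list[MarkCall] = []
    for (mark, condition), reads in sorted(reads_by_mark_condition.items()):
        index = reads if isinstance(reads, IntervalIndex) else IntervalIndex(reads)
        lib = stats[(mark, condition)]
        counts = np.array([index.count(w.interval) for w in windows], dtype=np.int64)
        lambdas = np.array(
            [background_rate(lib, w.interval.length) for w in windows], dtype=float
        )
        folds = counts / lambdas
        pvals = poisson.sf(counts - 1, lambdas)
        pvals[counts == 0] = 1.0
        qvals = bh_adjust(pvals)
        present = (folds >= min_fold) & (qvals < alpha)
        calls.extend(
            MarkCall(
                gene_id=w.gene_id,
                mark=mark,
                condition=condition,
                count=int(c),
                lambda_bg=float(l),
                fold=float(f),
                p_value=float(p),
                q_value=float(q),
                present=bool(pr),
            )
            for w, c, l, f, p, q, pr in zip(
                windows, counts, lambdas, folds, pvals, qvals, present
            )
        )
    return calls
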