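"""Promoter chromatin-state classification and the transition screen.

A promoter's state in one condition is determined by two booleans — H3K4me3
present, H3K27me3 present — giving four categories: bivalent (both),
K4-monovalent (activating mark only), K27-monovalent (repressive mark only)
and unmarked. The screen retains genes whose promoter resolves from bivalent
in the precursor condition to K4-monovalent in the differentiated condition
(the poised-to-active switch), then intersects those promoters with TF peak
calls and optionally annotates an expression log2 fold change.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace
from enum import Enum

import pandas as pd

from .calling import MarkCall
from .core import GenomicInterval, IntervalIndex, PromoterWindow

__all__ = [
    "ChromatinState",
    "StateTransition",
    "CandidateRecord",
    "classify_state",
    "detect_switch",
    "screen_transitions",
    "intersect_tf",
    "annotate_expression",
]

logger = logging.getLogger(__name__)

MARKS = ("H3K4me3", "H3K27me3")
CONDITIONS = ("pre", "post")


class ChromatinState(str, Enum):
    BIVALENT = "bivalent"
    K4_MONOVALENT = "k4_monovalent"
    K27_MONOVALENT = "k27_monovalent"
    UNMARKED = "unmarked"

    def __str__(self) -> str:  # report-friendly
        return self.value


@dataclass(frozen=True, slots=True)
class StateTransition:
    gene_id: str
    state_pre: ChromatinState
    state_post: ChromatinState
    is_switch: bool

    def __post_init__(self) -> None:
        expected = detect_switch(self.state_pre, self.state_post)
        if self.is_switch != expected:
            raise ValueError(
                f"is_switch={self.is_switch} inconsistent with "
                f"({self.state_pre}, {self.state_post})"
            )


@dataclass(frozen=True, slots=True)
class CandidateRecord:
    """One row of the candidate report: a switch gene and its TF-binding status."""

    gene_id: str
    symbol: str
    state_pre: ChromatinState
    state_post: ChromatinState
    is_switch: bool
    tf_bound: bool
    log2fc_expression: float | None = None


def classify_state(k4_present: bool, k27_present: bool) -> ChromatinState:
    """Map the two mark-presence booleans to a promoter chromatin state."""
    if k4_present and k27_present:
        return ChromatinState.BIVALENT
    if k4_present:
        return ChromatinState.K4_MONOVALENT
    if k27_present:
        return ChromatinState.K27_MONOVALENT
    return ChromatinState.UNMARKED


def detect_switch(state_pre: ChromatinState, state_post: ChromatinState) -> bool:
    """True only for the bivalent -> K4-monovalent resolution.

    Other transitions (bivalent -> unmarked, K27 -> K4, constitutive K4, ...)
    are reported in the transition table but are not screen hits.
    """
    return (
        state_pre is ChromatinState.BIVALENT
        and state_post is ChromatinState.K4_MONOVALENT
    )


def screen_transitions(mark_calls: Iterable[MarkCall]) -> list[StateTransition]:
    """Fold per-cell mark calls into one StateTransition per gene.

    Expects up to one call per (gene, mark, condition) cell; a duplicated cell
    is an input error, a missing cell degrades to "mark absent" with a logged
    warning (sparse peak files are normal for real data). Output is sorted by
    gene_id for determinism.
    """
    presence: dict[str, dict[tuple[str, str], bool]] = {}
    for call in mark_calls:
        key = (call.mark, call.condition)
        cells = presence.setdefault(call.gene_id, {})
        if key in cells:
            raise ValueError(
                f"duplicated mark-call cell for gene {call.gene_id!r}, "
                f"mark {call.mark}, condition {call.condition}"
            )
        cells[key] = call.present

    transitions = []
    n_missing = 0
    for gene_id in sorted(presence):
        cells = presence[gene_id]
        n_missing += 4 - len(cells)
        state_pre = classify_state(
            cells.get(("H3K4me3", "pre"), False), cells.get(("H3K27me3", "pre"), False)
        )
        state_post = classify_state(
            cells.get(("H3K4me3", "post"), False), cells.get(("H3K27me3", "post"), False)
        )
        transitions.append(
            StateTransition(
                gene_id=gene_id,
                state_pre=state_pre,
                state_post=state_post,
                is_switch=detect_switch(state_pre, state_post),
            )
        )
    if n_missing:
        logger.warning("%d missing mark-call cells treated as absent", n_missing)
    return transitions


def intersect_tf(
    switch_genes: Sequence[StateTransition],
    windows: Mapping[str, PromoterWindow],
    tf_peaks: Sequence[GenomicInterval] | IntervalIndex,
    symbols: Mapping[str, str] | None = None,
) -> list[CandidateRecord]:
    """Flag each switch gene whose promoter window overlaps >= 1 TF peak by >= 1 bp.

    Returns one CandidateRecord per is_switch gene (non-switch transitions are
    not candidates); the final candidate set is the tf_bound subset. `symbols`
    maps gene_id -> display symbol (defaults to the gene_id itself).
    """
    index = tf_peaks if isinstance(tf_peaks, IntervalIndex) else IntervalIndex(tf_peaks)
    records = []
    for tr in switch_genes:
        if not tr.is_switch:
            continue
        try:
            window = windows[tr.gene_id]
        except KeyError:
            raise KeyError(f"switch gene {tr.gene_id!r} has no promoter window") from None
        bound = index.count(window.interval) > 0
        symbol = symbols[tr.gene_id] if symbols is not None else tr.gene_id
        records.append(
            CandidateRecord(
                gene_id=tr.gene_id,
                symbol=symbol,
                state_pre=tr.state_pre,
                state_post=tr.state_post,
                is_switch=True,
                tf_bound=bound,
            )
        )
    return records


def annotate_expression(
    candidates: Sequence[CandidateRecord],
    counts_pre: pd.Series,
    counts_post: pd.Series,
    pseudocount: float = 0.5,
) -> list[CandidateRecord]:
    """Attach log2((CPM_post + pc) / (CPM_pre + pc)) to each candidate.

    CPM = count * 1e6 / library_total, with library totals taken as the column
    sums of the full counts tables (not just the candidate genes). Genes absent
    from either table keep a missing value — never an imputed 0. Informational
    only: annotation never filters the candidate set.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    total_pre = float(counts_pre.sum())
    total_post = float(counts_post.sum())
    out = []
    for rec in candidates:
        if rec.gene_id in counts_pre.index and rec.gene_id in counts_post.index:
            cpm_pre = float(counts_pre[rec.gene_id]) * 1e6 / total_pre
            cpm_post = float(counts_post[rec.gene_id]) * 1e6 / total_post
            lfc = math.log2((cpm_post + pseudocount) / (cpm_pre + pseudocount))
            out.append(replace(rec, log2fc_expression=lfc))
        else:
            out.append(replace(rec, log2fc_expression=None))
    return out
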