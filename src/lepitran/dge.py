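"""Digital gene expression from read-to-PUT alignments.

Counting model: a read is attributed to a trimmed gold-tier PUT iff at
least 95% of its length aligns with perfect sequence identity (zero
mismatches inside aligned blocks).  Each read counts toward at most one
PUT — the alignment with the most matched bases wins, ties resolved to the
lexicographically smallest PUT id so results are reproducible.  Counts of
PUTs sharing the same reference protein are accumulated to that protein,
then normalized by the condition's **total** read count (not the assigned
count).  Fold changes are ratios of normalized values, reported with an
up/down direction with respect to infection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .psl import PslAlignment

__all__ = [
    "ReadAssignment",
    "ExpressionRecord",
    "assign_reads",
    "count_to_protein",
    "normalize",
    "rank_fold_changes",
    "MIN_ALIGNED_FRACTION",
]

MIN_ALIGNED_FRACTION = 0.95


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    put_id: str
    matched_bases: int
    read_len: int


@dataclass(frozen=True)
class ExpressionRecord:
    protein_id: str
    raw: dict
    normalized: dict
    fold: float
    direction: str  # "up" | "down", with respect to the infected condition


def assign_reads(
    alignments: Iterable[PslAlignment],
    min_fraction: float = MIN_ALIGNED_FRACTION,
) -> list[ReadAssignment]:
    """Pick at most one PUT per read from its candidate alignments.

    Candidates must be mismatch-free and match at least
    ``ceil(min_fraction * read_len)`` bases.  The winner has the most
    matched bases; ties go to the smallest PUT id.
    """
    best: dict[str, ReadAssignment] = {}
    for aln in alignments:
        if aln.mismatches != 0:
            continue
        if aln.matches < math.ceil(min_fraction * aln.read_len):
            continue
        cand = ReadAssignment(aln.read_id, aln.target_id, aln.matches, aln.read_len)
        cur = best.get(aln.read_id)
        if cur is None or (-cand.matched_bases, cand.put_id) < (
            -cur.matched_bases,
            cur.put_id,
        ):
            best[aln.read_id] = cand
    return list(best.values())


def count_to_protein(
    assignments: Iterable[ReadAssignment], put_to_protein: Mapping[str, str]
) -> dict[str, int]:
    """Accumulate per-PUT read counts to their reference proteins."""
    counts: dict[str, int] = {}
    for a in assignments:
        try:
            protein = put_to_protein[a.put_id]
        except KeyError:
            raise KeyError(
                f"assigned PUT {a.put_id!r} missing from PUT-to-protein map"
            ) from None
        counts[protein] = counts.get(protein, 0) + 1
    return counts


def normalize(counts: Mapping[str, int], total_reads: int) -> dict[str, float]:
    """Divide counts by the condition's total read count."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if sum(counts.values()) > total_reads:
        raise ValueError("counts exceed the stated total read count")
    return {k: v / total_reads for k, v in counts.items()}


def rank_fold_changes(
    control: Mapping[str, float],
    infected: Mapping[str, float],
    min_value: float = 0.0,
) -> tuple[list[ExpressionRecord], list[str]]:
    """Rank proteins by fold change between two normalized count maps.

    ``control`` and ``infected`` are normalized expression maps (each on
    its own condition total).  Proteins with value > ``min_value`` in both
    conditions get ``fold = max/min`` and a direction (infected > control
    is "up"); proteins expressed in exactly one condition carry no finite
    fold and are returned separately as the "exclusive" list.  Records are
    sorted by fold descending (ties by protein id).
    """
    records: list[ExpressionRecord] = []
    exclusive: list[str] = []
    for pid in sorted(set(control) | set(infected)):
        c = control.get(pid, 0.0)
        i = infected.get(pid, 0.0)
        if c <= min_value or i <= min_value:
            if c > min_value or i > min_value:
                exclusive.append(pid)
            continue
        fold = max(c, i) / min(c, i)
        direction = "up" if i >= c else "down"
        records.append(
            ExpressionRecord(
                protein_id=pid,
                raw={},
                normalized={"control": c, "infected": i},
                fold=fold,
                direction=direction,
            )
        )
    records.sort(key=lambda r: (-r.fold, r.protein_id))
    return records, exclusive


def fold_change_table(
    control_counts: Mapping[str, int],
    infected_counts: Mapping[str, int],
    control_total: int,
    infected_total: int,
    min_count: int = 1,
) -> tuple[list[ExpressionRecord], list[str]]:
    """Full counting-to-ranking path from raw per-protein counts.

    Proteins need a raw count of at least ``min_count`` in both conditions
    to receive a fold; the returned records carry raw and normalized values
    per condition.
    """
    c_norm = normalize(control_counts, control_total)
    i_norm = normalize(infected_counts, infected_total)
    records: list[ExpressionRecord] = []
    exclusive: list[str] = []
    for pid in sorted(set(control_counts) | set(infected_counts)):
        c_raw = control_counts.get(pid, 0)
        i_raw = infected_counts.get(pid, 0)
        if c_raw < min_count or i_raw < min_count:
            if c_raw >= min_count or i_raw >= min_count:
                exclusive.append(pid)
            continue
        c, i = c_norm[pid], i_norm[pid]
        fold = max(c, i) / min(c, i)
        records.append(
            ExpressionRecord(
                protein_id=pid,
                raw={"control": c_raw, "infected": i_raw},
                normalized={"control": c, "infected": i},
                fold=fold,
                direction="up" if i >= c else "down",
            )
        )
    records.sort(key=lambda r: (-r.fold, r.protein_id))
    return records, exclusive
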