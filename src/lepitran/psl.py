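"""Reader/writer for Blat's 21-column PSL alignment format.

Coordinates are 0-based half-open, as in the format definition.  Only the
headerless dialect is consumed; the optional 5-line header emitted by
``blat`` without ``-noHead`` is tolerated and skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator

__all__ = ["PslAlignment", "read_psl", "write_psl"]


@dataclass(frozen=True)
class PslAlignment:
    read_id: str
    target_id: str
    matches: int
    mismatches: int
    read_len: int
    strand: str
    q_start: int
    q_end: int
    target_len: int
    t_start: int
    t_end: int
    block_sizes: tuple[int, ...]
    q_starts: tuple[int, ...]
    t_starts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.matches + self.mismatches > self.read_len:
            raise ValueError(
                f"{self.read_id}: matches+mismatches exceed read length"
            )
        if list(self.t_starts) != sorted(self.t_starts):
            raise ValueError(f"{self.read_id}: target blocks not sorted")


def _ints(field: str) -> tuple[int, ...]:
    return tuple(int(x) for x in field.rstrip(",").split(",") if x)


def read_psl(path_or_handle) -> Iterator[PslAlignment]:
    handle: IO[str] = (
        path_or_handle if hasattr(path_or_handle, "read") else open(path_or_handle)
    )
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("psLayout", "match", "-", " ")):
            continue
        cols = line.split("\t")
        if len(cols) != 21:
            raise ValueError(f"PSL line {lineno}: expected 21 columns, got {len(cols)}")
        yield PslAlignment(
            read_id=cols[9],
            target_id=cols[13],
            matches=int(cols[0]),
            mismatches=int(cols[1]),
            read_len=int(cols[10]),
            strand=cols[8],
            q_start=int(cols[11]),
            q_end=int(cols[12]),
            target_len=int(cols[14]),
            t_start=int(cols[15]),
            t_end=int(cols[16]),
            block_sizes=_ints(cols[18]),
            q_starts=_ints(cols[19]),
            t_starts=_ints(cols[20]),
        )


def write_psl(alignments: Iterable[PslAlignment], path_or_handle) -> int:
    handle = (
        path_or_handle
        if hasattr(path_or_handle, "write")
        else open(path_or_handle, "w")
    )
    n = 0
    for a in alignments:
        rep_matches = 0
        n_count = 0
        fields = [
            a.matches, a.mismatches, rep_matches, n_count,
            0, 0, 0, 0,  # q/t insert counts and bases: gapless records only
            a.strand, a.read_id, a.read_len, a.q_start, a.q_end,
            a.target_id, a.target_len, a.t_start, a.t_end,
            len(a.block_sizes),
            ",".join(map(str, a.block_sizes)) + ",",
            ",".join(map(str, a.q_starts)) + ",",
            ",".join(map(str, a.t_starts)) + ",",
        ]
        handle.write("\t".join(map(str, fields)) + "\n")
        n += 1
    if not hasattr(path_or_handle, "write"):
        handle.close()
    return n
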