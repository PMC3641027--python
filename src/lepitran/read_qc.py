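"""Read cleaning for short-read RNA-Seq data.

Implements the quality-control chain applied to raw Illumina reads before
assembly and expression counting:

1. quality-score conversion from the FASTQ ASCII encoding (Phred+33 or the
   older Phred+64 Illumina dialect) to integer Phred scores;
2. purging of artifact reads (single-nucleotide composition);
3. clipping of maximal terminal spans in which every base is Q20 or below
   (Q20 corresponds to a 1/100 base-call error rate);
4. a minimum-length filter of 36 bases;
5. a quality-fraction filter requiring >= 90% of bases at Q21 or higher;
6. masking of all remaining bases at Q20 or below with 'N'.

All thresholds are exposed as parameters with these defaults.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

__all__ = [
    "Read",
    "RawRead",
    "QcStats",
    "MalformedFastqError",
    "read_fastq",
    "write_fastq",
    "convert_quality",
    "is_artifact",
    "clip_terminal",
    "fraction_filter",
    "mask_low_quality",
    "qc_pipeline",
]

MIN_LENGTH = 36
CLIP_QMAX = 20
FRACTION_QMIN = 21
MIN_FRACTION = 0.90
MASK_QMAX = 20


class MalformedFastqError(ValueError):
    """Raised when a FASTQ record cannot be decoded under the declared offset."""


@dataclass(frozen=True)
class RawRead:
    """A FASTQ record whose quality string has not yet been decoded."""

    id: str
    bases: str
    qual_str: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qual_str):
            raise MalformedFastqError(
                f"read {self.id!r}: sequence and quality lengths differ"
            )


@dataclass(frozen=True)
class Read:
    """A read with integer per-base Phred scores."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id!r}: bases/quals length mismatch")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class QcStats:
    """Tallies accumulated over one pass of the QC chain."""

    input_reads: int = 0
    input_bases: int = 0
    retained_reads: int = 0
    retained_bases: int = 0
    clipped_bases: int = 0
    masked_bases: int = 0
    artifact_reads: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def _open_text(path, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path_or_handle) -> Iterator[RawRead]:
    """Parse four-line FASTQ records; gzip-transparent when given a path."""
    handle = (
        path_or_handle
        if hasattr(path_or_handle, "read")
        else _open_text(path_or_handle)
    )
    lineno = 0
    while True:
        header = handle.readline()
        if not header:
            break
        seq = handle.readline()
        plus = handle.readline()
        qual = handle.readline()
        lineno += 4
        if not qual:
            raise MalformedFastqError(f"truncated FASTQ record at line {lineno}")
        if not header.startswith("@") or not plus.startswith("+"):
            raise MalformedFastqError(f"malformed FASTQ record at line {lineno - 3}")
        yield RawRead(header[1:].strip().split()[0], seq.strip(), qual.strip())


def write_fastq(reads: Iterable[Read], path_or_handle, offset: int = 33) -> int:
    """Write reads as four-line FASTQ with the given quality offset."""
    handle = (
        path_or_handle
        if hasattr(path_or_handle, "write")
        else _open_text(path_or_handle, "wt")
    )
    n = 0
    for read in reads:
        qual = "".join(chr(q + offset) for q in read.quals)
        handle.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")
        n += 1
    if not hasattr(path_or_handle, "write"):
        handle.close()
    return n


def encode_quality(read: Read, offset: int = 33) -> RawRead:
    """Inverse of :func:`convert_quality`; used when writing fixtures."""
    return RawRead(read.id, read.bases, "".join(chr(q + offset) for q in read.quals))


def convert_quality(raw: RawRead, offset: int) -> Read:
    """Decode an ASCII quality string to Phred integers.

    ``offset`` must be 33 or 64.  Any character whose code point falls below
    the offset makes the record undecodable and raises
    :class:`MalformedFastqError` naming the read.
    """
    if offset not in (33, 64):
        raise ValueError(f"unsupported quality offset {offset}")
    quals = tuple(ord(c) - offset for c in raw.qual_str)
    if quals and min(quals) < 0:
        raise MalformedFastqError(
            f"read {raw.id!r}: quality character below offset {offset}"
        )
    return Read(raw.id, raw.bases, quals)


def is_artifact(read: Read) -> bool:
    """True when the base composition is a single nucleotide, ignoring N."""
    distinct = set(read.bases) - {"N"}
    return len(distinct) <= 1


def clip_terminal(
    read: Read, qmax: int = CLIP_QMAX, min_len: int = MIN_LENGTH
) -> Read | None:
    """Clip maximal low-quality terminal spans from both ends.

    A terminal span qualifies when every base in it has quality <= ``qmax``.
    Returns ``None`` (discard) when fewer than ``min_len`` bases remain.
    """
    lo, hi = 0, len(read)
    while lo < hi and read.quals[lo] <= qmax:
        lo += 1
    while hi > lo and read.quals[hi - 1] <= qmax:
        hi -= 1
    if hi - lo < min_len:
        return None
    if lo == 0 and hi == len(read):
        return read
    return Read(read.id, read.bases[lo:hi], read.quals[lo:hi])


def fraction_filter(
    read: Read, qmin: int = FRACTION_QMIN, min_fraction: float = MIN_FRACTION
) -> bool:
    """True iff at least ``min_fraction`` of bases have quality >= ``qmin``."""
    if len(read) == 0:
        return False
    good = sum(1 for q in read.quals if q >= qmin)
    return good / len(read) >= min_fraction


def mask_low_quality(read: Read, qmax: int = MASK_QMAX) -> Read:
    """Replace every base with quality <= ``qmax`` by 'N'; scores unchanged."""
    bases = "".join(
        "N" if q <= qmax else b for b, q in zip(read.bases, read.quals)
    )
    return Read(read.id, bases, read.quals)


def qc_pipeline(
    raw_reads: Iterable[RawRead],
    offset: int,
    *,
    min_len: int = MIN_LENGTH,
    clip_qmax: int = CLIP_QMAX,
    frac_qmin: int = FRACTION_QMIN,
    min_fraction: float = MIN_FRACTION,
    mask_qmax: int = MASK_QMAX,
) -> tuple[list[Read], QcStats]:
    """Run the full QC chain: convert, purge artifacts, clip, filter, mask."""
    stats = QcStats()
    retained: list[Read] = []
    for raw in raw_reads:
        read = convert_quality(raw, offset)
        stats.input_reads += 1
        stats.input_bases += len(read)
        if is_artifact(read):
            stats.artifact_reads += 1
            continue
        clipped = clip_terminal(read, qmax=clip_qmax, min_len=min_len)
        if clipped is None:
            stats.clipped_bases += len(read)
            continue
        stats.clipped_bases += len(read) - len(clipped)
        if not fraction_filter(clipped, qmin=frac_qmin, min_fraction=min_fraction):
            continue
        masked = mask_low_quality(clipped, qmax=mask_qmax)
        stats.masked_bases += sum(
            1 for a, b in zip(clipped.bases, masked.bases) if a != b and b == "N"
        )
        stats.retained_reads += 1
        stats.retained_bases += len(masked)
        retained.append(masked)
    return retained, stats
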