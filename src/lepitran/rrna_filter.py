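"""rRNA depletion: drop reads that align to an rRNA reference locus.

Ribosomal RNA dominates total-RNA libraries; reads aligning to an rRNA gene
locus are discarded before assembly and expression counting.  This module
consumes pre-computed PSL alignments of the QC-passed reads against the
rRNA reference — running the aligner itself is outside its scope — and
partitions the read stream on a minimum-matched-bases threshold.
"""

from __future__ import annotations

import warnings
from typing import Iterable

from .psl import PslAlignment
from .read_qc import QcStats, Read

__all__ = ["deplete", "DEFAULT_MIN_MATCHES"]

DEFAULT_MIN_MATCHES = 30


def deplete(
    reads: Iterable[Read],
    alignments: Iterable[PslAlignment],
    min_matches: int = DEFAULT_MIN_MATCHES,
) -> tuple[list[Read], QcStats]:
    """Partition reads into retained (non-rRNA) and discarded (rRNA) sets.

    A read is discarded when at least one alignment reports
    ``matches >= min_matches``.  Input order is preserved in the retained
    stream.  Alignments naming read ids absent from the stream trigger a
    warning and are ignored.
    """
    reads = list(reads)
    known = {r.id for r in reads}
    hit_ids: set[str] = set()
    for aln in alignments:
        if aln.read_id not in known:
            warnings.warn(
                f"alignment references unknown read id {aln.read_id!r}; ignored",
                stacklevel=2,
            )
            continue
        if aln.matches >= min_matches:
            hit_ids.add(aln.read_id)
    stats = QcStats(
        input_reads=len(reads),
        input_bases=sum(len(r) for r in reads),
    )
    retained = [r for r in reads if r.id not in hit_ids]
    stats.retained_reads = len(retained)
    stats.retained_bases = sum(len(r) for r in retained)
    return retained, stats
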