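"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written as direct transcriptions of the filtering
and classification rules — position sets instead of interval merges,
per-read loops instead of the streaming pipeline, exhaustive substring
scans instead of split-based ORF extraction — so agreement with the
library is a meaningful check rather than a tautology.
"""

from __future__ import annotations


def oracle_tier(put_len: int, subject_len: int, hsps: list[dict]) -> str:
    """Direct-inequality tier checker; hsps carry s_start/s_end/positives/align_len."""
    if not hsps:
        return "none"
    if len(hsps) == 1:
        h = hsps[0]
        span = h["s_end"] - h["s_start"] + 1
        if (
            put_len >= 300
            and subject_len >= 100
            and h["positives"] / h["align_len"] >= 0.75
            and span / subject_len >= 0.90
        ):
            return "gold"
    positions: set[int] = set()
    for h in hsps:
        positions.update(range(h["s_start"], h["s_end"] + 1))
    coverage = len(positions) / subject_len
    if put_len >= 100 and coverage >= 0.75:
        return "silver"
    if put_len >= 100 and coverage >= 0.30:
        return "bronze"
    return "none"


def oracle_qc(bases: str, quals: tuple[int, ...]):
    """Per-read QC decision: returns (bases, quals) if retained else None."""
    if len(set(bases) - {"N"}) <= 1:
        return None
    i, j = 0, len(quals)
    while i < j and quals[i] <= 20:
        i += 1
    while j > i and quals[j - 1] <= 20:
        j -= 1
    b, q = bases[i:j], quals[i:j]
    if len(b) < 36:
        return None
    if sum(1 for x in q if x >= 21) / len(q) < 0.90:
        return None
    masked = "".join("N" if x <= 20 else c for c, x in zip(b, q))
    return masked, q


def oracle_longest_orf(frames) -> tuple[int, str]:
    """Exhaustive substring scan for the longest stop-free peptide."""
    frame_order = (1, 2, 3, -1, -2, -3)
    best = (-1, 0, 0, "")  # (length, frame_rank, start, peptide)
    for rank, (frame, pep) in enumerate(zip(frame_order, frames)):
        n = len(pep)
        for i in range(n + 1):
            for j in range(i, n + 1):
                sub = pep[i:j]
                if "*" in sub:
                    break
                if len(sub) > best[0]:
                    best = (len(sub), rank, i, sub)
    length, rank, _, pep = best
    return frame_order[rank] if length >= 0 else 1, pep


def random_hit_geometry(rng):
    """One randomized (put_len, subject_len, hsps) tuple with boundary bias."""
    put_len = int(
        rng.choice([299, 300, 301, int(rng.integers(100, 700)), int(rng.integers(50, 120))])
    )
    subject_len = int(rng.choice([99, 100, 101, 1000, int(rng.integers(60, 300))]))
    n_hsps = int(rng.choice([1, 1, 1, 2, 3]))
    hsps = []
    for _ in range(n_hsps):
        if subject_len == 1000 and rng.random() < 0.5:
            # exercise the 0.899 / 0.900 coverage boundary exactly
            span = int(rng.choice([899, 900, 901]))
        else:
            span = int(rng.integers(1, subject_len + 1))
        s_start = int(rng.integers(1, subject_len - span + 2))
        if rng.random() < 0.3:
            # decoupled (gapped) alignment length hitting the 0.749 / 0.750
            # positives-fraction boundary exactly
            align_len = 1000
            positives = int(rng.choice([749, 750, 751]))
        else:
            align_len = span
            positives = int(rng.integers(0, align_len + 1))
        hsps.append(
            {
                "s_start": s_start,
                "s_end": s_start + span - 1,
                "align_len": align_len,
                "positives": positives,
            }
        )
    return put_len, subject_len, hsps
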