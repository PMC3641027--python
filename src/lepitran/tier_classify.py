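"""Homology-tier classification of assembled transcripts (PUTs).

Each putatively unique transcript (PUT) is compared against a protein
database with BLASTX; the geometry of its top-scoring hit places it in one
of three mutually disjoint quality tiers:

* **gold** — a single HSP, PUT >= 300 nt, subject protein >= 100 aa, at
  least 75% of aligned residues positively similar, and the hit spanning at
  least 90% of the subject's length.  Gold PUTs are treated as essentially
  full-length gene proxies; their aligned region is trimmed to a CDS and
  translated.
* **silver** — PUT >= 100 nt and hits (merged over HSPs in subject
  coordinates) covering at least 75% of the subject.
* **bronze** — PUT >= 100 nt and merged coverage of at least 30%.

A PUT failing all three criteria sets, or lacking any hit, is left
untiered.  The cascade is evaluated top-down so the tiers are disjoint by
construction.

The input carrier is an extended BLAST tabular dialect with one HSP per
line::

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore ppos slen

(the standard ``-outfmt 6`` columns plus percent-positives and subject
length).  Query lengths come from the PUT FASTA, not the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio.Seq import Seq

__all__ = [
    "HSP",
    "HomologyHit",
    "TierAssignment",
    "TrimmedGene",
    "TierThresholds",
    "parse_blast_tabular",
    "write_blast_tabular",
    "top_hit",
    "merged_subject_coverage",
    "assign_tier",
    "trim_and_translate",
    "classify_all",
    "read_fasta",
    "write_fasta",
]

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore ppos slen"
).split()


@dataclass(frozen=True)
class HSP:
    """One high-scoring segment pair (contiguous local alignment)."""

    q_start: int  # 1-based inclusive, nucleotides; q_start > q_end on minus strand
    q_end: int
    s_start: int  # 1-based inclusive, amino acids; always s_start <= s_end
    s_end: int
    align_len: int  # aligned columns, amino acids
    positives: int  # positively-similar columns
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.positives > self.align_len:
            raise ValueError("positives exceed alignment length")
        if self.s_start > self.s_end:
            raise ValueError("subject coordinates reversed")

    @property
    def positives_frac(self) -> float:
        return self.positives / self.align_len if self.align_len else 0.0

    @property
    def subject_span(self) -> int:
        return self.s_end - self.s_start + 1

    @property
    def is_minus(self) -> bool:
        return self.q_start > self.q_end


@dataclass
class HomologyHit:
    """All HSPs of one query against one subject."""

    query_id: str
    subject_id: str
    subject_len: int
    hsps: list[HSP] = field(default_factory=list)

    @property
    def best_bitscore(self) -> float:
        return max(h.bitscore for h in self.hsps)

    @property
    def best_evalue(self) -> float:
        return min(h.evalue for h in self.hsps)


@dataclass(frozen=True)
class TierAssignment:
    put_id: str
    tier: str  # gold | silver | bronze | none
    subject_id: str | None
    reason: str


@dataclass(frozen=True)
class TrimmedGene:
    put_id: str
    cds: str
    protein: str
    frame: int


@dataclass(frozen=True)
class TierThresholds:
    """Knobs of the tier cascade, defaulting to the published criteria."""

    gold_min_put_len: int = 300
    gold_min_subject_len: int = 100
    gold_min_positives: float = 0.75
    gold_min_span: float = 0.90
    silver_min_put_len: int = 100
    silver_min_coverage: float = 0.75
    bronze_min_put_len: int = 100
    bronze_min_coverage: float = 0.30


DEFAULT_THRESHOLDS = TierThresholds()


def parse_blast_tabular(path_or_handle) -> dict[str, list[HomologyHit]]:
    """Parse the 14-column dialect, grouping HSPs per (query, subject).

    Hits for each query are sorted by best bitscore descending (ties by
    lower E-value, then subject id).
    """
    handle: IO[str] = (
        path_or_handle if hasattr(path_or_handle, "read") else open(path_or_handle)
    )
    grouped: dict[tuple[str, str], HomologyHit] = {}
    order: dict[str, list[tuple[str, str]]] = {}
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != len(BLAST_COLUMNS):
            raise ValueError(
                f"BLAST tabular line {lineno}: expected {len(BLAST_COLUMNS)} "
                f"columns, got {len(cols)}"
            )
        qid, sid = cols[0], cols[1]
        align_len = int(cols[3])
        ppos = float(cols[12])
        hsp = HSP(
            q_start=int(cols[6]),
            q_end=int(cols[7]),
            s_start=int(cols[8]),
            s_end=int(cols[9]),
            align_len=align_len,
            positives=round(ppos / 100.0 * align_len),
            bitscore=float(cols[11]),
            evalue=float(cols[10]),
        )
        key = (qid, sid)
        if key not in grouped:
            grouped[key] = HomologyHit(qid, sid, int(cols[13]))
            order.setdefault(qid, []).append(key)
        grouped[key].hsps.append(hsp)
    result: dict[str, list[HomologyHit]] = {}
    for qid, keys in order.items():
        hits = [grouped[k] for k in keys]
        hits.sort(key=lambda h: (-h.best_bitscore, h.best_evalue, h.subject_id))
        result[qid] = hits
    return result


def write_blast_tabular(hits: Iterable[HomologyHit], path_or_handle) -> int:
    """Serialize hits back to the 14-column dialect (one line per HSP)."""
    handle = (
        path_or_handle
        if hasattr(path_or_handle, "write")
        else open(path_or_handle, "w")
    )
    n = 0
    for hit in hits:
        for h in hit.hsps:
            pident = 100.0 * h.positives / h.align_len  # identity not tracked
            fields = [
                hit.query_id, hit.subject_id,
                f"{pident:.2f}", h.align_len, 0, 0,
                h.q_start, h.q_end, h.s_start, h.s_end,
                f"{h.evalue:.2e}", f"{h.bitscore:.1f}",
                f"{100.0 * h.positives / h.align_len:.2f}",
                hit.subject_len,
            ]
            handle.write("\t".join(map(str, fields)) + "\n")
            n += 1
    if not hasattr(path_or_handle, "write"):
        handle.close()
    return n


def top_hit(hits: list[HomologyHit]) -> HomologyHit:
    """Best hit by bitscore; ties by lower E-value, then subject id."""
    if not hits:
        raise ValueError("top_hit of an empty hit list")
    return min(hits, key=lambda h: (-h.best_bitscore, h.best_evalue, h.subject_id))


def merged_subject_coverage(hit: HomologyHit) -> float:
    """Fraction of the subject covered by the union of HSP subject spans."""
    intervals = sorted((h.s_start, h.s_end) for h in hit.hsps)
    covered = 0
    cur_start, cur_end = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_end + 1:
            covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    covered += cur_end - cur_start + 1
    return covered / hit.subject_len


def assign_tier(
    put_len: int,
    hit: HomologyHit | None,
    thresholds: TierThresholds = DEFAULT_THRESHOLDS,
) -> TierAssignment:
    """Place one PUT into gold/silver/bronze/none from its top hit."""
    t = thresholds
    if hit is None or not hit.hsps:
        return TierAssignment(
            put_id="" if hit is None else hit.query_id,
            tier="none", subject_id=None, reason="no hit",
        )
    put_id, sid = hit.query_id, hit.subject_id
    if (
        len(hit.hsps) == 1
        and put_len >= t.gold_min_put_len
        and hit.subject_len >= t.gold_min_subject_len
        and hit.hsps[0].positives_frac >= t.gold_min_positives
        and hit.hsps[0].subject_span / hit.subject_len >= t.gold_min_span
    ):
        return TierAssignment(put_id, "gold", sid, "single-HSP full-length hit")
    coverage = merged_subject_coverage(hit)
    if put_len >= t.silver_min_put_len and coverage >= t.silver_min_coverage:
        return TierAssignment(
            put_id, "silver", sid, f"merged coverage {coverage:.3f} >= 0.75"
        )
    if put_len >= t.bronze_min_put_len and coverage >= t.bronze_min_coverage:
        return TierAssignment(
            put_id, "bronze", sid, f"merged coverage {coverage:.3f} >= 0.30"
        )
    return TierAssignment(put_id, "none", None, "criteria not met")


def hsp_frame(put_len: int, hsp: HSP) -> int:
    """BLASTX-style reading frame of an HSP given the query length."""
    if hsp.is_minus:
        return -(((put_len - hsp.q_start) % 3) + 1)
    return ((hsp.q_start - 1) % 3) + 1


def trim_and_translate(put_id: str, put_seq: str, hit: HomologyHit) -> TrimmedGene:
    """Trim a gold PUT to its aligned span and translate it.

    End sequences outside the single HSP are removed; on minus-frame hits
    the excised region is reverse-complemented first.  Translation uses the
    standard genetic code, drops any trailing partial codon, renders
    internal stops as '*', and codons containing N (masked bases) as 'X'.
    """
    if len(hit.hsps) != 1:
        raise ValueError(f"{put_id}: trimming requires a single-HSP hit")
    h = hit.hsps[0]
    lo, hi = min(h.q_start, h.q_end), max(h.q_start, h.q_end)
    if lo < 1 or hi > len(put_seq):
        raise ValueError(f"{put_id}: HSP coordinates outside sequence")
    sub = put_seq[lo - 1 : hi]
    if h.is_minus:
        sub = str(Seq(sub).reverse_complement())
    cds = sub[: len(sub) - len(sub) % 3]
    protein = str(Seq(cds).translate(table=1))
    return TrimmedGene(put_id, cds, protein, hsp_frame(len(put_seq), h))


def classify_all(
    puts: dict[str, str],
    hits_by_query: dict[str, list[HomologyHit]],
    thresholds: TierThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[TierAssignment], list[TrimmedGene]]:
    """Tier every PUT and trim/translate the gold subset."""
    assignments: list[TierAssignment] = []
    genes: list[TrimmedGene] = []
    for put_id, seq in puts.items():
        hits = hits_by_query.get(put_id, [])
        best = top_hit(hits) if hits else None
        assn = assign_tier(len(seq), best, thresholds)
        if best is None:
            assn = TierAssignment(put_id, "none", None, "no hit")
        assignments.append(assn)
        if assn.tier == "gold" and best is not None:
            genes.append(trim_and_translate(put_id, seq, best))
    return assignments, genes


def read_fasta(path_or_handle) -> dict[str, str]:
    """Minimal FASTA reader returning an ordered id -> sequence map."""
    handle = (
        path_or_handle if hasattr(path_or_handle, "read") else open(path_or_handle)
    )
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    for line in handle:
        line = line.strip()
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif line:
            chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path_or_handle, width: int = 70) -> None:
    handle = (
        path_or_handle
        if hasattr(path_or_handle, "write")
        else open(path_or_handle, "w")
    )
    for name, seq in seqs.items():
        handle.write(f">{name}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")
    if not hasattr(path_or_handle, "write"):
        handle.close()
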