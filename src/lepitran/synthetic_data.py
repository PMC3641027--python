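"""Synthetic study worlds with planted ground truth.

This module generates every input the pipeline consumes — a small protein
reference, transcripts engineered to land in a chosen homology tier,
two-condition read sets with planted abundance fold changes and a
two-state quality model, rRNA contaminant reads, a toy three-domain GO
ontology, and replicated qPCR Ct tables — so each downstream stage can be
tested against known truth without any external data.

Key constructions:

* Transcripts are back-translated from reference proteins with one fixed
  codon per amino acid, so the planted BLASTX hit geometry (coordinates,
  coverage, positives) is exact by construction rather than the output of
  an aligner.
* Planted expression fold changes are realized exactly as ratios of
  abundance fractions between conditions: differentially expressed
  transcripts get their stated ratio, and only the remaining transcripts
  are renormalized.
* The read quality model is two-state — a high-quality body around Q38
  with optional geometric-length low-quality (~Q15) terminal spans — the
  minimal shape that exercises terminal clipping, the quality-fraction
  filter, and low-quality masking.
* All randomness flows from a single integer seed through one named
  generator per operation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .psl import PslAlignment
from .qpcr import CT_COLUMNS, CtTable
from .read_qc import Read
from .tier_classify import HSP, HomologyHit

__all__ = [
    "Protein",
    "Transcript",
    "SyntheticWorld",
    "QualModel",
    "SimRead",
    "make_world",
    "simulate_reads",
    "emit_blastx_tabular",
    "align_exact",
    "make_toy_ontology",
    "write_obo",
    "make_ct_table",
    "make_domtbl_lines",
    "write_external2go",
    "back_translate",
    "CODON_FOR",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"
CONDITIONS = ("control", "infected")
DESTINIES = ("gold", "silver", "bronze", "none")

# Fixed, deterministic codon per amino acid (lexicographically smallest in
# the standard code) so back-translated frames are exact.
_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_FOR: dict[str, str] = {}
for codon, aa in sorted(_standard.forward_table.items()):
    CODON_FOR.setdefault(aa, codon)


def back_translate(protein: str) -> str:
    return "".join(CODON_FOR[aa] for aa in protein)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=n))


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Protein:
    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PlantedHSP:
    q_start: int  # 1-based inclusive on the transcript; q_start > q_end on minus
    q_end: int
    s_start: int  # 1-based inclusive on the protein
    s_end: int

    @property
    def align_len(self) -> int:
        return self.s_end - self.s_start + 1


@dataclass(frozen=True)
class Transcript:
    id: str
    seq: str
    protein_id: str | None
    destiny: str  # gold | silver | bronze | none
    hsps: tuple[PlantedHSP, ...] = ()
    minus: bool = False

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SyntheticWorld:
    proteins: list[Protein]
    transcripts: list[Transcript]
    abundances: dict[str, dict[str, float]]  # condition -> transcript id -> fraction
    planted_folds: dict[str, float]  # transcript id -> infected/control ratio
    rrna_reference: str
    seed: int

    def protein(self, pid: str) -> Protein:
        return next(p for p in self.proteins if p.id == pid)

    @property
    def put_to_protein(self) -> dict[str, str]:
        return {
            t.id: t.protein_id for t in self.transcripts if t.protein_id is not None
        }


def _allocate(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items to destiny fractions."""
    total = sum(fractions.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"tier_mix fractions sum to {total}, expected 1")
    if any(f < 0 for f in fractions.values()):
        raise ValueError("tier_mix fractions must be non-negative")
    raw = {k: n * f for k, f in fractions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    leftover = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: (counts[k] + 1 - raw[k], k))[:leftover]:
        counts[k] += 1
    return counts


def _plant_transcript(
    rng: np.random.Generator,
    tid: str,
    destiny: str,
    protein: Protein | None,
) -> Transcript:
    """Build one transcript whose planted hit geometry forces its tier."""
    if destiny == "none":
        length = int(rng.integers(150, 400))
        return Transcript(tid, _random_nt(rng, length), None, destiny)

    assert protein is not None
    plen = len(protein)
    flank5 = int(rng.integers(5, 30))
    flank3 = int(rng.integers(5, 30))

    if destiny == "silver" and rng.random() < 0.5:
        # gold-disqualified by HSP count: two HSPs jointly covering >= 90%
        cov = int(np.ceil(rng.uniform(0.91, 0.96) * plen))
        gap = int(rng.integers(3, 9))
        cov = min(cov, plen - gap)
        c1, c2 = cov // 2, cov - cov // 2
        s1 = int(rng.integers(1, plen - cov - gap + 2))
        seg1 = (s1, s1 + c1 - 1)
        seg2 = (s1 + c1 + gap, s1 + c1 + gap + c2 - 1)
        spacer = _random_nt(rng, int(rng.integers(6, 21)))
        cds1 = back_translate(protein.seq[seg1[0] - 1 : seg1[1]])
        cds2 = back_translate(protein.seq[seg2[0] - 1 : seg2[1]])
        seq = _random_nt(rng, flank5) + cds1 + spacer + cds2 + _random_nt(rng, flank3)
        q1 = (flank5 + 1, flank5 + len(cds1))
        off2 = flank5 + len(cds1) + len(spacer)
        q2 = (off2 + 1, off2 + len(cds2))
        hsps = (
            PlantedHSP(q1[0], q1[1], seg1[0], seg1[1]),
            PlantedHSP(q2[0], q2[1], seg2[0], seg2[1]),
        )
        return Transcript(tid, seq, protein.id, destiny, hsps)

    if destiny == "gold":
        cov_frac = rng.uniform(0.92, 1.0)
    elif destiny == "silver":
        cov_frac = rng.uniform(0.76, 0.88)
    elif destiny == "bronze":
        cov_frac = rng.uniform(0.32, 0.68)
    else:
        raise ValueError(f"unknown destiny {destiny!r}")
    n_aa = min(plen, int(np.ceil(cov_frac * plen)))
    s_start = int(rng.integers(1, plen - n_aa + 2))
    cds = back_translate(protein.seq[s_start - 1 : s_start - 1 + n_aa])
    seq = _random_nt(rng, flank5) + cds + _random_nt(rng, flank3)
    hsp = PlantedHSP(flank5 + 1, flank5 + len(cds), s_start, s_start + n_aa - 1)
    minus = bool(rng.random() < 0.3)
    if minus:
        L = len(seq)
        seq = _revcomp(seq)
        hsp = PlantedHSP(L - hsp.q_start + 1, L - hsp.q_end + 1, hsp.s_start, hsp.s_end)
    return Transcript(tid, seq, protein.id, destiny, (hsp,), minus)


def make_world(
    n_proteins: int = 20,
    n_transcripts: int = 40,
    tier_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    fold_changes: Mapping[str, float] | None = None,
    de_control_fraction: float = 0.002,
    rrna_len: int = 2000,
) -> SyntheticWorld:
    """Generate a deterministic world with planted tier destinies and folds.

    ``tier_mix`` maps destinies (gold/silver/bronze/none) to fractions
    summing to one; counts are allocated by largest remainder so stated
    mixes are hit exactly.  ``fold_changes`` maps transcript indices (int)
    or ids (str) to planted infected/control abundance ratios; those
    transcripts receive a control-condition abundance fraction of
    ``de_control_fraction`` each, and only non-differential transcripts
    are renormalized, so planted ratios are exact.
    """
    if n_proteins < 1 or n_transcripts < 1:
        raise ValueError("counts must be positive")
    tier_mix = dict(tier_mix or {"gold": 0.25, "silver": 0.25, "bronze": 0.25, "none": 0.25})
    unknown = set(tier_mix) - set(DESTINIES)
    if unknown:
        raise ValueError(f"unknown destinies in tier_mix: {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    proteins = [
        Protein(f"P{i:04d}", _random_aa(rng, int(rng.integers(110, 260))))
        for i in range(n_proteins)
    ]

    counts = _allocate(n_transcripts, tier_mix)
    destinies: list[str] = []
    for d in DESTINIES:
        destinies.extend([d] * counts.get(d, 0))

    transcripts: list[Transcript] = []
    homolog_idx = 0  # round-robin protein assignment keeps PUT->protein injective
    for i, destiny in enumerate(destinies):
        protein = None
        if destiny != "none":
            protein = proteins[homolog_idx % n_proteins]
            homolog_idx += 1
        transcripts.append(_plant_transcript(rng, f"T{i:04d}", destiny, protein))

    # abundances: random base fractions, planted ratios realized exactly
    folds: dict[str, float] = {}
    for key, f in (fold_changes or {}).items():
        tid = transcripts[key].id if isinstance(key, int) else key
        if f <= 0:
            raise ValueError(f"planted fold for {tid} must be positive")
        folds[tid] = float(f)
    base = rng.uniform(0.5, 1.5, size=len(transcripts))
    ids = [t.id for t in transcripts]
    de_ids = set(folds)
    de_mass_ctl = de_control_fraction * len(de_ids)
    de_mass_inf = de_control_fraction * sum(folds.values())
    if de_mass_ctl >= 1.0 or de_mass_inf >= 1.0:
        raise ValueError("planted differential transcripts exceed unit abundance")
    non_de = [i for i, tid in enumerate(ids) if tid not in de_ids]
    base_non_de = base[non_de] / base[non_de].sum()
    control = {}
    infected = {}
    for j, i in enumerate(non_de):
        control[ids[i]] = float(base_non_de[j] * (1.0 - de_mass_ctl))
        infected[ids[i]] = float(base_non_de[j] * (1.0 - de_mass_inf))
    for tid, f in folds.items():
        control[tid] = de_control_fraction
        infected[tid] = de_control_fraction * f
    abundances = {
        "control": {tid: control[tid] for tid in ids},
        "infected": {tid: infected[tid] for tid in ids},
    }
    for cond, frac in abundances.items():
        assert math.isclose(sum(frac.values()), 1.0, abs_tol=1e-9), cond

    return SyntheticWorld(
        proteins=proteins,
        transcripts=transcripts,
        abundances=abundances,
        planted_folds=folds,
        rrna_reference=_random_nt(rng, rrna_len),
        seed=seed,
    )


@dataclass(frozen=True)
class QualModel:
    """Two-state quality model: high-quality body, low-quality terminal spans."""

    high_q: int = 38
    low_q: int = 15
    jitter: int = 2
    terminal_low_prob: float = 0.5
    terminal_span_mean: float = 4.0


@dataclass(frozen=True)
class SimRead(Read):
    source_id: str = ""
    source_pos: int = -1
    is_rrna: bool = False


def _qual_matrix(
    rng: np.random.Generator, model: QualModel, n: int, length: int
) -> np.ndarray:
    j = model.jitter
    if j > 0:
        quals = rng.integers(model.high_q - j, model.high_q + j + 1, size=(n, length))
    else:
        quals = np.full((n, length), model.high_q, dtype=np.int64)
    if model.terminal_low_prob > 0:
        max_span = length // 3
        for end in (0, 1):
            active = rng.random(n) < model.terminal_low_prob
            spans = np.minimum(
                rng.geometric(1.0 / model.terminal_span_mean, size=n), max_span
            ) * active
            if j > 0:
                lows = rng.integers(
                    max(0, model.low_q - j), model.low_q + j + 1, size=(n, max_span)
                )
            else:
                lows = np.full((n, max_span), model.low_q, dtype=np.int64)
            for i in np.nonzero(spans)[0]:
                s = int(spans[i])
                if end == 0:
                    quals[i, :s] = lows[i, :s]
                else:
                    quals[i, length - s :] = lows[i, :s]
    return quals


def simulate_reads(
    world: SyntheticWorld,
    condition: str,
    n_reads: int,
    read_len: int = 72,
    qual_model: QualModel | None = None,
    rrna_fraction: float = 0.0,
    seed: int = 0,
) -> list[SimRead]:
    """Draw reads from transcripts per abundance, plus rRNA contaminants.

    Reads are exact substrings of their source sequence (sequencing errors
    are not simulated; low-confidence base *calls* are expressed through
    the quality model instead).  The number of rRNA reads is binomial in
    ``rrna_fraction``.
    """
    if not world.transcripts:
        raise ValueError("cannot simulate reads from an empty world")
    model = qual_model or QualModel()
    seqs = [t.seq for t in world.transcripts]
    shortest = min(len(s) for s in seqs)
    if read_len > shortest or read_len > len(world.rrna_reference):
        raise ValueError(
            f"read_len {read_len} exceeds the shortest source sequence ({shortest})"
        )
    rng = np.random.default_rng(seed)
    fracs = world.abundances[condition]
    probs = np.array([fracs[t.id] for t in world.transcripts])
    probs = probs / probs.sum()

    is_rrna = rng.random(n_reads) < rrna_fraction
    tx_idx = rng.choice(len(seqs), size=n_reads, p=probs)
    quals = _qual_matrix(rng, model, n_reads, read_len)
    constant = model.jitter == 0 and model.terminal_low_prob == 0
    shared = tuple(int(q) for q in quals[0]) if constant else None

    reads: list[SimRead] = []
    rrna = world.rrna_reference
    for i in range(n_reads):
        if is_rrna[i]:
            src_id, src = "rRNA", rrna
        else:
            t = world.transcripts[int(tx_idx[i])]
            src_id, src = t.id, t.seq
        pos = int(rng.integers(0, len(src) - read_len + 1))
        qt = shared if constant else tuple(int(q) for q in quals[i])
        reads.append(
            SimRead(
                id=f"{condition}_r{i:06d}",
                bases=src[pos : pos + read_len],
                quals=qt,
                source_id=src_id,
                source_pos=pos,
                is_rrna=bool(is_rrna[i]),
            )
        )
    return reads


def emit_blastx_tabular(world: SyntheticWorld) -> list[HomologyHit]:
    """Emit per-transcript BLASTX records matching the planted geometry.

    Transcripts with a ``none`` destiny emit no record.  Positives equal
    the alignment length (the back-translation is an exact match), the
    bitscore scales with alignment length, and multi-HSP transcripts emit
    one record with all their HSPs.
    """
    if not world.proteins:
        raise ValueError("world has no proteins")
    hits: list[HomologyHit] = []
    for t in world.transcripts:
        if t.destiny == "none" or t.protein_id is None:
            continue
        subject_len = len(world.protein(t.protein_id))
        hit = HomologyHit(t.id, t.protein_id, subject_len)
        for h in t.hsps:
            hit.hsps.append(
                HSP(
                    q_start=h.q_start,
                    q_end=h.q_end,
                    s_start=h.s_start,
                    s_end=h.s_end,
                    align_len=h.align_len,
                    positives=h.align_len,
                    bitscore=round(1.9 * h.align_len, 1),
                    evalue=1e-50,
                )
            )
        hits.append(hit)
    return hits


def align_exact(
    reads: Iterable[Read], targets: Mapping[str, str], k: int = 20
) -> list[PslAlignment]:
    """Fixture aligner: exact full-length substring matches on both strands.

    A k-mer anchor index over the targets makes lookups O(1) per read.
    Only reads matching a target exactly over their whole length produce a
    record (no partial or gapped alignments), so every emitted record has
    zero mismatches and full-length match count.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for tid, seq in targets.items():
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((tid, pos))

    out: list[PslAlignment] = []
    for read in reads:
        L = len(read.bases)
        if L < k:
            continue
        for strand, s in (("+", read.bases), ("-", _revcomp(read.bases))):
            for tid, pos in index.get(s[:k], ()):
                target = targets[tid]
                if target[pos : pos + L] == s:
                    out.append(
                        PslAlignment(
                            read_id=read.id,
                            target_id=tid,
                            matches=L,
                            mismatches=0,
                            read_len=L,
                            strand=strand,
                            q_start=0,
                            q_end=L,
                            target_len=len(target),
                            t_start=pos,
                            t_end=pos + L,
                            block_sizes=(L,),
                            q_starts=(0,),
                            t_starts=(pos,),
                        )
                    )
    return out


def make_toy_ontology(
    depth: int = 3, branching: int = 3, seed: int = 0
) -> nx.DiGraph:
    """A three-domain toy GO DAG with is_a edges and some multi-parent terms.

    Each domain root gets ``branching`` direct children (the candidate
    GO-Slim terms), then ``depth - 1`` further levels; roughly a third of
    deeper terms get a second parent to exercise multi-path rollups.
    """
    if depth < 2:
        raise ValueError("depth must be at least 2")
    from .annotate import GO_ROOTS

    rng = np.random.default_rng(seed)
    graph = nx.DiGraph()
    counter = 1
    for root_id, namespace in sorted(GO_ROOTS.items()):
        graph.add_node(root_id, name=namespace, namespace=namespace)
        levels: list[list[str]] = [[root_id]]
        for level in range(1, depth + 1):
            nodes = []
            n_here = branching if level == 1 else branching * 2
            for _ in range(n_here):
                term = f"GO:{7000000 + counter:07d}"
                counter += 1
                graph.add_node(
                    term, name=f"synthetic term {counter}", namespace=namespace
                )
                parent = levels[level - 1][int(rng.integers(len(levels[level - 1])))]
                graph.add_edge(term, parent)
                if level >= 2 and rng.random() < 0.35:
                    # second parent from any shallower level, including the
                    # slim level, to create diamonds with multiple rollups
                    pool = [
                        p
                        for lvl in levels[1:level]
                        for p in lvl
                        if p != parent
                    ]
                    if pool:
                        graph.add_edge(term, pool[int(rng.integers(len(pool)))])
                nodes.append(term)
            levels.append(nodes)
    assert nx.is_directed_acyclic_graph(graph)
    return graph


def write_obo(graph: nx.DiGraph, path_or_handle) -> None:
    """Serialize an ontology graph as minimal OBO 1.2."""
    handle: IO[str] = (
        path_or_handle
        if hasattr(path_or_handle, "write")
        else open(path_or_handle, "w")
    )
    handle.write("format-version: 1.2\nontology: synthetic-go\n")
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        handle.write(
            f"\n[Term]\nid: {node}\nname: {data.get('name', node)}\n"
            f"namespace: {data.get('namespace', '')}\n"
        )
        for parent in sorted(graph.successors(node)):
            handle.write(f"is_a: {parent} ! {graph.nodes[parent].get('name', '')}\n")
    if not hasattr(path_or_handle, "write"):
        handle.close()


def make_ct_table(
    genes: Sequence[str],
    fold_changes: Mapping[str, float],
    n_bio: int = 3,
    n_tech: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    controls: Sequence[str] = ("rRNA_18S", "EF_Tu"),
    base_ct: float = 20.0,
) -> CtTable:
    """Replicated Ct measurements with planted expression fold changes.

    Control-condition ΔCt values are centered at zero (gene Ct equals the
    endogenous-control Ct); infected-condition gene Cts are shifted by
    -log2(fold).  Gaussian technical noise of ``noise_sd`` cycles is added
    to every individual measurement.
    """
    import pandas as pd

    if n_bio < 1 or n_tech < 1:
        raise ValueError("replicate counts must be at least 1")
    for g, f in fold_changes.items():
        if f <= 0:
            raise ValueError(f"planted fold for {g!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for condition in CONDITIONS:
        for bio in range(1, n_bio + 1):
            for gene in list(controls) + list(genes):
                if gene in controls:
                    shift = 0.0
                elif condition == "infected":
                    shift = -math.log2(fold_changes.get(gene, 1.0))
                else:
                    shift = 0.0
                for tech in range(1, n_tech + 1):
                    ct = base_ct + shift + rng.normal(0.0, noise_sd)
                    rows.append((gene, condition, bio, tech, ct))
    df = pd.DataFrame(rows, columns=CT_COLUMNS)
    return CtTable(df, frozenset(controls))


def make_domtbl_lines(
    records: Iterable[tuple[str, str, str, float, float]]
) -> str:
    """Render (query, family_acc, family_name, evalue, score) tuples as an
    hmmscan --domtblout-like table."""
    lines = [
        "# target name        accession   tlen query name           "
        "accession   qlen   E-value  score  bias ..."
    ]
    for query, acc, name, evalue, score in records:
        lines.append(
            f"{name:<20} {acc:<11} 200 {query:<20} -          300 "
            f"{evalue:9.2g} {score:6.1f}   0.1   1   1 {evalue:9.2g} "
            f"{evalue:9.2g} {score:6.1f}   0.1     1   200     1   200     "
            f"1   200 0.95 synthetic family"
        )
    return "\n".join(lines) + "\n"


def write_external2go(
    mapping: Mapping[str, Sequence[str]], prefix: str, path_or_handle
) -> None:
    """Write an external2go table (e.g. pfam2go) from an id -> GO ids map."""
    handle = (
        path_or_handle
        if hasattr(path_or_handle, "write")
        else open(path_or_handle, "w")
    )
    handle.write("!version: synthetic\n")
    for ext_id in sorted(mapping):
        for go_id in mapping[ext_id]:
            handle.write(f"{prefix}:{ext_id} {ext_id} > GO:synthetic ; {go_id}\n")
    if not hasattr(path_or_handle, "write"):
        handle.close()
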