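"""Functional annotation rollups: Pfam -> GO -> GO-Slim -> KEGG.

Protein-family evidence comes from hmmscan domain-table reports (the
scanner itself is not run here).  Pfam accessions are mapped to Gene
Ontology terms through the standard ``pfam2go`` table, GO terms are
abstracted to GO-Slim terms — defined here as the penultimate ancestors of
a term, i.e. the direct ``is_a`` children of an ontology root lying on a
path from the term to that root — and fine-grained GO terms are mapped to
KEGG Ligand reaction records via ``kegg2go``.

For transcripts without a curated protein translation, the longest ORF
over all six reading frames is used as the query peptide; an ORF is a
maximal stop-free stretch (no start-codon requirement).

Ontologies are held as :class:`networkx.DiGraph` objects with child ->
parent ``is_a`` edges and ``name``/``namespace`` node attributes; OBO files
are read through :mod:`obonet`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet
from Bio.Seq import Seq

__all__ = [
    "PfamHit",
    "AnnotationTally",
    "six_frame_translate",
    "longest_orf",
    "parse_domtbl_top_hit",
    "read_external2go",
    "pfam_to_go",
    "go_slim",
    "go_slim_tally",
    "go_to_kegg",
    "load_obo",
    "ontology_roots",
    "GO_ROOTS",
]

FRAME_ORDER = (1, 2, 3, -1, -2, -3)

# Canonical root term ids of the three GO domains.
GO_ROOTS = {
    "GO:0008150": "biological_process",
    "GO:0005575": "cellular_component",
    "GO:0003674": "molecular_function",
}

DEFAULT_EVALUE_CUTOFF = 1e-2


@dataclass(frozen=True)
class PfamHit:
    query_id: str
    family_acc: str
    family_name: str
    full_seq_evalue: float
    bitscore: float


@dataclass
class AnnotationTally:
    """Multiset of annotation identifiers with unique/total summaries."""

    counts: Counter = field(default_factory=Counter)

    def add(self, identifier: str, n: int = 1) -> None:
        self.counts[identifier] += n

    @property
    def unique(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def most_common(self, n: int | None = None) -> list[tuple[str, int]]:
        return self.counts.most_common(n)


def six_frame_translate(seq: str) -> tuple[str, ...]:
    """Translate in frames +1,+2,+3,-1,-2,-3; stops as '*', partial codons dropped."""
    if len(seq) < 3:
        return ("",) * 6
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    frames = []
    for strand_seq in (fwd, rev):
        for off in range(3):
            sub = strand_seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames.append(str(sub.translate(table=1)))
    return tuple(frames)


def longest_orf(frames: Iterable[str]) -> tuple[int, str]:
    """Longest stop-free peptide stretch across the six frames.

    Ties are broken by frame order +1,+2,+3,-1,-2,-3, then leftmost
    position, making the published "selected arbitrarily" rule
    deterministic.  Returns ``(frame, peptide)``; the peptide may be empty.
    """
    best_len, best_frame, best_pep = -1, FRAME_ORDER[0], ""
    for frame, pep in zip(FRAME_ORDER, frames):
        for run in pep.split("*"):
            if len(run) > best_len:
                best_len, best_frame, best_pep = len(run), frame, run
    return best_frame, best_pep


def parse_domtbl_top_hit(
    path_or_handle, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> dict[str, PfamHit]:
    """Select the top Pfam family per query from hmmscan --domtblout output.

    Ranking is by full-sequence E-value ascending (hmmscan's default hit
    order), ties by higher bitscore, then lexicographic accession.  Queries
    whose best E-value exceeds the cutoff are left unannotated.
    """
    handle: IO[str] = (
        path_or_handle if hasattr(path_or_handle, "read") else open(path_or_handle)
    )
    best: dict[str, PfamHit] = {}
    for lineno, line in enumerate(handle, 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split(maxsplit=22)
        if len(cols) < 14:
            raise ValueError(f"domtbl line {lineno}: too few columns")
        try:
            hit = PfamHit(
                query_id=cols[3],
                family_acc=cols[1],
                family_name=cols[0],
                full_seq_evalue=float(cols[6]),
                bitscore=float(cols[7]),
            )
        except ValueError as exc:
            raise ValueError(f"domtbl line {lineno}: {exc}") from exc
        if hit.full_seq_evalue > evalue_cutoff:
            continue
        cur = best.get(hit.query_id)
        if cur is None or (
            (hit.full_seq_evalue, -hit.bitscore, hit.family_acc)
            < (cur.full_seq_evalue, -cur.bitscore, cur.family_acc)
        ):
            best[hit.query_id] = hit
    return best


def _strip_version(acc: str) -> str:
    return acc.split(".")[0]


def read_external2go(path_or_handle, prefix: str) -> dict[str, list[str]]:
    """Parse an external2go mapping (pfam2go, kegg2go, ...).

    Lines look like ``Pfam:PF00001 7tm_1 > GO:... ; GO:0004930``; '!' lines
    are comments.  Returns external id (version-stripped) -> GO ids.
    """
    handle = (
        path_or_handle if hasattr(path_or_handle, "read") else open(path_or_handle)
    )
    mapping: dict[str, list[str]] = {}
    want = prefix.rstrip(":") + ":"
    for line in handle:
        line = line.strip()
        if not line or line.startswith("!"):
            continue
        if not line.startswith(want) or " > " not in line:
            continue
        left, right = line.split(" > ", 1)
        ext_id = _strip_version(left.split()[0][len(want):])
        go_id = right.rsplit(";", 1)[-1].strip()
        mapping.setdefault(ext_id, []).append(go_id)
    return mapping


def load_obo(path_or_handle) -> nx.DiGraph:
    """Load an OBO 1.2 ontology, keeping only is_a edges (child -> parent)."""
    multi = obonet.read_obo(path_or_handle)
    graph = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        graph.add_node(
            node,
            name=data.get("name", node),
            namespace=data.get("namespace", ""),
        )
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    return graph


def ontology_roots(graph: nx.DiGraph) -> set[str]:
    return {n for n in graph.nodes if graph.out_degree(n) == 0}


def go_slim(term: str, graph: nx.DiGraph) -> set[str]:
    """Penultimate ancestors of a term: root children on its is_a paths.

    Roots themselves map to the empty set (the three domain roots carry no
    information); a direct child of a root is its own GO-Slim term.
    """
    if term not in graph:
        raise KeyError(f"unknown ontology term {term!r}")
    roots = ontology_roots(graph)
    if term in roots:
        return set()
    ancestors = nx.descendants(graph, term) | {term}
    return {
        t
        for t in ancestors
        if t not in roots and any(p in roots for p in graph.successors(t))
    }


def pfam_to_go(
    hits: Mapping[str, PfamHit],
    pfam2go: Mapping[str, list[str]],
    graph: nx.DiGraph,
) -> tuple[dict[str, AnnotationTally], AnnotationTally]:
    """Roll Pfam hits up to GO terms, stratified by ontology domain.

    Every hit contributes all GO terms mapped to its family (families may
    map to zero, one, or several terms).  GO ids absent from the ontology
    are tallied separately under the returned ``unmapped`` tally with a
    warning-free contract: callers inspect it explicitly.
    """
    domains = sorted(set(GO_ROOTS.values()))
    tallies = {d: AnnotationTally() for d in domains}
    unmapped = AnnotationTally()
    for hit in hits.values():
        for go_id in pfam2go.get(_strip_version(hit.family_acc), []):
            if go_id in graph:
                domain = graph.nodes[go_id].get("namespace", "")
                tallies.setdefault(domain, AnnotationTally()).add(go_id)
            else:
                unmapped.add(go_id)
    return tallies, unmapped


def go_slim_tally(
    go_tallies: Mapping[str, AnnotationTally],
    graph: nx.DiGraph,
    mode: str = "set",
) -> dict[str, AnnotationTally]:
    """GO-Slim rollup of per-domain GO tallies.

    ``mode='set'`` counts each slim term once per annotated term occurrence
    set; ``mode='multiset'`` multiplies by the term's own count.  Terms with
    multiple root-child ancestors contribute all of them.
    """
    if mode not in ("set", "multiset"):
        raise ValueError(f"unknown tally mode {mode!r}")
    out: dict[str, AnnotationTally] = {}
    for domain, tally in go_tallies.items():
        slim = AnnotationTally()
        for term, count in tally.counts.items():
            for s in sorted(go_slim(term, graph)):
                slim.add(s, count if mode == "multiset" else 1)
        out[domain] = slim
    return out


def go_to_kegg(
    terms: Iterable[str], kegg2go: Mapping[str, list[str]]
) -> tuple[AnnotationTally, float]:
    """Map GO terms onto KEGG reaction identifiers.

    ``kegg2go`` maps KEGG ids to GO ids; the inverse index is built here.
    Returns the KEGG tally and the fraction of unique input GO terms having
    at least one KEGG mapping.
    """
    go_to_kegg_idx: dict[str, list[str]] = {}
    for kegg_id, go_ids in kegg2go.items():
        for go_id in go_ids:
            go_to_kegg_idx.setdefault(go_id, []).append(kegg_id)
    tally = AnnotationTally()
    unique_terms = set(terms)
    mapped = 0
    for term in sorted(unique_terms):
        keggs = go_to_kegg_idx.get(term, [])
        if keggs:
            mapped += 1
        for k in keggs:
            tally.add(f"KEGG:{k}" if not k.startswith("KEGG:") else k)
    fraction = mapped / len(unique_terms) if unique_terms else 0.0
    return tally, fraction
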