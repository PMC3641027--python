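import io

import networkx as nx
import numpy as np
import pytest

from lepitran import annotate as ann, synthetic_data as sd

from oracle_impls import oracle_longest_orf


class TestSixFrame:
    def test_stop_codon_rendered(self):
        assert ann.six_frame_translate("ATGTAA")[0] == "M*"

    def test_reverse_frame_equals_forward_of_revcomp(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 120))))
            rc = str(__import__("Bio.Seq", fromlist=["Seq"]).Seq(seq).reverse_complement())
            assert ann.six_frame_translate(seq)[3] == ann.six_frame_translate(rc)[0]

    def test_frame_lengths(self):
        frames = ann.six_frame_translate("A" * 100)
        for off, pep in zip((0, 1, 2, 0, 1, 2), frames):
            assert len(pep) == (100 - off) // 3

    def test_too_short_sequence_gives_empty_frames(self):
        assert ann.six_frame_translate("AT") == ("",) * 6


class TestLongestOrf:
    def test_longest_run_across_frames(self):
        frames = ("MKL*A", "MK*LLLL", "", "", "", "")
        assert ann.longest_orf(frames) == (2, "LLLL")

    def test_tie_resolved_by_frame_order(self):
        frames = ("AA*CC", "", "", "GG*TT", "", "")
        assert ann.longest_orf(frames) == (1, "AA")

    def test_agrees_with_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 300))))
            frames = ann.six_frame_translate(seq)
            frame, pep = ann.longest_orf(frames)
            o_frame, o_pep = oracle_longest_orf(frames)
            assert (frame, pep) == (o_frame, o_pep)


class TestDomtbl:
    def domtbl(self, records):
        return io.StringIO(sd.make_domtbl_lines(records))

    def test_lowest_evalue_family_selected(self):
        hits = ann.parse_domtbl_top_hit(
            self.domtbl([("q1", "PF1", "famA", 1e-3, 20.0), ("q1", "PF2", "famB", 1e-5, 15.0)])
        )
        assert hits["q1"].family_acc == "PF2"

    def test_hit_above_cutoff_leaves_query_unannotated(self):
        hits = ann.parse_domtbl_top_hit(self.domtbl([("q1", "PF1", "famA", 0.5, 20.0)]))
        assert hits == {}

    def test_empty_stream(self):
        assert ann.parse_domtbl_top_hit(io.StringIO("")) == {}

    def test_evalue_tie_broken_by_score_then_accession(self):
        hits = ann.parse_domtbl_top_hit(
            self.domtbl(
                [
                    ("q1", "PF2", "famB", 1e-4, 30.0),
                    ("q1", "PF1", "famA", 1e-4, 30.0),
                    ("q1", "PF3", "famC", 1e-4, 40.0),
                ]
            )
        )
        assert hits["q1"].family_acc == "PF3"

    def test_malformed_line_names_line_number(self):
        with pytest.raises(ValueError, match="line 1"):
            ann.parse_domtbl_top_hit(io.StringIO("only three columns here\n"))


class TestGoSlim:
    def chain_graph(self):
        g = nx.DiGraph()
        root = "GO:0008150"
        g.add_node(root, name="biological_process", namespace="biological_process")
        for term in ("A", "B", "C"):
            g.add_node(term, name=term, namespace="biological_process")
        g.add_edge("A", root)
        g.add_edge("B", "A")
        g.add_edge("C", "B")
        return g

    def diamond_graph(self):
        g = nx.DiGraph()
        root = "GO:0003674"
        g.add_node(root, name="molecular_function", namespace="molecular_function")
        for term in ("A1", "A2", "C"):
            g.add_node(term, name=term, namespace="molecular_function")
        g.add_edge("A1", root)
        g.add_edge("A2", root)
        g.add_edge("C", "A1")
        g.add_edge("C", "A2")
        return g

    def test_chain_returns_penultimate_ancestor(self):
        assert ann.go_slim("C", self.chain_graph()) == {"A"}

    def test_diamond_returns_both_paths(self):
        assert ann.go_slim("C", self.diamond_graph()) == {"A1", "A2"}

    def test_root_returns_empty_set(self):
        assert ann.go_slim("GO:0008150", self.chain_graph()) == set()

    def test_root_child_is_its_own_slim_term(self):
        assert ann.go_slim("A", self.chain_graph()) == {"A"}

    def test_unknown_term_raises(self):
        with pytest.raises(KeyError):
            ann.go_slim("GO:9999999", self.chain_graph())

    def test_slim_terms_are_root_children_in_declared_domain(self, toy_ontology):
        roots = ann.ontology_roots(toy_ontology)
        for term in toy_ontology.nodes:
            for slim in ann.go_slim(term, toy_ontology):
                parents = set(toy_ontology.successors(slim))
                assert parents & roots
                (root,) = parents & roots
                assert (
                    toy_ontology.nodes[root]["namespace"]
                    == toy_ontology.nodes[term]["namespace"]
                )

    def test_obo_round_trip(self, toy_ontology, tmp_path):
        path = tmp_path / "toy.obo"
        sd.write_obo(toy_ontology, path)
        back = ann.load_obo(str(path))
        assert set(back.nodes) == set(toy_ontology.nodes)
        assert set(back.edges) == set(toy_ontology.edges)
        assert nx.is_directed_acyclic_graph(back)


class TestRollups:
    def test_pfam_to_go_hand_computed_tally(self, toy_ontology):
        terms = [n for n in toy_ontology.nodes if n.startswith("GO:7")]
        bp = [t for t in terms if toy_ontology.nodes[t]["namespace"] == "biological_process"]
        hits = {
            "p1": ann.PfamHit("p1", "PF00001.5", "famA", 1e-5, 50.0),
            "p2": ann.PfamHit("p2", "PF00001.5", "famA", 1e-4, 40.0),
            "p3": ann.PfamHit("p3", "PF00002", "famB", 1e-3, 30.0),
            "p4": ann.PfamHit("p4", "PF00003", "famC", 1e-3, 30.0),
            "p5": ann.PfamHit("p5", "PF00004", "famD", 1e-3, 30.0),
        }
        pfam2go = {
            "PF00001": [bp[0], bp[1]],  # two proteins x two terms -> total 4
            "PF00002": [bp[0]],
            "PF00003": [],  # family with no GO terms contributes nothing
            "PF00004": ["GO:0000404"],  # absent from ontology -> unmapped
        }
        tallies, unmapped = ann.pfam_to_go(hits, pfam2go, toy_ontology)
        t = tallies["biological_process"]
        assert t.total == 5 and t.unique == 2
        assert t.counts[bp[0]] == 3 and t.counts[bp[1]] == 2
        assert unmapped.total == 1
        # removing a protein never increases any count
        smaller, _ = ann.pfam_to_go(
            {k: v for k, v in hits.items() if k != "p1"}, pfam2go, toy_ontology
        )
        for term, count in smaller["biological_process"].counts.items():
            assert count <= t.counts[term]

    def test_go_to_kegg_fraction(self):
        kegg2go = {"R00001": ["GO:1"], "R00002": ["GO:1", "GO:2"]}
        tally, frac = ann.go_to_kegg(["GO:1", "GO:2", "GO:3", "GO:4"], kegg2go)
        assert frac == pytest.approx(0.5)
        assert tally.total == 3  # GO:1 -> 2 KEGG ids, GO:2 -> 1
        assert ann.go_to_kegg([], kegg2go)[1] == 0.0

    def test_go_to_kegg_reproduces_published_style_fraction(self):
        """A fixture with 7 of 148 unique terms mapped gives ~4.7%."""
        terms = [f"GO:{i:07d}" for i in range(148)]
        kegg2go = {f"R{i:05d}": [terms[i]] for i in range(7)}
        _, frac = ann.go_to_kegg(terms, kegg2go)
        assert frac == pytest.approx(7 / 148)
        assert round(100 * frac, 1) == 4.7

    def test_external2go_parsing(self):
        text = (
            "!version date: 2011/01/10\n"
            "Pfam:PF00001 7tm_1 > GO:receptor activity ; GO:0004930\n"
            "Pfam:PF00001 7tm_1 > GO:membrane ; GO:0016020\n"
            "Pfam:PF00002 other > GO:binding ; GO:0005488\n"
        )
        mapping = ann.read_external2go(io.StringIO(text), "Pfam")
        assert mapping == {
            "PF00001": ["GO:0004930", "GO:0016020"],
            "PF00002": ["GO:0005488"],
        }

    def test_slim_tally_modes(self, toy_ontology):
        terms = [
            n for n in toy_ontology.nodes
            if n.startswith("GO:7")
            and toy_ontology.nodes[n]["namespace"] == "molecular_function"
        ]
        tally = ann.AnnotationTally()
        tally.add(terms[0], 3)
        sets = ann.go_slim_tally({"molecular_function": tally}, toy_ontology, "set")
        multi = ann.go_slim_tally({"molecular_function": tally}, toy_ontology, "multiset")
        assert set(sets["molecular_function"].counts.values()) == {1}
        assert set(multi["molecular_function"].counts.values()) == {3}
        with pytest.raises(ValueError):
            ann.go_slim_tally({}, toy_ontology, "bogus")
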