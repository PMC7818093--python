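"""Format readers/writers: parsing, validation, canonicalisation, round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reentrant_scope import io as fio
from reentrant_scope.types import (
    Contact,
    ContactMap,
    FormatError,
    Sequence,
    SSProfile,
    TopologyProfile,
)


class TestFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">s1\nACDEFG\n")
        (seq,) = fio.read_fasta(path)
        assert (seq.id, seq.residues, seq.L) == ("s1", "ACDEFG", 6)

    def test_multi_record_order_preserved(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a\nAC\n>b\nGH\n")
        seqs = fio.read_fasta(path)
        assert [s.id for s in seqs] == ["a", "b"]
        assert all(s.L == 2 for s in seqs)

    def test_invalid_character_names_record(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">s\nAC1DE\n")
        with pytest.raises(FormatError, match="s"):
            fio.read_fasta(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text("")
        with pytest.raises(FormatError):
            fio.read_fasta(path)

    def test_round_trip(self, tmp_path):
        seqs = [Sequence("x", "ACDEFGHIKLMNPQRSTVWYX" * 5), Sequence("y", "GG")]
        path = tmp_path / "rt.fasta"
        fio.write_fasta(path, seqs)
        assert fio.read_fasta(path) == seqs


class TestCaspRR:
    def test_direct_parse(self, tmp_path):
        path = tmp_path / "m.rr"
        path.write_text("2 5 0 8 0.9\n")
        cmap = fio.read_casp_rr(path, L=10)
        assert cmap.contacts == [Contact(2, 5, 0.9)]

    def test_reversed_pair_canonicalised(self, tmp_path):
        path = tmp_path / "m.rr"
        path.write_text("5 2 0 8 0.9\n")
        assert fio.read_casp_rr(path, L=10).contacts == [Contact(2, 5, 0.9)]

    def test_duplicate_keeps_max_score(self, tmp_path):
        path = tmp_path / "m.rr"
        path.write_text("2 5 0 8 0.4\n5 2 0 8 0.9\n")
        assert fio.read_casp_rr(path, L=10).contacts == [Contact(2, 5, 0.9)]

    def test_index_out_of_bounds(self, tmp_path):
        path = tmp_path / "m.rr"
        path.write_text("2 11 0 8 0.9\n")
        with pytest.raises(FormatError, match=r"\[1, 10\]"):
            fio.read_casp_rr(path, L=10)

    def test_score_out_of_range(self, tmp_path):
        path = tmp_path / "m.rr"
        path.write_text("2 5 0 8 1.5\n")
        with pytest.raises(FormatError, match="score"):
            fio.read_casp_rr(path, L=10)

    def test_header_lines_skipped(self, tmp_path):
        path = tmp_path / "m.rr"
        path.write_text("PFRMAT RR\nACDEF\n1 6 0 8 0.5\nEND\n")
        assert len(fio.read_casp_rr(path, L=10)) == 1

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_round_trip_exact_to_six_decimals(self, tmp_path_factory, data):
        L = data.draw(st.integers(10, 60))
        pairs = data.draw(
            st.sets(
                st.tuples(st.integers(1, L), st.integers(1, L)).filter(
                    lambda p: p[0] < p[1]
                ),
                min_size=1,
                max_size=30,
            )
        )
        scores = data.draw(
            st.lists(
                st.floats(0, 1).map(lambda x: round(x, 6)),
                min_size=len(pairs),
                max_size=len(pairs),
            )
        )
        cmap = ContactMap(L, [Contact(i, j, s)
                              for (i, j), s in zip(sorted(pairs), scores)])
        path = tmp_path_factory.mktemp("rr") / "m.rr"
        fio.write_casp_rr(path, cmap)
        again = fio.read_casp_rr(path, L)
        assert again.pair_set() == cmap.pair_set()
        got = {(c.i, c.j): c.score for c in again.contacts}
        for c in cmap.contacts:
            assert got[(c.i, c.j)] == pytest.approx(c.score, abs=5e-7)


class TestContactMapInvariants:
    def test_canonical_order_enforced(self):
        cmap = ContactMap(10, [Contact(7, 3, 0.5)])
        assert cmap.contacts == [Contact(3, 7, 0.5)]

    def test_self_contact_rejected(self):
        with pytest.raises(FormatError):
            ContactMap(10, [Contact(3, 3, 0.5)])

    def test_out_of_range_rejected(self):
        with pytest.raises(FormatError):
            ContactMap(10, [Contact(0, 3, 0.5)])


class TestProfiles:
    def test_ss2_round_trip(self, tmp_path):
        seq = Sequence("s", "ACDEF")
        conf = np.array([[0.9, 0.05, 0.05]] * 3 + [[0.1, 0.1, 0.8]] * 2)
        ss = SSProfile("HHHCC", conf)
        path = tmp_path / "a.ss2"
        fio.write_ss2(path, ss, seq)
        again = fio.read_ss2(path)
        assert again.states == ss.states
        np.testing.assert_allclose(again.confidences, conf, atol=1e-3)

    def test_ss2_confidence_must_sum_to_one(self):
        with pytest.raises(FormatError, match="sums"):
            SSProfile("HH", np.array([[0.5, 0.1, 0.1], [0.9, 0.05, 0.05]]))

    def test_topcons_round_trip(self, tmp_path):
        topo = TopologyProfile("iiiMMMMMoooMMMMMiii")
        path = tmp_path / "a.topo"
        fio.write_topcons(path, topo)
        assert fio.read_topcons(path) == topo

    def test_topology_segments_tile_chain(self):
        topo = TopologyProfile("iiMMMoo")
        assert topo.segments == [(1, 2, "i"), (3, 5, "M"), (6, 7, "o")]
        assert topo.membrane_segments() == [(3, 5)]

    def test_invalid_topology_code(self):
        with pytest.raises(FormatError):
            TopologyProfile("iixMM")


class TestPdbModel:
    def test_round_trip_coordinates(self, tmp_path, deda):
        path = tmp_path / "m.pdb"
        fio.write_pdb_model(path, deda.model)
        again = fio.read_pdb_model(path)
        assert again.L == deda.model.L
        for a, b in zip(again.residues, deda.model.residues):
            assert a.index == b.index and a.aa == b.aa
            np.testing.assert_allclose(a.ca, b.ca, atol=2e-3)
            assert (a.cb is None) == (b.cb is None)

    def test_glycine_has_no_cb(self, tmp_path, deda):
        path = tmp_path / "m.pdb"
        fio.write_pdb_model(path, deda.model)
        again = fio.read_pdb_model(path)
        glycines = [r for r in again.residues if r.aa == "G"]
        assert glycines and all(r.cb is None for r in glycines)


PDBTM_ONE_CHAIN = """<?xml version="1.0"?>
<pdbtm ID="1xyz">
  <CHAIN CHAINID="A" TYPE="alpha">
    <REGION seq_beg="1" seq_end="39" type="1"/>
    <REGION seq_beg="40" seq_end="52" type="L"/>
    <REGION seq_beg="53" seq_end="80" type="2"/>
  </CHAIN>
</pdbtm>
"""

PDBTM_SIDES_ONLY = """<?xml version="1.0"?>
<pdbtm ID="2xyz">
  <CHAIN CHAINID="B" TYPE="alpha">
    <REGION seq_beg="1" seq_end="30" type="1"/>
    <REGION seq_beg="31" seq_end="60" type="2"/>
  </CHAIN>
</pdbtm>
"""


class TestPdbtmRegions:
    def test_reentrant_region_mapped(self, tmp_path):
        path = tmp_path / "a.xml"
        path.write_text(PDBTM_ONE_CHAIN)
        (ann,) = fio.read_pdbtm_regions(path)
        assert ann.chain == "A"
        assert ann.of_code("reentrant") == [(40, 52, "reentrant")]

    def test_sides_only_means_no_reentrants(self, tmp_path):
        path = tmp_path / "a.xml"
        path.write_text(PDBTM_SIDES_ONLY)
        (ann,) = fio.read_pdbtm_regions(path)
        assert ann.of_code("reentrant") == []
        assert len(ann.regions) == 2

    def test_two_chains_order_preserved(self, tmp_path):
        two = PDBTM_ONE_CHAIN.replace(
            "</pdbtm>",
            '<CHAIN CHAINID="B"><REGION seq_beg="5" seq_end="9" type="H"/>'
            "</CHAIN></pdbtm>",
        )
        path = tmp_path / "a.xml"
        path.write_text(two)
        anns = fio.read_pdbtm_regions(path)
        assert [a.chain for a in anns] == ["A", "B"]

    def test_unknown_code_preserved_with_warning(self, tmp_path):
        odd = PDBTM_ONE_CHAIN.replace('type="L"', 'type="Q"')
        path = tmp_path / "a.xml"
        path.write_text(odd)
        with pytest.warns(UserWarning, match="unknown region code"):
            (ann,) = fio.read_pdbtm_regions(path)
        assert any(r.code == "Q" for r in ann.regions)

    def test_malformed_xml_is_format_error(self, tmp_path):
        path = tmp_path / "a.xml"
        path.write_text("<pdbtm><CHAIN CHAINID='A'>")
        with pytest.raises(FormatError, match="malformed XML"):
            fio.read_pdbtm_regions(path)
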