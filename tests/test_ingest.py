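"""Input-table parsing and the unique-KO / longest-isoform filters."""

import pytest
from hypothesis import given, settings, strategies as st

from domevol.errors import FormatError, UniquenessError
from domevol.ingest import (
    KoalaAssignment,
    Organism,
    ProteinRecord,
    read_koala_assignments,
    read_organism_registry,
    read_protein_table,
    select_longest_isoform,
    select_unique_ko,
    write_koala_assignments,
    write_organism_registry,
    write_protein_table,
)


# ---------------------------------------------------------------------------
# organism registry
# ---------------------------------------------------------------------------

REGISTRY_HEADER = "org_id\tname\tsuperdomain\ttaxonomy_id\tsource_tags\n"


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestOrganismRegistry:
    def test_parses_row(self, tmp_path):
        p = write(tmp_path, "r.tsv",
                  REGISTRY_HEADER + "hsa\tHomo sapiens\tEukaryota\t9606\tSFA,GEO_hic\n")
        orgs = read_organism_registry(p)
        assert len(orgs) == 1
        assert orgs[0].org_id == "hsa"
        assert orgs[0].superdomain == "Eukaryota"
        assert orgs[0].source_tags == ("SFA", "GEO_hic")

    def test_header_only_is_empty(self, tmp_path):
        assert read_organism_registry(write(tmp_path, "r.tsv", REGISTRY_HEADER)) == []

    def test_unknown_superdomain_rejected(self, tmp_path):
        p = write(tmp_path, "r.tsv",
                  REGISTRY_HEADER + "mja\tM jannaschii\tArchaea\t2190\t\n")
        with pytest.raises(FormatError, match="line 2"):
            read_organism_registry(p)

    def test_duplicate_org_id_rejected(self, tmp_path):
        p = write(tmp_path, "r.tsv",
                  REGISTRY_HEADER
                  + "hsa\tHomo sapiens\tEukaryota\t9606\t\n"
                  + "hsa\tagain\tEukaryota\t9606\t\n")
        with pytest.raises(UniquenessError, match="hsa"):
            read_organism_registry(p)

    def test_org_code_shape_enforced(self):
        with pytest.raises(FormatError):
            Organism("toolong5", "x", "Eukaryota", 1)

    def test_round_trip(self, tmp_path):
        orgs = [
            Organism("hsa", "Homo sapiens", "Eukaryota", 9606, ("SFA",)),
            Organism("eco", "Escherichia coli", "Bacteria", 511145),
            Organism("HHV1", "Human Herpesvirus 1", "Viruses", 10298),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_organism_registry(orgs, p1)
        write_organism_registry(read_organism_registry(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# KofamKOALA assignments
# ---------------------------------------------------------------------------

class TestKoala:
    def test_parses_detail_tsv(self, tmp_path):
        text = (
            "#\tgene name\tKO\tthrshld\tscore\tE-value\tKO definition\n"
            "*\tXP_1\tK16822\t50.2\t123.4\t1e-30\tFRMD6\n"
            "\tXP_2\tK00001\t80\t40.1\t0.002\talcohol dehydrogenase\n"
        )
        rows = read_koala_assignments(write(tmp_path, "k.tsv", text))
        assert len(rows) == 2
        assert rows[0].significant and rows[0].ko_number == "K16822"
        assert not rows[1].significant and rows[1].score == pytest.approx(40.1)

    def test_bad_numeric_names_line(self, tmp_path):
        text = "*\tXP_1\tK16822\t50.2\tnot_a_number\t1e-30\tx\n"
        with pytest.raises(FormatError, match="line 1"):
            read_koala_assignments(write(tmp_path, "k.tsv", text))

    def test_round_trip(self, tmp_path):
        rows = [
            KoalaAssignment("XP_1", "K16822", 123.4, 50.2, 1e-30, True),
            KoalaAssignment("XP_2", "K00001", 40.0, 80.0, 0.002, False),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_koala_assignments(rows, p1)
        write_koala_assignments(read_koala_assignments(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# unique-KO filter
# ---------------------------------------------------------------------------

def A(refseq, ko, sig=True):
    return KoalaAssignment(refseq, ko, 100.0, 50.0, 1e-20, sig)


class TestUniqueKo:
    def test_multi_ko_protein_dropped(self):
        mapping, report = select_unique_ko(
            [A("p1", "K00001"), A("p2", "K00001"), A("p2", "K00002")]
        )
        assert mapping == {"p1": "K00001"}
        assert report.n_dropped_multi_ko == 1
        assert report.dropped_multi_ko == ["p2"]

    def test_nonsignificant_rows_ignored(self):
        mapping, report = select_unique_ko([A("p1", "K00001", sig=False)])
        assert mapping == {}
        assert report.n_dropped_no_significant == 1

    def test_repeated_identical_ko_counts_once(self):
        mapping, _ = select_unique_ko([A("p1", "K00003"), A("p1", "K00003")])
        assert mapping == {"p1": "K00003"}

    @given(st.permutations([
        A("p1", "K00001"), A("p1", "K00001"), A("p2", "K00001"),
        A("p2", "K00002"), A("p3", "K00009", sig=False),
    ]))
    @settings(deadline=None)
    def test_order_independent_and_idempotent(self, rows):
        """The map depends only on the row multiset, not on row order,
        and distinct-KO counting matches brute force over the fixture."""
        mapping, _ = select_unique_ko(rows)
        # brute-force oracle: distinct significant KOs per protein
        expected = {}
        for refseq in {r.refseq_id for r in rows}:
            kos = {r.ko_number for r in rows if r.refseq_id == refseq and r.significant}
            if len(kos) == 1:
                expected[refseq] = kos.pop()
        assert mapping == expected
        again, _ = select_unique_ko(
            [A(r, k) for r, k in mapping.items()]
        )
        assert again == mapping


# ---------------------------------------------------------------------------
# longest isoform
# ---------------------------------------------------------------------------

def P(refseq, length, group="g1", org="hsa"):
    return ProteinRecord(refseq, "GENE", org, length, isoform_group=group)


class TestLongestIsoform:
    def test_longest_wins(self):
        out = select_longest_isoform([P("XP_a", 300), P("XP_b", 450)])
        assert [r.refseq_id for r in out] == ["XP_b"]
        assert out[0].is_longest

    def test_tie_broken_by_refseq(self):
        out = select_longest_isoform([P("XP_b", 300), P("XP_a", 300)])
        assert [r.refseq_id for r in out] == ["XP_a"]

    def test_one_per_group(self):
        records = (
            [P("a1", 100, "g1")]
            + [P(f"b{i}", 100 + i, "g2") for i in range(2)]
            + [P(f"c{i}", 100 + i, "g3") for i in range(5)]
        )
        out = select_longest_isoform(records)
        assert len(out) == 3
        by_group = {r.isoform_group: r for r in out}
        # brute-force max per group
        for g in ("g1", "g2", "g3"):
            expected = max(
                (r for r in records if r.isoform_group == g),
                key=lambda r: (r.length_aa, [-ord(c) for c in r.refseq_id]),
            )
            assert by_group[g].refseq_id == expected.refseq_id

    @given(st.lists(
        st.tuples(st.integers(1, 500), st.sampled_from("abcde")),
        min_size=1, max_size=30,
    ))
    @settings(deadline=None)
    def test_group_count_conserved(self, spec):
        records = [
            P(f"XP_{i}", length, group) for i, (length, group) in enumerate(spec)
        ]
        out = select_longest_isoform(records)
        assert len(out) == len({r.isoform_group for r in records})


def test_fasta_length_crosscheck_flags_mismatches(tmp_path):
    from domevol.ingest import crosscheck_lengths

    fasta = tmp_path / "prot.fa"
    fasta.write_text(">XP_1\nMKV\n>XP_2\nMKVLW\n")
    records = [P("XP_1", 3, "g1"), P("XP_2", 4, "g2"), P("XP_3", 9, "g3")]
    assert crosscheck_lengths(records, fasta) == ["XP_2"]


def test_protein_table_round_trip(tmp_path):
    records = [
        ProteinRecord("XP_1", "FRMD6", "hsa", 622, "chr14", "+", "FRMD6_hsa"),
        ProteinRecord("XP_2", "MYLIP", "rno", 445, "chr5", "-", "MYLIP_rno"),
    ]
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_protein_table(records, p1)
    assert read_protein_table(p1) == records
    write_protein_table(read_protein_table(p1), p2)
    assert p1.read_bytes() == p2.read_bytes()
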