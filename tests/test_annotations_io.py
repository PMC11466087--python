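from collections import Counter

import numpy as np
import pytest

from tolrad.annotations_io import (
    AnnotationFormatError,
    EmptyAnnotationSetError,
    PfamAnnotationSet,
    build_frequency_table,
    compute_frequencies,
    read_eggnog_annotations,
    read_pfam_table,
    write_eggnog_annotations,
    write_pfam_table,
)

EGGNOG_3ROW = (
    "## emapper version 2\n"
    "#query\tseed_ortholog\tDescription\tPFAMs\n"
    "p1\t-\t-\tPF00300\n"
    "p2\t-\t-\tPF00300,PF07992\n"
    "p3\t-\t-\t-\n"
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestEggnogDialect:
    def test_three_row_fixture_counts(self, tmp_path):
        aset = read_eggnog_annotations(_write(tmp_path, "a.ann", EGGNOG_3ROW), "g1")
        assert aset.total_instances == 3
        assert aset.domain_counts() == Counter({"PF00300": 2, "PF07992": 1})
        assert len(aset.records) == 3

    def test_all_missing_cells_give_empty_multiset(self, tmp_path):
        text = "#query\tPFAMs\np1\t-\np2\t-\n"
        aset = read_eggnog_annotations(_write(tmp_path, "a.ann", text), "g1")
        assert aset.total_instances == 0
        assert all(not doms for _, doms in aset.records)

    def test_footer_block_and_crlf_and_trailing_blanks_ignored(self, tmp_path):
        text = (
            "## meta\r\n#query\tPFAMs\r\np1\tPF00001\r\n"
            "## 1 queries scanned\r\n## total time: 2s\r\np_ghost\tPF09999\r\n\r\n\r\n"
        )
        aset = read_eggnog_annotations(_write(tmp_path, "a.ann", text), "g1")
        assert aset.domain_counts() == Counter({"PF00001": 1})
        assert [pid for pid, _ in aset.records] == ["p1"]

    def test_missing_pfams_column_names_found_columns(self, tmp_path):
        text = "#query\tseed_ortholog\tKEGG\np1\t-\t-\n"
        with pytest.raises(AnnotationFormatError, match="KEGG"):
            read_eggnog_annotations(_write(tmp_path, "a.ann", text), "g1")

    def test_bad_token_warns_skips_and_tallies(self, tmp_path):
        text = "#query\tPFAMs\np1\tPF00001,NOT_A_PFAM,PF00002\n"
        with pytest.warns(UserWarning, match="NOT_A_PFAM"):
            aset = read_eggnog_annotations(_write(tmp_path, "a.ann", text), "g1")
        assert aset.total_instances == 2
        assert aset.skipped_tokens == 1

    def test_roundtrip_preserves_generator_counts(self, tmp_path, small_cohort):
        sets, _, _ = small_cohort
        for aset in sets[:3]:
            path = tmp_path / f"{aset.genome_id}.emapper.annotations"
            write_eggnog_annotations(aset, path)
            back = read_eggnog_annotations(path, aset.genome_id)
            assert back.domain_counts() == aset.domain_counts()
            assert back.total_instances == aset.total_instances


class TestPfamTableDialect:
    def test_counts_with_repeats(self, tmp_path):
        text = "protein_id\tpfam_ids\np1\tPF00001;PF00001\np2\tPF00002\n"
        aset = read_pfam_table(_write(tmp_path, "a.tsv", text), "g1")
        assert aset.domain_counts() == Counter({"PF00001": 2, "PF00002": 1})
        assert aset.total_instances == 3

    def test_version_suffix_stripped(self, tmp_path):
        text = "protein_id\tpfam_ids\np1\tPF00300.23\n"
        aset = read_pfam_table(_write(tmp_path, "a.tsv", text), "g1")
        assert aset.domain_counts() == Counter({"PF00300": 1})

    def test_duplicate_protein_rows_rejected(self, tmp_path):
        text = "protein_id\tpfam_ids\np1\tPF00001\np1\tPF00002\n"
        with pytest.raises(AnnotationFormatError, match="duplicate"):
            read_pfam_table(_write(tmp_path, "a.tsv", text), "g1")

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(AnnotationFormatError, match="empty"):
            read_pfam_table(_write(tmp_path, "a.tsv", ""), "g1")

    def test_write_read_write_is_byte_identical(self, tmp_path, small_cohort):
        sets, _, _ = small_cohort
        aset = sets[0]
        p1, p2 = tmp_path / "one.tsv", tmp_path / "two.tsv"
        write_pfam_table(aset, p1)
        write_pfam_table(read_pfam_table(p1, aset.genome_id), p2)
        assert p1.read_bytes() == p2.read_bytes()


def _random_aset(rng, gid="g"):
    n_dom = int(rng.integers(1, 8))
    domains = [f"PF{10000 + i:05d}" for i in range(n_dom)]
    records = []
    for p in range(int(rng.integers(1, 6))):
        doms = [domains[int(j)] for j in rng.integers(0, n_dom, size=int(rng.integers(0, 5)))]
        records.append((f"p{p}", doms))
    return PfamAnnotationSet(genome_id=gid, records=records)


class TestFrequencies:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 2, "B": 2}, {"A": 0.5, "B": 0.5}),
            ({"A": 1, "B": 3}, {"A": 0.25, "B": 0.75}),
        ],
    )
    def test_simple_ratios(self, counts, expected):
        records = [(f"p{d}", [d] * c) for d, c in counts.items()]
        aset = PfamAnnotationSet(genome_id="g", records=records)
        assert compute_frequencies(aset) == expected

    def test_matches_bruteforce_tally_on_random_multisets(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            aset = _random_aset(rng)
            if aset.total_instances == 0:
                continue
            # independent oracle: flat tally of every instance token
            flat = [d for _, doms in aset.records for d in doms]
            oracle = {d: flat.count(d) / len(flat) for d in set(flat)}
            assert compute_frequencies(aset) == oracle

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            aset = _random_aset(rng)
            if aset.total_instances == 0:
                continue
            assert sum(compute_frequencies(aset).values()) == pytest.approx(1, abs=1e-9)

    def test_scale_invariance(self):
        base = PfamAnnotationSet("g", [("p1", ["PF00001", "PF00002", "PF00002"])])
        tripled = PfamAnnotationSet("g", base.records * 3)
        assert compute_frequencies(base) == compute_frequencies(tripled)

    def test_empty_set_is_an_explicit_error(self):
        aset = PfamAnnotationSet("mag0", [("p1", [])])
        with pytest.raises(EmptyAnnotationSetError, match="mag0"):
            compute_frequencies(aset)


class TestFrequencyTable:
    def test_disjoint_domains_give_identity_rows(self):
        a = PfamAnnotationSet("g1", [("p", ["PF00001"])])
        b = PfamAnnotationSet("g2", [("p", ["PF00002"])])
        t = build_frequency_table([a, b])
        assert t.frequencies.values.tolist() == [[1.0, 0.0], [0.0, 1.0]]
        assert t.counts.values.tolist() == [[1, 0], [0, 1]]

    def test_restriction_to_absent_domain_is_zero_column(self):
        a = PfamAnnotationSet("g1", [("p", ["PF00001"])])
        t = build_frequency_table([a], domains=["PF00001", "PF09999"])
        assert t.frequencies["PF09999"].tolist() == [0.0]

    def test_table_equals_stacked_per_genome_frequencies(self, small_cohort):
        sets, _, _ = small_cohort
        t = build_frequency_table(sets)
        for aset in sets:
            freqs = compute_frequencies(aset)
            row = t.frequencies.loc[aset.genome_id]
            for d in t.domain_ids:
                assert row[d] == freqs.get(d, 0.0)

    def test_full_universe_row_sums_are_one(self, small_cohort):
        sets, _, _ = small_cohort
        t = build_frequency_table(sets)
        assert np.allclose(t.frequencies.sum(axis=1), 1.0, atol=1e-9)

    def test_duplicate_genome_id_rejected(self):
        a = PfamAnnotationSet("g1", [("p", ["PF00001"])])
        with pytest.raises(ValueError, match="duplicate"):
            build_frequency_table([a, a])

    def test_tsv_roundtrip_preserves_frequencies(self, tmp_path, small_cohort):
        from tolrad.annotations_io import FrequencyTable

        sets, _, _ = small_cohort
        t = build_frequency_table(sets)
        t.to_tsv(tmp_path / "f.tsv")
        back = FrequencyTable.from_tsv(tmp_path / "f.tsv")
        assert np.allclose(back.frequencies.values, t.frequencies.values)
        assert back.domain_ids == t.domain_ids
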