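import numpy as np
import pytest
from hypothesis import given, strategies as st

import mampep as mp
from mampep.generator import GeneratedPeptide


class TestLabelFromIc50:
    @pytest.mark.parametrize("ic50,expected", [
        (32.0, 1), (499.9, 1), (500.0, 0), (500.1, 0), (20000.0, 0),
    ])
    def test_strict_threshold(self, ic50, expected):
        assert mp.label_from_ic50(ic50) == expected

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_rejects_non_positive(self, bad):
        with pytest.raises(ValueError):
            mp.label_from_ic50(bad)

    @given(st.floats(min_value=1e-3, max_value=1e6),
           st.floats(min_value=1e-3, max_value=1e6))
    def test_monotone_non_increasing(self, a, b):
        lo, hi = sorted([a, b])
        assert mp.label_from_ic50(lo) >= mp.label_from_ic50(hi)


class TestPeptideRecord:
    def test_lowercase_normalized(self):
        assert mp.PeptideRecord("llfgypvyv").sequence == "LLFGYPVYV"

    def test_non_canonical_residue_named_in_error(self):
        with pytest.raises(mp.SequenceError, match="'X'"):
            mp.PeptideRecord("LLFGXPVYV")

    def test_label_ic50_consistency_enforced(self):
        mp.PeptideRecord("LLFGYPVYV", ic50=32.0, label=1)
        with pytest.raises(ValueError, match="inconsistent"):
            mp.PeptideRecord("LLFGYPVYV", ic50=32.0, label=0)


class TestReadPeptideTable:
    def test_csv_with_ic50_gets_labels(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("peptide,ic50\nLLFGYPVYV,32\nAAAAKAAAA,20000\n")
        ds = mp.read_peptide_table(p)
        assert [r.label for r in ds] == [1, 0]
        assert [r.sequence for r in ds] == ["LLFGYPVYV", "AAAAKAAAA"]

    def test_fasta_unlabeled(self, tmp_path):
        p = tmp_path / "d.fasta"
        p.write_text(">pep1\nNLVPMVATV\n")
        ds = mp.read_peptide_table(p)
        assert len(ds) == 1
        assert ds[0].sequence == "NLVPMVATV" and ds[0].label is None

    def test_bad_residue_reports_row_and_char(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("peptide\nLLFGYPVYV\nLLFGXPVYV\n")
        with pytest.raises(ValueError, match=r"row 3.*'X'"):
            mp.read_peptide_table(p)

    def test_missing_peptide_column(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("seq\nLLFGYPVYV\n")
        with pytest.raises(ValueError, match="peptide"):
            mp.read_peptide_table(p)

    def test_non_numeric_and_negative_ic50_rejected(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("peptide,ic50\nLLFGYPVYV,high\n")
        with pytest.raises(ValueError, match="non-numeric"):
            mp.read_peptide_table(p)
        p.write_text("peptide,ic50\nLLFGYPVYV,-3\n")
        with pytest.raises(ValueError, match="non-positive"):
            mp.read_peptide_table(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            mp.read_peptide_table(tmp_path / "absent.csv")

    def test_length_bounds_enforced(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("peptide\nLLFGYPV\n")  # 7-mer
        with pytest.raises(ValueError, match="length"):
            mp.read_peptide_table(p)

    def test_exact_duplicates_dropped_conflicts_kept(self, tmp_path, caplog):
        p = tmp_path / "d.csv"
        p.write_text("peptide,label\nLLFGYPVYV,1\nLLFGYPVYV,1\nLLFGYPVYV,0\n")
        with caplog.at_level("WARNING"):
            ds = mp.read_peptide_table(p)
        assert len(ds) == 2  # one exact dup removed, conflict retained
        assert "conflicting" in caplog.text


class TestSplitDataset:
    def _dataset(self, n):
        rng = np.random.default_rng(3)
        recs = []
        seen = set()
        while len(recs) < n:
            s = "".join(mp.AA_ALPHABET[i] for i in rng.integers(0, 20, 9))
            if s not in seen:
                seen.add(s)
                recs.append(mp.PeptideRecord(s))
        return mp.Dataset(records=recs)

    @pytest.mark.parametrize("fraction,n_test", [(0.05, 5), (0.01, 1)])
    def test_split_sizes(self, fraction, n_test):
        ds = self._dataset(100)
        tr, te = mp.split_dataset(ds, fraction, seed=7)
        assert (len(tr), len(te)) == (100 - n_test, n_test)
        assert set(tr.sequences()) | set(te.sequences()) == set(ds.sequences())
        assert not set(tr.sequences()) & set(te.sequences())

    def test_same_seed_identical(self):
        ds = self._dataset(40)
        a = mp.split_dataset(ds, 0.1, seed=5)
        b = mp.split_dataset(ds, 0.1, seed=5)
        assert a[0].sequences() == b[0].sequences()
        assert a[1].sequences() == b[1].sequences()

    @given(st.integers(min_value=0, max_value=10_000))
    def test_partition_for_all_seeds(self, seed):
        ds = self._dataset(23)
        tr, te = mp.split_dataset(ds, 0.3, seed=seed)
        assert sorted(tr.sequences() + te.sequences()) == sorted(ds.sequences())
        assert not set(tr.sequences()) & set(te.sequences())

    def test_too_small_dataset(self):
        with pytest.raises(ValueError):
            mp.split_dataset(self._dataset(1), 0.5, seed=0)


class TestGeneratedRoundTrip:
    def test_empty_collection_header_only(self, tmp_path):
        p = tmp_path / "g.csv"
        mp.write_generated(p, [])
        assert p.read_text().strip().startswith("parent,generated,mutated_site")
        assert len(p.read_text().strip().splitlines()) == 1

    def test_single_mutant_schema(self, tmp_path):
        g = GeneratedPeptide(parent="LLFGYPVYV", generated="LLFAYPVYV",
                             mutated_site=4, parent_prob=0.9,
                             site_scores=np.arange(9, dtype=float))
        p = tmp_path / "g.csv"
        mp.write_generated(p, [g])
        row = p.read_text().strip().splitlines()[1]
        assert row.split(",")[4].count(";") == 8  # 9 semicolon-joined scores

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        gens = [
            GeneratedPeptide(parent="LLFGYPVYV", generated="LLFAYPVYV",
                             mutated_site=4, parent_prob=0.75,
                             site_scores=rng.standard_normal(9),
                             oracle_ic50=123.4),
            GeneratedPeptide(parent="NLVPMVATV", generated="NLVPMVATA",
                             mutated_site=9, parent_prob=None),
        ]
        p = tmp_path / "g.csv"
        mp.write_generated(p, gens)
        back = mp.read_generated(p)
        assert [g.parent for g in back] == [g.parent for g in gens]
        assert [g.generated for g in back] == [g.generated for g in gens]
        assert [g.mutated_site for g in back] == [4, 9]
        np.testing.assert_allclose(back[0].site_scores, gens[0].site_scores,
                                   rtol=1e-8)
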