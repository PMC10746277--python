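"""Spacer-counting contract: exact matching, discard rules, merging."""

import numpy as np
import pandas as pd
import pytest

from aeroscreen.counting import CountMatrix, count_spacers, merge_columns
from aeroscreen.simulate import revcomp


def write_fastq(path, seqs):
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")


def embed(spacer, rng, length=60, rc=False):
    bases = "ACGT"
    seq = spacer if not rc else revcomp(spacer)
    pad = length - len(seq)
    left = rng.integers(0, pad + 1)
    flank = lambda n: "".join(rng.choice(list(bases), size=n))
    return flank(left) + seq + flank(pad - left)


class TestCountSpacers:
    def test_empty_fastq_all_zero(self, toy_library, tmp_path):
        f1 = tmp_path / "e.fastq"
        f1.write_text("")
        counts, rep = count_spacers(f1, None, toy_library)
        assert (counts == 0).all()
        assert rep.n_pairs == 0

    def test_three_reads_with_one_spacer(self, toy_library, tmp_path):
        rng = np.random.default_rng(0)
        s1 = toy_library.sequence.iloc[0]
        f1 = tmp_path / "a.fastq"
        write_fastq(f1, [embed(s1, rng) for _ in range(3)])
        counts, rep = count_spacers(f1, None, toy_library)
        assert counts[toy_library.spacer_id.iloc[0]] == 3
        assert counts.sum() == 3 and rep.n_counted == 3

    def test_two_spacers_in_one_read_discarded(self, toy_library, tmp_path):
        s1, s2 = toy_library.sequence.iloc[0], toy_library.sequence.iloc[1]
        f1 = tmp_path / "a.fastq"
        write_fastq(f1, [s1 + "ACGT" + s2])
        counts, rep = count_spacers(f1, None, toy_library)
        assert counts.sum() == 0
        assert rep.n_ambiguous == 1

    def test_same_spacer_in_both_mates_counts_once(self, toy_library, tmp_path):
        rng = np.random.default_rng(1)
        s1 = toy_library.sequence.iloc[0]
        f1, f2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(f1, [embed(s1, rng)])
        write_fastq(f2, [embed(s1, rng, rc=True)])
        counts, rep = count_spacers(f1, f2, toy_library)
        assert counts[toy_library.spacer_id.iloc[0]] == 1

    def test_revcomp_searching_flag(self, toy_library, tmp_path):
        rng = np.random.default_rng(2)
        s1 = toy_library.sequence.iloc[0]
        f1 = tmp_path / "a.fastq"
        write_fastq(f1, [embed(s1, rng, rc=True)])
        with_rc, _ = count_spacers(f1, None, toy_library, search_revcomp=True)
        without, _ = count_spacers(f1, None, toy_library, search_revcomp=False)
        assert with_rc.sum() == 1 and without.sum() == 0

    def test_tally_conservation_and_permutation_invariance(self, toy_library, tmp_path):
        rng = np.random.default_rng(3)
        seqs = []
        for _ in range(200):
            r = rng.random()
            if r < 0.5:
                sp = toy_library.sequence.iloc[rng.integers(len(toy_library))]
                seqs.append(embed(sp, rng, rc=rng.random() < 0.5))
            elif r < 0.8:
                seqs.append(embed("".join(rng.choice(list("ACGT"), 20)), rng))
            else:
                s1, s2 = toy_library.sequence.iloc[:2]
                seqs.append(s1 + "AC" + s2)
        f1 = tmp_path / "a.fastq"
        write_fastq(f1, seqs)
        counts, rep = count_spacers(f1, None, toy_library)
        assert rep.n_counted + rep.n_no_match + rep.n_ambiguous == rep.n_pairs == 200
        assert counts.sum() == rep.n_counted

        perm = list(np.random.default_rng(4).permutation(seqs))
        f2 = tmp_path / "b.fastq"
        write_fastq(f2, perm)
        counts2, _ = count_spacers(f2, None, toy_library)
        pd.testing.assert_series_equal(counts, counts2)

    def test_brute_force_oracle_agreement(self, toy_library, tmp_path):
        rng = np.random.default_rng(5)
        seqs = []
        for _ in range(500):
            if rng.random() < 0.6:
                sp = toy_library.sequence.iloc[rng.integers(len(toy_library))]
                seqs.append(embed(sp, rng, rc=rng.random() < 0.5))
            else:
                seqs.append(embed("".join(rng.choice(list("ACGT"), 20)), rng))
        f1 = tmp_path / "a.fastq"
        write_fastq(f1, seqs)
        counts, _ = count_spacers(f1, None, toy_library)

        # independent brute-force scan over all (read, spacer) pairs
        oracle = dict.fromkeys(toy_library.spacer_id, 0)
        for read in seqs:
            hits = {
                sid
                for sid, sp in zip(toy_library.spacer_id, toy_library.sequence)
                if sp in read or sp in revcomp(read)
            }
            if len(hits) == 1:
                oracle[hits.pop()] += 1
        assert counts.to_dict() == oracle

    def test_duplicate_spacer_sequences_rejected(self, toy_library, tmp_path):
        dup = toy_library.copy()
        dup.loc[1, "sequence"] = dup.loc[0, "sequence"]
        f1 = tmp_path / "a.fastq"
        f1.write_text("")
        with pytest.raises(ValueError, match="duplicate"):
            count_spacers(f1, None, dup)

    def test_wrong_length_spacer_rejected(self, toy_library, tmp_path):
        bad = toy_library.copy()
        bad.loc[0, "sequence"] = "ACGT"
        f1 = tmp_path / "a.fastq"
        f1.write_text("")
        with pytest.raises(ValueError, match="20"):
            count_spacers(f1, None, bad)

    def test_mate_count_mismatch_rejected(self, toy_library, tmp_path):
        f1, f2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_fastq(f1, ["A" * 40, "C" * 40])
        write_fastq(f2, ["A" * 40])
        with pytest.raises(ValueError, match="differ"):
            count_spacers(f1, f2, toy_library)


class TestMergeColumns:
    def sheet(self, sids):
        return pd.DataFrame(
            dict(sample_id=sids, condition="aerobic", timepoint="Ti",
                 replicate=range(1, len(sids) + 1))
        )

    def test_single_column_identity(self):
        col = pd.Series({"s1": 3, "s2": 0})
        m = merge_columns({"a": col}, self.sheet(["a"]))
        assert m.counts["a"].to_dict() == {"s1": 3, "s2": 0}

    def test_disjoint_spacers_union_with_zeros(self):
        m = merge_columns(
            {"a": pd.Series({"s1": 2}), "b": pd.Series({"s2": 5})},
            self.sheet(["a", "b"]),
        )
        assert m.counts.loc["s1", "b"] == 0
        assert m.counts.loc["s2", "a"] == 0
        assert m.counts.loc["s1", "a"] == 2

    def test_column_order_invariance(self):
        cols = {"a": pd.Series({"s1": 1, "s2": 2}), "b": pd.Series({"s1": 3, "s2": 4})}
        m1 = merge_columns(cols, self.sheet(["a", "b"]))
        m2 = merge_columns(dict(reversed(list(cols.items()))), self.sheet(["a", "b"]))
        pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_missing_sample_column_rejected(self):
        with pytest.raises(ValueError, match="no count column"):
            merge_columns({"a": pd.Series({"s1": 1})}, self.sheet(["a", "b"]))


class TestCountMatrix:
    def test_duplicate_spacer_ids_rejected(self):
        counts = pd.DataFrame({"a": [1, 2]}, index=["s1", "s1"])
        with pytest.raises(ValueError, match="duplicate"):
            CountMatrix(counts, pd.DataFrame(dict(sample_id=["a"], condition=["aerobic"],
                                                  timepoint=["Ti"], replicate=[1])))

    def test_sample_missing_from_sheet_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2]}, index=["s1"])
        sheet = pd.DataFrame(dict(sample_id=["a"], condition=["aerobic"],
                                  timepoint=["Ti"], replicate=[1]))
        with pytest.raises(ValueError, match="absent"):
            CountMatrix(counts, sheet)

    def test_tsv_roundtrip(self, tmp_path):
        counts = pd.DataFrame({"a": [1, 0], "b": [2, 9]},
                              index=pd.Index(["s1", "s2"], name="spacer_id"))
        sheet = pd.DataFrame(dict(sample_id=["a", "b"], condition="aerobic",
                                  timepoint=["Ti", "Tf"], replicate=[1, 1]))
        m = CountMatrix(counts, sheet)
        m.to_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        back = CountMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(m.counts, back.counts)
        pd.testing.assert_frame_equal(m.samples, back.samples)
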