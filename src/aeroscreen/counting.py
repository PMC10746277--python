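"""Exact k-mer spacer counting in amplicon reads.

The counting contract mirrors the screen's: a read pair increments
exactly one spacer's count when exactly one library spacer occurs as an
exact 20-nt substring of either mate (each searched on both strands by
default); pairs matching zero or two-plus distinct spacers are discarded
and tallied. No trimming or fuzzy matching is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

SPACER_LEN = 20

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class CountMatrix:
    """Integer spacers x samples count matrix with its sample sheet.

    ``counts``: DataFrame indexed by spacer_id, one column per sample_id.
    ``samples``: DataFrame with columns sample_id, condition, timepoint,
    replicate (one row per matrix column).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate spacer_ids in count matrix")
        self.samples = self.samples.reset_index(drop=True)
        sheet = set(self.samples.sample_id)
        missing = [c for c in self.counts.columns if c not in sheet]
        if missing:
            raise ValueError(f"samples absent from sample sheet: {missing}")
        self.counts = self.counts.astype(np.int64)

    def sample_ids(self, condition: str | None = None, timepoint: str | None = None) -> list[str]:
        sel = self.samples
        if condition is not None:
            sel = sel[sel.condition == condition]
        if timepoint is not None:
            sel = sel[sel.timepoint == timepoint]
        return list(sel.sample_id)

    def merge(self, other: "CountMatrix") -> "CountMatrix":
        counts = self.counts.join(other.counts, how="outer").fillna(0)
        samples = pd.concat([self.samples, other.samples], ignore_index=True)
        return CountMatrix(counts, samples)

    def to_tsv(self, counts_path, samples_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t")
        return cls(counts, samples)


@dataclass
class DiscardReport:
    """Per-sample tallies of read pairs that did not contribute a count."""

    n_pairs: int = 0
    n_counted: int = 0
    n_no_match: int = 0
    n_ambiguous: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _spacer_lut(library: pd.DataFrame) -> dict[str, str]:
    seqs = library.sequence.str.upper()
    if (seqs.str.len() != SPACER_LEN).any():
        bad = library.spacer_id[seqs.str.len() != SPACER_LEN].tolist()
        raise ValueError(f"spacers not {SPACER_LEN} nt: {bad[:5]}")
    if seqs.duplicated().any():
        dups = seqs[seqs.duplicated()].tolist()
        raise ValueError(f"duplicate spacer sequences in library: {dups[:5]}")
    return dict(zip(seqs, library.spacer_id))


def _matches(seq: str, lut: dict[str, str], search_revcomp: bool) -> set[str]:
    found: set[str] = set()
    views = (seq, _revcomp(seq)) if search_revcomp else (seq,)
    for s in views:
        for i in range(len(s) - SPACER_LEN + 1):
            hit = lut.get(s[i : i + SPACER_LEN])
            if hit is not None:
                found.add(hit)
    return found


def _read_fastq(path) -> list[str]:
    out = []
    with pysam.FastxFile(str(path)) as fh:
        for i, rec in enumerate(fh):
            if rec.sequence is None:
                raise ValueError(f"{path}: malformed FASTQ record at index {i}")
            out.append(rec.sequence.upper())
    return out


def count_spacers(
    fastq1,
    fastq2=None,
    library: pd.DataFrame = None,
    search_revcomp: bool = True,
) -> tuple[pd.Series, DiscardReport]:
    """Count exact spacer occurrences in one sample's read pairs.

    Returns a counts Series indexed by spacer_id (zeros included) and a
    DiscardReport. A pair counts once per matched spacer even when the
    spacer occurs in both mates or repeatedly within a mate.
    """
    lut = _spacer_lut(library)
    reads1 = _read_fastq(fastq1)
    reads2 = _read_fastq(fastq2) if fastq2 is not None else None
    if reads2 is not None and len(reads1) != len(reads2):
        raise ValueError(
            f"mate files differ in read count: {len(reads1)} vs {len(reads2)}"
        )

    counts = dict.fromkeys(library.spacer_id, 0)
    rep = DiscardReport(n_pairs=len(reads1))
    for i, r1 in enumerate(reads1):
        found = _matches(r1, lut, search_revcomp)
        if reads2 is not None:
            found |= _matches(reads2[i], lut, search_revcomp)
        if len(found) == 1:
            counts[found.pop()] += 1
            rep.n_counted += 1
        elif not found:
            rep.n_no_match += 1
        else:
            rep.n_ambiguous += 1
    series = pd.Series(counts, name="count")
    series.index.name = "spacer_id"
    return series, rep


def merge_columns(columns: dict[str, pd.Series], samples: pd.DataFrame) -> CountMatrix:
    """Assemble per-sample count columns into a CountMatrix.

    Every sample in the sheet must have a column; spacers missing from a
    column are filled with zero.
    """
    missing = [s for s in samples.sample_id if s not in columns]
    if missing:
        raise ValueError(f"no count column for samples: {missing}")
    counts = pd.DataFrame(
        {sid: columns[sid] for sid in samples.sample_id}
    ).fillna(0)
    counts.index.name = "spacer_id"
    return CountMatrix(counts, samples)
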