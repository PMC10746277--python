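"""Readers/writers for the pipeline's on-disk formats.

Genomes travel as FASTA (Biopython), annotations as GFF3 with 1-based
inclusive ``gene`` features (gffutils for reading), everything tabular
as TSV. BED6 transcript input converts from 0-based half-open to the
1-based inclusive coordinates used internally.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(genome: str, path, name: str = "chr") -> None:
    SeqIO.write([SeqRecord(Seq(genome), id=name, description="")], str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(annotation: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.itertuples(index=False):
            attrs = f"ID={g.gene_id}"
            if "tu_id" in annotation.columns and isinstance(g.tu_id, str):
                attrs += f";tu_id={g.tu_id}"
            fh.write(
                f"{g.replicon}\taeroscreen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            dict(
                gene_id=feat.attributes.get("ID", [feat.id])[0],
                replicon=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return pd.DataFrame(rows)


def write_tu_gff3(tu_table: pd.DataFrame, path) -> None:
    """TU table as GFF3 operon features with gene children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tu in tu_table.itertuples(index=False):
            fh.write(
                f"{tu.replicon}\taeroscreen\toperon\t{tu.start}\t{tu.end}\t.\t"
                f"{tu.strand}\t.\tID={tu.tu_id}\n"
            )
            for gid in str(tu.members).split(","):
                fh.write(
                    f"{tu.replicon}\taeroscreen\tgene\t.\t.\t.\t{tu.strand}\t.\t"
                    f"ID={gid};Parent={tu.tu_id}\n"
                )


def read_transcripts(path) -> pd.DataFrame:
    """Transcript table from TSV (replicon/start/end/strand/source_label)
    or BED6 (converted to 1-based inclusive)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["replicon", "start", "end", "source_label", "score", "strand"],
        )
        return pd.DataFrame(
            dict(
                replicon=bed.replicon,
                start=bed.start + 1,
                end=bed.end,
                strand=bed.strand,
                source_label=bed.source_label,
            )
        )
    return pd.read_csv(path, sep="\t")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
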