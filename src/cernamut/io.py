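"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython, GTF through pyranges; everything tabular is
pandas TSV. All writers round-trip through the matching readers.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import FormatError


def normalize_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def read_fasta(path: str | Path, *, rna: bool = False) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` map.

    With ``rna=True`` sequences are normalized to the uppercase RNA
    alphabet (T -> U); both T and U inputs are accepted.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        out[rec.id] = normalize_rna(s) if rna else s
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, *, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_tsv(df: pd.DataFrame, path: str | Path, *, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample matrix of non-negative normalized expression values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise FormatError(f"negative expression values in {path}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_gtf_exons(path: str | Path) -> pd.DataFrame:
    """Read exon features from a GTF file.

    Returns a frame with columns transcript_id, gene_id, chrom, strand,
    start, end (1-based inclusive) and biotype, one row per exon.
    """
    import pyranges as pr

    gr = pr.read_gtf(str(path))
    df = gr.df
    df = df[df["Feature"] == "exon"].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["transcript_id", "gene_id", "chrom", "strand", "start", "end", "biotype"]
        )
    biotype_col = "gene_type" if "gene_type" in df.columns else "gene_biotype"
    if biotype_col not in df.columns:
        df["gene_type"] = "other"
        biotype_col = "gene_type"
    out = pd.DataFrame(
        {
            "transcript_id": df["transcript_id"].values,
            "gene_id": df["gene_id"].values,
            "chrom": df["Chromosome"].astype(str).values,
            "strand": df["Strand"].astype(str).values,
            # pyranges is 0-based half-open; convert back to 1-based inclusive
            "start": df["Start"].values + 1,
            "end": df["End"].values,
            "biotype": df[biotype_col].values,
        }
    )
    return out.sort_values(["transcript_id", "start"], kind="stable").reset_index(drop=True)


def write_gtf_exons(exons: pd.DataFrame, path: str | Path) -> None:
    """Write exon rows (columns as produced by :func:`read_gtf_exons`) as GTF."""
    with open(path, "w") as fh:
        for row in exons.itertuples(index=False):
            attrs = (
                f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}"; '
                f'gene_type "{row.biotype}";'
            )
            fh.write(
                f"{row.chrom}\tcernamut\texon\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


_GMT_SEP = re.compile(r"\t")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT text (name, description, members per line)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = _GMT_SEP.split(line)
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, description, >=1 member")
            members = {g for g in parts[2:] if g}
            if not members:
                raise FormatError(f"{path}:{ln}: empty gene set {parts[0]!r}")
            sets[parts[0]] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")
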