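"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats (all tab-separated unless noted, all coordinates 0-based
half-open, gzip-transparent by ``.gz`` extension):

* FASTQ with the UID carried in the read name after the final underscore
  (``@r17_ACGTAC``) — the common UMI-extraction convention.
* Read table ("SAM-like TSV"): ``read_id  chrom  pos  strand  uid
  sequence`` with a ``#``-prefixed header line.  ``pos`` is the 0-based 5'
  mapping coordinate and ``sequence`` is in reference orientation.
* Truth table TSV (simulator ground truth), consensus-read TSV.
* MAF-like mutation table (``patient_id  gene  count``) plus a gene-length
  TSV (``gene  length``).
* BED-like region file (``chrom  start  end [name]``).
* Mutation list (``chrom  pos  ref  alt``), known-SNP positions
  (``chrom  pos``).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .consensus import ConsensusRead, TaggedRead
from .panel import MutationCatalog

_READS_HEADER = "#read_id\tchrom\tpos\tstrand\tuid\tsequence"
_CONSENSUS_HEADER = "#chrom\tpos\tstrand\tuid\tfamily_size\tsequence"


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, newline="" if "w" in mode else None)


class FormatError(ValueError):
    """Malformed line in an input file (reports the line number)."""


def write_fastq(reads: Sequence[TaggedRead], path) -> None:
    """Write reads as FASTQ, UID appended to the read name as ``_UID``."""
    with _open_text(path, "wt") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}_{read.uid}\n{read.sequence}\n+\n")
            fh.write("I" * len(read.sequence) + "\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read a UID-suffixed FASTQ; returns (read_id, uid, sequence) tuples.

    FASTQ carries no mapping information, so the result is not a list of
    :class:`TaggedRead`; pair it with a read table for full records.
    """
    out = []
    with _open_text(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            name, _, uid = rec.id.rpartition("_")
            if not name:
                raise FormatError(f"read name without _UID suffix: {rec.id!r}")
            out.append((name, uid, str(rec.seq)))
    return out


def write_reads_tsv(reads: Sequence[TaggedRead], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(_READS_HEADER + "\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.pos}\t{r.strand}\t{r.uid}\t{r.sequence}\n")


def read_reads_tsv(path) -> list[TaggedRead]:
    reads = []
    with _open_text(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            read_id, chrom, pos, strand, uid, seq = parts
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad position {pos!r}") from exc
            reads.append(TaggedRead(read_id, chrom, pos_i, strand, uid, seq))
    return reads


# Back-compat aliases matching the on-disk format's historical name.
write_sam_tsv = write_reads_tsv
read_sam_tsv = read_reads_tsv


def write_consensus_tsv(consensus: Sequence[ConsensusRead], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(_CONSENSUS_HEADER + "\n")
        for c in consensus:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.strand}\t{c.uid}\t{c.family_size}\t{c.sequence}\n")


def read_consensus_tsv(path) -> list[ConsensusRead]:
    out = []
    with _open_text(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            chrom, pos, strand, uid, size, seq = parts
            out.append(ConsensusRead(chrom, int(pos), strand, uid, seq, int(size)))
    return out


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"seq_errors": str, "uid_errors": str})
    df["tumor"] = df["tumor"].astype(bool)
    return df


def read_catalog(maf_path, lengths_path) -> MutationCatalog:
    """Build a mutation catalog from a MAF-like TSV and a gene-length TSV."""
    maf = pd.read_csv(maf_path, sep="\t")
    for col in ("patient_id", "gene", "count"):
        if col not in maf.columns:
            raise FormatError(f"{maf_path}: missing column {col!r}")
    lengths = pd.read_csv(lengths_path, sep="\t")
    for col in ("gene", "length"):
        if col not in lengths.columns:
            raise FormatError(f"{lengths_path}: missing column {col!r}")
    counts = (
        maf.pivot_table(index="patient_id", columns="gene", values="count",
                        aggfunc="sum", fill_value=0)
        .astype(int)
    )
    gene_lengths = lengths.set_index("gene")["length"]
    counts = counts.reindex(columns=gene_lengths.index, fill_value=0)
    return MutationCatalog(counts=counts, gene_lengths=gene_lengths)


def write_catalog(catalog: MutationCatalog, maf_path, lengths_path) -> None:
    long = (
        catalog.counts.stack()
        .rename("count")
        .reset_index()
        .rename(columns={"level_0": "patient_id", "level_1": "gene"})
    )
    long.columns = ["patient_id", "gene", "count"]
    long = long.loc[long["count"] > 0]
    long.to_csv(maf_path, sep="\t", index=False)
    catalog.gene_lengths.rename("length").rename_axis("gene").reset_index().to_csv(
        lengths_path, sep="\t", index=False
    )


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """BED-like region file: chrom, start, end, optional name."""
    out = []
    with _open_text(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            name = parts[3] if len(parts) > 3 else f"region{lineno}"
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def read_mutations(path) -> list[tuple[str, int, str, str]]:
    """Minimal VCF-like TSV: chrom, pos (0-based), ref, alt."""
    out = []
    with _open_text(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            out.append((parts[0], int(parts[1]), parts[2], parts[3]))
    return out


def read_snp_positions(path) -> list[int]:
    """Known-SNP mask: chrom, pos per line (chrom ignored downstream)."""
    out = []
    with _open_text(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out.append(int(parts[1]))
    return out


def write_json_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
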