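"""File plumbing: count tables, ranked tables, FASTQ.

Count and ranked tables are TSV (peptide strings never need quoting there);
CSV is accepted on input via a flag. FASTQ goes through Biopython.
"""

from __future__ import annotations

import gzip
from collections import Counter
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .deconvolution import RoundCounts


class ParseError(ValueError):
    """Malformed table row, reported with its line number."""


def write_counts_table(counts: RoundCounts, path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tcount\n")
        for pep, c in sorted(counts.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{pep}\t{c}\n")


def read_counts_table(path, round_id: str | None = None,
                      sep: str = "\t") -> RoundCounts:
    """Parse a (peptide, count) table; malformed or negative rows raise
    :class:`ParseError` with the offending line number."""
    path = Path(path)
    counts: Counter = Counter()
    with open(path) as fh:
        header = fh.readline()
        if header and not header.lower().startswith("peptide"):
            raise ParseError(f"{path}:1: expected header 'peptide{sep}count'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            pep, raw = parts
            try:
                c = int(raw)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: count {raw!r} is not an integer") \
                    from None
            if c < 0:
                raise ParseError(f"{path}:{lineno}: negative count {c}")
            counts[pep] += c
    return RoundCounts(round_id=round_id or path.stem, counts=counts)


def write_ranked_table(ranked: pd.DataFrame, path) -> None:
    ranked.to_csv(path, sep="\t", index=False)


def read_ranked_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fastq(reads, path) -> None:
    """Write (read_id, sequence, quality-string) triples as FASTQ
    (gzipped if the path ends in .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path):
    """Yield read sequences (uppercase strings) from FASTQ or FASTA,
    gzipped or plain."""
    p = str(path)
    base = p[:-3] if p.endswith(".gz") else p
    fmt = "fasta" if base.endswith((".fa", ".fasta")) else "fastq"
    opener = gzip.open if p.endswith(".gz") else open
    with opener(p, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield str(rec.seq).upper()
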