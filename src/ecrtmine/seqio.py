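"""FASTA / BED input-output and small sequence utilities.

All coordinates in this package are 0-based, half-open, on the forward
strand (BED convention).  Genome records carry their assembly-gap (N-run)
annotation because gap length enters both the E-value search space and the
per-megabase density denominator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_FAMILY_RE = re.compile(r"family=(\S+)")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def n_runs(seq: str, min_run: int = 1) -> list[tuple[int, int]]:
    """Intervals of consecutive N characters of length >= ``min_run``."""
    return [
        (m.start(), m.end())
        for m in re.finditer(r"[Nn]+", seq)
        if m.end() - m.start() >= min_run
    ]


@dataclass
class GenomeRecord:
    """A named nucleotide sequence with its assembly-gap annotation."""

    id: str
    seq: str
    min_gap_run: int = 1
    gaps: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        self.gaps = n_runs(self.seq, self.min_gap_run)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gap_length(self) -> int:
        return sum(e - s for s, e in self.gaps)

    @property
    def effective_length(self) -> int:
        """Assembly length with gap bases excluded."""
        return len(self.seq) - self.gap_length


@dataclass(frozen=True)
class LibraryProtein:
    """A reference RT-domain protein with its family tag."""

    id: str
    family: str
    seq: str


def read_genomes(path: str | Path, min_gap_run: int = 1) -> list[GenomeRecord]:
    return [
        GenomeRecord(rec.id, str(rec.seq), min_gap_run=min_gap_run)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_genomes(genomes: Iterable[GenomeRecord], path: str | Path) -> None:
    recs = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    SeqIO.write(recs, str(path), "fasta")


def read_protein_library(path: str | Path) -> list[LibraryProtein]:
    """Read a labelled protein FASTA with headers ``>id family=<label>``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _FAMILY_RE.search(rec.description)
        if m is None:
            raise ValueError(f"record {rec.id!r} lacks a family=<label> tag")
        out.append(LibraryProtein(rec.id, m.group(1), str(rec.seq).upper()))
    return out


def write_protein_library(lib: Iterable[LibraryProtein], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in lib:
            fh.write(f">{p.id} family={p.family}\n{p.seq}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(
    rows: Iterable[tuple[str, int, int, str, int, str]], path: str | Path
) -> None:
    """6-column BED: chrom, start, end, name, score, strand."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
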