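"""Genome bundle: sequences plus gene models, with FASTA/GFF3 round-trip.

All in-memory coordinates are 0-based half-open. GFF3 output follows the
format's 1-based closed convention.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving ambiguous bases."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Gene:
    """A gene model with exons in genomic order (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        self.exons = sorted(self.exons)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    @property
    def tss(self) -> int:
        """Transcription start position (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """Transcription termination position (0-based)."""
        return self.end - 1 if self.strand == "+" else self.start

    def acceptor_sites(self) -> list[int]:
        """3' splice-site positions (intron ends in transcription orientation)."""
        if self.strand == "+":
            return [iv[1] for iv in self.introns]
        return [iv[0] for iv in self.introns]


@dataclass
class GenomeBundle:
    """Genome sequences keyed by chromosome plus gene models."""

    chroms: dict[str, str]
    genes: list[Gene]

    def chrom_length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); reverse-complemented when strand is '-'."""
        if chrom not in self.chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self.chroms[chrom]) or start > end:
            raise IndexError(
                f"interval [{start},{end}) out of bounds for {chrom} "
                f"(length {len(self.chroms[chrom])})"
            )
        seq = self.chroms[chrom][start:end].upper()
        return revcomp(seq) if strand == "-" else seq

    def genes_by_chrom(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def sequence_digest(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.chroms):
            h.update(name.encode())
            h.update(self.chroms[name].encode())
        return h.hexdigest()

    # ---------------------------------------------------------------- I/O

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(self.chroms[name]), id=name, description="")
            for name in sorted(self.chroms)
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    def write_gff(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name in sorted(self.chroms):
                fh.write(f"##sequence-region {name} 1 {len(self.chroms[name])}\n")
            for gene in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            "rloopscan",
                            "gene",
                            str(gene.start + 1),
                            str(gene.end),
                            ".",
                            gene.strand,
                            ".",
                            f"ID={gene.gene_id}",
                        ]
                    )
                    + "\n"
                )
                for i, (es, ee) in enumerate(gene.exons, start=1):
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                "rloopscan",
                                "exon",
                                str(es + 1),
                                str(ee),
                                ".",
                                gene.strand,
                                ".",
                                f"ID={gene.gene_id}.e{i};Parent={gene.gene_id}",
                            ]
                        )
                        + "\n"
                    )

    @classmethod
    def read(cls, fasta: str | Path, gff: str | Path) -> "GenomeBundle":
        chroms = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")
        }
        genes: dict[str, Gene] = {}
        exons: dict[str, list[tuple[int, int]]] = {}
        with open(gff) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9:
                    continue
                chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols[:9]
                attr = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                if ftype == "gene":
                    gid = attr["ID"]
                    genes[gid] = Gene(
                        gene_id=gid,
                        chrom=chrom,
                        strand=strand,
                        start=int(start) - 1,
                        end=int(end),
                    )
                elif ftype == "exon":
                    parent = attr.get("Parent", attr.get("ID", "").rsplit(".", 1)[0])
                    exons.setdefault(parent, []).append((int(start) - 1, int(end)))
        for gid, gene in genes.items():
            gene.exons = sorted(exons.get(gid, [(gene.start, gene.end)]))
        return cls(chroms=chroms, genes=list(genes.values()))


def fasta_digest(path: str | Path) -> str:
    """Digest of the sequence content of a FASTA file (ignores wrapping)."""
    h = hashlib.sha256()
    for rec in sorted(SeqIO.parse(str(path), "fasta"), key=lambda r: r.id):
        h.update(rec.id.encode())
        h.update(str(rec.seq).upper().encode())
    return h.hexdigest()


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
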