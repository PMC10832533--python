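"""Genome container and flat-file I/O.

Internally all coordinates are 0-based half-open on the forward strand;
GFF3 output/input converts to/from the 1-based inclusive convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


def feature_length(start_1based: int, end_1based: int) -> int:
    """Length in nt of a feature given printed 1-based inclusive coordinates.

    This is the convention used when reporting annotated feature spans
    (e.g. an RNA gene printed as ``120,876-121,272`` spans 397 nt).
    """
    if end_1based < start_1based:
        raise ValueError("end before start")
    return end_1based - start_1based + 1


@dataclass
class Gene:
    """A gene feature: 0-based half-open [start, end) on `strand`."""

    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def cds(self, genome_seq: str) -> str:
        """Coding sequence in reading orientation."""
        s = genome_seq[self.start : self.end]
        return s if self.strand == "+" else revcomp(s)


@dataclass
class GenomeBundle:
    """A replicon sequence plus its stranded gene annotation."""

    seq: str
    genes: list[Gene] = field(default_factory=list)
    name: str = "plasmid"
    circular: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    # ---------------------------------------------------------------- I/O

    def write_fasta(self, path) -> None:
        rec = SeqRecord(Seq(self.seq), id=self.name, description="")
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
            writer.write_file([rec])

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {self.name} 1 {len(self.seq)}\n")
            for g in self.genes:
                fh.write(
                    "\t".join(
                        [
                            self.name,
                            "plasmidtx",
                            "gene",
                            str(g.start + 1),
                            str(g.end),
                            ".",
                            g.strand,
                            ".",
                            f"ID={g.gene_id}",
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def read(cls, fasta_path, gff3_path, circular: bool = False) -> "GenomeBundle":
        rec = next(SeqIO.parse(fasta_path, "fasta"))
        genes = read_gff3_genes(gff3_path)
        return cls(seq=str(rec.seq).upper(), genes=genes, name=rec.id, circular=circular)


def read_gff3_genes(path) -> list[Gene]:
    """Read `type=gene` rows of a GFF3 file (1-based inclusive -> internal)."""
    cols = [
        "seqid", "source", "type", "start", "end",
        "score", "strand", "phase", "attributes",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    genes = []
    for row in df.itertuples():
        if row.type != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
        )
        genes.append(
            Gene(
                gene_id=attrs.get("ID", f"gene{row.Index}"),
                start=int(row.start) - 1,
                end=int(row.end),
                strand=row.strand,
            )
        )
    return genes


def gene_lengths(genes: list[Gene]) -> pd.Series:
    return pd.Series({g.gene_id: g.length for g in genes}, name="length")
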