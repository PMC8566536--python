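"""Shared on-disk formats and light genomic containers.

The pipeline exchanges data through plain-text standards: FASTA for
sequences (via Bio.SeqIO), GFF3 (1-based, inclusive; ``gene`` and ``CDS``
features) for annotation, TSV for count matrices and sample sheets, and a
VCF-convention site table for candidate RNA-editing sites (read back
through pysam).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


# ---------------------------------------------------------------------------
# sequences

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an id -> uppercase sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# annotation

@dataclass
class Gene:
    """One annotated gene. Coordinates are 1-based and inclusive.

    ``cds`` holds (start, end) intervals in genomic coordinates, sorted
    ascending regardless of strand; for minus-strand genes the coding
    order is the reverse of this list.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"gene {self.gene_id}: bad coordinates {self.start}..{self.end}")

    def coding_sequence(self, genome: dict[str, str]) -> str:
        """Spliced CDS, 5'->3' on the transcript strand."""
        contig = genome[self.contig]
        parts = [contig[s - 1:e] for s, e in sorted(self.cds)]
        seq = "".join(parts)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


class Annotation:
    """An ordered collection of genes with id lookup."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = list(genes)
        self._index: dict[str, Gene] = {}
        for g in self.genes:
            if g.gene_id in self._index:
                raise ValueError(f"duplicate gene id in annotation: {g.gene_id}")
            self._index[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __getitem__(self, gene_id: str) -> Gene:
        return self._index[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def gene_lengths(self) -> pd.Series:
        """Spliced CDS length per gene (bp), the length used for TPM."""
        out = {}
        for g in self.genes:
            if g.cds:
                out[g.gene_id] = sum(e - s + 1 for s, e in g.cds)
            else:
                out[g.gene_id] = g.end - g.start + 1
        return pd.Series(out, name="length")

    # -- GFF3 round trip ----------------------------------------------------

    def to_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for g in self.genes:
            lines.append("\t".join([
                g.contig, "quillcycle", "gene", str(g.start), str(g.end),
                ".", g.strand, ".", f"ID={g.gene_id}",
            ]))
            for i, (s, e) in enumerate(sorted(g.cds)):
                lines.append("\t".join([
                    g.contig, "quillcycle", "CDS", str(s), str(e),
                    ".", g.strand, "0", f"ID={g.gene_id}.cds{i};Parent={g.gene_id}",
                ]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gff3(cls, path: str | Path) -> "Annotation":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=GFF_COLUMNS,
            dtype={"start": int, "end": int},
        )
        genes: dict[str, Gene] = {}
        order: list[str] = []
        for row in df.itertuples(index=False):
            attrs = dict(
                kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
            )
            if row.type == "gene":
                gid = attrs["ID"]
                if gid in genes:
                    raise ValueError(f"duplicate gene id in GFF3: {gid}")
                genes[gid] = Gene(gid, row.seqid, int(row.start), int(row.end), row.strand)
                order.append(gid)
            elif row.type == "CDS":
                parent = attrs.get("Parent")
                if parent is None or parent not in genes:
                    raise ValueError(f"CDS with unknown Parent at {row.seqid}:{row.start}")
                genes[parent].cds.append((int(row.start), int(row.end)))
        for g in genes.values():
            g.cds.sort()
        return cls(genes[g] for g in order)


# ---------------------------------------------------------------------------
# count matrix + sample sheet

def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Counts TSV: rows = genes, header ``gene_id`` then sample ids."""
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_sample_sheet(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = {"zt_hour", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


def write_gene_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene_id")


def read_gene_lengths(path: str | Path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="gene_id")["length"]
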