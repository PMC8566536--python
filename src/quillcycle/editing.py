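"""Plastid RNA-editing site calling and characterization.

Candidate sites come from an upstream pileup/variant-calling step as a
VCF-convention table (one biallelic SNV per row with read depth, site
quality, a mapping-quality-bias test p-value and alt-allele read count).
Calling applies hard filters — depth >= 20, QUAL >= 20, bias p >= 0.05 —
then an alternate-allele-frequency cut at 10%.  Each passing site is
classified on the transcript strand of every overlapping gene: a genomic
C>T inside a plus-strand gene, or G>A inside a minus-strand gene, is a
C-to-U edit; T>C / A>G the (rare) U-to-C reverse; anything else "other".
Sites inside a CDS additionally get their codon and amino-acid effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io import Annotation

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SiteRecord:
    """One candidate site as read from the pileup table."""

    contig: str
    pos: int            # 1-based
    ref: str
    alt: str
    depth: int
    qual: float
    bias_p: float       # mapping-quality-bias test p-value (bcftools MQB)
    alt_count: int

    def __post_init__(self) -> None:
        if self.alt_count > self.depth:
            raise ValueError(
                f"{self.contig}:{self.pos}: alt count {self.alt_count} exceeds depth {self.depth}"
            )


@dataclass
class EditSite:
    """A site that survived all filters, with classification attached."""

    contig: str
    pos: int
    ref: str
    alt: str
    depth: int
    qual: float
    bias_p: float
    alt_count: int
    af: float
    edit_class: str            # C-to-U | U-to-C | other
    gene_id: str | None = None
    strand: str | None = None
    intergenic: bool = False
    codon_number: int | None = None
    codon_position: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    synonymous: bool | None = None


# ---------------------------------------------------------------------------
# VCF-convention IO

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=MQB,Number=1,Type=Float,Description="Mapping quality bias test p-value">
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele read count">
"""


def write_sites_vcf(records: Sequence[SiteRecord], path: str | Path,
                    contig_lengths: dict[str, int] | None = None) -> None:
    lines = [VCF_HEADER.rstrip("\n")]
    for name, length in (contig_lengths or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in sorted(records, key=lambda r: (r.contig, r.pos)):
        info = f"DP={r.depth};MQB={r.bias_p:.6g};AC={r.alt_count}"
        lines.append(
            f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:.6g}\t.\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _first(value):
    return value[0] if isinstance(value, tuple) else value


def read_sites_vcf(path: str | Path) -> list[SiteRecord]:
    """Read a site table, keeping multi-allelic/non-SNV rows for the filter
    stage to count and drop."""
    out: list[SiteRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            alt = ",".join(alts) if alts else "."
            out.append(SiteRecord(
                contig=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                depth=int(rec.info.get("DP", 0)),
                qual=float(rec.qual if rec.qual is not None else 0.0),
                bias_p=float(rec.info.get("MQB", 1.0)),
                alt_count=int(_first(rec.info.get("AC", 0))),
            ))
    return out


# ---------------------------------------------------------------------------
# calling

def filter_sites(records: Iterable[SiteRecord], min_depth: int = 20,
                 min_qual: float = 20.0, min_bias_p: float = 0.05) -> list[SiteRecord]:
    """Hard filters: keep depth >= min_depth AND qual >= min_qual AND
    bias p >= min_bias_p.  Multi-allelic and non-SNV rows are dropped
    (counted in the log), mirroring a bcftools view -v snps -m2 -M2 step.
    """
    passing: list[SiteRecord] = []
    n_nonsnv = 0
    for r in records:
        if len(r.ref) != 1 or len(r.alt) != 1 or r.ref not in "ACGT" or r.alt not in "ACGT":
            n_nonsnv += 1
            continue
        if r.depth >= min_depth and r.qual >= min_qual and r.bias_p >= min_bias_p:
            passing.append(r)
    if n_nonsnv:
        logger.info("filter_sites: dropped %d multi-allelic/non-SNV records", n_nonsnv)
    return passing


def merge_site_tables(tables: Sequence[Sequence[SiteRecord]],
                      min_samples: int = 1) -> list[SiteRecord]:
    """Merge per-sample site tables by (contig, pos, ref, alt).

    Each RNA-seq sample is called independently upstream; a site is kept
    when at least ``min_samples`` tables contain it, represented by the
    record with the highest depth (depth/qual/bias are per-sample
    quantities, so the best-supported observation stands for the site).
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    grouped: dict[tuple, list[SiteRecord]] = {}
    for table in tables:
        for r in table:
            grouped.setdefault((r.contig, r.pos, r.ref, r.alt), []).append(r)
    merged = [max(rs, key=lambda r: (r.depth, r.qual))
              for rs in grouped.values() if len(rs) >= min_samples]
    merged.sort(key=lambda r: (r.contig, r.pos, r.alt))
    return merged


def _gene_tree(annotation: Annotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    return trees


def intersect_genes(sites: Sequence[SiteRecord], annotation: Annotation
                    ) -> list[tuple[SiteRecord, str | None]]:
    """Assign each site to every gene whose 1-based inclusive interval
    covers it; sites hitting no gene yield a single (site, None) row."""
    trees = _gene_tree(annotation)
    out: list[tuple[SiteRecord, str | None]] = []
    for s in sites:
        hits = trees.get(s.contig, IntervalTree())[s.pos]
        if not hits:
            out.append((s, None))
        else:
            for iv in sorted(hits, key=lambda iv: iv.data):
                out.append((s, iv.data))
    return out


def _strand_class(ref: str, alt: str, strand: str) -> str:
    if strand == "-":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    if (ref, alt) == ("C", "T"):
        return "C-to-U"
    if (ref, alt) == ("T", "C"):
        return "U-to-C"
    return "other"


def classify_edits(passing: Sequence[SiteRecord], annotation: Annotation,
                   genome: dict[str, str], min_af: float = 0.10) -> list[EditSite]:
    """Apply the allele-frequency cut and classify each surviving site on
    the strand of every overlapping gene.

    Intergenic sites are classified on the plus strand and flagged rather
    than dropped.  Sites falling inside a CDS also receive codon-effect
    annotation.
    """
    edits: list[EditSite] = []
    for site, gene_id in intersect_genes(passing, annotation):
        if site.pos > len(genome.get(site.contig, "")):
            raise ValueError(f"site {site.contig}:{site.pos} beyond contig end")
        af = site.alt_count / site.depth if site.depth else 0.0
        if af < min_af:
            continue
        if gene_id is None:
            edits.append(EditSite(
                site.contig, site.pos, site.ref, site.alt, site.depth, site.qual,
                site.bias_p, site.alt_count, af,
                edit_class=_strand_class(site.ref, site.alt, "+"),
                intergenic=True,
            ))
            continue
        gene = annotation[gene_id]
        es = EditSite(
            site.contig, site.pos, site.ref, site.alt, site.depth, site.qual,
            site.bias_p, site.alt_count, af,
            edit_class=_strand_class(site.ref, site.alt, gene.strand),
            gene_id=gene_id, strand=gene.strand,
        )
        if any(s <= site.pos <= e for s, e in gene.cds):
            annotate_codon_effect(es, annotation, genome)
        edits.append(es)
    return edits


def annotate_codon_effect(site: EditSite, annotation: Annotation,
                          genome: dict[str, str]) -> EditSite:
    """Fill in codon number/position and the amino-acid consequence for a
    site inside the CDS of its assigned gene.  Mutates and returns `site`.
    """
    gene = annotation[site.gene_id]
    cds = sorted(gene.cds)
    # transcript-strand offset of the site within the spliced CDS, 1-based
    offset = 0
    found = False
    if gene.strand == "+":
        for s, e in cds:
            if s <= site.pos <= e:
                offset += site.pos - s + 1
                found = True
                break
            offset += e - s + 1
    else:
        for s, e in reversed(cds):
            if s <= site.pos <= e:
                offset += e - site.pos + 1
                found = True
                break
            offset += e - s + 1
    if not found:
        raise ValueError(f"site {site.contig}:{site.pos} not inside CDS of {site.gene_id}")

    cds_seq = gene.coding_sequence(genome)
    if len(cds_seq) % 3:
        logger.warning("gene %s: CDS length %d not divisible by 3; trailing partial codon skipped",
                       gene.gene_id, len(cds_seq))
    codon_number = math.ceil(offset / 3)
    codon_position = (offset - 1) % 3 + 1
    codon_start = (codon_number - 1) * 3
    ref_codon = cds_seq[codon_start:codon_start + 3]
    if len(ref_codon) < 3:
        return site  # partial trailing codon, no effect call
    alt_base = site.alt if gene.strand == "+" else _COMPLEMENT[site.alt]
    alt_codon = ref_codon[:codon_position - 1] + alt_base + ref_codon[codon_position:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    site.codon_number = codon_number
    site.codon_position = codon_position
    site.ref_codon = ref_codon
    site.alt_codon = alt_codon
    site.ref_aa = ref_aa
    site.alt_aa = alt_aa
    site.synonymous = ref_aa == alt_aa
    return site


def edits_to_frame(edits: Sequence[EditSite]):
    """Tabulate calls for the TSV output."""
    import pandas as pd

    return pd.DataFrame([vars(e) for e in edits])
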