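"""Synthetic study generator with known truth.

Everything the pipeline consumes can be generated here under a single
seed: a genome with strand-mixed, non-overlapping genes and 500-bp
upstream flanks; a diel RNA-seq count matrix (by default 10 timepoints
every 3 h over a 27-h span under 12L:12D, 3 replicates each, ~10% of
expressed genes cycling); promoters with planted cis-regulatory motifs;
plastid-style candidate RNA-editing site tables; and aligned paralog
codon pairs diverged by a chosen number of synonymous substitutions.
Every generator records its ground truth so downstream calls can be
scored for sensitivity, precision and phase accuracy.

The negative-binomial replicate-noise model is a surrogate for real
library noise, not an inference from any particular dataset; see the
methods note for what it does and does not emulate.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cre import PromoterSet
from .cycling import sinusoid_wave, spike_trace, triangle_wave
from .diel_expression import CountMatrix
from .editing import SiteRecord
from .io import Annotation, Gene, reverse_complement
from .molevo import (BASES, CODON_TABLE, FOURFOLD_PREFIXES, CodonAlignment,
                     codon_synonymous_sites, is_transversion)

SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
STOP_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa == "*")

DEFAULT_TIMEPOINTS = (1, 4, 7, 10, 13, 16, 19, 22, 25, 28)
DEFAULT_FAMILY_MIX = {"sinusoid": 0.06, "triangle": 0.02, "spike": 0.02,
                      "arrhythmic": 0.90}


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic diel study.

    ``trace_family_mix`` is a distribution over all four trace families
    (summing to 1); its non-arrhythmic mass must equal
    ``cycler_fraction``.  The same seed reproduces byte-identical
    outputs from every generator.
    """

    n_genes: int = 1000
    n_contigs: int = 5
    timepoints: tuple = DEFAULT_TIMEPOINTS
    replicates_per_timepoint: int = 3
    cycler_fraction: float = 0.10
    trace_family_mix: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_MIX))
    dispersion: float = 0.05
    library_size_range: tuple = (400_000, 600_000)
    amplitude_range: tuple = (0.6, 1.0)
    period: float = 24.0
    low_expr_fraction: float = 0.20
    low_expr_tpm: float = 0.3
    cds_codon_range: tuple = (100, 300)
    intergenic_gap: int = 600
    edge_truncated_fraction: float = 0.05
    max_contig_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        tp = list(self.timepoints)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        mix = self.trace_family_mix
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("trace_family_mix must sum to 1")
        if any(not 0 <= v <= 1 for v in mix.values()):
            raise ValueError("trace_family_mix proportions must be in [0,1]")
        if not 0 <= self.cycler_fraction <= 1:
            raise ValueError("cycler_fraction must be in [0,1]")
        if abs((1.0 - mix.get("arrhythmic", 0.0)) - self.cycler_fraction) > 1e-9:
            raise ValueError("cycler_fraction must equal the non-arrhythmic mix mass")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if any(a < 0 for a in self.amplitude_range) or self.amplitude_range[1] > 1:
            raise ValueError("amplitudes must lie in [0,1] to keep means non-negative")
        if not 0 <= self.edge_truncated_fraction <= 1:
            raise ValueError("edge_truncated_fraction must be in [0,1]")


@dataclass
class TruthTable:
    """Ground-truth records for emitted artifacts; one table per domain."""

    genes: pd.DataFrame | None = None        # placement + promoter truth
    expression: pd.DataFrame | None = None   # cycling truth per gene
    motifs: pd.DataFrame | None = None
    edits: pd.DataFrame | None = None
    pairs: pd.DataFrame | None = None

    def merged(self, other: "TruthTable") -> "TruthTable":
        out = TruthTable()
        for name in ("genes", "expression", "motifs", "edits", "pairs"):
            mine, theirs = getattr(self, name), getattr(other, name)
            setattr(out, name, theirs if theirs is not None else mine)
        return out

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("genes", "expression", "motifs", "edits", "pairs"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome + annotation

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    middle = rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
    stop = STOP_CODONS[rng.integers(0, len(STOP_CODONS))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in middle) + stop


def generate_genome_annotation(design: SyntheticDesign
                               ) -> tuple[dict[str, str], Annotation, TruthTable]:
    """Emit a genome and annotation with known gene placement.

    Genes are placed non-overlapping on both strands with >= 500 bp of
    upstream flank, except for an ``edge_truncated_fraction`` of genes
    that sit on their own short contigs with < 500 bp of upstream
    sequence, to exercise promoter clipping.
    """
    rng = np.random.default_rng([design.seed, 11])
    n_trunc = round(design.edge_truncated_fraction * design.n_genes)
    trunc_ids = set(rng.choice(design.n_genes, size=n_trunc, replace=False).tolist())

    contig_parts: dict[str, list[str]] = {}
    contig_pos: dict[str, int] = {}
    genes: list[Gene] = []
    truth_rows = []
    lo, hi = design.cds_codon_range

    for gi in range(design.n_genes):
        gene_id = f"g{gi + 1:05d}"
        n_codons = int(rng.integers(lo, hi + 1))
        cds = _random_cds(rng, n_codons)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_seq = cds if strand == "+" else reverse_complement(cds)
        if gi in trunc_ids:
            # dedicated short contig: the gene sits closer than 500 bp
            # to the edge on its promoter side
            contig = f"ctgE{gi + 1:05d}"
            short = int(rng.integers(50, 451))
            if strand == "+":
                seq = _random_seq(rng, short) + gene_seq + _random_seq(rng, 60)
                start = short + 1
            else:
                seq = _random_seq(rng, 60) + gene_seq + _random_seq(rng, short)
                start = 61
            end = start + len(gene_seq) - 1
            contig_parts[contig] = [seq]
            contig_pos[contig] = len(seq)
            promoter_len = short
        else:
            contig = f"ctg{gi % design.n_contigs + 1:03d}"
            if contig not in contig_parts:
                contig_parts[contig] = []
                contig_pos[contig] = 0
            gap = _random_seq(rng, design.intergenic_gap)
            contig_parts[contig].extend([gap, gene_seq])
            start = contig_pos[contig] + design.intergenic_gap + 1
            end = start + len(gene_seq) - 1
            contig_pos[contig] = end
            promoter_len = 500
        genes.append(Gene(gene_id, contig, start, end, strand, [(start, end)]))
        truth_rows.append((gene_id, contig, start, end, strand, len(cds),
                           gi in trunc_ids, promoter_len))

    genome: dict[str, str] = {}
    for contig in sorted(contig_parts):
        if not contig.startswith("ctgE"):
            # trailing flank so the last minus-strand gene keeps its promoter
            contig_parts[contig].append(_random_seq(rng, design.intergenic_gap))
        genome[contig] = "".join(contig_parts[contig])
        if design.max_contig_length is not None and len(genome[contig]) > design.max_contig_length:
            raise ValueError(
                f"contig {contig} needs {len(genome[contig])} bp for its genes, "
                f"exceeding max_contig_length={design.max_contig_length}"
            )

    truth = TruthTable(genes=pd.DataFrame(
        truth_rows,
        columns=["gene_id", "contig", "start", "end", "strand", "cds_length",
                 "promoter_truncated", "promoter_length"],
    ))
    return genome, Annotation(genes), truth


# ---------------------------------------------------------------------------
# diel counts

def _wave_factor(family: str, timepoints: np.ndarray, period: float,
                 phase: float) -> np.ndarray:
    if family == "sinusoid":
        return sinusoid_wave(timepoints, period, phase)
    if family == "triangle":
        return triangle_wave(timepoints, period, phase)
    if family == "spike":
        circ = np.minimum(np.abs(timepoints % 24 - phase),
                          24 - np.abs(timepoints % 24 - phase))
        at = timepoints[int(np.argmin(circ))]
        return spike_trace(timepoints, at)
    if family == "arrhythmic":
        return np.zeros_like(timepoints, dtype=float)
    raise ValueError(f"unknown trace family: {family}")


def generate_diel_counts(design: SyntheticDesign, annotation: Annotation
                         ) -> tuple[CountMatrix, TruthTable]:
    """Negative-binomial diel counts around waveform-modulated means.

    Mean trace per cycler = baseline x (1 + amplitude x waveform); counts
    scale with gene length and a per-sample library size, so TPM
    computation is exercised nontrivially.  A ``low_expr_fraction`` of
    genes is placed below 1 mean TPM to exercise the expression filter.
    """
    rng = np.random.default_rng([design.seed, 23])
    gene_ids = annotation.gene_ids
    n = len(gene_ids)
    lengths = annotation.gene_lengths().reindex(gene_ids)
    tps = np.asarray(design.timepoints, float)

    rel = rng.lognormal(mean=math.log(50), sigma=1.0, size=n)
    n_low = int(design.low_expr_fraction * n)
    low_idx = rng.choice(n, size=n_low, replace=False)
    low_mask = np.zeros(n, bool)
    low_mask[low_idx] = True
    if n_low:
        s_high = rel[~low_mask].sum()
        rel[low_mask] = (design.low_expr_tpm / 1e6) * s_high * rng.uniform(
            0.2, 1.0, size=n_low)

    n_cyclers = round(design.cycler_fraction * n)
    expressed_idx = np.flatnonzero(~low_mask)
    if n_cyclers > len(expressed_idx):
        raise ValueError("cycler_fraction exceeds the expressed-gene fraction")
    cycler_idx = rng.choice(expressed_idx, size=n_cyclers, replace=False)
    families = np.array(["arrhythmic"] * n, dtype=object)
    phases = np.full(n, np.nan)
    amplitudes = np.zeros(n)
    if n_cyclers:
        mix = {k: v for k, v in design.trace_family_mix.items()
               if k != "arrhythmic" and v > 0}
        fam_names = sorted(mix)
        fam_p = np.array([mix[f] for f in fam_names])
        families[cycler_idx] = np.array(fam_names, dtype=object)[
            rng.choice(len(fam_names), size=n_cyclers, p=fam_p / fam_p.sum())]
        phases[cycler_idx] = rng.integers(0, 24, size=n_cyclers)
        amplitudes[cycler_idx] = rng.uniform(*design.amplitude_range, size=n_cyclers)

    wave = np.zeros((n, len(tps)))
    for i in cycler_idx:
        wave[i] = _wave_factor(families[i], tps, design.period, phases[i])
    mean_trace = rel[:, None] * (1 + amplitudes[:, None] * wave)

    samples, cols = [], []
    for t in design.timepoints:
        for r in range(1, design.replicates_per_timepoint + 1):
            samples.append((f"ZT{t:02d}_r{r}", t, r))
    counts = np.zeros((n, len(samples)), dtype=np.int64)
    len_kb = lengths.values / 1000.0
    for j, (sid, t, r) in enumerate(samples):
        lib = int(rng.integers(*design.library_size_range))
        ti = list(design.timepoints).index(t)
        weight = mean_trace[:, ti] * len_kb
        mu = lib * weight / weight.sum()
        if design.dispersion <= 1e-9:
            counts[:, j] = rng.poisson(mu)
        else:
            size = 1.0 / design.dispersion
            counts[:, j] = rng.negative_binomial(size, size / (size + mu))
        cols.append(sid)

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=cols)
    design_df = pd.DataFrame(
        [(sid, t, r) for sid, t, r in samples],
        columns=["sample_id", "zt_hour", "replicate"],
    ).set_index("sample_id")
    cm = CountMatrix(counts_df, design_df, lengths)
    truth = TruthTable(expression=pd.DataFrame({
        "gene_id": gene_ids,
        "is_cycler": families != "arrhythmic",
        "family": families,
        "period_h": np.where(families != "arrhythmic", design.period, np.nan),
        "phase_zt": phases,
        "amplitude": amplitudes,
        "baseline_rel": rel,
        "low_expressed": low_mask,
    }))
    return cm, truth


# ---------------------------------------------------------------------------
# motif planting

def plant_motifs(promoters: PromoterSet, motif: str, target_genes: list[str],
                 insertion_rate: float, seed: int) -> tuple[PromoterSet, TruthTable]:
    """Overwrite ``motif`` at a uniform random offset into a seeded
    fraction of the target promoters; everything else is untouched."""
    if not 0 <= insertion_rate <= 1:
        raise ValueError("insertion_rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    seqs = dict(promoters.sequences)
    rows = []
    for gid in target_genes:
        if gid not in seqs:
            raise KeyError(f"target gene {gid} missing from promoter set")
        seq = seqs[gid]
        if len(motif) > len(seq):
            raise ValueError(f"motif longer than promoter of {gid}")
        planted = rng.random() < insertion_rate
        offset = -1
        if planted:
            offset = int(rng.integers(0, len(seq) - len(motif) + 1))
            seqs[gid] = seq[:offset] + motif + seq[offset + len(motif):]
        rows.append((gid, motif, planted, offset))
    truth = TruthTable(motifs=pd.DataFrame(
        rows, columns=["gene_id", "motif", "planted", "offset"]))
    return PromoterSet(seqs, dict(promoters.truncated)), truth


def plant_motif_in_genome(genome: dict[str, str], annotation: Annotation,
                          gene_id: str, motif: str, offset: int,
                          promoter_length: int = 500) -> dict[str, str]:
    """Write ``motif`` into the genome so that the strand-corrected
    promoter of ``gene_id`` carries it starting at ``offset`` (0-based
    from the promoter's 5' end)."""
    gene = annotation[gene_id]
    contig = genome[gene.contig]
    L = len(motif)
    if gene.strand == "+":
        p0 = gene.start - 1 - promoter_length   # 0-based promoter start
        if p0 < 0:
            raise ValueError(f"gene {gene_id}: promoter truncated, cannot plant at {offset}")
        lo = p0 + offset
        new = contig[:lo] + motif + contig[lo + L:]
    else:
        hi = gene.end + promoter_length - offset
        lo = hi - L
        if hi > len(contig):
            raise ValueError(f"gene {gene_id}: promoter truncated, cannot plant at {offset}")
        new = contig[:lo] + reverse_complement(motif) + contig[hi:]
    out = dict(genome)
    out[gene.contig] = new
    return out


# ---------------------------------------------------------------------------
# codon pairs

def _synonymous_alternatives(codon: str, pos: int) -> list[str]:
    aa = CODON_TABLE[codon]
    return [b for b in BASES
            if b != codon[pos]
            and CODON_TABLE[codon[:pos] + b + codon[pos + 1:]] == aa
            and aa != "*"]


@functools.lru_cache(maxsize=None)
def _weighted_changes(codon: str, kappa: float) -> tuple:
    """All synonymous single-base changes of one codon as
    (position, base, weight) with a kappa transition weight."""
    return tuple(
        (p, b, kappa if not is_transversion(codon[p], b) else 1.0)
        for p in range(3) for b in _synonymous_alternatives(codon, p))


def simulate_codon_pairs(n_pairs: int, n_codons: int, target_syn_subs: int,
                         seed: int, kappa: float = 2.0
                         ) -> tuple[list[CodonAlignment], TruthTable]:
    """Diverge paralog pairs by a fixed number of synonymous events.

    One sequence stays ancestral; the other accumulates
    ``target_syn_subs`` synonymous single-nucleotide substitutions at
    positions chosen uniformly among currently-eligible sites, the
    replacement base weighted ``kappa``:1 transition:transversion.
    Multiple hits at one site are allowed, so the realized pairwise
    difference can be below the event count.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    rng = np.random.default_rng(seed)
    pairs, rows = [], []
    for pi in range(n_pairs):
        pair_id = f"pair{pi + 1:04d}"
        codons = [SENSE_CODONS[i]
                  for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]
        ancestor = list(codons)
        eligible0 = [(ci, p) for ci, c in enumerate(codons) for p in range(3)
                     if _synonymous_alternatives(c, p)]
        if target_syn_subs > len(eligible0):
            raise ValueError(
                f"pair {pair_id}: {target_syn_subs} substitutions requested but only "
                f"{len(eligible0)} synonymous sites available"
            )
        n_tv_4d = 0
        # events are uniform over synonymous single-nucleotide *changes*
        # (a four-fold site draws 3x the rate of a two-fold site, the
        # same weighting NG86 uses for site counting), tilted kappa:1
        # transition:transversion; per-codon change lists are maintained
        # incrementally as the sequence mutates
        per_codon = [_weighted_changes(c, kappa) for c in codons]
        codon_wt = np.array([sum(w for *_, w in ch) for ch in per_codon])
        for _ in range(target_syn_subs):
            ci = int(rng.choice(len(codons), p=codon_wt / codon_wt.sum()))
            changes = per_codon[ci]
            w = np.array([wt for *_, wt in changes])
            p, b, _ = changes[rng.choice(len(changes), p=w / w.sum())]
            codon = codons[ci]
            if p == 2 and codon[:2] in FOURFOLD_PREFIXES and is_transversion(codon[2], b):
                n_tv_4d += 1
            codons[ci] = codon[:p] + b + codon[p + 1:]
            per_codon[ci] = _weighted_changes(codons[ci], kappa)
            codon_wt[ci] = sum(wt for *_, wt in per_codon[ci])
        seq_a, seq_b = "".join(ancestor), "".join(codons)
        pairs.append(CodonAlignment(pair_id, seq_a, seq_b))
        syn_sites = sum(codon_synonymous_sites(c) for c in ancestor)
        rows.append((pair_id, n_codons, target_syn_subs, n_tv_4d, syn_sites))
    truth = TruthTable(pairs=pd.DataFrame(
        rows, columns=["pair_id", "n_codons", "n_syn_subs",
                       "n_transversions_4d", "ancestor_syn_sites"]))
    return pairs, truth


# ---------------------------------------------------------------------------
# RNA-editing sites

def _genic_positions(genome: dict[str, str], annotation: Annotation,
                     transcript_base: str) -> list[tuple[str, int, str, str, str]]:
    """(contig, pos, ref, gene_id, strand) of genic positions whose
    transcript-strand base equals ``transcript_base``."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = []
    for gene in annotation:
        contig = genome[gene.contig]
        want = transcript_base if gene.strand == "+" else comp[transcript_base]
        for pos in range(gene.start, gene.end + 1):
            if contig[pos - 1] == want:
                out.append((gene.contig, pos, want, gene.gene_id, gene.strand))
    return out


def simulate_editing_sites(genome: dict[str, str], annotation: Annotation,
                           n_edits: int, seed: int, n_noise: int | None = None,
                           af_range: tuple = (0.15, 0.9),
                           depth_range: tuple = (25, 120),
                           utoc_fraction: float = 0.1
                           ) -> tuple[list[SiteRecord], TruthTable]:
    """Plant true edit sites that pass every filter plus noise sites that
    each fail at least one (depth, QUAL, bias p, or allele frequency).

    True edits are C-to-U on the transcript strand except a
    ``utoc_fraction`` of U-to-C sites.
    """
    rng = np.random.default_rng(seed)
    if n_noise is None:
        n_noise = n_edits // 2
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    pools = {"C-to-U": _genic_positions(genome, annotation, "C"),
             "U-to-C": _genic_positions(genome, annotation, "T")}
    n_utoc = round(utoc_fraction * n_edits)
    wanted = [("C-to-U", n_edits - n_utoc), ("U-to-C", n_utoc)]
    records, rows = [], []
    taken: set[tuple[str, int]] = set()

    def draw_site(edit_type: str):
        pool = pools[edit_type]
        if not pool:
            raise ValueError(f"no eligible positions for {edit_type} edits")
        for _ in range(10_000):
            contig, pos, want, gid, strand = pool[rng.integers(0, len(pool))]
            if (contig, pos) not in taken:
                taken.add((contig, pos))
                ref = genome[contig][pos - 1]
                # transcript C>T maps to genomic C>T (+) or G>A (-)
                t_alt = "T" if edit_type == "C-to-U" else "C"
                alt = t_alt if strand == "+" else comp[t_alt]
                return contig, pos, ref, alt, gid, strand
        raise ValueError("could not find an unused eligible position")

    for edit_type, count in wanted:
        if count > len(pools[edit_type]):
            raise ValueError(f"n_edits exceeds eligible {edit_type} positions")
        for _ in range(count):
            contig, pos, ref, alt, gid, strand = draw_site(edit_type)
            depth = int(rng.integers(max(20, depth_range[0]), depth_range[1] + 1))
            af = rng.uniform(max(af_range[0], 0.10), af_range[1])
            alt_count = max(math.ceil(0.10 * depth), round(af * depth))
            alt_count = min(alt_count, depth)
            qual = float(rng.uniform(30, 60))
            bias_p = float(rng.uniform(0.10, 1.0))
            records.append(SiteRecord(contig, pos, ref, alt, depth, qual,
                                      bias_p, alt_count))
            rows.append((contig, pos, ref, alt, gid, strand, edit_type, depth,
                         alt_count, alt_count / depth, qual, bias_p, True, "pass"))

    fail_modes = ["depth", "qual", "bias", "af"]
    for _ in range(n_noise):
        edit_type = "C-to-U" if rng.random() >= utoc_fraction else "U-to-C"
        contig, pos, ref, alt, gid, strand = draw_site(edit_type)
        mode = fail_modes[rng.integers(0, len(fail_modes))]
        depth = int(rng.integers(5, 20)) if mode == "depth" \
            else int(rng.integers(max(20, depth_range[0]), depth_range[1] + 1))
        qual = float(rng.uniform(2, 19.9)) if mode == "qual" else float(rng.uniform(30, 60))
        bias_p = float(rng.uniform(0.0, 0.049)) if mode == "bias" \
            else float(rng.uniform(0.10, 1.0))
        if mode == "af":
            alt_count = int(0.095 * depth)          # strictly below 10%
            while alt_count / depth >= 0.10 and alt_count > 0:
                alt_count -= 1
        else:
            af = rng.uniform(max(af_range[0], 0.10), af_range[1])
            alt_count = min(depth, max(math.ceil(0.10 * depth), round(af * depth)))
        records.append(SiteRecord(contig, pos, ref, alt, depth, qual, bias_p, alt_count))
        rows.append((contig, pos, ref, alt, gid, strand, edit_type, depth,
                     alt_count, alt_count / depth if depth else 0.0, qual,
                     bias_p, False, mode))

    truth = TruthTable(edits=pd.DataFrame(rows, columns=[
        "contig", "pos", "ref", "alt", "gene_id", "strand", "edit_type",
        "depth", "alt_count", "af", "qual", "bias_p", "passes", "fail_mode"]))
    records.sort(key=lambda r: (r.contig, r.pos))
    return records, truth
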