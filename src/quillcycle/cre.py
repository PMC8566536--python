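"""Phase-binned promoter k-mer enrichment and motif clustering.

Promoters (500 bp upstream of the annotated gene start, strand-corrected)
of cycling genes are split into 24 phase bins by the ZT hour of peak
expression.  Every 3–7-mer is tested per bin for over-representation
(promoter presence, one-tailed hypergeometric) against the genome-wide
promoter background, with Benjamini–Hochberg correction across all
k-mer x bin tests jointly.  Significant k-mers are clustered by ungapped
overlap similarity into motifs with IUPAC consensus strings and 24-bin
-log10(q) phase profiles, then compared against a small catalog of known
circadian cis-regulatory elements (ME, EE, CBS, G-box, TCP15, TBX).
A targeted Fisher-exact scan tests catalog motifs in CAM-gene promoters
against non-cycling-paralog backgrounds.
"""

from __future__ import annotations

import itertools
import logging
import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .cycling import CyclingCall
from .io import Annotation, reverse_complement

logger = logging.getLogger(__name__)

IUPAC_TO_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
BASES_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_TO_BASES.items()}

#: Known circadian cis-regulatory elements (consensus on the promoter strand).
KNOWN_CIRCADIAN_CRES = {
    "ME": "CCACAC",        # Morning Element
    "EE": "AAATATCT",      # Evening Element
    "CBS": "AAAAATCT",     # CCA1-binding site
    "G-box": "CACGTG",
    "TCP15": "NGGNCCCAC",  # TCP15-binding motif
    "TBX": "AAACCCT",      # Telobox
}

#: Morning-phased element recovered de novo in quillwort promoters; no
#: external transcription-factor identity is claimed for it.
UNIDENTIFIED_MORNING_CRE = "AGAATAAG"


@dataclass
class PromoterSet:
    """Strand-corrected promoter sequences (5'->3' toward the gene start)."""

    sequences: dict[str, str]
    truncated: dict[str, bool]

    def __post_init__(self) -> None:
        for gid, seq in self.sequences.items():
            if set(seq) - set("ACGTN"):
                raise ValueError(f"promoter {gid}: alphabet outside ACGTN")

    def __len__(self) -> int:
        return len(self.sequences)

    def lengths(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.sequences.items()}


@dataclass
class MotifCluster:
    members: list[str]
    consensus: str
    profile_mean: np.ndarray    # 24 bins of mean -log10(q) over members
    profile_sd: np.ndarray


# ---------------------------------------------------------------------------
# promoter extraction

def extract_promoters(genome: dict[str, str], annotation: Annotation,
                      length: int = 500) -> PromoterSet:
    """The `length` bases immediately upstream of each gene start.

    Plus strand: bases ending just before the gene start.  Minus strand:
    bases starting just after the gene end, reverse-complemented.  Clipped
    at contig edges (truncated flag); overlaps with neighbors are kept.
    """
    seqs: dict[str, str] = {}
    trunc: dict[str, bool] = {}
    for gene in annotation:
        contig = genome[gene.contig]
        if gene.end > len(contig):
            raise ValueError(f"gene {gene.gene_id} extends beyond contig {gene.contig}")
        if gene.strand == "+":
            lo = max(0, gene.start - 1 - length)
            seq = contig[lo:gene.start - 1]
        else:
            hi = min(len(contig), gene.end + length)
            seq = reverse_complement(contig[gene.end:hi])
        seqs[gene.gene_id] = seq
        trunc[gene.gene_id] = len(seq) < length
    return PromoterSet(seqs, trunc)


# ---------------------------------------------------------------------------
# k-mer enrichment

def promoter_kmers(seq: str, kmin: int, kmax: int) -> set[str]:
    """All k-mers (kmin..kmax) present in a promoter; k-mers containing N
    are skipped.  Presence, not occurrence count."""
    out: set[str] = set()
    for k in range(kmin, kmax + 1):
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if "N" not in kmer:
                out.add(kmer)
    return out


def kmer_enrichment(promoters: PromoterSet, calls: list[CyclingCall],
                    k_range: tuple[int, int] = (3, 7), fdr_alpha: float = 0.05,
                    joint_fdr: bool = True) -> tuple[pd.DataFrame, set[str]]:
    """Per-(k-mer, phase-bin) over-representation against the genome-wide
    promoter background.

    Foreground of bin b: promoters of cyclers whose phase rounds to b.
    One-tailed hypergeometric p on promoter presence, BH-adjusted across
    all tests jointly (or per bin with ``joint_fdr=False``).  A k-mer is
    cycling-associated when q < fdr_alpha in at least one bin.
    """
    kmin, kmax = k_range
    kmer_sets = {g: promoter_kmers(s, kmin, kmax) for g, s in promoters.sequences.items()}
    bg_counter: Counter = Counter()
    for s in kmer_sets.values():
        bg_counter.update(s)
    bg_size = len(kmer_sets)
    vocab = sorted(bg_counter)

    bins: dict[int, list[str]] = {}
    for c in calls:
        if not c.is_cycler:
            continue
        if c.gene_id not in kmer_sets:
            raise ValueError(f"cycler {c.gene_id} has no promoter")
        bins.setdefault(int(round(c.phase)) % 24, []).append(c.gene_id)

    frames = []
    kcount = np.array([bg_counter[k] for k in vocab])
    for b in range(24):
        genes = bins.get(b, [])
        if not genes:
            logger.info("kmer_enrichment: phase bin %d empty, skipped", b)
            continue
        fg_counter: Counter = Counter()
        for g in genes:
            fg_counter.update(kmer_sets[g])
        fg = np.array([fg_counter.get(k, 0) for k in vocab])
        p = scipy.stats.hypergeom.sf(fg - 1, bg_size, kcount, len(genes))
        frames.append(pd.DataFrame({
            "kmer": vocab, "phase_bin": b,
            "fg_count": fg, "fg_size": len(genes),
            "bg_count": kcount, "bg_size": bg_size,
            "p": p,
        }))
    if not frames:
        return pd.DataFrame(columns=["kmer", "phase_bin", "fg_count", "fg_size",
                                     "bg_count", "bg_size", "p", "q"]), set()
    tests = pd.concat(frames, ignore_index=True)
    if joint_fdr:
        tests["q"] = multipletests(tests["p"].values, method="fdr_bh")[1]
    else:
        tests["q"] = np.nan
        for b, idx in tests.groupby("phase_bin").groups.items():
            tests.loc[idx, "q"] = multipletests(tests.loc[idx, "p"].values,
                                                method="fdr_bh")[1]
    significant = set(tests.loc[tests["q"] < fdr_alpha, "kmer"])
    return tests, significant


# ---------------------------------------------------------------------------
# k-mer clustering into motifs

def _best_overlap(a: str, b: str, min_overlap: int = 4) -> tuple[float, int, int]:
    """Best ungapped overlap of b against a over all shifts.

    Returns (identity, overlap_length, shift) of the max-identity
    alignment (ties to the longer overlap, then the smaller shift).
    """
    best = (-1.0, 0, 0)
    for shift in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        lo = max(0, shift)
        hi = min(len(a), shift + len(b))
        if hi - lo < min_overlap:
            continue
        matches = sum(1 for i in range(lo, hi) if a[i] == b[i - shift])
        ident = matches / (hi - lo)
        cand = (ident, hi - lo, -abs(shift))
        if cand > (best[0], best[1], -abs(best[2])):
            best = (ident, hi - lo, shift)
    return best


def _similar(a: str, b: str, min_overlap: int = 4, min_identity: float = 0.85) -> bool:
    if a in b or b in a:
        return True
    ident, ov, _ = _best_overlap(a, b, min_overlap)
    return ov >= min_overlap and ident >= min_identity


def _consensus(members: list[str]) -> str:
    seed = max(members, key=lambda m: (len(m), [-ord(c) for c in m]))
    offsets = {}
    for m in members:
        if m == seed:
            offsets[m] = 0
        else:
            _, _, shift = _best_overlap(seed, m)
            offsets[m] = shift
    lo = min(offsets.values())
    hi = max(offsets[m] + len(m) for m in members)
    cols: list[Counter] = [Counter() for _ in range(hi - lo)]
    for m, off in offsets.items():
        for i, base in enumerate(m):
            cols[off - lo + i][base] += 1
    out = []
    for col in cols:
        if not col:
            out.append("N")
            continue
        top = max(col.values())
        winners = frozenset(b for b, c in col.items() if c == top)
        out.append(BASES_TO_IUPAC.get(winners, "N"))
    return "".join(out)


def cluster_significant_kmers(tests: pd.DataFrame, fdr_alpha: float = 0.05,
                              min_overlap: int = 4, min_identity: float = 0.85
                              ) -> list[MotifCluster]:
    """Single-linkage clustering of significant k-mers by ungapped-overlap
    similarity (identity >= 0.85 over >= 4 bp, or substring containment),
    with an IUPAC majority consensus and a 24-bin phase profile of
    -log10(q) per cluster."""
    sig = sorted(set(tests.loc[tests["q"] < fdr_alpha, "kmer"]))
    if not sig:
        return []
    parent = list(range(len(sig)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(sig)), 2):
        if _similar(sig[i], sig[j], min_overlap, min_identity):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[str]] = {}
    for i, kmer in enumerate(sig):
        groups.setdefault(find(i), []).append(kmer)

    # q per (kmer, bin); untested bins count as q = 1 (no evidence)
    qtab = tests.pivot_table(index="kmer", columns="phase_bin", values="q",
                             aggfunc="min")
    clusters = []
    for root in sorted(groups):
        members = sorted(groups[root])
        logq = np.zeros((len(members), 24))
        for i, m in enumerate(members):
            for b in range(24):
                q = qtab.at[m, b] if (m in qtab.index and b in qtab.columns) else np.nan
                if not np.isnan(q):
                    logq[i, b] = -np.log10(max(q, 1e-300))
        clusters.append(MotifCluster(
            members=members,
            consensus=_consensus(members),
            profile_mean=logq.mean(axis=0),
            profile_sd=logq.std(axis=0),
        ))
    return clusters


# ---------------------------------------------------------------------------
# catalog matching and targeted enrichment

def _iupac_match(a: str, b: str) -> bool:
    try:
        return bool(set(IUPAC_TO_BASES[a]) & set(IUPAC_TO_BASES[b]))
    except KeyError as exc:
        raise ValueError(f"malformed IUPAC letter: {exc}") from None


def match_known_cres(clusters: list[MotifCluster],
                     catalog: dict[str, str] | None = None,
                     min_overlap: int = 5, max_mismatches: int = 1
                     ) -> dict[str, list[tuple[str, int, int]]]:
    """Annotate cluster consensi with catalog CRE names.

    A cluster matches an entry when some ungapped alignment has <= 1
    IUPAC-aware mismatch over >= 5 informative positions (positions
    where neither letter is the N wildcard, so a match cannot ride on
    wildcards alone).  Returns consensus -> matches as
    (name, mismatches, informative overlap), best first.
    """
    catalog = KNOWN_CIRCADIAN_CRES if catalog is None else catalog
    if not catalog:
        raise ValueError("empty CRE catalog")
    out: dict[str, list[tuple[str, int, int]]] = {}
    for cluster in clusters:
        cons = cluster.consensus
        hits = []
        for name, motif in catalog.items():
            best = None
            for shift in range(-(len(motif) - min_overlap), len(cons) - min_overlap + 1):
                lo, hi = max(0, shift), min(len(cons), shift + len(motif))
                if hi - lo < min_overlap:
                    continue
                mm = informative = 0
                for i in range(lo, hi):
                    a, b = cons[i], motif[i - shift]
                    if not _iupac_match(a, b):
                        mm += 1
                        informative += 1
                    elif a != "N" and b != "N":
                        informative += 1
                if informative < min_overlap:
                    continue
                if mm <= max_mismatches and (best is None or (mm, -informative) < best):
                    best = (mm, -informative)
            if best is not None:
                hits.append((name, best[0], -best[1]))
        hits.sort(key=lambda h: (h[1], -h[2], h[0]))
        out[cons] = hits
    return out


def iupac_regex(motif: str) -> re.Pattern:
    try:
        return re.compile("".join(
            f"[{IUPAC_TO_BASES[c]}]" if len(IUPAC_TO_BASES[c]) > 1 else IUPAC_TO_BASES[c]
            for c in motif))
    except KeyError as exc:
        raise ValueError(f"malformed IUPAC letter: {exc}") from None


def motif_present(seq: str, motif: str, both_strands: bool = False) -> bool:
    pat = iupac_regex(motif)
    if pat.search(seq):
        return True
    return bool(both_strands and pat.search(reverse_complement(seq)))


def targeted_motif_enrichment(fg: PromoterSet, bg: PromoterSet,
                              catalog: dict[str, str] | None = None,
                              both_strands: bool = False) -> pd.DataFrame:
    """Fisher-exact over-representation of catalog motifs in foreground
    promoters (e.g. cycling CAM genes) vs a background promoter set
    (e.g. their non-cycling paralogs); BH across motifs."""
    catalog = KNOWN_CIRCADIAN_CRES if catalog is None else catalog
    if not catalog:
        raise ValueError("empty CRE catalog")
    if not len(fg) or not len(bg):
        raise ValueError("foreground and background promoter sets must be nonempty")
    rows = []
    for name, motif in sorted(catalog.items()):
        a = sum(motif_present(s, motif, both_strands) for s in fg.sequences.values())
        b = sum(motif_present(s, motif, both_strands) for s in bg.sequences.values())
        table = [[a, len(fg) - a], [b, len(bg) - b]]
        p = scipy.stats.fisher_exact(table, alternative="greater")[1]
        rows.append((name, motif, a, len(fg), b, len(bg), p))
    out = pd.DataFrame(rows, columns=["name", "motif", "fg_present", "fg_size",
                                      "bg_present", "bg_size", "p"])
    out["q"] = multipletests(out["p"].values, method="fdr_bh")[1]
    return out
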