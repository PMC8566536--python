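"""Pairwise synonymous/nonsynonymous divergence and the paranome
Ks-distribution signal of whole-genome duplication.

Ks and Ka follow Nei & Gojobori (1986): per-codon synonymous site
fractions averaged over the two sequences, difference counts averaged
with equal weight over all minimal mutational pathways for multi-hit
codons, and Jukes–Cantor correction d = -(3/4) ln(1 - (4/3) p).  The
saturation-resistant companion statistic is 4dtv — the transversion
fraction at shared four-fold degenerate third positions — with the
standard correction -(1/2) ln(1 - 2 * raw).  An ancient WGD shows up as
a peak in the Gaussian-KDE density of the clipped paranome Ks values.
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.signal
import scipy.stats
from Bio.Data.CodonTable import standard_dna_table

from .io import read_fasta, write_fasta

logger = logging.getLogger(__name__)

BASES = "ACGT"
PURINES = frozenset("AG")

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

#: Codon prefixes whose third position is four-fold degenerate.
FOURFOLD_PREFIXES = frozenset(
    p for p in ("".join(t) for t in itertools.product(BASES, repeat=2))
    if len({CODON_TABLE[p + b] for b in BASES}) == 1 and CODON_TABLE[p + "A"] != "*"
)


def is_transversion(a: str, b: str) -> bool:
    return (a in PURINES) != (b in PURINES)


@dataclass(frozen=True)
class CodonAlignment:
    """Two aligned, gap-aware coding sequences (length divisible by 3)."""

    pair_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"pair {self.pair_id}: aligned lengths differ")
        if len(self.seq_a) % 3:
            raise ValueError(f"pair {self.pair_id}: alignment length not divisible by 3")
        if set(self.seq_a + self.seq_b) - set("ACGT-"):
            raise ValueError(f"pair {self.pair_id}: alphabet outside ACGT-")

    def codons(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i:i + 3], self.seq_b[i:i + 3]


@dataclass
class CodonPairResult:
    pair_id: str
    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0
    ks: float | None = None
    ka: float | None = None
    fourfold_sites: int = 0
    fourdtv_raw: float | None = None
    fourdtv_corrected: float | None = None
    flags: list[str] = field(default_factory=list)


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; undefined for p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


@functools.lru_cache(maxsize=None)
def codon_synonymous_sites(codon: str) -> float:
    """Number of synonymous sites in a codon: at each position, the
    fraction of the 3 single-nucleotide changes that preserve the amino
    acid (changes to stop codons are not counted as synonymous)."""
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if CODON_TABLE[mut] == aa and CODON_TABLE[mut] != "*":
                s += 1 / 3
    return s


@functools.lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts for one codon pair,
    averaged with equal weight over all orderings of the single-base
    steps.  Steps through stop codons count as nonsynonymous."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    sd = nd = 0.0
    paths = list(itertools.permutations(positions))
    for path in paths:
        cur = c1
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if CODON_TABLE[nxt] == CODON_TABLE[cur] and CODON_TABLE[nxt] != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
    n = len(paths)
    return sd / n, nd / n


def ng86(pair: CodonAlignment, min_codons: int = 10) -> CodonPairResult:
    """Nei–Gojobori Ks/Ka for one aligned pair.

    Codons containing a gap in either sequence are excluded entirely;
    codons that are stops in either sequence are skipped with a log line.
    Rates are flagged undefined when the JC correction saturates.
    """
    res = CodonPairResult(pair.pair_id)
    s = n = sd = nd = 0.0
    used = 0
    for ca, cb in pair.codons():
        if "-" in ca or "-" in cb:
            continue
        if CODON_TABLE[ca] == "*" or CODON_TABLE[cb] == "*":
            logger.info("pair %s: internal stop codon skipped", pair.pair_id)
            continue
        used += 1
        s += (codon_synonymous_sites(ca) + codon_synonymous_sites(cb)) / 2
        dsd, dnd = _pathway_diffs(ca, cb)
        sd += dsd
        nd += dnd
    if used < min_codons:
        raise ValueError(
            f"pair {pair.pair_id}: only {used} ungapped codon pairs (need >= {min_codons})"
        )
    n = 3 * used - s
    res.syn_sites, res.nonsyn_sites = s, n
    res.syn_diffs, res.nonsyn_diffs = sd, nd
    ps = sd / s if s > 0 else None
    pn = nd / n if n > 0 else None
    res.ks = jukes_cantor(ps) if ps is not None else None
    res.ka = jukes_cantor(pn) if pn is not None else None
    if ps is not None and res.ks is None:
        res.flags.append("ks_saturated")
    if pn is not None and res.ka is None:
        res.flags.append("ka_saturated")
    return res


def four_dtv(pair: CodonAlignment) -> CodonPairResult:
    """Four-fold degenerate transversion rate.

    A third position qualifies when both codons are gap-free, share their
    first two bases and that prefix is four-fold degenerate.  raw = the
    transversion fraction among qualifying positions; corrected =
    -(1/2) ln(1 - 2 raw), undefined at raw >= 0.5.
    """
    res = CodonPairResult(pair.pair_id)
    qualifying = tv = 0
    for ca, cb in pair.codons():
        if "-" in ca or "-" in cb:
            continue
        if ca[:2] == cb[:2] and ca[:2] in FOURFOLD_PREFIXES:
            qualifying += 1
            if ca[2] != cb[2] and is_transversion(ca[2], cb[2]):
                tv += 1
    res.fourfold_sites = qualifying
    if qualifying == 0:
        res.flags.append("no_fourfold_sites")
        return res
    raw = tv / qualifying
    res.fourdtv_raw = raw
    if raw >= 0.5:
        res.flags.append("fourdtv_saturated")
    else:
        res.fourdtv_corrected = -0.5 * math.log(1 - 2 * raw)
    return res


def analyze_pair(pair: CodonAlignment, min_codons: int = 10) -> CodonPairResult:
    """Ks/Ka plus 4dtv in one result."""
    res = ng86(pair, min_codons=min_codons)
    tv = four_dtv(pair)
    res.fourfold_sites = tv.fourfold_sites
    res.fourdtv_raw = tv.fourdtv_raw
    res.fourdtv_corrected = tv.fourdtv_corrected
    res.flags.extend(tv.flags)
    return res


def results_to_frame(results):
    import pandas as pd

    return pd.DataFrame([{
        "pair_id": r.pair_id, "Ks": r.ks, "Ka": r.ka,
        "syn_sites": r.syn_sites, "nonsyn_sites": r.nonsyn_sites,
        "syn_diffs": r.syn_diffs, "nonsyn_diffs": r.nonsyn_diffs,
        "fourfold_sites": r.fourfold_sites,
        "fourdtv_raw": r.fourdtv_raw, "fourdtv_corrected": r.fourdtv_corrected,
        "flags": ";".join(r.flags),
    } for r in results]).set_index("pair_id")


# ---------------------------------------------------------------------------
# paranome Ks distribution

@dataclass
class KsDistribution:
    values: np.ndarray        # clipped Ks values used for the KDE
    grid: np.ndarray
    density: np.ndarray
    peaks: list[tuple[float, float]]   # (location, prominence), by prominence

    @property
    def peak_locations(self) -> list[float]:
        return [loc for loc, _ in self.peaks]


def paranome_ks_distribution(ks_values, ks_min: float = 0.05, ks_max: float = 5.0,
                             bandwidth: str | float = "silverman",
                             grid_points: int = 512,
                             min_values: int = 50,
                             prominence_fraction: float = 0.05) -> KsDistribution:
    """Gaussian KDE of the clipped paranome Ks values with peak calling.

    Values outside [ks_min, ks_max] are discarded (allelic/recent
    duplicates and saturated pairs).  Peaks are density maxima with
    prominence >= ``prominence_fraction`` of the max density, sorted by
    prominence.
    """
    vals = np.asarray([v for v in ks_values if v is not None and np.isfinite(v)], float)
    vals = vals[(vals >= ks_min) & (vals <= ks_max)]
    if len(vals) < min_values:
        raise ValueError(f"only {len(vals)} Ks values in [{ks_min}, {ks_max}] "
                         f"(need >= {min_values})")
    kde = scipy.stats.gaussian_kde(vals, bw_method=bandwidth)
    grid = np.linspace(ks_min, ks_max, grid_points)
    density = kde(grid)
    idx, props = scipy.signal.find_peaks(density,
                                         prominence=prominence_fraction * density.max())
    peaks = sorted(
        [(float(grid[i]), float(p)) for i, p in zip(idx, props["prominences"])],
        key=lambda t: -t[1],
    )
    return KsDistribution(vals, grid, density, peaks)


# ---------------------------------------------------------------------------
# paired-FASTA IO: two records per pair, ids <pair>_a / <pair>_b

def write_pair_fasta(pairs, path: str | Path) -> None:
    seqs = {}
    for p in pairs:
        seqs[f"{p.pair_id}_a"] = p.seq_a
        seqs[f"{p.pair_id}_b"] = p.seq_b
    write_fasta(seqs, path)


def read_pair_fasta(path: str | Path) -> list[CodonAlignment]:
    seqs = read_fasta(path)
    pairs: dict[str, dict[str, str]] = {}
    for name, seq in seqs.items():
        if not (name.endswith("_a") or name.endswith("_b")):
            raise ValueError(f"paired FASTA record {name!r} lacks _a/_b suffix")
        pairs.setdefault(name[:-2], {})[name[-1]] = seq
    out = []
    for pid in sorted(pairs):
        d = pairs[pid]
        if set(d) != {"a", "b"}:
            raise ValueError(f"pair {pid}: missing mate record")
        out.append(CodonAlignment(pid, d["a"], d["b"]))
    return out
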