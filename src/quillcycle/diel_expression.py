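"""Count normalization, expression filtering, outlier screening and the
per-gene regression screen for time-structured expression.

The input is a gene x sample matrix of raw counts from a Zeitgeber-time
(ZT) course — by default 10 timepoints every 3 h over 27 h under a
12 h light / 12 h dark regime, 3 replicates each.  The module provides:

* TPM, used for the >= 1 mean-TPM expressed-gene filter and downstream
  cycling detection;
* DESeq2-style median-of-ratios size factors;
* edgeR-style TMM scaling with log2-CPM output;
* classical (Torgerson) MDS with an automated replicate-outlier flag;
* a per-gene polynomial-in-ZT regression screen (maSigPro-style first
  stage): OLS F-test against the intercept-only model, significant at
  raw p < 0.001 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Raw counts with the sample design and gene lengths needed for TPM.

    counts: genes x samples, non-negative integers.
    design: indexed by sample id with columns ``zt_hour`` and ``replicate``.
    lengths: per-gene length in bp (spliced CDS length for TPM).
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("count matrix contains negative entries")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            bad = self.lengths.index[self.lengths.isna()][:5].tolist()
            raise ValueError(f"genes missing lengths, e.g. {bad}")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")

    def subset_samples(self, keep: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts[keep], self.design.loc[keep], self.lengths)


@dataclass
class ExpressionMatrix:
    """Expression values on a stated scale."""

    values: pd.DataFrame
    scale: str  # "TPM" | "median-of-ratios" | "log2-CPM" | ...

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("expression matrix contains non-finite values")


@dataclass
class OutlierReport:
    coordinates: pd.DataFrame       # samples x (dim1, dim2)
    centroid_distance: pd.Series
    flagged: pd.Series              # bool per sample
    flag_multiplier: float

    @property
    def flagged_samples(self) -> list[str]:
        return self.flagged.index[self.flagged].tolist()


# ---------------------------------------------------------------------------


def compute_tpm(cm: CountMatrix) -> ExpressionMatrix:
    """Transcripts per million: 1e6 * (count/length) / sum(count/length)."""
    lib = cm.counts.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValueError(f"zero library size in sample(s): {zero}")
    rate = cm.counts.div(cm.lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return ExpressionMatrix(tpm, "TPM")


def filter_expressed(expr: ExpressionMatrix, min_mean_tpm: float = 1.0) -> list[str]:
    """Expressed genes: mean TPM across all samples >= threshold.

    The boundary is kept: genes *below* 1 TPM are the ones considered
    not expressed.
    """
    if expr.scale != "TPM":
        raise ValueError(f"filter_expressed requires TPM scale, got {expr.scale!r}")
    mean = expr.values.mean(axis=1)
    return mean.index[mean >= min_mean_tpm].tolist()


def median_of_ratios_normalize(cm: CountMatrix) -> tuple[ExpressionMatrix, pd.Series]:
    """DESeq2 median-of-ratios size factors and normalized counts.

    Reference genes are those with nonzero counts in every sample; the
    size factor of a sample is the median over reference genes of
    count / geometric-mean-across-samples.
    """
    counts = cm.counts
    ref = (counts > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "pseudo-reference fallback is disabled"
        )
    logc = np.log(counts.loc[ref].astype(float))
    log_geomean = logc.mean(axis=1)
    ratios = logc.sub(log_geomean, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    # scale to geometric mean 1 so re-estimation is exactly idempotent
    size_factors /= np.exp(np.log(size_factors).mean())
    size_factors.name = "size_factor"
    normalized = counts.div(size_factors, axis=1)
    return ExpressionMatrix(normalized, "median-of-ratios"), size_factors


def _tmm_factor(obs: np.ndarray, ref: np.ndarray, m_trim: float, a_trim: float) -> float:
    lib_obs, lib_ref = obs.sum(), ref.sum()
    both = (obs > 0) & (ref > 0)
    o, r = obs[both].astype(float), ref[both].astype(float)
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # asymptotic (delta-method) variance of M, edgeR's precision weights
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.allclose(m, 0, atol=1e-10):
        return 1.0  # identical composition shortcut, matches edgeR
    n = len(m)
    m_lo, m_hi = np.floor(n * m_trim) + 1, n - np.floor(n * m_trim)
    a_lo, a_hi = np.floor(n * a_trim) + 1, n - np.floor(n * a_trim)
    rank_m = scipy.stats.rankdata(m)
    rank_a = scipy.stats.rankdata(a)
    keep = (rank_m >= m_lo) & (rank_m <= m_hi) & (rank_a >= a_lo) & (rank_a <= a_hi)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    return float(2 ** (np.sum(w * m[keep]) / np.sum(w)))


def cpm_tmm(cm: CountMatrix, m_trim: float = 0.30, a_trim: float = 0.05,
            prior_count: float = 0.5) -> tuple[ExpressionMatrix, pd.Series]:
    """TMM scaling factors and log2-CPM values.

    Reference sample: the one whose 75th count-fraction percentile is
    closest to the mean across samples.  Factors are normalized to a
    geometric mean of 1 and the returned matrix is
    log2(count / (lib * factor) * 1e6 + prior_count).
    """
    counts = cm.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    frac = counts.div(lib, axis=1)
    p75 = frac.apply(lambda c: np.percentile(c[c > 0], 75) if (c > 0).any() else 0.0)
    ref_sample = (p75 - p75.mean()).abs().idxmin()
    ref = counts[ref_sample].values
    factors = pd.Series(
        {s: _tmm_factor(counts[s].values, ref, m_trim, a_trim) for s in counts.columns},
        name="tmm_factor",
    )
    factors /= np.exp(np.log(factors).mean())
    eff_lib = lib * factors
    cpm = counts.div(eff_lib, axis=1) * 1e6
    return ExpressionMatrix(np.log2(cpm + prior_count), "log2-CPM"), factors


def classical_mds(dist: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson's classical scaling of a symmetric distance matrix."""
    n = dist.shape[0]
    d2 = dist ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    return coords


def mds_outlier_screen(expr: ExpressionMatrix, design: pd.DataFrame,
                       flag_multiplier: float = 3.0) -> OutlierReport:
    """Flag replicate outliers on a 2-D classical MDS embedding.

    Distances are Euclidean on log2(value + 1) (linear scales) or on the
    values directly (log scales).  A sample is flagged when its distance
    to its timepoint centroid exceeds ``flag_multiplier`` x the median of
    all centroid distances.
    """
    samples = expr.values.columns.tolist()
    if len(samples) < 3:
        raise ValueError("MDS outlier screen needs at least 3 samples")
    tp = design.loc[samples, "zt_hour"]
    if tp.value_counts().min() < 2:
        raise ValueError("every timepoint needs >= 2 replicates for the outlier screen")
    x = expr.values.values.T.astype(float)
    if not expr.scale.startswith("log"):
        x = np.log2(x + 1)
    dist = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(x))
    coords = pd.DataFrame(classical_mds(dist), index=samples, columns=["dim1", "dim2"])
    centroids = coords.groupby(tp).transform("mean")
    d = np.sqrt(((coords - centroids) ** 2).sum(axis=1))
    d.name = "centroid_distance"
    cutoff = flag_multiplier * float(d.median())
    flagged = d > cutoff + 1e-9  # epsilon guards the all-identical case
    flagged.name = "flagged"
    return OutlierReport(coords, d, flagged, flag_multiplier)


def regression_screen(expr: ExpressionMatrix, design: pd.DataFrame,
                      degree: int = 2, alpha: float = 0.001) -> pd.DataFrame:
    """Per-gene OLS of expression on a polynomial of ZT hour.

    F-test of the degree-``degree`` polynomial against the intercept-only
    model; a gene is significant at raw p < alpha (no multiple-testing
    correction).  Constant genes get F = 0, p = 1.
    """
    samples = expr.values.columns.tolist()
    t = design.loc[samples, "zt_hour"].values.astype(float)
    if len(np.unique(t)) < degree + 2:
        raise ValueError(f"need >= {degree + 2} distinct timepoints for degree {degree}")
    x = np.vander(t, degree + 1, increasing=True)
    if np.linalg.matrix_rank(x) < degree + 1:
        raise ValueError("rank-deficient polynomial design")
    y = expr.values.values.astype(float)          # genes x samples
    n = len(t)
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y.T - x @ beta
    rss = (resid ** 2).sum(axis=0)
    tss = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df1, df2 = degree, n - degree - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((tss - rss) / df1) / (rss / df2)
    p = scipy.stats.f.sf(f, df1, df2)
    const = tss <= 1e-12 * np.maximum(1.0, np.abs(y).max(axis=1))
    f = np.where(const, 0.0, f)
    p = np.where(const, 1.0, p)
    # perfect fits: RSS == 0 with structure present
    exact = (~const) & (rss <= 1e-12 * np.maximum(tss, 1e-300))
    f = np.where(exact, np.inf, f)
    p = np.where(exact, 0.0, p)
    out = pd.DataFrame({"F": f, "p": p}, index=expr.values.index)
    for k in range(degree + 1):
        out[f"coef_{k}"] = beta[k]
    out["significant"] = out["p"] < alpha
    return out
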