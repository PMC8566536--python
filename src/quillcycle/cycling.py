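"""Archetype-correlation detection of time-of-day cycling genes.

A library of archetypal diel traces — sinusoids, triangle waves (rough
linear interpolations of sinusoids) and single-timepoint spikes — is
sampled at the observed ZT hours over a grid of periods (20–28 h, 1-h
steps) and phases (0–23 h, 1-h steps).  Each gene's replicate-collapsed
trace is Pearson-correlated against every model; genes whose best
correlation exceeds R > 0.8 are called cyclers, with phase and period
taken from the best-fitting model.  The phase convention is the ZT hour
of the model's peak, mod 24 (ZT0 = lights-on).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diel_expression import ExpressionMatrix

logger = logging.getLogger(__name__)

FAMILY_ORDER = {"sinusoid": 0, "triangle": 1, "spike": 2}

#: Curated CAM-pathway role vocabulary (carboxylation/decarboxylation enzymes
#: plus regulators) used to label CAM gene sets.
CAM_PATHWAY_LABELS = frozenset({
    "beta-CA",              # beta carbonic anhydrase
    "PEPC-plant-type",      # phosphoenolpyruvate carboxylase, plant-type clade
    "PEPC-bacterial-type",  # PEPC, bacterial-type clade
    "PPCK",                 # PEPC kinase
    "MDH",                  # malate dehydrogenase
    "NADP-ME",              # NADP malic enzyme
    "PEPCK",                # PEP carboxykinase
    "PPDK",                 # pyruvate orthophosphate dikinase
})


def sinusoid_wave(t: np.ndarray, period: float, phase: float) -> np.ndarray:
    """Cosine peaking at t = phase (+ k * period), range [-1, 1]."""
    return np.cos(2 * np.pi * (np.asarray(t, float) - phase) / period)


def triangle_wave(t: np.ndarray, period: float, phase: float) -> np.ndarray:
    """Piecewise-linear wave with the same extrema as the sinusoid:
    +1 at t = phase, -1 half a period later."""
    x = np.mod(np.asarray(t, float) - phase, period) / period
    return np.where(x <= 0.5, 1 - 4 * x, 4 * x - 3)


def spike_trace(timepoints: np.ndarray, at: float) -> np.ndarray:
    """1 at the single sampled timepoint ``at``, 0 elsewhere."""
    t = np.asarray(timepoints, float)
    return (t == at).astype(float)


@dataclass(frozen=True)
class CycleModel:
    family: str
    period: float          # inf for spike models (aperiodic archetype)
    phase: float           # ZT hour of the model peak, mod 24
    trace: tuple           # values at the observation timepoints

    def sort_key(self) -> tuple:
        # deterministic tie-break: smaller period, then phase, then family
        return (self.period, self.phase, FAMILY_ORDER[self.family])


@dataclass
class CyclingCall:
    gene_id: str
    family: str | None
    period: float | None
    phase: float | None
    r: float
    is_cycler: bool


def build_model_library(timepoints, periods=range(20, 29), phases=range(0, 24),
                        families=("sinusoid", "triangle", "spike")) -> list[CycleModel]:
    """One model per (family, period, phase) for the periodic families and
    one spike model per timepoint.  Models whose sampled trace has zero
    variance are dropped (and logged).  Returned sorted by the tie-break
    key so a first-argmax scan is deterministic.
    """
    t = np.asarray(list(timepoints), float)
    if len(t) < 4:
        raise ValueError("need at least 4 timepoints")
    periods = list(periods)
    phases = list(phases)
    if ("sinusoid" in families or "triangle" in families) and (not periods or not phases):
        raise ValueError("empty period or phase grid")
    wave = {"sinusoid": sinusoid_wave, "triangle": triangle_wave}
    models: list[CycleModel] = []
    n_dropped = 0
    for family in families:
        if family == "spike":
            for at in t:
                trace = spike_trace(t, at)
                if np.ptp(trace) == 0:
                    n_dropped += 1
                    continue
                models.append(CycleModel("spike", float("inf"), float(at % 24), tuple(trace)))
        elif family in wave:
            for period in periods:
                for phase in phases:
                    trace = wave[family](t, float(period), float(phase))
                    if np.ptp(trace) < 1e-12:
                        n_dropped += 1
                        continue
                    models.append(CycleModel(family, float(period), float(phase), tuple(trace)))
        else:
            raise ValueError(f"unknown model family: {family}")
    if n_dropped:
        logger.info("build_model_library: dropped %d zero-variance models", n_dropped)
    models.sort(key=CycleModel.sort_key)
    return models


def library_to_frame(library: list[CycleModel], timepoints) -> pd.DataFrame:
    """One row per model with its trace sampled at the timepoints."""
    rows = []
    for m in library:
        row = {"family": m.family, "period": m.period, "phase": m.phase}
        row.update({f"ZT{t:g}": v for t, v in zip(timepoints, m.trace)})
        rows.append(row)
    return pd.DataFrame(rows)


def collapse_replicates(expr: ExpressionMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint mean expression, columns sorted by ZT hour."""
    tp = design.loc[expr.values.columns, "zt_hour"]
    collapsed = expr.values.T.groupby(tp.values).mean().T
    return collapsed[sorted(collapsed.columns)]


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 1e-12 * np.maximum(1.0, np.abs(x).max(axis=1))
    z = np.where(ok[:, None], (x - mu) / np.where(ok[:, None], sd, 1.0), 0.0)
    return z, ok


def classify_cycling(expr: ExpressionMatrix, design: pd.DataFrame,
                     library: list[CycleModel], r_threshold: float = 0.8,
                     collapse: bool = False) -> list[CyclingCall]:
    """Correlate every gene's trace with every archetypal model.

    By default each model trace is expanded to one value per sample
    (replicates share their timepoint's model value) and the correlation
    runs over all samples; ``collapse=True`` instead correlates
    replicate-collapsed per-timepoint means.  The per-sample default
    keeps the null distribution of the best-model R tight enough for the
    R > 0.8 call threshold to stay specific at 10 timepoints.

    Best model = first argmax of Pearson R over the tie-break-sorted
    library.  Constant genes get R = 0 and are never cyclers.
    """
    collapsed = collapse_replicates(expr, design)
    timepoints = np.asarray(collapsed.columns, float)
    if any(len(m.trace) != len(timepoints) for m in library):
        raise ValueError("model traces do not match the observed timepoints")
    m = np.array([mod.trace for mod in library], float)
    if collapse:
        y = collapsed.values.astype(float)
    else:
        samples = expr.values.columns
        zt = design.loc[samples, "zt_hour"].values.astype(float)
        tp_index = {t: i for i, t in enumerate(timepoints)}
        missing = [t for t in zt if t not in tp_index]
        if missing:
            raise ValueError(f"sample timepoint(s) {sorted(set(missing))} missing from models")
        m = m[:, [tp_index[t] for t in zt]]
        y = expr.values.values.astype(float)
    zy, gene_ok = _standardize_rows(y)
    zm, _ = _standardize_rows(m)
    r = (zy @ zm.T) / y.shape[1]             # genes x models
    library_sorted = sorted(library, key=CycleModel.sort_key)
    if library_sorted != library:
        raise ValueError("model library must be in tie-break order "
                         "(use build_model_library)")
    # ties within 1e-12 (e.g. phase-aliased traces on coarse sampling)
    # resolve to the first model in tie-break order
    best = np.argmax(r >= r.max(axis=1, keepdims=True) - 1e-12, axis=1)
    calls: list[CyclingCall] = []
    for i, gene in enumerate(collapsed.index):
        if not gene_ok[i]:
            calls.append(CyclingCall(gene, None, None, None, 0.0, False))
            continue
        b = library_sorted[best[i]]
        rb = float(np.clip(r[i, best[i]], -1.0, 1.0))
        calls.append(CyclingCall(gene, b.family, b.period, b.phase, rb, rb > r_threshold))
    return calls


def calls_to_frame(calls: list[CyclingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.family, c.period, c.phase, c.r, c.is_cycler) for c in calls],
        columns=["gene_id", "family", "period", "phase", "R", "is_cycler"],
    ).set_index("gene_id")


def cycling_summary(calls: list[CyclingCall], n_expressed: int | None = None) -> dict:
    """Counts, cycler fraction and a 1-h phase histogram over [0, 24)."""
    if not calls:
        raise ValueError("no cycling calls to summarize")
    cyclers = [c for c in calls if c.is_cycler]
    denom = n_expressed if n_expressed is not None else len(calls)
    hist = {h: 0 for h in range(24)}
    for c in cyclers:
        hist[int(c.phase) % 24] += 1
    return {
        "n_genes": len(calls),
        "n_cyclers": len(cyclers),
        "cycler_fraction": len(cyclers) / denom if denom else 0.0,
        "phase_histogram": hist if cyclers else {},
    }


@dataclass
class CamGeneSet:
    """Curated CAM-pathway homologs: gene id -> pathway label."""

    members: dict[str, str]

    def __post_init__(self) -> None:
        bad = set(self.members.values()) - CAM_PATHWAY_LABELS
        if bad:
            raise ValueError(f"unknown CAM pathway label(s): {sorted(bad)}")


def identify_cam_cycling_genes(calls: list[CyclingCall], cam_set: CamGeneSet
                               ) -> tuple[pd.DataFrame, list[str]]:
    """CAM-associated genes: curated homologs that also cycle.

    Returns the annotated intersection plus a warnings list for curated
    ids absent from the call set (never silently dropped).
    """
    by_gene = {c.gene_id: c for c in calls}
    rows, warnings = [], []
    for gene_id, label in sorted(cam_set.members.items()):
        call = by_gene.get(gene_id)
        if call is None:
            warnings.append(f"CAM gene {gene_id} ({label}) absent from cycling calls")
            continue
        if call.is_cycler:
            rows.append((gene_id, label, call.family, call.period, call.phase, call.r))
    for w in warnings:
        logger.warning(w)
    table = pd.DataFrame(
        rows, columns=["gene_id", "label", "family", "period", "phase", "R"]
    ).set_index("gene_id")
    return table, warnings
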