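"""End-to-end orchestration: TOML config, staged execution, manifest.

A run executes the toggled stages in order — simulate, normalize,
screen, cycling, cre, editing, molevo — under one global seed that fans
out to per-stage seeds by fixed offsets, so any stage can be re-run in
isolation reproducibly.  The resolved configuration and a manifest
(parameters, input checksums, per-stage outputs) are written beside the
outputs; identical config and inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from pathlib import Path

import pandas as pd

from . import __version__
from . import cre, cycling, diel_expression, editing, io, molevo, synthdata

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "screen", "cycling", "cre", "editing", "molevo")

# per-stage seed offsets (stable contract; keep derived seeds < 2**31)
SEED_OFFSETS = {"simulate": 0, "editing_sim": 101, "pairs_sim": 202}

_DESIGN_KEYS = {f.name for f in dataclasses.fields(synthdata.SyntheticDesign)} - {"seed"}

ALLOWED_KEYS: dict[str, set] = {
    "run": {"outdir", "seed", "stages"},
    "simulate": _DESIGN_KEYS | {"n_edits", "n_noise", "n_pairs", "n_codons",
                                "target_syn_subs", "kappa"},
    "normalize": {"flag_multiplier", "drop_outliers"},
    "screen": {"alpha", "degree"},
    "cycling": {"r_threshold", "min_mean_tpm", "families"},
    "cre": {"kmin", "kmax", "fdr_alpha", "promoter_length", "joint_fdr"},
    "editing": {"min_depth", "min_qual", "min_bias_p", "min_af"},
    "molevo": {"ks_min", "ks_max"},
}


class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    def __init__(self, data: dict):
        for section, values in data.items():
            if section not in ALLOWED_KEYS:
                raise ValueError(f"unknown config section: {section!r}")
            if not isinstance(values, dict):
                raise ValueError(f"config section {section!r} must be a table")
            unknown = set(values) - ALLOWED_KEYS[section]
            if unknown:
                raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
        self.data = data
        run = data.get("run", {})
        self.outdir = Path(run.get("outdir", "quillcycle_run"))
        self.seed = int(run.get("seed", 0))
        self.stages = tuple(run.get("stages", STAGES))
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            return cls(tomllib.load(fh))

    def section(self, name: str) -> dict:
        return dict(self.data.get(name, {}))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "config": config.data}
    _write_json(config.data, out / "resolved_config.json")

    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("[%s] starting", stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, out)
        except Exception as exc:
            logger.error("[%s] failed: %s", stage, exc)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": sorted(str(p.relative_to(out)) for p in outputs),
            "checksums": {str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)},
        }
        logger.info("[%s] done (%d outputs)", stage, len(outputs))

    _write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    opts = config.section("simulate")
    sim_extra = {k: opts.pop(k) for k in ("n_edits", "n_noise", "n_pairs", "n_codons",
                                          "target_syn_subs", "kappa") if k in opts}
    if "trace_family_mix" in opts:
        opts["trace_family_mix"] = dict(opts["trace_family_mix"])
    for tup_key in ("timepoints", "library_size_range", "amplitude_range",
                    "cds_codon_range"):
        if tup_key in opts:
            opts[tup_key] = tuple(opts[tup_key])
    design = synthdata.SyntheticDesign(seed=config.seed + SEED_OFFSETS["simulate"], **opts)

    genome, annotation, truth_g = synthdata.generate_genome_annotation(design)
    counts, truth_e = synthdata.generate_diel_counts(design, annotation)
    records, truth_ed = synthdata.simulate_editing_sites(
        genome, annotation,
        n_edits=int(sim_extra.get("n_edits", 30)),
        n_noise=sim_extra.get("n_noise"),
        seed=config.seed + SEED_OFFSETS["editing_sim"])
    pairs, truth_p = synthdata.simulate_codon_pairs(
        n_pairs=int(sim_extra.get("n_pairs", 80)),
        n_codons=int(sim_extra.get("n_codons", 150)),
        target_syn_subs=int(sim_extra.get("target_syn_subs", 60)),
        kappa=float(sim_extra.get("kappa", 2.0)),
        seed=config.seed + SEED_OFFSETS["pairs_sim"])

    io.write_fasta(genome, out / "genome.fasta")
    annotation.to_gff3(out / "annotation.gff3")
    io.write_counts(counts.counts, out / "counts.tsv")
    io.write_sample_sheet(counts.design, out / "samples.tsv")
    io.write_gene_lengths(counts.lengths, out / "gene_lengths.tsv")
    editing.write_sites_vcf(records, out / "sites.vcf",
                            {c: len(s) for c, s in genome.items()})
    molevo.write_pair_fasta(pairs, out / "pairs.fasta")
    truth = truth_g.merged(truth_e).merged(truth_ed).merged(truth_p)
    truth.to_dir(out / "truth")
    files = [out / n for n in ("genome.fasta", "annotation.gff3", "counts.tsv",
                               "samples.tsv", "gene_lengths.tsv", "sites.vcf",
                               "pairs.fasta")]
    files += sorted((out / "truth").glob("truth_*.tsv"))
    return files


def _load_counts(out: Path) -> diel_expression.CountMatrix:
    return diel_expression.CountMatrix(
        io.read_counts(out / "counts.tsv"),
        io.read_sample_sheet(out / "samples.tsv"),
        io.read_gene_lengths(out / "gene_lengths.tsv"),
    )


def _stage_normalize(config: PipelineConfig, out: Path) -> list[Path]:
    opts = config.section("normalize")
    cm = _load_counts(out)
    tpm = diel_expression.compute_tpm(cm)
    normalized, size_factors = diel_expression.median_of_ratios_normalize(cm)
    report = diel_expression.mds_outlier_screen(
        tpm, cm.design, flag_multiplier=float(opts.get("flag_multiplier", 3.0)))
    kept = [s for s in tpm.values.columns if s not in set(report.flagged_samples)] \
        if opts.get("drop_outliers", False) else list(tpm.values.columns)
    tpm.values[kept].to_csv(out / "tpm.tsv", sep="\t", index_label="gene_id")
    size_factors.to_csv(out / "size_factors.tsv", sep="\t", index_label="sample_id")
    rep = report.coordinates.copy()
    rep["centroid_distance"] = report.centroid_distance
    rep["flagged"] = report.flagged
    rep.to_csv(out / "mds_outliers.tsv", sep="\t", index_label="sample_id")
    return [out / "tpm.tsv", out / "size_factors.tsv", out / "mds_outliers.tsv"]


def _stage_screen(config: PipelineConfig, out: Path) -> list[Path]:
    opts = config.section("screen")
    design = io.read_sample_sheet(out / "samples.tsv")
    tpm = diel_expression.ExpressionMatrix(
        pd.read_csv(out / "tpm.tsv", sep="\t", index_col="gene_id"), "TPM")
    res = diel_expression.regression_screen(
        tpm, design, degree=int(opts.get("degree", 2)),
        alpha=float(opts.get("alpha", 0.001)))
    res.to_csv(out / "regression_screen.tsv", sep="\t", index_label="gene_id")
    return [out / "regression_screen.tsv"]


def _stage_cycling(config: PipelineConfig, out: Path) -> list[Path]:
    opts = config.section("cycling")
    design = io.read_sample_sheet(out / "samples.tsv")
    tpm = diel_expression.ExpressionMatrix(
        pd.read_csv(out / "tpm.tsv", sep="\t", index_col="gene_id"), "TPM")
    expressed = diel_expression.filter_expressed(
        tpm, min_mean_tpm=float(opts.get("min_mean_tpm", 1.0)))
    expr = diel_expression.ExpressionMatrix(tpm.values.loc[expressed], "TPM")
    families = tuple(opts.get("families", ("sinusoid", "triangle", "spike")))
    timepoints = sorted(design.loc[expr.values.columns, "zt_hour"].unique())
    library = cycling.build_model_library(timepoints, families=families)
    cycling.library_to_frame(library, timepoints).to_csv(
        out / "model_library.tsv", sep="\t", index=False)
    calls = cycling.classify_cycling(expr, design, library,
                                     r_threshold=float(opts.get("r_threshold", 0.8)))
    cycling.calls_to_frame(calls).to_csv(out / "cycling_calls.tsv", sep="\t")
    summary = cycling.cycling_summary(calls, n_expressed=len(expressed))
    summary["n_expressed"] = len(expressed)
    _write_json(summary, out / "cycling_summary.json")
    return [out / "model_library.tsv", out / "cycling_calls.tsv",
            out / "cycling_summary.json"]


def _stage_cre(config: PipelineConfig, out: Path) -> list[Path]:
    opts = config.section("cre")
    genome = io.read_fasta(out / "genome.fasta")
    annotation = io.Annotation.from_gff3(out / "annotation.gff3")
    promoters = cre.extract_promoters(genome, annotation,
                                      length=int(opts.get("promoter_length", 500)))
    io.write_fasta(promoters.sequences, out / "promoters.fasta")
    calls_df = pd.read_csv(out / "cycling_calls.tsv", sep="\t", index_col="gene_id")
    calls = [cycling.CyclingCall(g, r.family, r.period, r.phase, r.R, bool(r.is_cycler))
             for g, r in calls_df.iterrows()]
    tests, significant = cre.kmer_enrichment(
        promoters, calls,
        k_range=(int(opts.get("kmin", 3)), int(opts.get("kmax", 7))),
        fdr_alpha=float(opts.get("fdr_alpha", 0.05)),
        joint_fdr=bool(opts.get("joint_fdr", True)))
    tests[tests["q"] < 0.25].to_csv(out / "kmer_tests.tsv", sep="\t", index=False)
    clusters = cre.cluster_significant_kmers(tests,
                                             fdr_alpha=float(opts.get("fdr_alpha", 0.05)))
    matches = cre.match_known_cres(clusters) if clusters else {}
    _write_json([{
        "members": c.members, "consensus": c.consensus,
        "profile_mean": [round(v, 6) for v in c.profile_mean],
        "profile_sd": [round(v, 6) for v in c.profile_sd],
        "known_cre_matches": matches.get(c.consensus, []),
    } for c in clusters], out / "motif_clusters.json")
    return [out / "promoters.fasta", out / "kmer_tests.tsv", out / "motif_clusters.json"]


def _stage_editing(config: PipelineConfig, out: Path) -> list[Path]:
    opts = config.section("editing")
    genome = io.read_fasta(out / "genome.fasta")
    annotation = io.Annotation.from_gff3(out / "annotation.gff3")
    records = editing.read_sites_vcf(out / "sites.vcf")
    passing = editing.filter_sites(records,
                                   min_depth=int(opts.get("min_depth", 20)),
                                   min_qual=float(opts.get("min_qual", 20)),
                                   min_bias_p=float(opts.get("min_bias_p", 0.05)))
    edits = editing.classify_edits(passing, annotation, genome,
                                   min_af=float(opts.get("min_af", 0.10)))
    editing.edits_to_frame(edits).to_csv(out / "edit_sites.tsv", sep="\t", index=False)
    return [out / "edit_sites.tsv"]


def _stage_molevo(config: PipelineConfig, out: Path) -> list[Path]:
    opts = config.section("molevo")
    pairs = molevo.read_pair_fasta(out / "pairs.fasta")
    results = [molevo.analyze_pair(p) for p in pairs]
    molevo.results_to_frame(results).to_csv(out / "ks_table.tsv", sep="\t")
    dist = molevo.paranome_ks_distribution(
        [r.ks for r in results],
        ks_min=float(opts.get("ks_min", 0.05)), ks_max=float(opts.get("ks_max", 5.0)))
    _write_json({
        "n_values": int(len(dist.values)),
        "grid": [round(float(x), 6) for x in dist.grid],
        "density": [round(float(x), 6) for x in dist.density],
        "peaks": [[round(loc, 4), round(prom, 6)] for loc, prom in dist.peaks],
    }, out / "ks_distribution.json")
    return [out / "ks_table.tsv", out / "ks_distribution.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "screen": _stage_screen,
    "cycling": _stage_cycling,
    "cre": _stage_cre,
    "editing": _stage_editing,
    "molevo": _stage_molevo,
}
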