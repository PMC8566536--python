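"""Generator truth-consistency, determinism and parameter checks."""

import numpy as np
import pytest

from quillcycle import cre, io, molevo, synthdata
from quillcycle.synthdata import SyntheticDesign


class TestDesignValidation:
    def test_defaults_are_consistent(self):
        SyntheticDesign()

    @pytest.mark.parametrize("kwargs", [
        dict(timepoints=(4, 1, 7)),
        dict(trace_family_mix={"sinusoid": 0.5, "arrhythmic": 0.2}),
        dict(cycler_fraction=0.5),     # inconsistent with default mix
        dict(period=-1.0),
        dict(amplitude_range=(0.5, 1.5)),
        dict(n_genes=0),
    ])
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticDesign(**kwargs)


class TestGenomeAnnotation:
    def test_seed_determinism_bytes(self, tmp_path):
        d = SyntheticDesign(n_genes=30, n_contigs=2, seed=7)
        outs = []
        for run in ("a", "b"):
            genome, ann, _ = synthdata.generate_genome_annotation(d)
            io.write_fasta(genome, tmp_path / f"{run}.fa")
            ann.to_gff3(tmp_path / f"{run}.gff3")
            outs.append(((tmp_path / f"{run}.fa").read_bytes(),
                         (tmp_path / f"{run}.gff3").read_bytes()))
        assert outs[0] == outs[1]

    def test_both_strands_emitted(self, tmp_path):
        d = SyntheticDesign(n_genes=100, n_contigs=4, seed=1)
        _, ann, _ = synthdata.generate_genome_annotation(d)
        ann.to_gff3(tmp_path / "x.gff3")
        strands = {line.split("\t")[6] for line in
                   (tmp_path / "x.gff3").read_text().splitlines()
                   if "\tgene\t" in line}
        assert strands == {"+", "-"}

    def test_no_truncation_gives_full_promoters(self):
        d = SyntheticDesign(n_genes=40, n_contigs=2, edge_truncated_fraction=0.0, seed=3)
        genome, ann, _ = synthdata.generate_genome_annotation(d)
        promoters = cre.extract_promoters(genome, ann)
        assert all(len(s) == 500 for s in promoters.sequences.values())
        assert not any(promoters.truncated.values())

    def test_truncated_fraction_has_short_promoters(self, small_genome):
        genome, ann, truth = small_genome
        promoters = cre.extract_promoters(genome, ann)
        tg = truth.genes.set_index("gene_id")
        for gid, is_trunc in tg["promoter_truncated"].items():
            assert promoters.truncated[gid] == is_trunc
            assert len(promoters.sequences[gid]) == tg.loc[gid, "promoter_length"]

    def test_genes_do_not_overlap_within_contig(self, small_genome):
        _, ann, _ = small_genome
        by_contig = {}
        for g in ann:
            by_contig.setdefault(g.contig, []).append((g.start, g.end))
        for spans in by_contig.values():
            spans.sort()
            assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))

    def test_contig_capacity_error(self):
        d = SyntheticDesign(n_genes=50, n_contigs=1, max_contig_length=5000, seed=0)
        with pytest.raises(ValueError, match="max_contig_length"):
            synthdata.generate_genome_annotation(d)


class TestDielCounts:
    def test_truth_covers_every_gene(self, sinusoid_study):
        _, counts, truth = sinusoid_study
        assert set(truth.expression["gene_id"]) == set(counts.counts.index)

    def test_noiseless_sinusoid_peaks_at_nearest_sample(self):
        d = SyntheticDesign(
            n_genes=20, n_contigs=2, cycler_fraction=1.0,
            trace_family_mix={"sinusoid": 1.0}, dispersion=0.0,
            amplitude_range=(0.9, 1.0), low_expr_fraction=0.0,
            edge_truncated_fraction=0.0, seed=5)
        _, ann, _ = synthdata.generate_genome_annotation(d)
        cm, truth = synthdata.generate_diel_counts(d, ann)
        te = truth.expression.set_index("gene_id")
        # phase 6 cycler means must peak at the ZT7 samples (nearest to 6)
        tp = cm.design["zt_hour"]
        means = cm.counts.T.groupby(tp.values).mean().T
        for gid, row in te[te["phase_zt"] == 6.0].iterrows():
            trace = means.loc[gid]
            peak = trace.idxmax() % 24
            assert peak == 7

    def test_near_zero_dispersion_gives_poisson_variance(self):
        d = SyntheticDesign(
            n_genes=400, n_contigs=3, cycler_fraction=0.0,
            trace_family_mix={"arrhythmic": 1.0}, dispersion=0.0,
            replicates_per_timepoint=3, low_expr_fraction=0.0,
            library_size_range=(500_000, 500_001),   # fixed depth isolates NB noise
            edge_truncated_fraction=0.0, seed=9)
        _, ann, _ = synthdata.generate_genome_annotation(d)
        cm, _ = synthdata.generate_diel_counts(d, ann)
        x = cm.counts.values.astype(float)
        # flat genes: all 30 samples share (nearly) one mean, so the
        # variance/mean ratio pooled across genes should sit near 1
        ratio = np.median(x.var(axis=1, ddof=1) / np.maximum(x.mean(axis=1), 1e-9))
        assert 0.8 < ratio < 1.3

    def test_overdispersion_exceeds_poisson(self):
        d = SyntheticDesign(
            n_genes=400, n_contigs=3, cycler_fraction=0.0,
            trace_family_mix={"arrhythmic": 1.0}, dispersion=0.2,
            library_size_range=(500_000, 500_001),
            low_expr_fraction=0.0, edge_truncated_fraction=0.0, seed=9)
        _, ann, _ = synthdata.generate_genome_annotation(d)
        cm, _ = synthdata.generate_diel_counts(d, ann)
        x = cm.counts.values.astype(float)
        ratio = np.median(x.var(axis=1, ddof=1) / np.maximum(x.mean(axis=1), 1e-9))
        assert ratio > 2.0


class TestPlantMotifs:
    def _promoters(self, rng, n=100):
        bases = np.array(list("ACGT"))
        seqs = {f"g{i:03d}": "".join(bases[rng.integers(0, 4, 200)]) for i in range(n)}
        return cre.PromoterSet(seqs, {k: False for k in seqs})

    def test_rate_one_plants_everywhere(self, rng):
        proms = self._promoters(rng, 50)
        out, truth = synthdata.plant_motifs(proms, "AAATATCT", list(proms.sequences),
                                            1.0, seed=1)
        assert all("AAATATCT" in s for s in out.sequences.values())
        assert truth.motifs["planted"].all()

    def test_rate_zero_is_identity(self, rng):
        proms = self._promoters(rng, 20)
        out, truth = synthdata.plant_motifs(proms, "CACGTG", list(proms.sequences),
                                            0.0, seed=1)
        assert out.sequences == proms.sequences
        assert not truth.motifs["planted"].any()

    def test_seeded_partial_rate_reproducible(self, rng):
        proms = self._promoters(rng, 100)
        out1, t1 = synthdata.plant_motifs(proms, "CCACAC", list(proms.sequences), 0.8, seed=4)
        out2, t2 = synthdata.plant_motifs(proms, "CCACAC", list(proms.sequences), 0.8, seed=4)
        assert out1.sequences == out2.sequences
        assert t1.motifs.equals(t2.motifs)
        n = t1.motifs["planted"].sum()
        assert 60 <= n <= 95  # seeded binomial draw around 80

    def test_missing_target_gene_raises(self, rng):
        proms = self._promoters(rng, 5)
        with pytest.raises(KeyError, match="missing"):
            synthdata.plant_motifs(proms, "ACGT", ["nope"], 1.0, seed=0)

    def test_truth_offsets_point_at_motif(self, rng):
        proms = self._promoters(rng, 40)
        out, truth = synthdata.plant_motifs(proms, "AGAATAAG", list(proms.sequences),
                                            1.0, seed=2)
        for _, row in truth.motifs.iterrows():
            seq = out.sequences[row.gene_id]
            assert seq[row.offset:row.offset + 8] == "AGAATAAG"


class TestCodonPairs:
    def test_zero_substitutions_identity(self):
        pairs, _ = synthdata.simulate_codon_pairs(3, 50, 0, seed=1)
        for p in pairs:
            assert p.seq_a == p.seq_b
            assert molevo.ng86(p).ks == 0.0

    def test_single_substitution_single_codon_mismatch(self):
        pairs, truth = synthdata.simulate_codon_pairs(5, 100, 1, seed=2)
        for p in pairs:
            mismatched = sum(ca != cb for ca, cb in p.codons())
            assert mismatched == 1
        assert (truth.pairs["n_syn_subs"] == 1).all()

    def test_excess_substitutions_rejected(self):
        with pytest.raises(ValueError, match="available"):
            synthdata.simulate_codon_pairs(1, 10, 500, seed=3)

    def test_truth_has_one_row_per_pair(self):
        pairs, truth = synthdata.simulate_codon_pairs(7, 30, 5, seed=4)
        assert list(truth.pairs["pair_id"]) == [p.pair_id for p in pairs]


class TestEditingSites:
    def test_seed_determinism_bytes(self, small_genome, tmp_path):
        genome, ann, _ = small_genome
        for run in ("a", "b"):
            recs, _ = synthdata.simulate_editing_sites(genome, ann, 20, seed=6)
            from quillcycle.editing import write_sites_vcf
            write_sites_vcf(recs, tmp_path / f"{run}.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_planted_truth_flags_thresholds(self, small_genome):
        genome, ann, _ = small_genome
        _, truth = synthdata.simulate_editing_sites(genome, ann, 25, seed=8)
        te = truth.edits
        passing = te[te["passes"]]
        assert (passing["depth"] >= 20).all()
        assert (passing["qual"] >= 20).all()
        assert (passing["bias_p"] >= 0.05).all()
        assert (passing["af"] >= 0.10).all()
        failing = te[~te["passes"]]
        assert len(failing) > 0
        below = ((failing["depth"] < 20) | (failing["qual"] < 20)
                 | (failing["bias_p"] < 0.05) | (failing["af"] < 0.10))
        assert below.all()

    def test_too_many_edits_rejected(self, small_genome):
        genome, ann, _ = small_genome
        with pytest.raises(ValueError):
            synthdata.simulate_editing_sites(genome, ann, 10 ** 7, seed=1)
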