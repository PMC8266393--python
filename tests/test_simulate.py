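import re

import numpy as np
import pandas as pd
import pytest

from spikequant.rnaseq import (
    ExpressionTable,
    average_replicates,
    class_summary,
    log2_change,
    normalize_counts,
    replicate_cv,
)
from spikequant.annotation import classify_tata, filter_detectable
from spikequant.simulate import (
    ClassEffect,
    ElongationSpec,
    SimulationConfig,
    SimulationError,
    simulate_annotation,
    simulate_counts,
    simulate_tracks,
)


def run_rnaseq_pipeline(counts, metas, genes):
    tbl = normalize_counts(ExpressionTable(counts), metas)
    detectable = filter_detectable(counts, genes)
    tbl = ExpressionTable(tbl.values.loc[detectable], state="normalized")
    avg = average_replicates(tbl, metas)
    lfc = log2_change(avg.values["IAA"], avg.values["DMSO"])
    labels = pd.Series({g.gene_id: g.class_label for g in genes})
    return lfc, class_summary(lfc, labels), tbl


class TestSimulateAnnotation:
    def test_empty_simulation(self):
        genes, genome = simulate_annotation(SimulationConfig(n_genes=0, seed=1))
        assert genes == [] and len(genome) == 1

    def test_seed_determinism_bit_identical(self):
        cfg = SimulationConfig(n_genes=40, seed=9)
        g1, seq1 = simulate_annotation(cfg)
        g2, seq2 = simulate_annotation(SimulationConfig(n_genes=40, seed=9))
        assert seq1 == seq2
        assert [(g.gene_id, g.start, g.end, g.strand, g.tss, g.class_label, g.tata)
                for g in g1] == [
            (g.gene_id, g.start, g.end, g.strand, g.tss, g.class_label, g.tata)
            for g in g2
        ]

    def test_genes_do_not_overlap(self):
        genes, _ = simulate_annotation(SimulationConfig(n_genes=100, seed=2))
        for a, b in zip(genes, genes[1:]):
            assert a.end < b.start

    def test_tata_fraction_one_plants_motif_everywhere(self):
        cfg = SimulationConfig(
            n_genes=60, seed=3,
            tata_fraction_per_class={"TFIID": 1.0, "CR": 1.0},
        )
        genes, genome = simulate_annotation(cfg)
        from spikequant.annotation import reverse_complement
        motif = re.compile("TATA[AT]A[AT]")
        for g in genes:
            if g.strand == "+":
                window = genome[g.chrom][g.tss - 200:g.tss]
            else:
                window = reverse_complement(genome[g.chrom][g.tss:g.tss + 200])
            assert motif.search(window), g.gene_id

    def test_planted_flags_recoverable_by_classifier(self):
        cfg = SimulationConfig(n_genes=120, seed=5)
        genes, genome = simulate_annotation(cfg)
        truth = {g.gene_id: g.tata for g in genes}
        for g in genes:
            g.tata = None
        classify_tata(genes, genome)
        assert {g.gene_id: g.tata for g in genes} == truth

    def test_chrom_length_too_small_raises(self):
        with pytest.raises(SimulationError, match="too small"):
            simulate_annotation(SimulationConfig(n_genes=50, chrom_length=1000, seed=1))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(SimulationError):
            SimulationConfig(class_fractions={"TFIID": 0.7, "CR": 0.7}).validate()


class TestSimulateCounts:
    def test_zero_noise_limit_identical_columns(self):
        cfg = SimulationConfig(
            n_genes=30, n_replicates=3, replicate_cv=0.0, nb_dispersion=0.0, seed=6,
            effect_spec={"TFIID": ClassEffect(0, 0), "CR": ClassEffect(0, 0)},
        )
        genes, _ = simulate_annotation(cfg)
        counts, metas, _ = simulate_counts(cfg, genes)
        dmso = [m.sample_id for m in metas if m.condition == "DMSO"]
        for col in dmso[1:]:
            assert (counts[col] == counts[dmso[0]]).all()

    def test_zero_replicates_rejected(self):
        cfg = SimulationConfig(n_genes=5, n_replicates=0, seed=1)
        genes, _ = simulate_annotation(cfg)
        with pytest.raises(SimulationError):
            simulate_counts(cfg, genes)

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_genes=25, seed=8)
        genes, _ = simulate_annotation(cfg)
        c1, m1, t1 = simulate_counts(cfg, genes)
        c2, m2, t2 = simulate_counts(cfg, genes)
        pd.testing.assert_frame_equal(c1, c2)
        assert [m.spike_reads for m in m1] == [m.spike_reads for m in m2]
        pd.testing.assert_series_equal(t1.true_log2fc, t2.true_log2fc)

    def test_spike_totals_near_design_ratio(self):
        cfg = SimulationConfig(n_genes=500, seed=10)
        genes, _ = simulate_annotation(cfg)
        _, metas, _ = simulate_counts(cfg, genes)
        dmso = [m for m in metas if m.condition == "DMSO"]
        for m in dmso:
            assert m.spike_reads / m.experimental_reads == pytest.approx(0.125, rel=0.1)

    def test_null_effect_recovers_zero_median(self):
        cfg = SimulationConfig(
            n_genes=2000, n_replicates=3, seed=12,
            effect_spec={"TFIID": ClassEffect(0, 0.2), "CR": ClassEffect(0, 0.2)},
        )
        genes, _ = simulate_annotation(cfg)
        counts, metas, _ = simulate_counts(cfg, genes)
        _, summary, _ = run_rnaseq_pipeline(counts, metas, genes)
        for cls in summary.index:
            assert abs(summary.loc[cls, "median_log2fc"]) < 0.1

    def test_depth_scaling_leaves_normalized_quantities_unchanged(self):
        base = SimulationConfig(
            n_genes=400, n_replicates=2, replicate_cv=0.0, nb_dispersion=0.0, seed=14,
        )
        scaled = SimulationConfig(
            n_genes=400, n_replicates=2, replicate_cv=0.0, nb_dispersion=0.0, seed=14,
            base_depth=2 * 450 * 400,
        )
        genes, _ = simulate_annotation(base)
        c1, m1, _ = simulate_counts(base, genes)
        c2, m2, _ = simulate_counts(scaled, genes)
        n1 = normalize_counts(ExpressionTable(c1), m1).values
        n2 = normalize_counts(ExpressionTable(c2), m2).values
        # deterministic counts: doubling expected depth leaves normalized
        # signal unchanged up to the rounding of integer reads (half a
        # normalized read unit ~ 0.5 * scale / spike_reads)
        unit = 10_000 / min(m.spike_reads for m in m1 + m2)
        np.testing.assert_allclose(n1.to_numpy(), n2.to_numpy(), rtol=0.02, atol=unit)

    def test_replicate_cv_recovered(self):
        cfg = SimulationConfig(n_genes=1500, n_replicates=3, replicate_cv=0.2, seed=16)
        genes, _ = simulate_annotation(cfg)
        counts, metas, _ = simulate_counts(cfg, genes)
        _, _, tbl = run_rnaseq_pipeline(counts, metas, genes)
        _, summary = replicate_cv(tbl, metas)
        assert 0.15 <= summary["median_cv_overall"] <= 0.25


class TestSimulateTracks:
    def test_seed_determinism(self):
        cfg = SimulationConfig(n_genes=20, n_replicates=2, seed=21)
        genes, _ = simulate_annotation(cfg)
        t1, m1, tr1 = simulate_tracks(cfg, genes, kind="promoter")
        t2, m2, tr2 = simulate_tracks(cfg, genes, kind="promoter")
        assert tr1.true_bound == tr2.true_bound
        assert tr1.true_summits == tr2.true_summits
        k = ("ip", "DMSO", 1)
        np.testing.assert_array_equal(t1[k].dense(cfg.chrom), t2[k].dense(cfg.chrom))

    def test_summits_inside_promoter_windows(self):
        from spikequant.annotation import promoter_window
        cfg = SimulationConfig(n_genes=80, seed=22)
        genes, _ = simulate_annotation(cfg)
        _, _, truth = simulate_tracks(cfg, genes, kind="promoter")
        windows = {g.gene_id: promoter_window(g) for g in genes}
        for gid, s in truth.true_summits.items():
            w = windows[gid]
            assert w.start <= s < w.end

    def test_unknown_kind_rejected(self):
        cfg = SimulationConfig(n_genes=2, seed=1)
        genes, _ = simulate_annotation(cfg)
        with pytest.raises(SimulationError):
            simulate_tracks(cfg, genes, kind="atac")

    def test_five_prime_shift_raises_traveling_ratio(self):
        from spikequant.coverage import normalize_chip
        from spikequant.elongation import traveling_ratio_table
        cfg = SimulationConfig(
            n_genes=150, n_replicates=1, seed=23,
            effect_spec={"TFIID": ClassEffect(0, 0), "CR": ClassEffect(0, 0)},
            elongation_spec=ElongationSpec(shift_coef=0.0, uniform_strength=1.0,
                                           shift_fraction=0.5),
        )
        genes, _ = simulate_annotation(cfg)
        tracks, metas, truth = simulate_tracks(cfg, genes, kind="polii")
        mb = {m.sample_id: m for m in metas}
        def norm(role, cond):
            return normalize_chip(
                tracks[(role, cond, 1)], mb[f"polii_{role}_{cond}_rep1"],
                mb[f"polii_input_{cond}_rep1"],
            )
        tr = traveling_ratio_table(norm("ip", "DMSO"), norm("ip", "IAA"), genes)
        shifted = truth.true_tr_shift[truth.true_tr_shift > 0].index
        unshifted = truth.true_tr_shift[truth.true_tr_shift == 0].index
        mean_shifted = tr.loc[tr.index.intersection(shifted), "log2_tr_change"].mean()
        mean_unshifted = tr.loc[tr.index.intersection(unshifted), "log2_tr_change"].mean()
        assert mean_shifted > mean_unshifted
        assert mean_shifted > 0.2
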