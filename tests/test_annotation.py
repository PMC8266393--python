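import re

import numpy as np
import pandas as pd
import pytest

from spikequant.annotation import (
    AnnotationError,
    GeneModel,
    assign_tss,
    classify_tata,
    filter_detectable,
    load_genes,
    promoter_window,
    write_genes_gff3,
    write_genes_tsv,
)
from spikequant.simulate import SimulationConfig, simulate_annotation


def _toy_genes():
    return [
        GeneModel("GA", "chrI", "+", 1000, 2000, 1100, tss=1000, pas=2000),
        GeneModel("GB", "chrI", "-", 3000, 4000, 3900, tss=4000, pas=3000,
                  biotype="dubious"),
        GeneModel("GC", "chrII", "+", 500, 1500, 600, tss=500, pas=1500),
    ]


class TestLoadGenes:
    def test_excluded_biotypes_removed(self, tmp_path):
        write_genes_tsv(_toy_genes(), tmp_path / "genes.tsv")
        genes = load_genes(tmp_path / "genes.tsv")
        assert [g.gene_id for g in genes] == ["GA", "GC"]

    def test_empty_file(self, tmp_path):
        (tmp_path / "empty.tsv").write_text(
            "gene_id\tchrom\tstrand\tstart\tend\tcds_start\ttss\tpas\tclass\tbiotype\n"
        )
        assert load_genes(tmp_path / "empty.tsv") == []

    def test_tsv_and_gff3_give_identical_models(self, tmp_path):
        cfg = SimulationConfig(n_genes=10, seed=4)
        genes, _ = simulate_annotation(cfg)
        write_genes_tsv(genes, tmp_path / "g.tsv")
        write_genes_gff3(genes, tmp_path / "g.gff3")
        from_tsv = load_genes(tmp_path / "g.tsv")
        from_gff = load_genes(tmp_path / "g.gff3")
        assert len(from_tsv) == len(from_gff) == 10
        for a, b in zip(from_tsv, from_gff):
            for attr in ("gene_id", "chrom", "strand", "start", "end",
                         "cds_start", "tss", "pas", "biotype", "class_label"):
                assert getattr(a, attr) == getattr(b, attr), attr

    def test_malformed_coordinates_name_the_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "gene_id\tchrom\tstrand\tstart\tend\tcds_start\ttss\tpas\tclass\tbiotype\n"
            "GX\tchrI\t+\toops\t200\t100\t\t\tunassigned\tverified\n"
        )
        with pytest.raises(AnnotationError, match="line 1"):
            load_genes(p)


class TestAssignTss:
    def test_fallback_plus_strand(self):
        g = GeneModel("G", "chrI", "+", 900, 2000, cds_start=1000)
        assign_tss([g], {})
        assert g.tss == 900 and g.tss_fallback

    def test_fallback_minus_strand(self):
        g = GeneModel("G", "chrI", "-", 200, 1100, cds_start=1000)
        assign_tss([g], {})
        assert g.tss == 1100 and g.tss_fallback

    def test_table_passthrough(self):
        g = GeneModel("G", "chrI", "+", 840, 2000, cds_start=1000)
        assign_tss([g], {"G": 850})
        assert g.tss == 850 and not g.tss_fallback

    def test_wrong_chromosome_rejected_with_fallback(self):
        g = GeneModel("G", "chrI", "+", 890, 2000, cds_start=1000)
        table = pd.DataFrame({"gene_id": ["G"], "tss": [850], "chrom": ["chrII"]})
        assign_tss([g], table)
        assert g.tss == 900 and g.tss_fallback

    def test_idempotent_composition(self):
        genes = [GeneModel("G", "chrI", "+", 900, 2000, cds_start=1000)]
        assign_tss(genes, {})
        first = genes[0].tss
        assign_tss(genes, {})
        assert genes[0].tss == first


class TestPromoterWindow:
    def test_plus_strand_default(self, plus_gene):
        w = promoter_window(plus_gene)
        assert (w.start, w.end) == (4700, 5100) and not w.clipped

    def test_minus_strand_mirror(self, minus_gene):
        w = promoter_window(minus_gene)
        assert (w.start, w.end) == (4900, 5300) and not w.clipped

    def test_clipping_at_chromosome_start(self):
        g = GeneModel("G", "chrI", "+", 100, 1200, cds_start=200, tss=100, pas=1200)
        w = promoter_window(g)
        assert (w.start, w.end) == (0, 200) and w.clipped

    def test_mirrored_windows_have_equal_length(self, plus_gene, minus_gene):
        wp = promoter_window(plus_gene)
        wm = promoter_window(minus_gene)
        assert wp.end - wp.start == wm.end - wm.start == 400
        # offsets mirror: + extends 300 left of tss, - extends 300 right
        assert plus_gene.tss - wp.start == wm.end - minus_gene.tss == 300

    def test_missing_tss_is_contract_violation(self):
        g = GeneModel("G", "chrI", "+", 100, 1200, cds_start=200)
        with pytest.raises(AnnotationError):
            promoter_window(g)


class TestClassifyTata:
    def test_consensus_match(self):
        g = GeneModel("G", "chrI", "+", 200, 900, cds_start=300, tss=200, pas=900)
        genome = {"chrI": "G" * 100 + "TATATAA" + "G" * 93 + "C" * 900}
        classify_tata([g], genome)
        assert g.tata is True

    def test_gc_window_is_negative(self):
        g = GeneModel("G", "chrI", "+", 200, 900, cds_start=300, tss=200, pas=900)
        classify_tata([g], {"chrI": "GC" * 600})
        assert g.tata is False

    def test_invariant_to_sequence_outside_window(self):
        g = GeneModel("G", "chrI", "+", 300, 900, cds_start=400, tss=300, pas=900)
        inside = "G" * 100 + "TATAAAA" + "G" * 93
        for outside in ("A" * 100, "TATATAT" + "C" * 93):
            genome = {"chrI": outside + inside + "TATATAA" + "C" * 593}
            classify_tata([g], genome)
            assert g.tata is True

    def test_matches_independent_regex_scan(self, rng):
        n = 200
        motif = re.compile("TATA[AT]A[AT]")
        genes, seqs = [], []
        genome_parts = []
        pos = 0
        for i in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            genome_parts.append(seq)
            strand = "+" if i % 2 == 0 else "-"
            tss = pos + 200 if strand == "+" else pos
            # footprint is irrelevant to the scan; keep it legal
            genes.append(
                GeneModel(f"g{i}", "chrI", strand, pos, pos + 200,
                          cds_start=pos + 100, tss=tss, pas=pos if strand == "-" else pos + 200)
            )
            seqs.append((seq, strand))
            pos += 200
        genome = {"chrI": "".join(genome_parts)}
        classify_tata(genes, genome)
        from spikequant.annotation import reverse_complement
        for g, (seq, strand) in zip(genes, seqs):
            window = seq if strand == "+" else reverse_complement(seq)
            assert g.tata == bool(motif.search(window)), g.gene_id


def test_fasta_reader_feeds_classifier_like_a_dict(tmp_path):
    """Indexed FASTA access gives the same TATA flags as in-memory strings."""
    from spikequant.annotation import load_genome
    from spikequant.simulate import SimulationConfig, simulate_annotation, write_genome_fasta

    cfg = SimulationConfig(n_genes=30, seed=6)
    genes, genome = simulate_annotation(cfg)
    write_genome_fasta(genome, tmp_path / "g.fa")
    truth = {g.gene_id: g.tata for g in genes}
    for g in genes:
        g.tata = None
    classify_tata(genes, load_genome(tmp_path / "g.fa"))
    assert {g.gene_id: g.tata for g in genes} == truth


class TestFilterDetectable:
    def test_single_zero_sample_removes_gene(self):
        counts = pd.DataFrame(
            {"s1": [5, 0, 2], "s2": [1, 3, 4]}, index=["a", "b", "c"]
        )
        assert filter_detectable(counts, ["a", "b", "c"]) == ["a", "c"]

    def test_all_positive_matrix_fully_retained(self):
        counts = pd.DataFrame(np.ones((3, 4)), index=list("abc"))
        assert filter_detectable(counts, list("abc")) == list("abc")

    def test_matches_brute_force_scan(self, rng):
        counts = pd.DataFrame(
            rng.poisson(1.2, size=(100, 10)),
            index=[f"g{i}" for i in range(100)],
        )
        expected = [g for g in counts.index if all(counts.loc[g] > 0)]
        assert filter_detectable(counts, list(counts.index)) == expected

    def test_reference_list_intersection(self):
        counts = pd.DataFrame({"s": [1, 2, 3]}, index=["a", "b", "c"])
        assert filter_detectable(counts, ["a", "b", "c"], reference_genes=["b", "c", "zz"]) == ["b", "c"]

    def test_unannotated_genes_dropped(self):
        counts = pd.DataFrame({"s": [1, 2]}, index=["a", "ghost"])
        assert filter_detectable(counts, ["a"]) == ["a"]
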