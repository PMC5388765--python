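"""Synthetic-data generator: planted structure, file validity, reproducibility."""

import io

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO

from phenolnet.colocation import GenomicFeature, parse_features
from phenolnet.gcn import load_expression
from phenolnet.mirna import ScoringScheme, score_duplex
from phenolnet.motifs import Motif, scan_motif
from phenolnet.simulate import (
    GenomeSpec,
    PlantedModule,
    SimulationDesign,
    default_genome_spec,
    round_half_up,
    simulate_expression,
    simulate_genome,
    simulate_mirna_pairs,
    simulate_promoters,
)

from .conftest import colocation_oracle


class TestSimulateExpression:
    def test_sample_count_is_design_product(self):
        d = SimulationDesign(n_cultivars=5, n_stages=4, replicates_per_cell=1,
                             modules=[], n_background=3)
        m = simulate_expression(d)
        assert len(m.sample_ids) == 20
        assert m.sample_ids[0] == "cultivar1_stage1_rep1"

    def test_identical_noiseless_profiles_correlate_exactly(self):
        d = SimulationDesign(
            modules=[PlantedModule("m", ["g1", "g2"], "ripening_up")], noise_sd=0.0
        )
        m = simulate_expression(d)
        r = np.corrcoef(m.data.loc["g1"], m.data.loc["g2"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_opposite_signs_give_exact_anticorrelation(self):
        d = SimulationDesign(
            modules=[PlantedModule("m", ["g1", "g2"], "ripening_up", signs=[1, -1])],
            noise_sd=0.0,
        )
        m = simulate_expression(d)
        r = np.corrcoef(m.data.loc["g1"], m.data.loc["g2"])[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_overlapping_module_genes_rejected_naming_duplicate(self):
        with pytest.raises(ValueError, match="gA"):
            SimulationDesign(
                modules=[
                    PlantedModule("m1", ["gA", "gB"]),
                    PlantedModule("m2", ["gA"]),
                ]
            )

    def test_within_module_r_target_met_without_noise(self):
        d = SimulationDesign(
            n_cultivars=5, n_stages=4, replicates_per_cell=3,
            modules=[PlantedModule("m", ["g1", "g2", "g3"], within_module_r=0.7)],
            noise_sd=0.0, seed=11,
        )
        m = simulate_expression(d)
        x = m.data.values
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(x[i], x[j])[0, 1]
                assert abs(r) >= 0.7 - 0.1

    def test_background_genes_uncorrelated_on_average(self):
        d = SimulationDesign(n_background=30, noise_sd=0.0, seed=5,
                             replicates_per_cell=2)
        m = simulate_expression(d)
        corr = np.corrcoef(m.data.values)
        off = corr[np.triu_indices(30, k=1)]
        assert abs(off.mean()) < 0.1

    def test_abundances_nonnegative_and_roundtrip(self, tmp_path):
        d = SimulationDesign(modules=[PlantedModule("m", ["g1", "g2"])],
                             n_background=5, noise_sd=6.0, seed=3)
        m = simulate_expression(d)
        assert (m.data.values >= 0).all()
        p = tmp_path / "expr.tsv"
        m.to_tsv(p)
        m2 = load_expression(p)
        pd.testing.assert_frame_equal(m.data, m2.data, check_names=False)


class TestSimulateGenome:
    def test_tandem_cluster_genes_all_within_colocation_window(self):
        spec = default_genome_spec()
        gff3, _ = simulate_genome(spec, seed=0)
        feats = {f.id: f for f in _parse_text(gff3)}
        lnc = feats["lnc_STS_cluster"]
        genes = [f for f in feats.values() if f.kind == "gene"]
        hits = colocation_oracle(lnc, genes, window=100_000)
        assert {f"STS{i:02d}" for i in range(1, 10)} <= hits
        assert "FAR1" not in hits

    def test_antisense_pair_overlaps_on_opposite_strands(self):
        spec = default_genome_spec()
        gff3, _ = simulate_genome(spec, seed=0)
        feats = {f.id: f for f in _parse_text(gff3)}
        lnc, gene = feats["lnc_antisense"], feats["GGT1"]
        assert lnc.overlaps(gene)
        assert lnc.strand != gene.strand

    def test_empty_feature_list_gives_headers_only(self):
        spec = GenomeSpec(chromosomes=[("chr1", 1000)], features=[])
        gff3, fasta = simulate_genome(spec, seed=0)
        assert gff3.startswith("##gff-version 3")
        assert len([ln for ln in gff3.splitlines() if not ln.startswith("#")]) == 0
        assert fasta.startswith(">chr1")

    def test_feature_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            GenomeSpec(
                chromosomes=[("chr1", 500)],
                features=[GenomicFeature("g1", "chr1", 100, 900, "+", "gene")],
            )

    def test_fasta_matches_declared_lengths_and_parses(self):
        spec = default_genome_spec()
        _, fasta = simulate_genome(spec, seed=0)
        recs = {r.id: r for r in SeqIO.parse(io.StringIO(fasta), "fasta")}
        for name, length in spec.chromosomes:
            assert len(recs[name].seq) == length

    def test_planted_promoter_motif_present_only_in_selected_genes(self):
        spec = default_genome_spec()
        myb = Motif("MYB_CCWACC", "CCWACC")
        planted = ["STS01", "STS02"]
        gff3, fasta = simulate_genome(spec, seed=2, planted_motif=myb,
                                      motif_gene_ids=planted, promoter_length=400)
        from phenolnet.motifs import extract_promoters

        genes = [f for f in _parse_text(gff3) if f.kind == "gene"]
        promoters = extract_promoters(genes, fasta, 400)
        hit_genes = {h.gene_id for h in scan_motif(promoters, myb)}
        assert hit_genes == set(planted)


class TestSimulatePromoters:
    def test_full_fraction_all_match(self):
        genes = [f"g{i}" for i in range(10)]
        fasta = simulate_promoters(genes, "CCWACC", 1.0, promoter_length=300, seed=0)
        proms = {r.id: str(r.seq) for r in SeqIO.parse(io.StringIO(fasta), "fasta")}
        hits = {h.gene_id for h in scan_motif(proms, Motif("m", "CCWACC"))}
        assert hits == set(genes)

    def test_zero_fraction_no_match_either_strand(self):
        genes = [f"g{i}" for i in range(10)]
        fasta = simulate_promoters(genes, "CCWACC", 0.0, promoter_length=300, seed=0)
        proms = {r.id: str(r.seq) for r in SeqIO.parse(io.StringIO(fasta), "fasta")}
        assert scan_motif(proms, Motif("m", "CCWACC")) == []

    def test_half_fraction_rounds_half_up(self):
        assert round_half_up(0.5 * 7) == 4
        genes = [f"g{i}" for i in range(7)]
        fasta = simulate_promoters(genes, "CCWACC", 0.5, promoter_length=200, seed=1)
        proms = {r.id: str(r.seq) for r in SeqIO.parse(io.StringIO(fasta), "fasta")}
        hits = {h.gene_id for h in scan_motif(proms, Motif("m", "CCWACC"))}
        assert len(hits) == 4

    def test_motif_longer_than_promoter_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            simulate_promoters(["g1"], "CCWACC", 1.0, promoter_length=4, seed=0)

    def test_sequences_have_stated_length(self):
        fasta = simulate_promoters(["a", "b"], "CANNTG", 1.0, promoter_length=123, seed=0)
        for rec in SeqIO.parse(io.StringIO(fasta), "fasta"):
            assert len(rec.seq) == 123


class TestSimulateMirnaPairs:
    TX = [("tx1", "ATGCGTACGTTAGCATCGGATCGATTACGCGATATCGGCTAGCTTAGC" * 3)]

    def test_perfect_pairs_score_zero(self):
        fa, truth = simulate_mirna_pairs(self.TX, n_pairs=2, mismatches=0, wobbles=0, seed=0)
        assert (truth["expectation"] == 0.0).all()

    def test_truth_matches_independent_duplex_scoring(self):
        # dual route: generator's penalty arithmetic vs the scorer itself
        fa, truth = simulate_mirna_pairs(self.TX, n_pairs=4, mismatches=1, wobbles=1, seed=3)
        mirnas = {r.id: str(r.seq) for r in SeqIO.parse(io.StringIO(fa), "fasta")}
        tx = dict(self.TX)
        for _, row in truth.iterrows():
            window = tx[row["transcript"]][row["window_start"]: row["window_start"] + 21]
            exp, _ = score_duplex(mirnas[row["mirna"]], window, ScoringScheme())
            assert exp == row["expectation"]

    def test_mismatch_outside_core_scores_one(self):
        fa, truth = simulate_mirna_pairs(self.TX, n_pairs=30, mismatches=1, wobbles=0, seed=9)
        outside = truth[~truth["mismatch_positions"].astype(int).between(2, 13)]
        assert not outside.empty
        assert (outside["expectation"] == 1.0).all()

    def test_wobble_inside_core_scores_doubled(self):
        fa, truth = simulate_mirna_pairs(self.TX, n_pairs=30, mismatches=0, wobbles=1, seed=9)
        inside = truth[truth["wobble_positions"].astype(int).between(2, 13)]
        assert not inside.empty
        assert (inside["expectation"] == 1.0).all()  # 0.5 x 2

    def test_short_transcript_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            fa, truth = simulate_mirna_pairs([("tiny", "ACGT")], n_pairs=1)
        assert truth.empty


class TestReproducibility:
    def test_same_seed_byte_identical(self):
        spec = default_genome_spec()
        assert simulate_genome(spec, seed=5) == simulate_genome(spec, seed=5)
        genes = ["a", "b", "c"]
        assert simulate_promoters(genes, "CCWACC", 0.5, 200, seed=5) == \
            simulate_promoters(genes, "CCWACC", 0.5, 200, seed=5)
        d = SimulationDesign(modules=[PlantedModule("m", ["g1"])], n_background=2, seed=5)
        pd.testing.assert_frame_equal(
            simulate_expression(d).data, simulate_expression(d).data
        )

    def test_emitted_files_parse_with_own_readers(self, tmp_path):
        spec = default_genome_spec()
        gff3, fasta = simulate_genome(spec, seed=1)
        p = tmp_path / "genome.gff3"
        p.write_text(gff3)
        feats = parse_features(p)
        assert {f.id for f in feats} == {f.id for f in spec.features}


def _parse_text(gff3_text: str):
    import tempfile, os
    from phenolnet.colocation import parse_features

    fd, path = tempfile.mkstemp(suffix=".gff3")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(gff3_text)
        return parse_features(path)
    finally:
        os.unlink(path)
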