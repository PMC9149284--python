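import dataclasses
import filecmp

import numpy as np
import pytest

from lmrnet.de import fpkm, tpm
from lmrnet.io import read_counts, read_fasta, read_gff3
from lmrnet.lncrna import classify_lncrna, filter_lncrna_candidates
from lmrnet.pipeline import gene_lengths_for_counts
from lmrnet.sim import (
    SimulationConfig,
    SimulationError,
    generate_annotation,
    generate_expression,
    plant_motifs,
    simulate,
    write_fixture,
)
from lmrnet.tf import MotifModel, scan_motif


def _log2(matrix):
    return np.log2(matrix.data + 1.0)


def _pcc(lv, a, b):
    return float(np.corrcoef(lv.loc[a], lv.loc[b])[0, 1])


class TestAnnotation:
    def test_four_lncrnas_realize_all_four_classes(self):
        cfg = SimulationConfig(
            n_genes=12, n_tfs=2, n_lncrnas=4, n_mirnas=2,
            planted_tf_edges=2, planted_mirna_edges=2,
            planted_lnc_cis_edges=0, planted_lnc_trans_edges=1, seed=3,
        )
        ann = generate_annotation(cfg)
        classes = {
            classify_lncrna(t, ann).lnc_class
            for t in ann.transcripts(roles=("lncRNA",))
        }
        assert classes == {"lincRNA", "intronic", "antisense", "sense"}

    def test_same_config_and_seed_reproduces_annotation(self, small_sim_config):
        a = generate_annotation(small_sim_config)
        b = generate_annotation(small_sim_config)
        assert [dataclasses.asdict(f) for f in a.features] == [
            dataclasses.asdict(f) for f in b.features
        ]

    def test_genes_do_not_overlap_except_lnc_classes(self, small_dataset):
        genes = sorted(
            small_dataset.annotation.genes(roles=("mRNA", "TF")),
            key=lambda g: g.start,
        )
        for g1, g2 in zip(genes, genes[1:]):
            assert g1.end <= g2.start

    def test_too_small_chromosome_rejected(self, small_sim_config):
        cfg = dataclasses.replace(small_sim_config, chrom_length=10_000)
        with pytest.raises(SimulationError, match="too small"):
            generate_annotation(cfg)

    def test_infeasible_edge_counts_rejected(self):
        with pytest.raises(SimulationError, match="target genes"):
            SimulationConfig(n_genes=5, planted_tf_edges=30).validate()


class TestMotifPlanting:
    def test_all_target_promoters_carry_their_motif(self, small_dataset):
        ds = small_dataset
        targets = {
            e.target_id: e.source_id
            for e in ds.truth.edges
            if e.mechanism == "tf_binding"
        }
        for gene, tf in targets.items():
            motif = ds.tf_motifs[tf]
            assert scan_motif(ds.promoters[gene], MotifModel("m", motif))

    def test_non_target_promoters_are_motif_free(self, small_dataset):
        ds = small_dataset
        targets = {e.target_id for e in ds.truth.edges if e.mechanism == "tf_binding"}
        clean = [g for g in ds.promoters if g not in targets]
        for gene in clean:
            for motif in set(ds.tf_motifs.values()):
                assert not scan_motif(ds.promoters[gene], MotifModel("m", motif))

    def test_recorded_placement_found_at_offset(self, small_dataset):
        ds = small_dataset
        by_gene = {p.gene_id: p for p in ds.truth.motif_placements}
        for gene, placement in by_gene.items():
            tf = next(
                e.source_id
                for e in ds.truth.edges
                if e.mechanism == "tf_binding" and e.target_id == gene
            )
            hits = scan_motif(ds.promoters[gene], MotifModel("m", ds.tf_motifs[tf]))
            assert any(
                h.offset == placement.offset and h.strand == placement.strand
                for h in hits
            )

    def test_no_planting_leaves_all_promoters_clean(self, small_sim_config):
        cfg = dataclasses.replace(small_sim_config, plant_motifs=False)
        ds = simulate(cfg)
        assert ds.truth.motif_placements == []
        for gene in ds.promoters:
            for motif in set(ds.tf_motifs.values()):
                assert not scan_motif(ds.promoters[gene], MotifModel("m", motif))


class TestExpression:
    def _noiseless(self, seed=1):
        cfg = SimulationConfig(
            n_genes=30, n_tfs=4, n_lncrnas=4, n_mirnas=4,
            planted_tf_edges=3, planted_mirna_edges=3,
            planted_lnc_cis_edges=0, planted_lnc_trans_edges=1,
            target_correlation=1.0, nb_dispersion=1e-4, seed=seed,
        )
        return simulate(cfg)

    def test_noiseless_limit_tf_pairs_approach_plus_one(self):
        ds = self._noiseless()
        lv = _log2(fpkm(ds.counts, gene_lengths_for_counts(ds.annotation)))
        for e in ds.truth.edges:
            if e.mechanism == "tf_binding":
                assert _pcc(lv, e.source_id, e.target_id) > 0.98

    def test_noiseless_limit_mirna_pairs_approach_minus_one(self):
        ds = self._noiseless()
        lv = _log2(fpkm(ds.counts, gene_lengths_for_counts(ds.annotation)))
        mi = _log2(tpm(ds.mirna_counts))
        for e in ds.truth.edges:
            if e.mechanism == "mirna_cleavage":
                r = float(np.corrcoef(mi.loc[e.source_id], lv.loc[e.target_id])[0, 1])
                assert r < -0.98

    def test_frozen_seed_tf_pcc_regression_baseline(self):
        """Reference run at the frozen seed: all 20 planted TF pairs exceed
        |PCC| 0.8 (weakest 0.97)."""
        cfg = SimulationConfig(
            n_genes=60, n_tfs=20, n_lncrnas=4, n_mirnas=4,
            planted_tf_edges=20, planted_mirna_edges=0,
            planted_lnc_cis_edges=0, planted_lnc_trans_edges=0, seed=1,
        )
        ds = simulate(cfg)
        lv = _log2(fpkm(ds.counts, gene_lengths_for_counts(ds.annotation)))
        pccs = [abs(_pcc(lv, e.source_id, e.target_id)) for e in ds.truth.edges]
        assert np.mean(np.array(pccs) > 0.8) == 1.0
        assert min(pccs) > 0.9

    def test_planted_pairs_dominate_decoy_pairs(self, small_dataset, rng):
        ds = small_dataset
        lv = _log2(fpkm(ds.counts, gene_lengths_for_counts(ds.annotation)))
        planted = [
            abs(_pcc(lv, e.source_id, e.target_id))
            for e in ds.truth.edges
            if e.mechanism in ("tf_binding", "lnc_trans")
        ]
        decoy_genes = [
            f for f in ds.counts.feature_ids if f not in ds.trajectories
        ]
        decoys = [
            abs(_pcc(lv, a, b))
            for a, b in zip(decoy_genes[:-1], decoy_genes[1:])
        ]
        assert min(planted) > max(decoys)

    def test_null_correlation_leaves_targets_flat(self, small_sim_config):
        cfg = dataclasses.replace(small_sim_config, target_correlation=0.0)
        ds = simulate(cfg)
        targets = {e.target_id for e in ds.truth.edges}
        assert not (set(ds.truth.expected_de_features) & targets)

    def test_expected_de_covers_targets_at_default_correlation(self, small_dataset):
        targets = {
            e.target_id
            for e in small_dataset.truth.edges
            if not e.target_id.startswith("mir")
        }
        assert targets <= set(small_dataset.truth.expected_de_features)

    def test_nonpositive_dispersion_rejected(self, small_sim_config):
        cfg = dataclasses.replace(small_sim_config, nb_dispersion=0.0)
        with pytest.raises(SimulationError, match="dispersion"):
            generate_expression(cfg)


class TestFixtureBundle:
    def test_byte_identical_reproduction(self, small_dataset, tmp_path):
        a = write_fixture(small_dataset, tmp_path / "a")
        ds2 = simulate(small_dataset.config)
        b = write_fixture(ds2, tmp_path / "b")
        for key in a:
            assert filecmp.cmp(a[key], b[key], shallow=False), key

    def test_round_trip_through_readers(self, small_dataset, tmp_path):
        paths = write_fixture(small_dataset, tmp_path / "fx")
        ann = read_gff3(paths["annotation"])
        assert len(ann) == len(small_dataset.annotation)
        counts = read_counts(paths["counts"], paths["samples"], paths["roles"])
        assert (counts.data.values == small_dataset.counts.data.values).all()
        genome = read_fasta(paths["genome"])["chr1"]
        assert genome == small_dataset.genome
        proms = read_fasta(paths["promoters_fasta"])
        assert proms == small_dataset.promoters

    def test_all_lncrnas_pass_the_candidate_filter(self, small_dataset):
        lnc_ids = list(small_dataset.lnc_seqs)
        retained = filter_lncrna_candidates(lnc_ids, small_dataset.lnc_seqs)
        assert retained == lnc_ids

    def test_edge_endpoints_exist(self, small_dataset):
        known = set(small_dataset.counts.feature_ids) | set(
            small_dataset.mirna_counts.feature_ids
        )
        for e in small_dataset.truth.edges:
            assert e.source_id in known and e.target_id in known

    def test_motif_placements_lie_within_promoters(self, small_dataset):
        P = small_dataset.config.promoter_length
        for p in small_dataset.truth.motif_placements:
            motif_len = len(next(iter(small_dataset.tf_motifs.values())))
            assert 0 <= p.offset <= P - motif_len
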