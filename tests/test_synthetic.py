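"""Synthetic study generator: determinism, consistency, planted structure."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spatialeqtl.digest import digest_genome, find_sites
from spatialeqtl.synthetic import (
    SITE,
    GroundTruth,
    SimConfig,
    generate_dataset,
    make_annotations_and_gwas,
    make_eqtl_table,
    make_genome,
    make_interactions,
)

SMALL = dict(
    n_chromosomes=2,
    chromosome_length=120_000,
    n_genes_per_chromosome=8,
    n_traits=4,
    n_planted_clusters=2,
    core_locus_size=2,
    private_egenes_per_trait=1,
)


def file_hashes(root):
    return {
        str(p.relative_to(root)): hashlib.md5(p.read_bytes()).hexdigest()
        for p in sorted(Path(root).rglob("*"))
        if p.is_file()
    }


class TestConfig:
    def test_rejects_zero_tissues(self):
        with pytest.raises(ValueError, match="n_tissues"):
            SimConfig(n_tissues=0)

    def test_rejects_short_chromosomes(self):
        with pytest.raises(ValueError):
            SimConfig(chromosome_length=5_000, site_spacing_mean=1_000)

    def test_rejects_oversized_core_locus(self):
        with pytest.raises(ValueError):
            SimConfig(core_locus_size=99)


class TestGenome:
    def test_deterministic_fasta(self, tmp_path):
        cfg = SimConfig(seed=1, **SMALL)
        make_genome(cfg, fasta_path=tmp_path / "a.fa")
        make_genome(cfg, fasta_path=tmp_path / "b.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_record_count(self):
        genome, _ = make_genome(SimConfig(seed=0, **SMALL))
        assert len(genome) == 2

    def test_planted_sites_are_exact(self):
        genome, sites = make_genome(SimConfig(seed=3, **SMALL))
        for chrom, seq in genome.items():
            assert list(find_sites(seq, SITE)) == sites[chrom]

    def test_fragment_count_near_poisson_expectation(self):
        cfg = SimConfig(
            seed=2,
            n_chromosomes=1,
            chromosome_length=50_000,
            site_spacing_mean=500,
            n_genes_per_chromosome=2,
            n_traits=2,
            n_planted_clusters=1,
            core_locus_size=1,
            private_egenes_per_trait=1,
        )
        genome, _ = make_genome(cfg)
        frag = digest_genome(genome)
        n = len(frag)
        assert 50 <= n <= 150  # within +-50% of length / spacing = 100

    def test_too_small_for_genes_errors(self):
        with pytest.raises(ValueError, match="too small"):
            make_genome(
                SimConfig(
                    seed=0,
                    n_chromosomes=1,
                    chromosome_length=30_000,
                    site_spacing_mean=500,
                    n_genes_per_chromosome=12,
                    core_locus_size=2,
                )
            )


@pytest.fixture(scope="module")
def built():
    cfg = SimConfig(seed=5)
    genome, _ = make_genome(cfg)
    return cfg, genome, make_annotations_and_gwas(cfg, genome)


class TestAnnotationsAndGwas:
    def test_cluster_partition(self, built):
        cfg, _, (_, _, _, gt) = built
        assert len(gt.trait_to_cluster) == 12
        sizes = pd.Series(list(gt.trait_to_cluster.values())).value_counts()
        assert sorted(sizes) == [4, 4, 4]

    def test_gwas_p_below_threshold(self, built):
        _, _, (_, _, gwas, _) = built
        assert (gwas["p"] < 5e-6).all()

    def test_core_locus_genes_adjacent(self, built):
        _, _, (genes, _, _, gt) = built
        for cluster, locus in gt.core_locus_genes.items():
            rows = genes.set_index("gene_id").loc[locus]
            assert rows["chrom"].nunique() == 1
            orders = sorted(rows["order"])
            assert orders == list(range(orders[0], orders[0] + len(locus)))

    def test_private_egenes_disjoint(self, built):
        _, _, (_, _, _, gt) = built
        seen = set()
        for genes in gt.private_egenes.values():
            assert not (set(genes) & seen)
            seen |= set(genes)

    def test_composite_rows_share_rsid_and_study(self, built):
        _, _, (_, _, gwas, gt) = built
        composite = [r for r, ts in gt.snp_to_traits.items() if len(ts) > 1]
        assert composite  # some multi-trait single-study SNPs exist
        for rsid in composite:
            rows = gwas[gwas["rsid"] == rsid]
            assert rows["study"].nunique() == 1
            assert rows["trait"].nunique() > 1

    def test_some_genes_have_multiple_isoforms(self, built):
        _, _, (_, isoforms, _, _) = built
        assert (isoforms.groupby("gene_id")["iso"].count() > 1).any()

    def test_snps_inside_fragments_never_on_cut_sites(self, built):
        cfg, genome, (_, _, _, gt) = built
        _, sites = make_genome(cfg)
        site_sets = {c: set(s) for c, s in sites.items()}
        for rsid, (chrom, pos) in gt.snp_positions.items():
            p0 = pos - 1
            assert not any(s <= p0 < s + 4 for s in site_sets[chrom]), rsid

    def test_ground_truth_matches_emitted_files(self, tmp_path):
        cfg = SimConfig(seed=6, **SMALL)
        ds = generate_dataset(cfg, tmp_path)
        gt = ds.ground_truth
        gwas = pd.read_csv(ds.gwas, sep="\t")
        for rec in gwas.itertuples(index=False):
            assert gt.snp_positions[rec.rsid] == (rec.chrom, rec.pos)
        gt2 = GroundTruth.from_json(ds.root / "ground_truth.json")
        assert gt2.trait_to_cluster == gt.trait_to_cluster
        assert set(gt2.true_eqtl_pairs) == set(gt.true_eqtl_pairs)


class TestInteractions:
    def test_noise_free_rows_only_support_the_true_pair(self, tmp_path):
        cfg = SimConfig(
            seed=7,
            n_chromosomes=1,
            chromosome_length=60_000,
            n_genes_per_chromosome=3,
            n_traits=1,
            n_planted_clusters=1,
            core_locus_size=1,
            private_egenes_per_trait=1,
            background_interactions=0,
            composite_snps_per_cluster=0,
            n_cell_lines=1,
            replicates_per_cell_line=1,
        )
        genome, _ = make_genome(cfg)
        _, _, _, gt = make_annotations_and_gwas(cfg, genome)
        frag = digest_genome(genome)
        tables = make_interactions(cfg, gt, frag)
        total = sum(len(t) for t in tables.values())
        snp_frags = set()
        for rsid, (chrom, pos) in gt.snp_positions.items():
            fr = frag[frag["chrom"] == chrom]
            idx = int(np.searchsorted(fr["start"].to_numpy(), pos - 1, "right") - 1)
            snp_frags.add((chrom, int(fr["index"].iloc[idx])))
        for t in tables.values():
            for rec in t.itertuples(index=False):
                assert (rec.chrom1, rec.frag1) in snp_frags or (
                    rec.chrom2,
                    rec.frag2,
                ) in snp_frags
        assert total >= len(gt.true_pair_keys())

    def test_refuses_foreign_digest(self):
        cfg = SimConfig(seed=7, **SMALL)
        genome, _ = make_genome(cfg)
        _, _, _, gt = make_annotations_and_gwas(cfg, genome)
        other = digest_genome({"chrX": "ACGT" * 100})
        with pytest.raises(ValueError, match="chromosome"):
            make_interactions(cfg, gt, other)


class TestEqtlTable:
    def test_true_rows_have_small_p(self):
        cfg = SimConfig(seed=8, true_eqtl_p_scale=1e-8)
        genome, _ = make_genome(cfg)
        _, _, _, gt = make_annotations_and_gwas(cfg, genome)
        tab = make_eqtl_table(cfg, gt)
        true_keys = set(gt.true_eqtl_pairs)
        is_true = [
            (r, g, t) in true_keys
            for r, g, t in tab[["rsid", "gene_id", "tissue"]].itertuples(index=False)
        ]
        tp = tab.loc[is_true, "p_nominal"]
        assert np.median(tp) < 1e-6
        assert (tab.loc[is_true, "nes"] != 0).all()

    def test_null_rows_uniform(self):
        """Pooled null p-values over 10 seeds pass a KS uniformity check."""
        pooled = []
        for seed in range(10):
            cfg = SimConfig(seed=seed, **SMALL)
            genome, _ = make_genome(cfg)
            _, _, _, gt = make_annotations_and_gwas(cfg, genome)
            tab = make_eqtl_table(cfg, gt)
            true_keys = set(gt.true_eqtl_pairs)
            is_null = [
                (r, g, t) not in true_keys
                for r, g, t in tab[["rsid", "gene_id", "tissue"]].itertuples(index=False)
            ]
            pooled.extend(tab.loc[is_null, "p_nominal"].tolist())
        assert stats.kstest(pooled, "uniform").pvalue > 0.01


class TestDataset:
    def test_byte_identical_regeneration(self, tmp_path):
        cfg = SimConfig(seed=9, **SMALL)
        generate_dataset(cfg, tmp_path / "a")
        generate_dataset(cfg, tmp_path / "b")
        assert file_hashes(tmp_path / "a") == file_hashes(tmp_path / "b")

    def test_expected_file_layout(self, dataset):
        assert dataset.fasta.exists() and dataset.gtf.exists()
        assert len(dataset.interaction_files) == 4  # 2 cell lines x 2 replicates
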