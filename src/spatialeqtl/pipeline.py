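"""End-to-end orchestration: files in, multimorbidity clusters out.

Ties the stages together for a directory of inputs (as produced by
:mod:`spatialeqtl.synthetic`, or real files in the same dialects): digest
the genome, assign SNPs and collapsed genes to fragments, aggregate Hi-C
contacts into spatial SNP-gene pairs, join the eQTL table under a single
BH family, build phenotype eGene sets, and bicluster the sharing matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from spatialeqtl import bicluster, digest, eqtl, interactions, multimorbidity

INTERACTION_FILE_RE = re.compile(r"(?P<cell_line>[^_/]+)_(?P<replicate>[^_/]+)_merged_nodups\.txt(\.gz)?$")


@dataclass
class PipelineResult:
    fragments: pd.DataFrame
    genes: pd.DataFrame
    gwas: pd.DataFrame
    pairs: pd.DataFrame
    observations: pd.DataFrame
    associations: pd.DataFrame
    significant: pd.DataFrame
    sets: multimorbidity.PhenotypeGeneSets
    filtered_sets: multimorbidity.PhenotypeGeneSets | None = None
    share: multimorbidity.ShareMatrix | None = None
    cobra: bicluster.CobraResult | None = None

    def cluster_assignment(self) -> dict[str, int]:
        """Phenotype label -> extracted column-cluster id (after biclustering)."""
        if self.share is None or self.cobra is None:
            raise ValueError("biclustering was not run")
        return dict(zip(self.share.labels, (int(c) for c in self.cobra.col_clusters)))


def discover_interaction_files(directory) -> dict[tuple[str, str], Path]:
    """Find merged_nodups files named ``{cell_line}_{replicate}_merged_nodups.txt``."""
    out: dict[tuple[str, str], Path] = {}
    for path in sorted(Path(directory).iterdir()):
        m = INTERACTION_FILE_RE.search(path.name)
        if m:
            out[(m.group("cell_line"), m.group("replicate"))] = path
    if not out:
        raise ValueError(f"no merged_nodups interaction files found in {directory}")
    return out


def run_pipeline(
    fasta,
    gtf,
    gwas_path,
    interaction_dir,
    eqtl_path,
    fdr_threshold: float = eqtl.FDR_THRESHOLD,
    cis_window: int = eqtl.CIS_WINDOW,
    min_egenes: int = 4,
    min_support: int = 1,
    run_biclustering: bool = True,
    gamma_n: int = 100,
    holdout_fraction: float = 0.1,
    seed: int = 0,
    k: int = 5,
    phi: float = 0.5,
    tol_cluster: float = 0.02,
) -> PipelineResult:
    """Run digest -> spatial pairs -> eQTL FDR -> sharing -> biclustering.

    ``seed`` controls only the hold-out of the biclustering validation; all
    other stages are deterministic functions of their inputs.
    """
    fragments = digest.digest_genome(fasta)
    genes = digest.collapse_gene_model(gtf)
    gwas = digest.read_gwas_table(gwas_path)
    snps = gwas.drop_duplicates("rsid")[["rsid", "chrom", "pos"]]
    snp_frag = digest.assign_snps_to_fragments(snps, fragments)
    gene_frag = digest.assign_genes_to_fragments(genes, fragments)
    tables = [
        interactions.parse_interactions(path, cl, rep, fragments=fragments)
        for (cl, rep), path in discover_interaction_files(interaction_dir).items()
    ]
    pairs, obs = interactions.find_spatial_pairs(
        snp_frag, gene_frag, tables, min_support=min_support
    )
    eqtl_table = eqtl.read_eqtl_table(eqtl_path)
    raw = eqtl.query_eqtls(pairs, eqtl_table)
    assoc = eqtl.annotate_associations(raw, threshold=fdr_threshold)
    if not assoc.empty:
        assoc = eqtl.classify_associations(assoc, snps, genes, cis_window=cis_window)
    significant = eqtl.filter_significant(assoc, threshold=fdr_threshold)
    sets = multimorbidity.build_phenotype_sets(gwas, significant)
    result = PipelineResult(
        fragments=fragments,
        genes=genes,
        gwas=gwas,
        pairs=pairs,
        observations=obs,
        associations=assoc,
        significant=significant,
        sets=sets,
    )
    if not run_biclustering:
        return result
    filtered = multimorbidity.filter_min_egenes(sets, min_count=min_egenes)
    if len(filtered.egenes) < 2:
        return result
    share = multimorbidity.share_matrix(filtered, mode="eGene")
    grid = bicluster.gamma_grid(n=gamma_n)
    cobra = bicluster.validate_path(
        share.values,
        grid=grid,
        holdout_fraction=holdout_fraction,
        seed=seed,
        k=k,
        phi=phi,
        tol_cluster=tol_cluster,
    )
    result.filtered_sets = filtered
    result.share = share
    result.cobra = cobra
    return result
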