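"""Spatial eQTL-eGene identification.

Spatial SNP-gene pairs are joined to an eQTL association table keyed by
(SNP, gene, tissue); pairs with no eQTL test are excluded *before*
multiple-testing correction, so the Benjamini-Hochberg family consists
only of tested spatial pairs.  Associations with adjusted p <= 0.05 are
spatial eQTL-eGene pairs.  Each association is classed cis (same
chromosome, < 1 Mb apart), trans-intrachromosomal (same chromosome,
>= 1 Mb) or trans-interchromosomal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

CIS_WINDOW = 1_000_000
FDR_THRESHOLD = 0.05

EQTL_COLUMNS = ["rsid", "gene_id", "tissue", "p_nominal", "nes"]


def read_eqtl_table(path) -> pd.DataFrame:
    """Read an eQTL TSV: rsid, gene_id, tissue, p_nominal, nes."""
    df = pd.read_csv(path, sep="\t")
    missing = set(EQTL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"eQTL table missing columns: {sorted(missing)}")
    return df


def query_eqtls(spatial_pairs: pd.DataFrame, eqtl_table: pd.DataFrame) -> pd.DataFrame:
    """Return eQTL rows whose (rsid, gene_id) is a spatial pair.

    Spatial pairs absent from the table (never tested) are dropped here,
    before the FDR adjustment, so they do not enter the test family.
    """
    keys = spatial_pairs[["rsid", "gene_id"]].drop_duplicates()
    return eqtl_table.merge(keys, on=["rsid", "gene_id"], how="inner").reset_index(
        drop=True
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Implements adj_(k) = min_{r >= k} m * p_(r) / r (capped at 1), with
    stable handling of ties.  Values outside [0, 1] are an error.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_significant(
    associations: pd.DataFrame, threshold: float = FDR_THRESHOLD
) -> pd.DataFrame:
    """Keep associations with p_adjusted <= threshold (spatial eQTL-eGene pairs)."""
    if "p_adjusted" not in associations.columns:
        raise ValueError("associations must carry a p_adjusted column; run adjust first")
    kept = associations[associations["p_adjusted"] <= threshold].reset_index(drop=True)
    return kept


def annotate_associations(
    associations: pd.DataFrame, threshold: float = FDR_THRESHOLD
) -> pd.DataFrame:
    """Add BH-adjusted p-values and a significance flag (single joint family)."""
    out = associations.copy()
    out["p_adjusted"] = adjust_bh(out["p_nominal"].to_numpy())
    out["significant"] = out["p_adjusted"] <= threshold
    return out


def classify_range(
    snp_chrom: str,
    snp_pos: int,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    cis_window: int = CIS_WINDOW,
) -> tuple[str, int | None]:
    """Classify one SNP-gene association as cis / trans_intra / trans_inter.

    ``snp_pos`` is 1-based; the gene region is 0-based half-open.  Distance
    is 0 if the SNP lies inside the region, otherwise the gap in bp to the
    nearest region edge; it is undefined (None) across chromosomes.
    """
    if gene_start >= gene_end:
        raise ValueError("gene region must satisfy start < end")
    if snp_chrom != gene_chrom:
        return "trans_inter", None
    p0 = snp_pos - 1
    if p0 < gene_start:
        dist = gene_start - p0
    elif p0 >= gene_end:
        dist = p0 - (gene_end - 1)
    else:
        dist = 0
    return ("cis" if dist < cis_window else "trans_intra"), int(dist)


def classify_associations(
    associations: pd.DataFrame,
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    cis_window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Vectorised cis/trans annotation of an association table.

    ``snps`` needs columns rsid, chrom, pos (1-based, one row per rsid);
    ``genes`` needs gene_id, chrom, start, end.  Adds ``range_class`` and
    ``distance`` columns (distance is NaN for trans_inter).
    """
    snp_map = snps.drop_duplicates("rsid").set_index("rsid")
    gene_map = genes.drop_duplicates("gene_id").set_index("gene_id")
    missing_snp = set(associations["rsid"]) - set(snp_map.index)
    if missing_snp:
        raise ValueError(f"SNPs without coordinates: {sorted(missing_snp)[:5]}")
    missing_gene = set(associations["gene_id"]) - set(gene_map.index)
    if missing_gene:
        raise ValueError(f"genes without regions: {sorted(missing_gene)[:5]}")
    out = associations.copy()
    sc = snp_map.loc[out["rsid"], "chrom"].to_numpy()
    sp = snp_map.loc[out["rsid"], "pos"].to_numpy(dtype=np.int64)
    gc = gene_map.loc[out["gene_id"], "chrom"].to_numpy()
    gs = gene_map.loc[out["gene_id"], "start"].to_numpy(dtype=np.int64)
    ge = gene_map.loc[out["gene_id"], "end"].to_numpy(dtype=np.int64)
    p0 = sp - 1
    dist = np.where(p0 < gs, gs - p0, np.where(p0 >= ge, p0 - (ge - 1), 0))
    same = sc == gc
    cls = np.where(
        ~same, "trans_inter", np.where(dist < cis_window, "cis", "trans_intra")
    )
    out["range_class"] = cls
    out["distance"] = np.where(same, dist, np.nan)
    return out


def compare_association_sets(set_spatial, set_distance_based) -> dict[str, int]:
    """Set algebra between spatially-informed and distance-only association keys.

    Both arguments are iterables of hashable keys, e.g. (rsid, gene_id,
    tissue) tuples.  Returns counts of shared, spatial-only and
    distance-only associations.
    """
    a = set(set_spatial)
    b = set(set_distance_based)
    return {
        "shared": len(a & b),
        "spatial_only": len(a - b),
        "distance_only": len(b - a),
    }


def summarize_tissue_cellline(
    significant: pd.DataFrame, observations: pd.DataFrame
) -> pd.DataFrame:
    """Per (tissue, cell line): mean nominal eQTL p and total supporting interactions.

    Significant associations are joined to the spatial observation table on
    (rsid, gene_id); each observation row is one supporting interaction in
    its cell line.  Empty groups are omitted.
    """
    joined = significant.merge(observations, on=["rsid", "gene_id"], how="inner")
    if joined.empty:
        return pd.DataFrame(
            columns=["tissue", "cell_line", "mean_p_nominal", "supporting_interactions"]
        )
    out = (
        joined.groupby(["tissue", "cell_line"], sort=True)
        .agg(
            mean_p_nominal=("p_nominal", "mean"),
            supporting_interactions=("rsid", "size"),
        )
        .reset_index()
    )
    return out
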