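"""Phenotype gene-sharing matrices, permutation null and commonality scoring.

A phenotype is the trait a SNP is associated with in the GWAS table; when
one study associates a SNP with several traits simultaneously, those
traits form a *composite phenotype* (label = sorted trait names joined by
"|").  Each phenotype accumulates the eGenes (and eQTL SNPs) of its
significant spatial associations.  Pairwise sharing between phenotypes i
and j is the asymmetric ratio

    a_ij = |eGenes_i intersect eGenes_j| / |eGenes_i|

To calibrate the observed sharing, all eGenes are pooled and randomly
reassigned to phenotypes preserving each phenotype's eGene count; the mean
of many such null matrices is the expected sharing under no pleiotropic
structure.  Within a phenotype cluster, an eGene's commonality index is
the fraction of member phenotypes whose eGene set contains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPOSITE_SEP = "|"


@dataclass
class PhenotypeGeneSets:
    """Per-phenotype eGene and eQTL-SNP sets.

    ``egenes`` and ``eqtls`` map phenotype label -> set of ids; labels are
    unique and composite labels deterministic (sorted traits joined by "|").
    """

    egenes: dict[str, set[str]]
    eqtls: dict[str, set[str]]

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.egenes.items()}

    def labels(self) -> list[str]:
        return sorted(self.egenes)


@dataclass
class ShareMatrix:
    """Asymmetric phenotype x phenotype sharing-ratio matrix (row = reference)."""

    labels: list[str]
    values: np.ndarray  # shape (n, n), a_ij in [0, 1], diagonal 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="phenotype")

    @classmethod
    def from_tsv(cls, path) -> "ShareMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def composite_label(traits) -> str:
    return COMPOSITE_SEP.join(sorted(set(traits)))


def build_phenotype_sets(
    gwas: pd.DataFrame, significant: pd.DataFrame
) -> PhenotypeGeneSets:
    """Assign each significant association's eGenes/eQTLs to phenotypes.

    Each (SNP, study) group of the GWAS table with k traits contributes the
    SNP's significant eGenes to a single phenotype: the trait itself when
    k = 1, the composite label when k > 1.  An association SNP absent from
    the GWAS table is an error.
    """
    snp_genes: dict[str, set[str]] = {}
    for rec in significant[["rsid", "gene_id"]].itertuples(index=False):
        snp_genes.setdefault(rec.rsid, set()).add(rec.gene_id)
    known = set(gwas["rsid"])
    missing = set(snp_genes) - known
    if missing:
        raise ValueError(f"association SNPs missing from GWAS table: {sorted(missing)[:5]}")
    egenes: dict[str, set[str]] = {}
    eqtls: dict[str, set[str]] = {}
    for (rsid, _study), grp in gwas.groupby(["rsid", "study"], sort=True):
        genes = snp_genes.get(rsid)
        if not genes:
            continue
        label = composite_label(grp["trait"])
        egenes.setdefault(label, set()).update(genes)
        eqtls.setdefault(label, set()).add(rsid)
    return PhenotypeGeneSets(egenes=egenes, eqtls=eqtls)


def _sets_for_mode(sets: PhenotypeGeneSets | dict, mode: str) -> dict[str, set[str]]:
    if isinstance(sets, PhenotypeGeneSets):
        if mode == "eGene":
            return sets.egenes
        if mode == "eQTL":
            return sets.eqtls
        raise ValueError(f"mode must be 'eGene' or 'eQTL', got {mode!r}")
    return sets


def share_matrix(sets, mode: str = "eGene") -> ShareMatrix:
    """Pairwise sharing ratios a_ij = |S_i ∩ S_j| / |S_i| over phenotypes.

    ``sets`` is a PhenotypeGeneSets (mode selects the eGene or eQTL sets)
    or a plain ``label -> set`` mapping.  Requires >= 2 phenotypes; an
    empty set is an error.
    """
    mapping = _sets_for_mode(sets, mode)
    labels = sorted(mapping)
    if len(labels) < 2:
        raise ValueError("share_matrix needs at least 2 phenotypes")
    for lab in labels:
        if not mapping[lab]:
            raise ValueError(f"phenotype {lab!r} has an empty set")
    universe = sorted(set().union(*mapping.values()))
    gene_idx = {g: i for i, g in enumerate(universe)}
    member = np.zeros((len(labels), len(universe)), dtype=bool)
    for i, lab in enumerate(labels):
        for g in mapping[lab]:
            member[i, gene_idx[g]] = True
    inter = member.astype(np.int64) @ member.T.astype(np.int64)
    sizes = member.sum(axis=1)
    values = inter / sizes[:, None]
    return ShareMatrix(labels=labels, values=values)


def filter_min_egenes(sets: PhenotypeGeneSets, min_count: int = 4) -> PhenotypeGeneSets:
    """Keep phenotypes whose own eGene count is >= min_count (default 4)."""
    keep = {k for k, v in sets.egenes.items() if len(v) >= min_count}
    if not keep:
        import warnings

        warnings.warn("no phenotype passes the minimum eGene filter", stacklevel=2)
    return PhenotypeGeneSets(
        egenes={k: set(v) for k, v in sets.egenes.items() if k in keep},
        eqtls={k: set(v) for k, v in sets.eqtls.items() if k in keep},
    )


def null_mean_matrix(
    sets, n_null: int = 1000, seed: int = 0, mode: str = "eGene"
) -> ShareMatrix:
    """Mean sharing matrix over permutation-null phenotype assignments.

    All eGenes are pooled; in every null replicate each phenotype draws its
    observed count of eGenes uniformly without replacement from the pool,
    independently across phenotypes (a gene may serve several phenotypes,
    as in the real data).  Per-replicate counts exactly match the observed
    counts.  Returns the element-wise mean of ``n_null`` null matrices;
    deterministic given ``seed``.
    """
    mapping = _sets_for_mode(sets, mode)
    labels = sorted(mapping)
    if len(labels) < 2:
        raise ValueError("need at least 2 phenotypes")
    pool = sorted(set().union(*mapping.values()))
    n_pool = len(pool)
    counts = np.array([len(mapping[lab]) for lab in labels])
    if (counts == 0).any():
        raise ValueError("empty phenotype set")
    if (counts > n_pool).any():
        raise ValueError("a phenotype requests more genes than the pool holds")
    rng = np.random.default_rng(seed)
    n_ph = len(labels)
    acc = np.zeros((n_ph, n_ph), dtype=float)
    for _ in range(n_null):
        member = null_assignment(rng, counts, n_pool)
        inter = member @ member.T
        acc += inter / counts[:, None]
    return ShareMatrix(labels=labels, values=acc / n_null)


def null_assignment(
    rng: np.random.Generator, counts: np.ndarray, n_pool: int
) -> np.ndarray:
    """One null replicate: boolean membership matrix (phenotype x pooled gene).

    Row i holds exactly ``counts[i]`` ones, drawn uniformly without
    replacement and independently across phenotypes.
    """
    member = np.zeros((len(counts), n_pool), dtype=np.int64)
    for i, c in enumerate(counts):
        member[i, rng.choice(n_pool, size=int(c), replace=False)] = 1
    return member


def commonality_index(cluster_members, sets, mode: str = "eGene") -> dict[str, float]:
    """Fraction of cluster phenotypes whose set contains each eGene.

    ``cluster_members`` is a subset of phenotype labels (empty clusters are
    an error).  eGenes carried by no member are omitted from the report.
    """
    mapping = _sets_for_mode(sets, mode)
    members = list(cluster_members)
    if not members:
        raise ValueError("cluster has no members")
    unknown = [m for m in members if m not in mapping]
    if unknown:
        raise ValueError(f"unknown phenotype labels: {unknown[:5]}")
    counts: dict[str, int] = {}
    for m in members:
        for g in mapping[m]:
            counts[g] = counts.get(g, 0) + 1
    size = len(members)
    return {g: c / size for g, c in sorted(counts.items())}


def read_omim_table(path) -> pd.DataFrame:
    """Read a genemap-style TSV: gene_id, phenotype, method_code (1-4)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "phenotype", "method_code"} - set(df.columns)
    if missing:
        raise ValueError(f"OMIM table missing columns: {sorted(missing)}")
    return df


def omim_summary(egenes, omim: pd.DataFrame) -> dict:
    """Annotated fraction and mapping-method distribution of an eGene list.

    Mapping-method codes follow the genemap convention: 1 = disorder
    associated, defect unknown; 2 = mapped by linkage only; 3 = causal
    mutation identified; 4 = contiguous-gene deletion/duplication.

    Returns ``{"fraction_annotated": ..., "method_distribution": {code:
    proportion}}`` where the distribution is over gene-phenotype rows of
    annotated eGenes.
    """
    codes = omim["method_code"].to_numpy()
    if not np.isin(codes, [1, 2, 3, 4]).all():
        bad = sorted(set(codes) - {1, 2, 3, 4})
        raise ValueError(f"invalid OMIM mapping-method codes: {bad}")
    genes = list(dict.fromkeys(egenes))
    if not genes:
        raise ValueError("empty eGene list")
    annotated_genes = set(omim["gene_id"])
    hit = [g for g in genes if g in annotated_genes]
    fraction = len(hit) / len(genes)
    rows = omim[omim["gene_id"].isin(hit)]
    dist: dict[int, float] = {}
    if not rows.empty:
        vc = rows["method_code"].value_counts(normalize=True)
        dist = {int(k): float(v) for k, v in sorted(vc.items())}
    return {"fraction_annotated": fraction, "method_distribution": dist}
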