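"""Synthetic study generator with planted ground truth.

Emits every input the pipeline consumes — genome FASTA, GTF transcript
model, GWAS-style SNP-trait table, per-replicate Hi-C interaction files in
the 9-column merged_nodups dialect, an eQTL association table and an
OMIM-genemap-like table — with a recoverable planted answer:

* traits are partitioned into clusters; every cluster shares a *core
  locus* of adjacent genes on one chromosome (its traits' common eGenes),
  and each trait additionally owns private eGenes drawn disjointly;
* each true (SNP, gene) pair is guaranteed >= 1 Hi-C contact between the
  SNP's restriction fragment and a fragment overlapping the gene, spread
  over the configured cell lines and replicates, on top of random
  background contacts;
* true (SNP, gene, tissue) rows in the eQTL table receive small p-values
  (scaled by ``true_eqtl_p_scale``) and non-zero effect sizes, all other
  rows uniform p-values.

Recognition sites (GATC by default conventions of the digest) are planted
at stochastic spacings into random non-GATC background sequence, so the
digest's expected fragment count is analytic.  SNPs are placed strictly
inside fragments, never on a cut site.  All outputs are byte-identical
for identical configurations (including seed).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from spatialeqtl.digest import digest_genome, find_sites

SITE = "GATC"
GENE_LEN_RANGE = (1000, 3000)
MIN_GENE_GAP = 500
CHROM_MARGIN = 2000
MIN_SNP_FRAGMENT_LEN = 12


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults are the small-study conditions used throughout the test
    suite: 12 traits in 3 planted clusters, core loci of 4 adjacent genes,
    3 private eGenes per trait, Hi-C from 2 cell lines x 2 replicates with
    random background contacts, and two eQTL tissues.
    """

    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 300_000
    site_spacing_mean: int = 1_000
    n_genes_per_chromosome: int = 15
    n_traits: int = 12
    n_planted_clusters: int = 3
    core_locus_size: int = 4
    private_egenes_per_trait: int = 3
    n_cell_lines: int = 2
    replicates_per_cell_line: int = 2
    background_interactions: int = 50
    true_eqtl_p_scale: float = 1e-8
    n_tissues: int = 2
    null_eqtl_rows_per_snp: int = 2
    composite_snps_per_cluster: int = 1
    supporting_obs_mean: float = 2.0

    def __post_init__(self):
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length": self.chromosome_length,
            "site_spacing_mean": self.site_spacing_mean,
            "n_genes_per_chromosome": self.n_genes_per_chromosome,
            "n_traits": self.n_traits,
            "n_planted_clusters": self.n_planted_clusters,
            "core_locus_size": self.core_locus_size,
            "private_egenes_per_trait": self.private_egenes_per_trait,
            "n_cell_lines": self.n_cell_lines,
            "replicates_per_cell_line": self.replicates_per_cell_line,
            "n_tissues": self.n_tissues,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        for name in ("background_interactions", "null_eqtl_rows_per_snp",
                     "composite_snps_per_cluster"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.chromosome_length <= 10 * self.site_spacing_mean:
            raise ValueError("chromosome_length must exceed 10 x site_spacing_mean")
        if self.core_locus_size > self.n_genes_per_chromosome:
            raise ValueError("core_locus_size cannot exceed n_genes_per_chromosome")
        if self.n_planted_clusters > self.n_traits:
            raise ValueError("cannot plant more clusters than traits")
        if not (0 < self.true_eqtl_p_scale <= 1):
            raise ValueError("true_eqtl_p_scale must lie in (0, 1]")
        if self.supporting_obs_mean < 1.0:
            raise ValueError("supporting_obs_mean must be >= 1")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def trait_names(self) -> list[str]:
        return [f"trait_{i + 1:02d}" for i in range(self.n_traits)]

    def tissue_names(self) -> list[str]:
        return [f"Tissue{i + 1:02d}" for i in range(self.n_tissues)]

    def cell_lines(self) -> list[str]:
        return [f"CL{i + 1}" for i in range(self.n_cell_lines)]

    def replicates(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.replicates_per_cell_line)]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted answer key, with coordinates matching the emitted files."""

    trait_to_cluster: dict[str, int]
    phenotype_to_cluster: dict[str, int]
    true_eqtl_pairs: list[tuple[str, str, str]]  # (rsid, gene_id, tissue)
    core_locus_genes: dict[int, list[str]]
    private_egenes: dict[str, list[str]]
    snp_positions: dict[str, tuple[str, int]]  # rsid -> (chrom, 1-based pos)
    gene_regions: dict[str, tuple[str, int, int]]  # gene -> (chrom, start, end)
    snp_to_traits: dict[str, list[str]]

    def true_pair_keys(self) -> set[tuple[str, str]]:
        return {(r, g) for r, g, _ in self.true_eqtl_pairs}

    def to_json(self, path) -> None:
        payload = {
            "trait_to_cluster": self.trait_to_cluster,
            "phenotype_to_cluster": self.phenotype_to_cluster,
            "true_eqtl_pairs": [list(t) for t in self.true_eqtl_pairs],
            "core_locus_genes": {str(k): v for k, v in self.core_locus_genes.items()},
            "private_egenes": self.private_egenes,
            "snp_positions": {k: list(v) for k, v in self.snp_positions.items()},
            "gene_regions": {k: list(v) for k, v in self.gene_regions.items()},
            "snp_to_traits": self.snp_to_traits,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            trait_to_cluster=d["trait_to_cluster"],
            phenotype_to_cluster=d["phenotype_to_cluster"],
            true_eqtl_pairs=[tuple(t) for t in d["true_eqtl_pairs"]],
            core_locus_genes={int(k): v for k, v in d["core_locus_genes"].items()},
            private_egenes=d["private_egenes"],
            snp_positions={k: (v[0], int(v[1])) for k, v in d["snp_positions"].items()},
            gene_regions={
                k: (v[0], int(v[1]), int(v[2])) for k, v in d["gene_regions"].items()
            },
            snp_to_traits=d["snp_to_traits"],
        )


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _min_chromosome_length(config: SimConfig) -> int:
    return (
        2 * CHROM_MARGIN
        + config.n_genes_per_chromosome * (GENE_LEN_RANGE[1] + MIN_GENE_GAP)
    )


BASES = np.frombuffer(b"ACGT", dtype="S1")


def make_genome(config: SimConfig, fasta_path=None) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Random genome with GATC sites planted at stochastic spacings.

    Site spacings are ~ Exponential(site_spacing_mean) (floored at 2 site
    lengths), so the digest's expected fragment count per chromosome is
    about chromosome_length / site_spacing_mean.  Accidental GATC
    occurrences in the random background are rejection-fixed, so the
    planted positions are exactly the digest's cut sites.

    Returns ``(sequences, site_positions)`` and optionally writes a FASTA.
    """
    if config.chromosome_length < _min_chromosome_length(config):
        raise ValueError(
            f"chromosome_length {config.chromosome_length} too small to host "
            f"{config.n_genes_per_chromosome} genes (need >= {_min_chromosome_length(config)})"
        )
    rng = _stage_rng(config, 1)
    site = np.frombuffer(SITE.encode(), dtype="S1")
    min_gap = 2 * len(SITE)
    genome: dict[str, str] = {}
    site_positions: dict[str, list[int]] = {}
    for chrom in config.chrom_names():
        L = config.chromosome_length
        gaps = min_gap + rng.exponential(
            max(config.site_spacing_mean - min_gap, 1), size=2 * L // config.site_spacing_mean + 16
        ).astype(np.int64)
        pos = np.cumsum(gaps)
        pos = pos[pos < L - len(SITE)]
        arr = BASES[rng.integers(0, 4, size=L)]
        for p in pos:
            arr[p : p + len(SITE)] = site
        seq = arr.tobytes().decode()
        planted = set(int(p) for p in pos)
        # rejection-fix accidental GATCs outside the planted intervals
        planted_cover = np.zeros(L, dtype=bool)
        for p in pos:
            planted_cover[p : p + len(SITE)] = True
        while True:
            occ = find_sites(seq, SITE)
            accidental = [int(o) for o in occ if int(o) not in planted]
            if not accidental:
                break
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            for o in accidental:
                for i in range(o, o + len(SITE)):
                    if not planted_cover[i]:
                        current = arr[i]
                        choices = [b for b in (b"A", b"C", b"G", b"T") if b != current]
                        arr[i] = choices[int(rng.integers(0, 3))]
                        break
            seq = arr.tobytes().decode()
        genome[chrom] = seq
        site_positions[chrom] = sorted(planted)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for chrom, seq in genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    return genome, site_positions


def _place_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping gene spans per chromosome, in genomic order.

    Leftover space after margins, gene bodies and minimum inter-gene gaps
    is distributed as random extra gaps (sorted uniform offsets).
    """
    out = []
    counter = 0
    for chrom in config.chrom_names():
        n = config.n_genes_per_chromosome
        lengths = rng.integers(GENE_LEN_RANGE[0], GENE_LEN_RANGE[1] + 1, size=n)
        slack = (
            config.chromosome_length
            - 2 * CHROM_MARGIN
            - int(lengths.sum())
            - (n - 1) * MIN_GENE_GAP
        )
        if slack < 0:
            raise ValueError(
                f"cannot place {n} genes on {chrom} without overlap "
                f"(chromosome too short by {-slack} bp)"
            )
        offsets = np.sort(rng.integers(0, slack + 1, size=n))
        cursor = CHROM_MARGIN
        prev_off = 0
        for i in range(n):
            start = cursor + int(offsets[i]) - prev_off
            prev_off = int(offsets[i])
            end = start + int(lengths[i])
            counter += 1
            out.append((f"GENE{counter:04d}", f"Gn{counter}", chrom, start, end, i))
            cursor = end + MIN_GENE_GAP
    return pd.DataFrame(
        out, columns=["gene_id", "gene_name", "chrom", "start", "end", "order"]
    )


def _isoforms(genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """1-2 isoforms per gene whose union span equals the gene region."""
    rows = []
    for pos, rec in enumerate(genes.itertuples(index=False)):
        length = rec.end - rec.start
        two = rec.order == 0 or rng.random() < 0.5  # first gene per chrom always 2
        if two and length >= 10:
            mid_hi = rec.start + int(np.ceil(0.7 * length))
            mid_lo = rec.start + int(np.floor(0.3 * length))
            rows.append((rec.gene_id, rec.gene_name, rec.chrom, rec.start, mid_hi, 1))
            rows.append((rec.gene_id, rec.gene_name, rec.chrom, mid_lo, rec.end, 2))
        else:
            rows.append((rec.gene_id, rec.gene_name, rec.chrom, rec.start, rec.end, 1))
    return pd.DataFrame(
        rows, columns=["gene_id", "gene_name", "chrom", "start", "end", "iso"]
    )


def write_gtf(isoforms: pd.DataFrame, path) -> None:
    """Write transcript+exon rows (GTF is 1-based inclusive)."""
    with open(path, "w") as fh:
        for rec in isoforms.itertuples(index=False):
            attrs = (
                f'gene_id "{rec.gene_id}"; transcript_id "{rec.gene_id}.{rec.iso}"; '
                f'gene_name "{rec.gene_name}";'
            )
            for feature in ("transcript", "exon"):
                fh.write(
                    f"{rec.chrom}\tsim\t{feature}\t{rec.start + 1}\t{rec.end}\t.\t+\t.\t{attrs}\n"
                )


def _pick_snp_site(
    fragments_by_chrom: dict[str, pd.DataFrame],
    chrom: str,
    rng: np.random.Generator,
) -> int:
    """1-based SNP position strictly inside a fragment, never on a cut site."""
    fr = fragments_by_chrom[chrom]
    ok = fr[(fr["end"] - fr["start"]) >= MIN_SNP_FRAGMENT_LEN]
    row = ok.iloc[int(rng.integers(0, len(ok)))]
    pos0 = int(rng.integers(row["start"] + len(SITE), row["end"]))
    return pos0 + 1


def make_annotations_and_gwas(
    config: SimConfig,
    genome: dict[str, str],
    gtf_path=None,
    gwas_path=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Plant clusters, genes, SNPs; emit GTF + GWAS table + ground truth.

    Traits are assigned round-robin to clusters.  Cluster c's core locus is
    a contiguous run of ``core_locus_size`` adjacent genes on chromosome
    ``c mod n_chromosomes``; private eGenes are drawn disjointly across
    traits from the remaining genes.  One SNP is created per (trait,
    target gene); additionally each cluster gets composite SNPs that a
    single study associates with two of the cluster's traits (emitted as
    two GWAS rows sharing rsid and study).  All GWAS p-values are < 5e-6.

    Returns ``(genes, isoforms, gwas, ground_truth)``.
    """
    rng = _stage_rng(config, 2)
    fragments = digest_genome(genome, SITE)
    fragments_by_chrom = {c: g.reset_index(drop=True) for c, g in fragments.groupby("chrom")}
    genes = _place_genes(config, rng)
    isoforms = _isoforms(genes, rng)

    traits = config.trait_names()
    K = config.n_planted_clusters
    trait_to_cluster = {t: i % K for i, t in enumerate(traits)}

    # core loci: disjoint contiguous windows of adjacent genes
    per_chrom_needed: dict[str, int] = {}
    for c in range(K):
        chrom = config.chrom_names()[c % config.n_chromosomes]
        per_chrom_needed[chrom] = per_chrom_needed.get(chrom, 0) + 1
    for chrom, n_loci in per_chrom_needed.items():
        if n_loci * config.core_locus_size > config.n_genes_per_chromosome:
            raise ValueError(
                f"cannot place {n_loci} disjoint core loci of {config.core_locus_size} "
                f"genes on {chrom}"
            )
    used_windows: dict[str, list[tuple[int, int]]] = {}
    core_locus_genes: dict[int, list[str]] = {}
    for c in range(K):
        chrom = config.chrom_names()[c % config.n_chromosomes]
        order = genes[genes["chrom"] == chrom].sort_values("order")
        n = len(order)
        taken = used_windows.setdefault(chrom, [])
        candidates = [
            s
            for s in range(0, n - config.core_locus_size + 1)
            if all(
                s + config.core_locus_size <= a or s >= b for a, b in taken
            )
        ]
        if not candidates:
            raise ValueError(f"no room for core locus of cluster {c} on {chrom}")
        s = int(rng.choice(candidates))
        taken.append((s, s + config.core_locus_size))
        core_locus_genes[c] = list(order["gene_id"].iloc[s : s + config.core_locus_size])

    core_all = {g for genes_ in core_locus_genes.values() for g in genes_}
    pool = [g for g in genes["gene_id"] if g not in core_all]
    need = config.private_egenes_per_trait * config.n_traits
    if need > len(pool):
        raise ValueError(
            f"not enough non-core genes for private eGenes ({need} needed, {len(pool)} free)"
        )
    perm = list(rng.permutation(pool))
    private_egenes = {
        t: sorted(perm[i * config.private_egenes_per_trait : (i + 1) * config.private_egenes_per_trait])
        for i, t in enumerate(traits)
    }

    gene_chrom = dict(zip(genes["gene_id"], genes["chrom"]))
    chroms = config.chrom_names()
    gwas_rows = []
    snp_positions: dict[str, tuple[str, int]] = {}
    snp_to_traits: dict[str, list[str]] = {}
    pair_targets: list[tuple[str, str]] = []  # (rsid, gene_id)
    counter = 0

    def place_snp(target_gene: str) -> str:
        nonlocal counter
        counter += 1
        rsid = f"rs{counter:05d}"
        if len(chroms) > 1 and rng.random() < 0.5:
            others = [c for c in chroms if c != gene_chrom[target_gene]]
            chrom = others[int(rng.integers(0, len(others)))]
        else:
            chrom = gene_chrom[target_gene]
        pos = _pick_snp_site(fragments_by_chrom, chrom, rng)
        snp_positions[rsid] = (chrom, pos)
        return rsid

    def gwas_p() -> float:
        return float(10 ** rng.uniform(-12, np.log10(4.9e-6)))

    for ti, trait in enumerate(traits):
        targets = core_locus_genes[trait_to_cluster[trait]] + private_egenes[trait]
        study = f"S{ti + 1:02d}"
        for gene in targets:
            rsid = place_snp(gene)
            gwas_rows.append((rsid, snp_positions[rsid][0], snp_positions[rsid][1], trait, study, gwas_p()))
            snp_to_traits[rsid] = [trait]
            pair_targets.append((rsid, gene))

    phenotype_to_cluster = dict(trait_to_cluster)
    for c in range(K):
        members = [t for t in traits if trait_to_cluster[t] == c]
        for j in range(config.composite_snps_per_cluster):
            if len(members) < 2:
                break
            pair_traits = sorted([members[0], members[1 + j % (len(members) - 1)]])
            gene = core_locus_genes[c][0]
            rsid = place_snp(gene)
            study = f"Scomp{c + 1}_{j + 1}"
            p = gwas_p()
            for t in pair_traits:
                gwas_rows.append((rsid, snp_positions[rsid][0], snp_positions[rsid][1], t, study, p))
            snp_to_traits[rsid] = pair_traits
            pair_targets.append((rsid, gene))
            label = "|".join(pair_traits)
            phenotype_to_cluster[label] = c

    tissues = config.tissue_names()
    true_pairs: list[tuple[str, str, str]] = []
    for rsid, gene in pair_targets:
        n_t = 1 + int(rng.binomial(config.n_tissues - 1, 0.5)) if config.n_tissues > 1 else 1
        chosen = sorted(rng.choice(config.n_tissues, size=n_t, replace=False))
        for t_idx in chosen:
            true_pairs.append((rsid, gene, tissues[int(t_idx)]))

    gwas = pd.DataFrame(
        gwas_rows, columns=["rsid", "chrom", "pos", "trait", "study", "p"]
    )
    gene_regions = {
        r.gene_id: (r.chrom, int(r.start), int(r.end)) for r in genes.itertuples(index=False)
    }
    gt = GroundTruth(
        trait_to_cluster=trait_to_cluster,
        phenotype_to_cluster=phenotype_to_cluster,
        true_eqtl_pairs=true_pairs,
        core_locus_genes=core_locus_genes,
        private_egenes=private_egenes,
        snp_positions=snp_positions,
        gene_regions=gene_regions,
        snp_to_traits=snp_to_traits,
    )
    if gtf_path is not None:
        write_gtf(isoforms, gtf_path)
    if gwas_path is not None:
        gwas.to_csv(gwas_path, sep="\t", index=False)
    return genes, isoforms, gwas, gt


def make_interactions(
    config: SimConfig,
    ground_truth: GroundTruth,
    fragments: pd.DataFrame,
    out_dir=None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-(cell line, replicate) merged_nodups interaction tables.

    Every true (SNP, gene) pair receives ``1 + Poisson(supporting_obs_mean
    - 1)`` supporting observations between the SNP's fragment and a random
    fragment overlapping the gene, each assigned to a random (cell line,
    replicate); ``background_interactions`` random fragment pairs are added
    to every file as noise.  The SNP end of a read is placed on end 1 or 2
    at random.  Fragment indices are validated against the digest.
    """
    rng = _stage_rng(config, 3)
    by_chrom = {c: g.sort_values("index").reset_index(drop=True) for c, g in fragments.groupby("chrom")}

    def frag_of(chrom: str, pos1: int) -> pd.Series:
        fr = by_chrom.get(chrom)
        if fr is None:
            raise ValueError(f"chromosome {chrom!r} not present in the digest")
        p0 = pos1 - 1
        idx = int(np.searchsorted(fr["start"].to_numpy(), p0, side="right") - 1)
        if idx < 0 or p0 >= int(fr["end"].iloc[-1]):
            raise ValueError(f"position {chrom}:{pos1} outside the digest")
        return fr.iloc[idx]

    combos = [(cl, rep) for cl in config.cell_lines() for rep in config.replicates()]
    rows_by_combo: dict[tuple[str, str], list[tuple]] = {c: [] for c in combos}
    read_counter = 0

    def emit(combo, chrom_a, frag_a, pos_a, chrom_b, frag_b, pos_b):
        nonlocal read_counter
        read_counter += 1
        name = f"RD{read_counter:06d}"
        s1, s2 = int(rng.integers(0, 2)) * 16, int(rng.integers(0, 2)) * 16
        if rng.random() < 0.5:  # SNP end appears as end 2 half the time
            rows_by_combo[combo].append(
                (name, s1, chrom_b, pos_b, frag_b, s2, chrom_a, pos_a, frag_a)
            )
        else:
            rows_by_combo[combo].append(
                (name, s1, chrom_a, pos_a, frag_a, s2, chrom_b, pos_b, frag_b)
            )

    seen: set[tuple[str, str]] = set()
    for rsid, gene, _tissue in ground_truth.true_eqtl_pairs:
        if (rsid, gene) in seen:
            continue
        seen.add((rsid, gene))
        s_chrom, s_pos = ground_truth.snp_positions[rsid]
        s_frag = frag_of(s_chrom, s_pos)
        g_chrom, g_start, g_end = ground_truth.gene_regions[gene]
        fr = by_chrom.get(g_chrom)
        if fr is None:
            raise ValueError(f"chromosome {g_chrom!r} not present in the digest")
        overlapping = fr[(fr["start"] < g_end) & (fr["end"] > g_start)]
        if overlapping.empty:
            raise ValueError(f"gene {gene} overlaps no fragment in the digest")
        n_obs = 1 + int(rng.poisson(config.supporting_obs_mean - 1.0))
        for _ in range(n_obs):
            g_row = overlapping.iloc[int(rng.integers(0, len(overlapping)))]
            combo = combos[int(rng.integers(0, len(combos)))]
            pos_a = int(rng.integers(s_frag["start"], s_frag["end"])) + 1
            pos_b = int(rng.integers(g_row["start"], g_row["end"])) + 1
            emit(
                combo,
                s_chrom,
                int(s_frag["index"]),
                pos_a,
                g_chrom,
                int(g_row["index"]),
                pos_b,
            )

    chrom_list = sorted(by_chrom)
    for combo in combos:
        for _ in range(config.background_interactions):
            picks = []
            for _end in range(2):
                chrom = chrom_list[int(rng.integers(0, len(chrom_list)))]
                fr = by_chrom[chrom]
                row = fr.iloc[int(rng.integers(0, len(fr)))]
                pos = int(rng.integers(row["start"], row["end"])) + 1
                picks.append((chrom, int(row["index"]), pos))
            emit(combo, *picks[0], *picks[1])

    from spatialeqtl.interactions import INTERACTION_COLUMNS

    out: dict[tuple[str, str], pd.DataFrame] = {}
    for combo in combos:
        df = pd.DataFrame(rows_by_combo[combo], columns=INTERACTION_COLUMNS)
        out[combo] = df
        if out_dir is not None:
            path = Path(out_dir) / f"{combo[0]}_{combo[1]}_merged_nodups.txt"
            with open(path, "w") as fh:
                for row in df.itertuples(index=False):
                    fh.write(" ".join(str(v) for v in row) + "\n")
    return out


def make_eqtl_table(
    config: SimConfig, ground_truth: GroundTruth, path=None
) -> pd.DataFrame:
    """eQTL association TSV: true rows small-p, null rows uniform-p.

    True (SNP, gene, tissue) rows draw p ~ Uniform(0, true_eqtl_p_scale)
    with a non-zero signed effect size; each SNP additionally gets
    ``null_eqtl_rows_per_snp`` rows against random non-target genes with
    p ~ Uniform(0, 1) and near-zero effect.
    """
    rng = _stage_rng(config, 4)
    tissues = config.tissue_names()
    rows = []
    pair_sign: dict[tuple[str, str], float] = {}
    for rsid, gene, tissue in ground_truth.true_eqtl_pairs:
        sign = pair_sign.setdefault((rsid, gene), 1.0 if rng.random() < 0.5 else -1.0)
        p = float(rng.uniform(0, 1) * config.true_eqtl_p_scale)
        nes = float(sign * rng.uniform(0.2, 1.0))
        rows.append((rsid, gene, tissue, p, nes))
    all_genes = sorted(ground_truth.gene_regions)
    true_partners: dict[str, set[str]] = {}
    for rsid, gene, _ in ground_truth.true_eqtl_pairs:
        true_partners.setdefault(rsid, set()).add(gene)
    seen = {(r, g, t) for r, g, t in ground_truth.true_eqtl_pairs}
    for rsid in sorted(ground_truth.snp_positions):
        for _ in range(config.null_eqtl_rows_per_snp):
            for _attempt in range(20):
                gene = all_genes[int(rng.integers(0, len(all_genes)))]
                tissue = tissues[int(rng.integers(0, len(tissues)))]
                if gene not in true_partners.get(rsid, set()) and (rsid, gene, tissue) not in seen:
                    seen.add((rsid, gene, tissue))
                    rows.append(
                        (rsid, gene, tissue, float(rng.uniform()), float(rng.normal(0, 0.05)))
                    )
                    break
    df = pd.DataFrame(rows, columns=["rsid", "gene_id", "tissue", "p_nominal", "nes"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def make_omim_table(
    config: SimConfig, ground_truth: GroundTruth, path=None, coverage: float = 0.6
) -> pd.DataFrame:
    """Genemap-like table over a random subset of genes (codes 1-4)."""
    rng = _stage_rng(config, 5)
    rows = []
    ph_counter = 0
    for gene in sorted(ground_truth.gene_regions):
        if rng.random() >= coverage:
            continue
        n_ph = 1 + int(rng.random() < 0.3)
        for _ in range(n_ph):
            ph_counter += 1
            code = int(rng.choice([1, 2, 3, 4], p=[0.10, 0.15, 0.65, 0.10]))
            rows.append((gene, f"mendelian_disorder_{ph_counter:03d}", code))
    df = pd.DataFrame(rows, columns=["gene_id", "phenotype", "method_code"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


@dataclass
class SyntheticDataset:
    """Paths and in-memory handles of one generated study."""

    root: Path
    fasta: Path
    gtf: Path
    gwas: Path
    eqtl: Path
    omim: Path
    interaction_files: dict[tuple[str, str], Path]
    config: SimConfig
    ground_truth: GroundTruth


def generate_dataset(config: SimConfig, out_dir) -> SyntheticDataset:
    """Generate and write the complete synthetic study to ``out_dir``."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    fasta = root / "genome.fa"
    genome, _sites = make_genome(config, fasta_path=fasta)
    gtf = root / "genes.gtf"
    gwas_path = root / "gwas.tsv"
    genes, isoforms, gwas, gt = make_annotations_and_gwas(
        config, genome, gtf_path=gtf, gwas_path=gwas_path
    )
    fragments = digest_genome(genome, SITE)
    inter_dir = root / "interactions"
    inter_dir.mkdir(exist_ok=True)
    tables = make_interactions(config, gt, fragments, out_dir=inter_dir)
    interaction_files = {
        combo: inter_dir / f"{combo[0]}_{combo[1]}_merged_nodups.txt" for combo in tables
    }
    eqtl_path = root / "eqtl.tsv"
    make_eqtl_table(config, gt, path=eqtl_path)
    omim_path = root / "omim.tsv"
    make_omim_table(config, gt, path=omim_path)
    gt.to_json(root / "ground_truth.json")
    config.to_json(root / "sim_config.json")
    return SyntheticDataset(
        root=root,
        fasta=fasta,
        gtf=gtf,
        gwas=gwas_path,
        eqtl=eqtl_path,
        omim=omim_path,
        interaction_files=interaction_files,
        config=config,
        ground_truth=gt,
    )
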