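"""Hi-C interaction parsing and spatial SNP-gene pair discovery.

Interaction files follow the 9-column ``merged_nodups`` dialect of cleaned
Hi-C read-pair mapping locations:

    read_name strand1 chrom1 pos1 frag1 strand2 chrom2 pos2 frag2

one file per (cell line, replicate).  A spatial SNP-gene pair is a SNP and
gene whose restriction fragments are captured in contact: for every read
pair with a SNP-harbouring fragment on either end, the partner fragment is
tested for overlap with a collapsed gene region.  Each qualifying
(record, SNP-end, overlapping gene) triple is one *supporting interaction*
observation; the number of distinct (SNP fragment, gene fragment) contact
pairs is the pair's *fragment interactions*.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

INTERACTION_COLUMNS = [
    "read_name",
    "strand1",
    "chrom1",
    "pos1",
    "frag1",
    "strand2",
    "chrom2",
    "pos2",
    "frag2",
]

PAIR_COLUMNS = [
    "rsid",
    "gene_id",
    "fragment_interactions",
    "supporting_interactions",
    "n_cell_lines",
    "n_replicates",
]

OBS_COLUMNS = [
    "rsid",
    "gene_id",
    "snp_chrom",
    "snp_fragment",
    "gene_chrom",
    "gene_fragment",
    "cell_line",
    "replicate",
]


@dataclass(frozen=True)
class InteractionRecord:
    read_name: str
    strand1: int
    chrom1: str
    pos1: int
    frag1: int
    strand2: int
    chrom2: str
    pos2: int
    frag2: int
    cell_line: str
    replicate: str


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_interactions(
    path,
    cell_line: str,
    replicate: str,
    fragments: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Parse one merged_nodups-dialect file into an interaction table.

    Every row must carry exactly 9 whitespace-separated columns; malformed
    rows raise with their 1-based line number.  If ``fragments`` is given,
    chromosome names and fragment indices are validated against the digest.

    Returns a DataFrame with the 9 data columns plus ``cell_line`` and
    ``replicate`` provenance columns.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 9:
                raise ValueError(
                    f"{path}: line {lineno}: expected 9 columns, got {len(fields)}"
                )
            rows.append(
                (
                    fields[0],
                    int(fields[1]),
                    fields[2],
                    int(fields[3]),
                    int(fields[4]),
                    int(fields[5]),
                    fields[6],
                    int(fields[7]),
                    int(fields[8]),
                )
            )
    df = pd.DataFrame(rows, columns=INTERACTION_COLUMNS)
    df["cell_line"] = cell_line
    df["replicate"] = replicate
    if fragments is not None and not df.empty:
        counts = fragments.groupby("chrom")["index"].max().to_dict()
        for end in ("1", "2"):
            chroms = df[f"chrom{end}"]
            unknown = ~chroms.isin(counts)
            if unknown.any():
                lineno = int(np.flatnonzero(unknown)[0]) + 1
                raise ValueError(
                    f"{path}: line {lineno}: unknown chromosome {chroms[unknown].iloc[0]!r}"
                )
            fmax = chroms.map(counts).to_numpy()
            bad = (df[f"frag{end}"].to_numpy() < 0) | (df[f"frag{end}"].to_numpy() > fmax)
            if bad.any():
                lineno = int(np.flatnonzero(bad)[0]) + 1
                raise ValueError(
                    f"{path}: line {lineno}: fragment index not present in digest"
                )
    return df


def iter_records(table: pd.DataFrame) -> Iterator[InteractionRecord]:
    """Stream a parsed interaction table as typed records."""
    for rec in table.itertuples(index=False):
        yield InteractionRecord(
            rec.read_name,
            int(rec.strand1),
            rec.chrom1,
            int(rec.pos1),
            int(rec.frag1),
            int(rec.strand2),
            rec.chrom2,
            int(rec.pos2),
            int(rec.frag2),
            rec.cell_line,
            rec.replicate,
        )


def find_spatial_pairs(
    snp_fragments: pd.DataFrame,
    gene_fragments: pd.DataFrame,
    interactions: pd.DataFrame | Iterable[pd.DataFrame],
    min_support: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate fragment contacts into spatial SNP-gene pairs.

    Both ends of every record are treated symmetrically: if either end's
    (chromosome, fragment) harbours >= 1 SNP, the partner end is tested for
    gene overlap, and each (record, SNP end, overlapping gene) triple
    contributes one observation.  A fragment overlapping k genes yields one
    observation for each of the k pairs.

    Parameters
    ----------
    snp_fragments
        DataFrame with columns ``rsid, chrom, fragment`` (one row per SNP).
    gene_fragments
        Long-format DataFrame ``gene_id, chrom, fragment``.
    interactions
        One parsed interaction table, or an iterable of them (one per
        cell-line replicate).
    min_support
        Retain pairs with at least this many supporting observations
        (default 1, i.e. every observed pair is kept and its support
        carried forward).

    Returns
    -------
    (pairs, observations)
        ``pairs`` has one row per (rsid, gene_id) with fragment_interactions,
        supporting_interactions, n_cell_lines, n_replicates;
        ``observations`` is the long-format evidence table.
    """
    if isinstance(interactions, pd.DataFrame):
        tables = [interactions]
    else:
        tables = list(interactions)
    if not tables:
        raise ValueError("at least one interaction table is required")
    snp_key = snp_fragments[["rsid", "chrom", "fragment"]]
    gene_key = gene_fragments[["gene_id", "chrom", "fragment"]]
    obs_parts = []
    for tab in tables:
        if tab.empty:
            continue
        for snp_end, gene_end in (("1", "2"), ("2", "1")):
            hit = tab.merge(
                snp_key,
                left_on=[f"chrom{snp_end}", f"frag{snp_end}"],
                right_on=["chrom", "fragment"],
                how="inner",
            )
            if hit.empty:
                continue
            hit = hit.merge(
                gene_key,
                left_on=[f"chrom{gene_end}", f"frag{gene_end}"],
                right_on=["chrom", "fragment"],
                how="inner",
                suffixes=("_snp", "_gene"),
            )
            if hit.empty:
                continue
            obs_parts.append(
                pd.DataFrame(
                    {
                        "rsid": hit["rsid"],
                        "gene_id": hit["gene_id"],
                        "snp_chrom": hit[f"chrom{snp_end}"],
                        "snp_fragment": hit[f"frag{snp_end}"],
                        "gene_chrom": hit[f"chrom{gene_end}"],
                        "gene_fragment": hit[f"frag{gene_end}"],
                        "cell_line": hit["cell_line"],
                        "replicate": hit["replicate"],
                    }
                )
            )
    if not obs_parts:
        empty_pairs = pd.DataFrame(columns=PAIR_COLUMNS)
        return empty_pairs, pd.DataFrame(columns=OBS_COLUMNS)
    obs = pd.concat(obs_parts, ignore_index=True)[OBS_COLUMNS]
    grouped = obs.groupby(["rsid", "gene_id"], sort=True)
    pairs = grouped.agg(
        supporting_interactions=("gene_fragment", "size"),
        n_cell_lines=("cell_line", "nunique"),
        n_replicates=("replicate", "nunique"),
    ).reset_index()
    frag_ints = (
        obs.drop_duplicates(
            ["rsid", "gene_id", "snp_chrom", "snp_fragment", "gene_chrom", "gene_fragment"]
        )
        .groupby(["rsid", "gene_id"], sort=True)
        .size()
        .rename("fragment_interactions")
        .reset_index()
    )
    pairs = pairs.merge(frag_ints, on=["rsid", "gene_id"], how="left")
    pairs = pairs[pairs["supporting_interactions"] >= min_support].reset_index(drop=True)
    keep = pairs.set_index(["rsid", "gene_id"]).index
    obs = obs[obs.set_index(["rsid", "gene_id"]).index.isin(keep)].reset_index(drop=True)
    return pairs[PAIR_COLUMNS], obs


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion Z test (two-sided).

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    Returns (z, two-sided normal p-value).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both groups must be non-empty")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def support_enrichment_test(
    pairs: pd.DataFrame, significant: Sequence[bool]
) -> tuple[float, float]:
    """Test whether multi-support pairs are enriched for eQTL significance.

    Pairs are partitioned into support > 1 (more than one supporting
    observation, i.e. seen in >1 replicate or >1 cell line) versus
    support = 1; ``significant`` flags each pair's eQTL status.  Returns
    the pooled two-proportion Z statistic and two-sided p-value; an empty
    partition is an error.
    """
    sig = np.asarray(significant, dtype=bool)
    if len(sig) != len(pairs):
        raise ValueError("significance flags must align with pairs")
    multi = pairs["supporting_interactions"].to_numpy() > 1
    n1, n2 = int(multi.sum()), int((~multi).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both support partitions must contain at least one pair")
    x1 = int(sig[multi].sum())
    x2 = int(sig[~multi].sum())
    return two_proportion_z(x1, n1, x2, n2)


def write_pairs(pairs: pd.DataFrame, obs: pd.DataFrame, pair_path, obs_path) -> None:
    pairs.to_csv(pair_path, sep="\t", index=False)
    obs.to_csv(obs_path, sep="\t", index=False)
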