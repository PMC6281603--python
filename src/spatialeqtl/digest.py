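"""In-silico restriction digest and fragment assignment.

The Hi-C libraries consumed downstream are prepared with MboI, a 4-cutter
that cleaves at the 5' end of its GATC recognition site (^GATC).  Digesting
the reference genome with the same enzyme yields, per chromosome, a table
of restriction fragments that tile the sequence exactly.  SNPs (points) and
collapsed gene models (intervals) are then assigned to the fragments that
harbour them; no binning or padding is applied around fragments.

Coordinate conventions
----------------------
Fragments and gene regions are 0-based half-open ``[start, end)``.  SNP
input positions are 1-based (the convention of variant annotation files)
and converted at ingest.
"""

from __future__ import annotations

import os
import re
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

GWAS_P_THRESHOLD = 5e-6

FRAGMENT_COLUMNS = ["chrom", "start", "end", "index"]


def _load_sequences(sequences) -> dict[str, str]:
    """Accept a mapping chrom -> sequence string, or a FASTA path."""
    if isinstance(sequences, (str, os.PathLike)):
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(sequences), "fasta")}
    return {str(k): str(v) for k, v in sequences.items()}


def find_sites(sequence: str, recognition_site: str = "GATC") -> np.ndarray:
    """All (possibly overlapping) 0-based start positions of the site."""
    pattern = re.compile("(?=" + re.escape(recognition_site.upper()) + ")")
    return np.array(
        [m.start() for m in pattern.finditer(sequence.upper())], dtype=np.int64
    )


def digest_genome(sequences, recognition_site: str = "GATC") -> pd.DataFrame:
    """Digest chromosome sequences into a restriction-fragment table.

    Cuts are placed at the 5' start of every occurrence of
    ``recognition_site`` (MboI chemistry for the default GATC).  Per
    chromosome the fragments tile ``[0, len)`` with no gaps or overlaps and
    carry consecutive 0-based ordinal indices; zero-length fragments (a cut
    at position 0) are dropped.

    Parameters
    ----------
    sequences
        Mapping ``chrom -> sequence`` or a FASTA file path.
    recognition_site
        Recognition sequence, length >= 1.

    Returns
    -------
    DataFrame with columns ``chrom, start, end, index``.
    """
    if len(recognition_site) < 1:
        raise ValueError("recognition_site must be non-empty")
    seqs = _load_sequences(sequences)
    if not seqs:
        raise ValueError("no sequences provided")
    rows = []
    for chrom, seq in seqs.items():
        n = len(seq)
        if n == 0:
            raise ValueError(f"empty sequence for chromosome {chrom!r}")
        cuts = find_sites(seq, recognition_site)
        bounds = np.concatenate([[0], cuts, [n]])
        starts = bounds[:-1]
        ends = bounds[1:]
        keep = ends > starts  # drop zero-length terminal fragments
        starts, ends = starts[keep], ends[keep]
        for i, (s, e) in enumerate(zip(starts, ends)):
            rows.append((chrom, int(s), int(e), i))
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def _check_tiling(frag: pd.DataFrame) -> None:
    for chrom, grp in frag.groupby("chrom", sort=False):
        grp = grp.sort_values("index")
        if not (np.asarray(grp["index"]) == np.arange(len(grp))).all():
            raise ValueError(f"fragment indices of {chrom} are not consecutive from 0")
        starts = np.asarray(grp["start"])
        ends = np.asarray(grp["end"])
        if starts[0] != 0 or (starts[1:] != ends[:-1]).any() or (starts >= ends).any():
            raise ValueError(f"fragments of {chrom} do not tile the chromosome")


def collapse_gene_model(gtf) -> pd.DataFrame:
    """Collapse all isoforms of each gene into one composite gene region.

    Every transcript/exon of a gene contributes its span; the composite
    region is ``[min start, max end)`` across isoforms, introns and
    inter-isoform gaps included.  A gene annotated on more than one
    chromosome is an error.

    Parameters
    ----------
    gtf
        GTF file path, or a DataFrame with columns
        ``gene_id, gene_name, chrom, start, end`` (0-based half-open)
        carrying one row per isoform.

    Returns
    -------
    DataFrame with one row per gene: ``gene_id, gene_name, chrom, start, end``.
    """
    if isinstance(gtf, pd.DataFrame):
        iso = gtf
    else:
        import gffutils

        db = gffutils.create_db(
            str(gtf),
            ":memory:",
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        rows = []
        for feat in db.all_features():
            if feat.featuretype not in ("transcript", "exon"):
                continue
            gene_id = feat.attributes.get("gene_id", [None])[0]
            if gene_id is None:
                raise ValueError(f"feature without gene_id at {feat.seqid}:{feat.start}")
            gene_name = feat.attributes.get("gene_name", [gene_id])[0]
            # gffutils keeps GTF 1-based inclusive coords; convert here
            rows.append((gene_id, gene_name, feat.seqid, feat.start - 1, feat.end))
        iso = pd.DataFrame(rows, columns=["gene_id", "gene_name", "chrom", "start", "end"])
    if iso.empty:
        raise ValueError("no gene features found")
    out = []
    for gene_id, grp in iso.groupby("gene_id", sort=True):
        chroms = grp["chrom"].unique()
        if len(chroms) > 1:
            raise ValueError(
                f"gene {gene_id} is annotated on multiple chromosomes: {sorted(chroms)}"
            )
        out.append(
            (
                gene_id,
                grp["gene_name"].iloc[0],
                chroms[0],
                int(grp["start"].min()),
                int(grp["end"].max()),
            )
        )
    return pd.DataFrame(out, columns=["gene_id", "gene_name", "chrom", "start", "end"])


def read_gwas_table(path) -> pd.DataFrame:
    """Read a GWAS-style SNP-trait association TSV.

    Expected columns: ``rsid, chrom, pos, trait, study, p`` with one row
    per (SNP, study, trait).  Rows with association p >= 5e-6 are rejected:
    the pipeline's inputs are genome-wide-suggestive associations only.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"rsid", "chrom", "pos", "trait", "study", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GWAS table missing columns: {sorted(missing)}")
    bad = df[df["p"] >= GWAS_P_THRESHOLD]
    if not bad.empty:
        raise ValueError(
            f"{len(bad)} GWAS rows have p >= {GWAS_P_THRESHOLD:g} "
            f"(first offender {bad.iloc[0]['rsid']})"
        )
    return df


def assign_snps_to_fragments(snps: pd.DataFrame, fragments: pd.DataFrame) -> pd.DataFrame:
    """Map each SNP (1-based ``pos``) to the single fragment harbouring it.

    Returns a copy of ``snps`` with a ``fragment`` column (per-chromosome
    ordinal index).  A position outside every fragment of its chromosome is
    an error naming the record.
    """
    _check_tiling(fragments)
    out = snps.copy()
    out["fragment"] = -1
    for chrom, grp in out.groupby("chrom", sort=False):
        fr = fragments[fragments["chrom"] == chrom].sort_values("index")
        if fr.empty:
            raise ValueError(f"no fragments for chromosome {chrom!r} (SNPs {list(grp['rsid'])[:3]}...)")
        starts = np.asarray(fr["start"])
        chrom_end = int(fr["end"].iloc[-1])
        pos0 = np.asarray(grp["pos"], dtype=np.int64) - 1  # 1-based -> 0-based
        oob = (pos0 < 0) | (pos0 >= chrom_end)
        if oob.any():
            rsid = grp.loc[grp.index[np.flatnonzero(oob)[0]], "rsid"]
            raise ValueError(f"SNP {rsid} position outside chromosome {chrom}")
        idx = np.searchsorted(starts, pos0, side="right") - 1
        out.loc[grp.index, "fragment"] = np.asarray(fr["index"])[idx]
    return out


def assign_genes_to_fragments(genes: pd.DataFrame, fragments: pd.DataFrame) -> pd.DataFrame:
    """Map each gene region to every fragment overlapping it by >= 1 bp.

    No padding is applied.  Returns a long-format DataFrame
    ``gene_id, chrom, fragment`` with one row per overlapped fragment.
    """
    _check_tiling(fragments)
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in fragments.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), int(i))
            for s, e, i in zip(grp["start"], grp["end"], grp["index"])
        )
    rows = []
    for rec in genes.itertuples(index=False):
        tree = trees.get(rec.chrom)
        if tree is None:
            raise ValueError(f"no fragments for chromosome {rec.chrom!r} (gene {rec.gene_id})")
        hits = sorted(iv.data for iv in tree.overlap(int(rec.start), int(rec.end)))
        if not hits:
            raise ValueError(f"gene {rec.gene_id} overlaps no fragment")
        rows.extend((rec.gene_id, rec.chrom, h) for h in hits)
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "fragment"])


def write_fragments(fragments: pd.DataFrame, path) -> None:
    """Write the fragment table as BED-like TSV (chrom, start, end, index)."""
    fragments[FRAGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _check_tiling(df)
    return df
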