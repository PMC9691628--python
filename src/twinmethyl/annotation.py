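"""Genomic-feature annotation: CpG density, gene proximity, clusters, categories.

Gene association uses the gene body expanded by a flank (default 10 kb) on
both sides, so distal and proximal promoter regions count on either strand;
any >=1 bp overlap with the region qualifies.  Functional categories come
from a user-supplied gene-to-category table rather than a live database.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_GENE_FLANK_BP = 10_000
DEFAULT_CLUSTER_WINDOW_MB = 2.0
DEFAULT_CLUSTER_MIN_COUNT = 3

GENE_COLUMNS = ["gene_id", "symbol", "chrom", "start", "end", "strand"]


def cpg_count(sequence: str) -> int:
    """Non-overlapping count of CG dinucleotides in a sequence."""
    return sequence.upper().count("CG")


def cpg_density(
    reference: Mapping[str, str], chrom: str, start: int, end: int
) -> float:
    """CpG per 100 bp of the region [start, end) on the reference.

    ``reference`` maps chromosome name to sequence (a plain dict or a
    ``pyfaidx.Fasta``-like object supporting slicing).
    """
    if chrom not in reference:
        raise ValueError(f"unknown chromosome {chrom!r}")
    seq = reference[chrom]
    length = len(seq)
    if not (0 <= start < end <= length):
        raise ValueError(
            f"region {chrom}:{start}-{end} outside sequence bounds (len {length})"
        )
    region = str(seq[start:end])
    return 100.0 * cpg_count(region) / (end - start)


def density_histogram(densities, max_bin: int = 10) -> pd.Series:
    """Integer-binned CpG/100 bp histogram (floor-binned, capped at max_bin)."""
    bins = np.minimum(np.floor(np.asarray(densities, dtype=float)), max_bin)
    return pd.Series(bins.astype(int)).value_counts().sort_index()


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Load gene records from a GTF/GFF file into a 0-based half-open frame."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        symbol = feat.attributes.get("gene_name", [gene_id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "symbol": symbol,
                "chrom": feat.seqid,
                "start": feat.start - 1,  # GTF is 1-based inclusive
                "end": feat.end,
                "strand": feat.strand if feat.strand in "+-" else ".",
            }
        )
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    if ((genes["end"] - genes["start"]) <= 0).any():
        raise ValueError(f"{path}: gene with non-positive length")
    return genes


def _gene_trees(genes: pd.DataFrame, flank: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples():
        tree = trees.setdefault(row.chrom, IntervalTree())
        tree.addi(max(0, row.start - flank), row.end + flank, row.gene_id)
    return trees


def associate_genes(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = DEFAULT_GENE_FLANK_BP,
) -> list[list[str]]:
    """Genes whose flank-expanded body overlaps each region by >=1 bp.

    Returns one sorted gene-id list per region row (empty for intergenic
    regions, which are retained unannotated).  Symmetric in strand: the
    flank is applied on both sides of the gene body.
    """
    trees = _gene_trees(genes, flank)
    out = []
    for row in regions.itertuples():
        tree = trees.get(row.chrom)
        hits = sorted({iv.data for iv in tree.overlap(row.start, row.end)}) if tree else []
        out.append(hits)
    return out


def flag_clusters(
    dmrs: pd.DataFrame,
    window_mb: float = DEFAULT_CLUSTER_WINDOW_MB,
    min_count: int = DEFAULT_CLUSTER_MIN_COUNT,
) -> np.ndarray:
    """Flag DMRs sitting in local clusters.

    A run of at least ``min_count`` consecutive DMRs on one chromosome whose
    overall span (max end - min start) fits within ``window_mb`` megabases is
    a cluster; every member of any qualifying run is flagged.  Defaults (3
    DMRs / 2 Mb) are explicit configuration, not a claim about any
    published criterion.
    """
    window_bp = int(window_mb * 1e6)
    flags = np.zeros(len(dmrs), dtype=bool)
    if dmrs.empty:
        return flags
    positions = {label: pos for pos, label in enumerate(dmrs.index)}
    order = dmrs.sort_values(["chrom", "start"], kind="stable")
    for _, sub in order.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        n = len(sub)
        for i in range(n):
            # widest run starting at i whose overall span fits; the span
            # max(ends[i..j]) - starts[i] is non-decreasing in j
            j = i
            span_end = ends[i]
            while j + 1 < n and max(span_end, ends[j + 1]) - starts[i] <= window_bp:
                j += 1
                span_end = max(span_end, ends[j])
            if j - i + 1 >= min_count:
                for label in idx[i : j + 1]:
                    flags[positions[label]] = True
    return flags


def assign_categories(
    gene_ids,
    category_table: pd.DataFrame,
) -> pd.Series:
    """Histogram of functional categories over a list of gene ids.

    ``category_table`` has columns ``gene`` and ``category``; duplicate gene
    rows with conflicting categories are rejected.  Genes missing from the
    table count as "unknown"; counts therefore sum to the number of gene ids
    passed in.
    """
    if not {"gene", "category"}.issubset(category_table.columns):
        raise ValueError("category table needs 'gene' and 'category' columns")
    dup = category_table.groupby("gene")["category"].nunique()
    conflicts = dup[dup > 1].index.tolist()
    if conflicts:
        raise ValueError(f"conflicting categories for genes: {conflicts}")
    lookup = category_table.drop_duplicates("gene").set_index("gene")["category"]
    cats = [lookup.get(g, "unknown") for g in gene_ids]
    return pd.Series(cats, dtype=object).value_counts().sort_index()


def annotate_dmrs(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    reference: Mapping[str, str] | None = None,
    flank: int = DEFAULT_GENE_FLANK_BP,
    cluster_window_mb: float = DEFAULT_CLUSTER_WINDOW_MB,
    cluster_min_count: int = DEFAULT_CLUSTER_MIN_COUNT,
) -> pd.DataFrame:
    """Attach gene links, cluster flags and (optionally) recomputed CpG
    density to a DMR table."""
    out = dmrs.copy()
    links = associate_genes(out, genes, flank=flank)
    out["genes"] = [";".join(g) for g in links]
    out["in_cluster"] = flag_clusters(out, cluster_window_mb, cluster_min_count)
    if reference is not None:
        out["cpg_density"] = [
            cpg_density(reference, r.chrom, r.start, r.end) for r in out.itertuples()
        ]
    return out
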