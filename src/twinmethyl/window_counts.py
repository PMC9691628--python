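"""Fixed-width genomic window grids, read counting, RPKM and top-window selection.

The unit of every downstream statistic is a 1 kb genomic window.  Each
chromosome is tiled with non-overlapping windows of uniform width; the last
window of a chromosome may be shorter.  Reads (as BED-style intervals) are
assigned to exactly one window by their midpoint, which conserves the total
read count and makes counting order-independent.

Coordinates are 0-based half-open everywhere in memory and on disk (BED
dialect); 1-based annotation formats are converted at the boundary by the
readers in :mod:`twinmethyl.annotation`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GRID_COLUMNS = ["chrom", "start", "end", "window", "short"]


@dataclass
class CountMatrix:
    """Windows x samples integer read counts plus per-sample library sizes.

    Attributes
    ----------
    counts :
        DataFrame indexed by global window index, one column per sample,
        non-negative integers.
    lib_sizes :
        Series of total mapped reads per sample.  Always at least the column
        sum of assigned counts (reads can map outside the grid).
    """

    counts: pd.DataFrame
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
        if self.lib_sizes.isna().any():
            missing = self.lib_sizes.index[self.lib_sizes.isna()].tolist()
            raise ValueError(f"library size missing for samples: {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        short = self.counts.sum(axis=0) > self.lib_sizes
        if short.any():
            raise ValueError(
                "library size smaller than assigned counts for "
                f"{self.lib_sizes.index[short].tolist()}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)], self.lib_sizes[list(samples)])

    # --- on-disk TSV with a "#library_sizes" header line -------------------
    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            sizes = "\t".join(str(int(s)) for s in self.lib_sizes)
            fh.write(f"#library_sizes\t{sizes}\n")
            self.counts.to_csv(fh, sep="\t", index_label="window")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[0] != "#library_sizes":
                raise ValueError(f"{path}: missing #library_sizes header line")
            sizes = [int(x) for x in header[1:]]
            counts = pd.read_csv(fh, sep="\t", index_col="window")
        return cls(counts, pd.Series(sizes, index=counts.columns))


def make_windows(chrom_sizes: Mapping[str, int], width: int = 1000) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping ``width`` bp windows.

    A chromosome of length L gets ceil(L / width) windows; the terminal
    window is truncated at L and flagged ``short``.  The returned frame has a
    global ``window`` index column spanning all chromosomes in input order.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    if not chrom_sizes:
        raise ValueError("empty chromosome set")
    frames = []
    offset = 0
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        starts = np.arange(0, length, width, dtype=np.int64)
        ends = np.minimum(starts + width, length)
        n = len(starts)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "window": np.arange(offset, offset + n),
                    "short": ends - starts < width,
                }
            )
        )
        offset += n
    grid = pd.concat(frames, ignore_index=True)
    return grid


def grid_chrom_sizes(grid: pd.DataFrame) -> dict[str, int]:
    """Recover the chromosome lengths a grid was built from."""
    return grid.groupby("chrom", sort=False)["end"].max().to_dict()


def count_reads(reads: pd.DataFrame, grid: pd.DataFrame) -> CountMatrix:
    """Assign read intervals to windows by midpoint and tabulate per sample.

    Parameters
    ----------
    reads :
        BED-like frame with columns chrom, start, end, sample (the BED name
        field carries the sample id).
    grid :
        Output of :func:`make_windows`.

    Each read lands in exactly one window: the one containing the midpoint
    ``(start + end) // 2``.  Reads whose midpoint falls beyond the chromosome
    end (or on an unknown chromosome) are logged and dropped; they still
    count toward the sample's library size.
    """
    required = {"chrom", "start", "end", "sample"}
    if not required.issubset(reads.columns):
        raise ValueError(f"reads frame needs columns {sorted(required)}")
    width = int((grid["end"] - grid["start"]).max())
    meta = {}
    for chrom, sub in grid.groupby("chrom", sort=False):
        meta[chrom] = (int(sub["window"].iloc[0]), int(sub["end"].max()), len(sub))

    samples = list(pd.unique(reads["sample"]))
    lib_sizes = reads["sample"].value_counts().reindex(samples).fillna(0).astype(int)

    n_windows = len(grid)
    mat = np.zeros((n_windows, len(samples)), dtype=np.int64)
    sample_pos = {s: j for j, s in enumerate(samples)}
    dropped = 0
    for chrom, sub in reads.groupby("chrom", sort=False):
        if chrom not in meta:
            dropped += len(sub)
            continue
        offset, chrom_len, n_chrom_windows = meta[chrom]
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        ok = (mid >= 0) & (mid < chrom_len)
        dropped += int((~ok).sum())
        widx = offset + np.minimum(mid[ok] // width, n_chrom_windows - 1)
        cols = np.array([sample_pos[s] for s in sub["sample"].to_numpy()[ok]])
        np.add.at(mat, (widx.astype(np.int64), cols), 1)
    if dropped:
        logger.warning("dropped %d reads outside the window grid", dropped)
    counts = pd.DataFrame(mat, index=grid["window"].to_numpy(), columns=samples)
    counts.index.name = "window"
    return CountMatrix(counts, lib_sizes)


def rpkm_normalize(cm: CountMatrix, grid: pd.DataFrame) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads.

    RPKM[w, s] = count[w, s] / (window_kb[w] * lib_size[s] / 1e6).  Uses the
    actual window length, so terminal short windows are normalized correctly.
    """
    if (cm.lib_sizes <= 0).any():
        bad = cm.lib_sizes.index[cm.lib_sizes <= 0].tolist()
        raise ValueError(f"zero/negative library size for samples {bad}")
    lengths = (
        grid.set_index("window")
        .loc[cm.counts.index, ["start", "end"]]
        .eval("end - start")
        .to_numpy()
    )
    kb = lengths / 1000.0
    per_million = cm.lib_sizes.to_numpy() / 1e6
    return cm.counts / np.outer(kb, per_million)


def select_top_windows(rpkm: pd.DataFrame, n: int = 100_000) -> pd.Index:
    """Windows with the highest mean RPKM across samples.

    Ties are broken by genomic order (the window index).  Asking for more
    windows than exist returns everything with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(rpkm):
        warnings.warn(
            f"requested top {n} windows but only {len(rpkm)} available; using all",
            stacklevel=2,
        )
        n = len(rpkm)
    mean = rpkm.mean(axis=1).to_numpy()
    order = np.lexsort((rpkm.index.to_numpy(), -mean))
    return rpkm.index[order[:n]]


def write_bed(df: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    """Write chrom/start/end (+ optional name column) as BED."""
    cols = df[["chrom", "start", "end"]].copy()
    if name_col is not None:
        cols[name_col] = df[name_col]
    cols.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, name: str | None = None) -> pd.DataFrame:
    """Read a 3- or 4-column BED file (0-based half-open)."""
    names = ["chrom", "start", "end"] + ([name] if name else [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#").iloc[:, : len(names)]
    df.columns = names
    return df
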