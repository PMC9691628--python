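"""Cross-comparison DMR overlap: pairwise counts, three-way Venn, extended
overlap against relaxed-threshold DMR sets.

The overlap relation throughout is >=1 bp genomic intersection.  Percent
overlaps are reported with the first ("strict") set as the denominator; a
member overlapping several regions of the other set still counts once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dmr_caller import DEFAULT_GAP_BP, DEFAULT_P_EXTEND, seed_and_extend

VENN_PATTERNS = ("100", "010", "001", "110", "101", "011", "111")


def _overlap_mask(set_a: pd.DataFrame, set_b: pd.DataFrame) -> np.ndarray:
    """Boolean per A-member: overlaps (>=1 bp) any B-member."""
    mask = np.zeros(len(set_a), dtype=bool)
    if set_a.empty or set_b.empty:
        return mask
    b_by_chrom = {
        chrom: sub.sort_values("start") for chrom, sub in set_b.groupby("chrom")
    }
    for pos, row in enumerate(set_a.itertuples()):
        sub = b_by_chrom.get(row.chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # B regions are internally disjoint and sorted, so it suffices to
        # check the last region starting before row.end
        i = int(np.searchsorted(starts, row.end, side="left")) - 1
        if i >= 0 and ends[i] > row.start:
            mask[pos] = True
    return mask


def interval_overlap_count(
    set_a: pd.DataFrame, set_b: pd.DataFrame
) -> tuple[int, float]:
    """How many regions of A share >=1 bp with B, and the percent of A.

    Percent is NaN when A is empty (undefined denominator).
    """
    n = int(_overlap_mask(set_a, set_b).sum())
    pct = 100.0 * n / len(set_a) if len(set_a) else float("nan")
    return n, pct


def venn3(
    set_pa: pd.DataFrame, set_walk: pd.DataFrame, set_bmi: pd.DataFrame
) -> dict[str, int]:
    """Three-way Venn region counts over DMR sets.

    Every DMR of every set is assigned a membership pattern (does it overlap
    set 1 / set 2 / set 3, its own set trivially yes) and counted once in
    that region; a set's marginal (sum of regions containing it, restricted
    to its own members) therefore equals its cardinality.
    """
    sets = (set_pa, set_walk, set_bmi)
    counts = dict.fromkeys(VENN_PATTERNS, 0)
    for i, own in enumerate(sets):
        masks = []
        for j, other in enumerate(sets):
            if j == i:
                masks.append(np.ones(len(own), dtype=bool))
            else:
                masks.append(_overlap_mask(own, other))
        for bits in zip(*masks):
            counts["".join("1" if b else "0" for b in bits)] += 1
    return counts


def extended_overlap(
    strict_a: pd.DataFrame,
    results_b: pd.DataFrame,
    p_relaxed: float = 0.05,
    p_extend: float = DEFAULT_P_EXTEND,
    gap_bp: int = DEFAULT_GAP_BP,
) -> tuple[int, float]:
    """Overlap of a strict DMR set with another comparison re-called at a
    relaxed seed threshold.

    Re-runs seed-and-extend on the full window results of comparison B with
    ``p_seed = p_relaxed`` (extension threshold never below its default),
    then counts strict-A members overlapping the relaxed B regions.
    """
    relaxed = seed_and_extend(
        results_b, p_seed=p_relaxed, p_extend=max(p_extend, p_relaxed), gap_bp=gap_bp
    )
    return interval_overlap_count(strict_a, relaxed)


def overlap_report(
    dmr_sets: dict[str, pd.DataFrame],
    results: dict[str, pd.DataFrame] | None = None,
    p_relaxed: float = 0.05,
) -> pd.DataFrame:
    """Pairwise strict and (optionally) extended overlaps for named DMR sets."""
    rows = []
    for name_a, set_a in dmr_sets.items():
        for name_b, set_b in dmr_sets.items():
            if name_a == name_b:
                continue
            n, pct = interval_overlap_count(set_a, set_b)
            row = {
                "set_a": name_a,
                "set_b": name_b,
                "n_a": len(set_a),
                "n_overlap_strict": n,
                "pct_overlap_strict": pct,
            }
            if results is not None and name_b in results:
                n_ext, pct_ext = extended_overlap(
                    set_a, results[name_b], p_relaxed=p_relaxed
                )
                row["n_overlap_extended"] = n_ext
                row["pct_overlap_extended"] = pct_ext
            rows.append(row)
    return pd.DataFrame(rows)
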