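"""Twin trait tables, discordance classification and sample-level QC.

The study design compares monozygotic (MZ) co-twins who differ on a defined
trait threshold, which controls genetic background.  Three discordance
definitions are supported:

* physical activity — one co-twin accumulates at least 150 min of moderate
  to vigorous physical activity (MVPA) per week and the other less than 150;
* neighborhood walkability — one co-twin lives in a "car dependent" or
  "somewhat walkable" neighborhood and the other in a "very walkable" or
  "walker's paradise" neighborhood (Walk Score style 0-100 categories);
* BMI — within-pair difference of at least 5 kg/m^2.

Male and female pairs are always analyzed separately; helpers here hard
partition by sex before anything statistical happens downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MVPA_THRESHOLD_MIN = 150.0
BMI_DISCORDANCE_KGM2 = 5.0
MAPPING_RATE_MIN = 0.70

#: Walk Score published categories.  The low side of the discordance rule is
#: {car dependent, somewhat walkable}; the high side {very walkable,
#: walker's paradise}.  Edges are configurable because the source analysis
#: never states them.
DEFAULT_WALK_BINS: tuple[tuple[float, float, str], ...] = (
    (0.0, 50.0, "car dependent"),
    (50.0, 70.0, "somewhat walkable"),
    (70.0, 90.0, "very walkable"),
    (90.0, 100.0, "walker's paradise"),
)
WALK_LOW_CATEGORIES = frozenset({"car dependent", "somewhat walkable"})
WALK_HIGH_CATEGORIES = frozenset({"very walkable", "walker's paradise"})

TRAIT_COLUMNS = [
    "participant_id",
    "pair_id",
    "sex",
    "mvpa_min_week",
    "walkability_score",
    "bmi",
    "waist_cm",
    "mapping_rate",
]

#: comparison key -> trait column it thresholds
COMPARISON_TRAIT = {
    "pa": "mvpa_min_week",
    "walkability": "walkability_score",
    "bmi": "bmi",
}


@dataclass(frozen=True)
class Participant:
    id: str
    pair_id: str
    sex: str
    mvpa_min_week: float
    walkability_score: float
    bmi: float
    waist_cm: float
    mapping_rate: float | None = None

    def __post_init__(self) -> None:
        if self.mvpa_min_week is not None and self.mvpa_min_week < 0:
            raise ValueError("MVPA must be non-negative")
        if not 0 <= self.walkability_score <= 100:
            raise ValueError("walkability score must be in [0, 100]")
        if self.bmi <= 0:
            raise ValueError("BMI must be positive")


@dataclass(frozen=True)
class TwinPair:
    """Exactly two same-sex members of an MZ pair."""

    pair_id: str
    members: tuple[Participant, Participant]

    def __post_init__(self) -> None:
        if len(self.members) != 2:
            raise ValueError("a twin pair has exactly two members")
        a, b = self.members
        if a.sex != b.sex:
            raise ValueError(f"pair {self.pair_id}: members differ in sex (MZ)")

    @property
    def sex(self) -> str:
        return self.members[0].sex


def build_pairs(traits: pd.DataFrame) -> list[TwinPair]:
    """Group a tidy trait table into validated twin pairs."""
    pairs = []
    for pair_id, sub in traits.groupby("pair_id", sort=True):
        if len(sub) != 2:
            raise ValueError(f"pair {pair_id} has {len(sub)} members, expected 2")
        members = tuple(
            Participant(
                id=row.participant_id,
                pair_id=pair_id,
                sex=row.sex,
                mvpa_min_week=row.mvpa_min_week,
                walkability_score=row.walkability_score,
                bmi=row.bmi,
                waist_cm=row.waist_cm,
                mapping_rate=getattr(row, "mapping_rate", None),
            )
            for row in sub.itertuples()
        )
        pairs.append(TwinPair(pair_id=pair_id, members=members))
    return pairs


def classify_pa_discordance(pair: TwinPair) -> tuple[bool, str | None, str | None]:
    """Physical-activity discordance: >=150 MVPA min/week vs <150.

    Returns (discordant, low_member_id, high_member_id); ids are None for
    concordant pairs.  Symmetric in member order.
    """
    a, b = pair.members
    if a.mvpa_min_week is None or b.mvpa_min_week is None or (
        np.isnan(a.mvpa_min_week) or np.isnan(b.mvpa_min_week)
    ):
        raise ValueError(f"pair {pair.pair_id}: missing MVPA")
    hi_a = a.mvpa_min_week >= MVPA_THRESHOLD_MIN
    hi_b = b.mvpa_min_week >= MVPA_THRESHOLD_MIN
    if hi_a == hi_b:
        return False, None, None
    low, high = (b, a) if hi_a else (a, b)
    return True, low.id, high.id


def walk_category(
    score: float, bins: Iterable[tuple[float, float, str]] = DEFAULT_WALK_BINS
) -> str:
    """Map a walkability score to its category; [low, high) bins, 100 inclusive."""
    if not 0 <= score <= 100:
        raise ValueError(f"walkability score {score} outside [0, 100]")
    for low, high, label in bins:
        if low <= score < high or (score == 100 and high == 100.0):
            return label
    raise ValueError(f"score {score} not covered by the bin map")


def classify_walkability_discordance(
    pair: TwinPair, bins: Iterable[tuple[float, float, str]] = DEFAULT_WALK_BINS
) -> tuple[bool, str | None, str | None]:
    """Discordant iff one member's category is on the low side and the
    co-twin's on the high side of the walkability scale."""
    a, b = pair.members
    cat_a = walk_category(a.walkability_score, bins)
    cat_b = walk_category(b.walkability_score, bins)
    a_low, b_low = cat_a in WALK_LOW_CATEGORIES, cat_b in WALK_LOW_CATEGORIES
    a_high, b_high = cat_a in WALK_HIGH_CATEGORIES, cat_b in WALK_HIGH_CATEGORIES
    if a_low and b_high:
        return True, a.id, b.id
    if b_low and a_high:
        return True, b.id, a.id
    return False, None, None


def classify_bmi_discordance(pair: TwinPair) -> tuple[bool, str | None, str | None]:
    """Discordant iff |BMI difference| >= 5 kg/m^2 within the pair."""
    a, b = pair.members
    if np.isnan(a.bmi) or np.isnan(b.bmi):
        raise ValueError(f"pair {pair.pair_id}: missing BMI")
    if abs(a.bmi - b.bmi) >= BMI_DISCORDANCE_KGM2:
        low, high = (a, b) if a.bmi < b.bmi else (b, a)
        return True, low.id, high.id
    return False, None, None


_CLASSIFIERS = {
    "pa": classify_pa_discordance,
    "walkability": classify_walkability_discordance,
    "bmi": classify_bmi_discordance,
}


def discordance_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-pair discordance flags and low/high arm assignment for all three
    comparisons.  One row per pair; columns ``{comp}_discordant``,
    ``{comp}_low``, ``{comp}_high``."""
    rows = []
    for pair in build_pairs(traits):
        row: dict = {"pair_id": pair.pair_id, "sex": pair.sex}
        for comp, fn in _CLASSIFIERS.items():
            try:
                flag, low, high = fn(pair)
            except ValueError as exc:  # missing trait -> pair excluded for comp
                logger.warning("pair %s excluded for %s: %s", pair.pair_id, comp, exc)
                flag, low, high = None, None, None
            row[f"{comp}_discordant"] = flag
            row[f"{comp}_low"] = low
            row[f"{comp}_high"] = high
        rows.append(row)
    return pd.DataFrame(rows)


def discordant_arms(
    traits: pd.DataFrame, comparison: str, sex: str | None = None
) -> tuple[list[str], list[str]]:
    """Low-arm and high-arm participant ids for one comparison, optionally
    restricted to one sex.  Arms are pair-matched and equally sized."""
    if comparison not in _CLASSIFIERS:
        raise ValueError(f"unknown comparison {comparison!r}")
    sub = traits if sex is None else traits[traits["sex"] == sex]
    table = discordance_table(sub)
    disc = table[table[f"{comparison}_discordant"] == True]  # noqa: E712
    return list(disc[f"{comparison}_low"]), list(disc[f"{comparison}_high"])


def apply_mapping_qc(
    traits: pd.DataFrame, min_rate: float = MAPPING_RATE_MIN
) -> pd.DataFrame:
    """Remove samples mapping below ``min_rate`` together with their co-twin.

    The retained table always contains complete pairs (even cardinality); an
    empty result is allowed and logged.
    """
    if "mapping_rate" not in traits.columns:
        raise ValueError("traits table lacks a mapping_rate column")
    rate = traits["mapping_rate"].astype(float)
    bad_pairs = set(traits.loc[rate.isna() | (rate < min_rate), "pair_id"])
    kept = traits[~traits["pair_id"].isin(bad_pairs)].copy()
    # also drop orphaned members so pairs stay intact
    sizes = kept.groupby("pair_id")["participant_id"].transform("size")
    kept = kept[sizes == 2]
    if bad_pairs:
        logger.warning(
            "mapping QC removed %d pairs (%s)", len(bad_pairs), sorted(bad_pairs)
        )
    if kept.empty:
        logger.warning("mapping QC removed every pair")
    return kept.reset_index(drop=True)


def numeric_trait_frame(traits: pd.DataFrame) -> pd.DataFrame:
    """Participant-indexed numeric trait matrix for correlation analyses.

    Continuous traits pass through; sex and per-comparison discordance flags
    are integer coded (codebook in :data:`TRAIT_CODEBOOK`).
    """
    table = discordance_table(traits).set_index("pair_id")
    df = traits.set_index("participant_id")
    out = pd.DataFrame(index=df.index)
    out["mvpa_min_week"] = df["mvpa_min_week"]
    out["walkability_score"] = df["walkability_score"]
    out["bmi"] = df["bmi"]
    out["waist_cm"] = df["waist_cm"]
    out["sex_code"] = (df["sex"] == "M").astype(int)
    for comp in _CLASSIFIERS:
        flags = table.loc[df["pair_id"], f"{comp}_discordant"]
        out[f"{comp}_discordant"] = (
            flags.fillna(False).astype(bool).astype(int).to_numpy()
        )
    return out


TRAIT_CODEBOOK: Mapping[str, Mapping[str, int]] = {
    "sex_code": {"F": 0, "M": 1},
    "pa_discordant": {"concordant": 0, "discordant": 1},
    "walkability_discordant": {"concordant": 0, "discordant": 1},
    "bmi_discordant": {"concordant": 0, "discordant": 1},
}


def load_traits(path: str | Path) -> pd.DataFrame:
    """Read a tidy one-row-per-participant traits TSV, validating the header."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"traits file {path} missing columns {missing}")
    return df


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, sep="\t", index=False, float_format="%.6g")
    codebook = Path(path).with_suffix(".codebook.json")
    codebook.write_text(json.dumps({k: dict(v) for k, v in TRAIT_CODEBOOK.items()}, indent=2))
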