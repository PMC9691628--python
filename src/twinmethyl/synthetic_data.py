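"""Synthetic twin-cohort MeDIP-seq study generator.

Generates a complete, self-consistent study — toy reference genome, window
grid with known CpG density, MZ twin cohort with trait discordance, NB
window counts with planted differential regions and latent trait-linked
modules, toy gene annotation — together with the ground truth needed to
score every downstream stage.

Statistical structure of the counts, for sample s and window w::

    count ~ NB(mean = mu_w * lib_s * exp(pair_s + delta_ws + m_ws), phi)

* ``mu_w`` — window baseline, proportional to (0.3 + 0.7 * CpG_w / mean CpG)
  times a log-normal wobble, emulating MeDIP coverage tracking CpG density;
* ``lib_s`` — per-sample library factor, uniform over +/-30%;
* ``pair_s`` — log-normal baseline shared by both co-twins of a pair
  (SD ``pair_effect_sd``).  The downstream group test is deliberately
  unpaired, so this term is a robustness stressor the analysis does NOT
  model;
* ``delta_ws`` = log2fc * ln 2 when w lies in a planted DMR and s is in the
  high arm of a pair discordant for that DMR's trait;
* ``m_ws`` — for latent-module windows, loading times a module driver
  ``d_s = sign * r * z(trait_s) + sqrt(1 - r^2) * noise``, which makes the
  module eigengene correlate ~r with its trait.

Planted DMRs never overlap latent-module windows, and planted DMRs keep a
minimum five-window buffer from each other so recovered regions stay
attributable.  Variance convention: Var = mu + phi * mu^2 (phi = 0 is
Poisson), matching the exact-test module.

Fixing ``config.seed`` fixes every output byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .window_counts import CountMatrix, make_windows

#: traits a planted DMR may be tied to (comparison keys)
DMR_TRAIT_CHOICES = ("pa", "walkability", "bmi")
#: numeric trait columns latent modules may drive
MODULE_TRAIT_CHOICES = ("mvpa_min_week", "walkability_score", "bmi")

#: published example magnitudes used for the anchored discordant pair
ANCHOR_MVPA = (66.0, 266.0)
ANCHOR_WALK = (25.7, 82.0)
ANCHOR_BMI = (28.4, 35.2)

_DMR_BUFFER_WINDOWS = 5  # keeps planted regions from chaining together


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults are the package's standard
    desk-scale study conditions (documented in the methods note)."""

    n_pairs_per_sex: int = 16
    n_chromosomes: int = 4
    chrom_length_bp: int = 2_500_000
    window_size_bp: int = 1000
    mean_depth: float = 30.0
    dispersion: float = 0.1
    pair_effect_sd: float = 0.3
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    n_planted_dmrs: int = 20
    dmr_span_windows: tuple[int, int] = (1, 5)
    dmr_log2fc: float = 2.0
    dmr_traits: tuple[str, ...] = DMR_TRAIT_CHOICES
    n_latent_modules: int = 3
    module_size_windows: int = 50
    module_trait_r: float = 0.7
    module_loading: float = 0.5
    fraction_discordant_pa: float = 0.4
    fraction_discordant_walkability: float = 0.3
    fraction_discordant_bmi: float = 0.15
    fraction_low_mapping: float = 0.0
    n_genes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size_bp <= 0:
            raise ValueError("window_size_bp must be positive")
        if self.chrom_length_bp % self.window_size_bp != 0:
            raise ValueError("chrom_length_bp must be a multiple of window_size_bp")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.module_trait_r <= 1:
            raise ValueError("module_trait_r must be in [0, 1]")
        if self.n_pairs_per_sex < 1:
            raise ValueError("need at least one pair per sex")
        lo, hi = self.dmr_span_windows
        if not 1 <= lo <= hi:
            raise ValueError("dmr_span_windows must be an increasing range >= 1")
        for t in self.dmr_traits:
            if t not in DMR_TRAIT_CHOICES:
                raise ValueError(f"unknown DMR trait {t!r}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chromosomes)
        }

    @property
    def n_windows(self) -> int:
        return self.n_chromosomes * (self.chrom_length_bp // self.window_size_bp)


@dataclass
class TruthSet:
    """Ground truth of a simulated study.

    ``planted_dmrs``: chrom, start, end, log2fc, trait (comparison key);
    spans align to window boundaries.  ``module_membership``: window index
    -> latent module id (windows absent are background).  ``trait_links``:
    module id -> (numeric trait column, sign).
    """

    planted_dmrs: pd.DataFrame
    module_membership: pd.Series
    trait_links: pd.DataFrame

    def __post_init__(self) -> None:
        mm = self.module_membership
        if mm.index.has_duplicates:
            raise ValueError("module membership must partition windows disjointly")

    def dmr_windows(self, grid: pd.DataFrame) -> set[int]:
        hits: set[int] = set()
        for row in self.planted_dmrs.itertuples():
            sub = grid[
                (grid["chrom"] == row.chrom)
                & (grid["start"] >= row.start)
                & (grid["end"] <= row.end)
            ]
            hits.update(int(w) for w in sub["window"])
        return hits

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_dmrs": self.planted_dmrs.to_dict(orient="records"),
            "module_membership": {
                str(k): int(v) for k, v in self.module_membership.items()
            },
            "trait_links": self.trait_links.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        payload = json.loads(Path(path).read_text())
        dmrs = pd.DataFrame(
            payload["planted_dmrs"],
            columns=["chrom", "start", "end", "log2fc", "trait"],
        )
        mm = pd.Series(
            {int(k): int(v) for k, v in payload["module_membership"].items()},
            dtype=int,
        )
        mm.index.name = "window"
        links = pd.DataFrame(
            payload["trait_links"], columns=["module", "trait", "sign"]
        )
        return cls(dmrs, mm, links)


@dataclass
class SyntheticStudy:
    """Bundle of everything one simulation produced."""

    config: SimulationConfig
    reference: dict[str, str]
    grid: pd.DataFrame  # window grid with a cpg column
    cohort: pd.DataFrame
    counts: CountMatrix
    truth: TruthSet
    genes: pd.DataFrame
    gene_categories: pd.DataFrame


# --------------------------------------------------------------------------
# reference + CpG density
# --------------------------------------------------------------------------

_BG_BYTES = np.frombuffer(b"ATG", dtype=np.uint8)  # no C: planted CGs stay exact


def generate_reference(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], pd.DataFrame]:
    """Toy reference with controlled per-window CpG density.

    Window backgrounds are drawn from {A, T, G} (no C), then the target
    number of CG dinucleotides is planted at distinct even offsets, so the
    written CpG count is exact by construction and target densities cycle
    over 1..10 CpG/100 bp.  A brute-force rescan of the FASTA reproduces the
    table.
    """
    grid = make_windows(config.chrom_sizes, config.window_size_bp)
    width = config.window_size_bp
    n_per_chrom = config.chrom_length_bp // width
    reference: dict[str, str] = {}
    cpg_counts = np.zeros(len(grid), dtype=int)
    target_density = (grid["window"].to_numpy() % 10) + 1  # CpG per 100 bp
    for chrom, length in config.chrom_sizes.items():
        arr = _BG_BYTES[rng.integers(0, 3, size=length)].copy()
        first = grid.index[grid["chrom"] == chrom][0]
        for k in range(n_per_chrom):
            gi = first + k
            start = k * width
            n_cpg = int(round(target_density[gi] * width / 100))
            slots = rng.choice(width // 2, size=n_cpg, replace=False) * 2 + start
            arr[slots] = ord("C")
            arr[slots + 1] = ord("G")
            cpg_counts[gi] = n_cpg
        reference[chrom] = arr.tobytes().decode("ascii")
    grid = grid.copy()
    grid["cpg"] = cpg_counts
    return reference, grid


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------


def _pick_discordant(
    rng: np.random.Generator, n_pairs: int, fraction: float
) -> np.ndarray:
    """Boolean mask of discordant pairs; pair 0 is always discordant when the
    fraction is positive, so the anchored published magnitudes appear."""
    n_disc = int(round(fraction * n_pairs))
    if fraction > 0:
        n_disc = max(1, n_disc)
    mask = np.zeros(n_pairs, dtype=bool)
    if n_disc == 0:
        return mask
    others = rng.permutation(np.arange(1, n_pairs))[: n_disc - 1]
    mask[0] = True
    mask[others] = True
    return mask


def generate_cohort(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Twin-pair trait table with configurable per-trait discordance.

    The first pair of each sex is discordant on every requested trait and
    carries the published example magnitudes (MVPA 66/266 min, walkability
    25.7/82.0, BMI 28.4/35.2), so boundary behavior of the classifiers is
    always exercised.
    """
    rows = []
    n = config.n_pairs_per_sex
    for sex in ("M", "F"):
        disc_pa = _pick_discordant(rng, n, config.fraction_discordant_pa)
        disc_walk = _pick_discordant(rng, n, config.fraction_discordant_walkability)
        disc_bmi = _pick_discordant(rng, n, config.fraction_discordant_bmi)
        low_map = _pick_discordant(rng, n, config.fraction_low_mapping) \
            if config.fraction_low_mapping > 0 else np.zeros(n, dtype=bool)
        for i in range(n):
            pair_id = f"{sex}{i + 1:02d}"
            # MVPA
            if disc_pa[i]:
                if i == 0:
                    lo, hi = ANCHOR_MVPA
                else:
                    lo = float(np.clip(rng.normal(66, 30), 0, 149))
                    hi = float(np.clip(rng.normal(266, 80), 150, 700))
                mvpa = [lo, hi]
            else:
                high_side = rng.random() < (0.5 if sex == "M" else 0.35)
                if high_side:
                    base = rng.uniform(160, 420)
                    mvpa = list(np.clip(base + rng.normal(0, 25, 2), 150, 700))
                else:
                    base = rng.uniform(10, 130)
                    mvpa = list(np.clip(base + rng.normal(0, 15, 2), 0, 149))
            # walkability
            if disc_walk[i]:
                if i == 0:
                    wlo, whi = ANCHOR_WALK
                else:
                    wlo = float(rng.uniform(5, 48))
                    whi = float(rng.uniform(71, 98))
                walk = [wlo, whi]
            else:
                if rng.random() < 0.5:
                    walk = list(rng.uniform(5, 68, 2))
                else:
                    walk = list(rng.uniform(70, 99, 2))
            # BMI
            if disc_bmi[i]:
                if i == 0:
                    blo, bhi = ANCHOR_BMI
                else:
                    blo = float(np.clip(rng.normal(26, 2.5), 19, 34))
                    bhi = blo + float(rng.uniform(5, 9))
                bmi = [blo, bhi]
            else:
                base = float(np.clip(rng.normal(27, 3.5), 19, 38))
                d = float(rng.uniform(0, 4.5))
                bmi = [base - d / 2, base + d / 2]
            # random member order so arm assignment is not positional
            order = rng.permutation(2)
            mapping = rng.uniform(0.75, 0.99, 2)
            if low_map[i]:
                mapping[rng.integers(2)] = rng.uniform(0.40, 0.69)
            for m, member in enumerate("ab"):
                k = order[m]
                b = bmi[k]
                rows.append(
                    {
                        "participant_id": f"{pair_id}{member}",
                        "pair_id": pair_id,
                        "sex": sex,
                        "mvpa_min_week": round(mvpa[k], 1),
                        "walkability_score": round(walk[k], 1),
                        "bmi": round(b, 1),
                        "waist_cm": round(
                            2.3 * b + (10 if sex == "M" else 2) + rng.normal(0, 3), 1
                        ),
                        "mapping_rate": round(float(mapping[m]), 3),
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# truth: planted DMRs and latent modules
# --------------------------------------------------------------------------


def plant_truth(
    config: SimulationConfig, grid: pd.DataFrame, rng: np.random.Generator
) -> TruthSet:
    """Choose latent-module windows and planted DMR spans.

    Module windows are scattered genome-wide; DMR spans are contiguous
    window runs that avoid module windows and keep a buffer from each other
    so recovery is unambiguous.
    """
    n_windows = len(grid)
    width = config.window_size_bp
    # latent modules: scattered windows, disjoint
    n_module_windows = config.n_latent_modules * config.module_size_windows
    if n_module_windows > n_windows // 2:
        raise ValueError("too many module windows for the genome size")
    module_windows = rng.choice(n_windows, size=n_module_windows, replace=False)
    membership = pd.Series(
        np.repeat(np.arange(config.n_latent_modules), config.module_size_windows),
        index=module_windows,
        dtype=int,
    ).sort_index()
    membership.index.name = "window"
    links = pd.DataFrame(
        {
            "module": np.arange(config.n_latent_modules),
            "trait": [
                MODULE_TRAIT_CHOICES[m % len(MODULE_TRAIT_CHOICES)]
                for m in range(config.n_latent_modules)
            ],
            "sign": [1 if m % 2 == 0 else -1 for m in range(config.n_latent_modules)],
        }
    )

    blocked = np.zeros(n_windows, dtype=bool)
    blocked[module_windows] = True
    chrom_of = grid["chrom"].to_numpy()
    start_of = grid["start"].to_numpy()
    lo, hi = config.dmr_span_windows
    records = []
    attempts = 0
    while len(records) < config.n_planted_dmrs:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place planted DMRs; genome too small")
        span = int(rng.integers(lo, hi + 1))
        w0 = int(rng.integers(0, n_windows - span + 1))
        w1 = w0 + span  # [w0, w1)
        if chrom_of[w0] != chrom_of[w1 - 1]:
            continue
        j0 = max(0, w0 - _DMR_BUFFER_WINDOWS)
        j1 = min(n_windows, w1 + _DMR_BUFFER_WINDOWS)
        if blocked[j0:j1].any():
            continue
        blocked[j0:j1] = True
        trait = config.dmr_traits[len(records) % len(config.dmr_traits)]
        records.append(
            {
                "chrom": chrom_of[w0],
                "start": int(start_of[w0]),
                "end": int(start_of[w0]) + span * width,
                "log2fc": config.dmr_log2fc,
                "trait": trait,
            }
        )
    dmrs = (
        pd.DataFrame(records, columns=["chrom", "start", "end", "log2fc", "trait"])
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )
    return TruthSet(dmrs, membership, links)


# --------------------------------------------------------------------------
# counts
# --------------------------------------------------------------------------


def generate_counts(
    config: SimulationConfig,
    grid: pd.DataFrame,
    cohort: pd.DataFrame,
    truth: TruthSet,
    rng: np.random.Generator,
) -> CountMatrix:
    """NB window counts with twin-pair baselines, planted DMR effects and
    latent trait-correlated modules.  Library size is the column sum (every
    simulated read falls in the grid)."""
    from .cohort import discordance_table  # local import avoids cycle at import time

    n_windows = len(grid)
    samples = cohort["participant_id"].tolist()
    n_samples = len(samples)

    cpg = grid["cpg"].to_numpy(dtype=float)
    mu_w = (
        config.mean_depth
        * (0.3 + 0.7 * cpg / max(cpg.mean(), 1e-9))
        * np.exp(rng.normal(0.0, 0.2, size=n_windows))
    )
    if (mu_w <= 0).any():
        raise ValueError("non-positive window mean")

    pair_ids = cohort["pair_id"].tolist()
    unique_pairs = list(dict.fromkeys(pair_ids))
    pair_fx = dict(
        zip(unique_pairs, rng.normal(0.0, config.pair_effect_sd, len(unique_pairs)))
    )
    log_sample = np.array([pair_fx[p] for p in pair_ids])
    lib_fac = rng.uniform(*config.lib_size_range, size=n_samples)

    # planted DMR effects: high arm of pairs discordant for the DMR's trait
    delta = np.zeros((n_windows, n_samples))
    arms = discordance_table(cohort)
    high_ids = {
        comp: set(arms.loc[arms[f"{comp}_discordant"] == True, f"{comp}_high"])  # noqa: E712
        for comp in DMR_TRAIT_CHOICES
    }
    sample_pos = {s: j for j, s in enumerate(samples)}
    win_index = {int(w): i for i, w in enumerate(grid["window"].to_numpy())}
    for row in truth.planted_dmrs.itertuples():
        cols = [sample_pos[s] for s in high_ids[row.trait] if s in sample_pos]
        sub = grid[
            (grid["chrom"] == row.chrom)
            & (grid["start"] >= row.start)
            & (grid["end"] <= row.end)
        ]
        rows_i = [win_index[int(w)] for w in sub["window"]]
        if cols:
            delta[np.ix_(rows_i, cols)] += row.log2fc * np.log(2)

    # latent modules: driver correlated with a numeric trait
    trait_vals = cohort.set_index("participant_id")
    r = config.module_trait_r
    for link in truth.trait_links.itertuples():
        t = trait_vals.loc[samples, link.trait].to_numpy(dtype=float)
        tz = (t - t.mean()) / (t.std() if t.std() > 0 else 1.0)
        driver = link.sign * r * tz + np.sqrt(max(0.0, 1 - r * r)) * rng.normal(
            0, 1, n_samples
        )
        members = truth.module_membership.index[
            truth.module_membership == link.module
        ]
        loadings = config.module_loading * rng.uniform(0.8, 1.2, len(members))
        rows_i = [win_index[int(w)] for w in members]
        delta[rows_i, :] += np.outer(loadings, driver)

    mean = mu_w[:, None] * lib_fac[None, :] * np.exp(log_sample[None, :] + delta)
    if config.dispersion > 0:
        r_nb = 1.0 / config.dispersion
        counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mean))
    else:
        counts = rng.poisson(mean)
    df = pd.DataFrame(counts, index=grid["window"].to_numpy(), columns=samples)
    df.index.name = "window"
    return CountMatrix(df, df.sum(axis=0))


# --------------------------------------------------------------------------
# genes + categories
# --------------------------------------------------------------------------

GENE_CATEGORIES = (
    "signaling",
    "transport",
    "transcription",
    "metabolism",
    "receptor",
    "cytoskeleton",
)


def generate_genes(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy gene models scattered over the reference plus a gene-to-category
    table for the functional-category histogram."""
    chroms = list(config.chrom_sizes)
    rows = []
    for g in range(config.n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(2_000, 50_000))
        start = int(rng.integers(0, max(1, config.chrom_length_bp - length)))
        gene_id = f"GENE{g + 1:04d}"
        rows.append(
            {
                "gene_id": gene_id,
                "symbol": gene_id,
                "chrom": chrom,
                "start": start,
                "end": start + length,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
    genes = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    cats = pd.DataFrame(
        {
            "gene": genes["gene_id"],
            "category": [
                GENE_CATEGORIES[int(rng.integers(len(GENE_CATEGORIES)))]
                for _ in range(len(genes))
            ],
        }
    )
    return genes, cats


# --------------------------------------------------------------------------
# top level + IO
# --------------------------------------------------------------------------


def simulate_study(config: SimulationConfig | None = None) -> SyntheticStudy:
    """Run the full generator under one seeded RNG stream."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    reference, grid = generate_reference(config, rng)
    cohort = generate_cohort(config, rng)
    truth = plant_truth(config, grid, rng)
    counts = generate_counts(config, grid, cohort, truth, rng)
    genes, cats = generate_genes(config, rng)
    return SyntheticStudy(config, reference, grid, cohort, counts, truth, genes, cats)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, str]:
    """Write every artifact of a study; returns a name -> path manifest.

    Formats: FASTA reference, BED window grid (cpg in the name column),
    counts TSV with library-size header, tidy traits TSV + codebook, GTF
    genes, category TSV, truth JSON.
    """
    from .cohort import write_traits

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    recs = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in study.reference.items()
    ]
    paths["reference"] = str(out / "reference.fa")
    SeqIO.write(recs, paths["reference"], "fasta")

    paths["windows"] = str(out / "windows.bed")
    study.grid[["chrom", "start", "end", "cpg"]].to_csv(
        paths["windows"], sep="\t", header=False, index=False
    )

    paths["counts"] = str(out / "counts.tsv")
    study.counts.to_tsv(paths["counts"])

    paths["traits"] = str(out / "traits.tsv")
    write_traits(study.cohort, paths["traits"])

    paths["truth"] = str(out / "truth.json")
    study.truth.to_json(paths["truth"])
    paths["truth_dmrs"] = str(out / "truth_dmrs.tsv")
    study.truth.planted_dmrs.to_csv(paths["truth_dmrs"], sep="\t", index=False)

    paths["genes"] = str(out / "genes.gtf")
    with open(paths["genes"], "w") as fh:
        for row in study.genes.itertuples():
            attrs = f'gene_id "{row.gene_id}"; gene_name "{row.symbol}";'
            fh.write(
                f"{row.chrom}\tsim\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )
    paths["gene_categories"] = str(out / "gene_categories.tsv")
    study.gene_categories.to_csv(paths["gene_categories"], sep="\t", index=False)

    paths["config"] = str(out / "sim_config.json")
    cfg = asdict(study.config)
    Path(paths["config"]).write_text(json.dumps(cfg, indent=2, default=list))
    return paths


def read_study(outdir: str | Path) -> SyntheticStudy:
    """Round-trip reader for :func:`write_study` output."""
    from .cohort import load_traits
    from .window_counts import read_bed

    out = Path(outdir)
    cfg_raw = json.loads((out / "sim_config.json").read_text())
    for key in ("lib_size_range", "dmr_span_windows", "dmr_traits"):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = SimulationConfig(**cfg_raw)

    reference = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(out / "reference.fa"), "fasta")
    }
    bed = read_bed(out / "windows.bed", name="cpg")
    grid = make_windows({c: int(bed[bed.chrom == c].end.max()) for c in bed.chrom.unique()},
                        config.window_size_bp)
    grid["cpg"] = bed["cpg"].to_numpy()
    cohort = load_traits(out / "traits.tsv")
    counts = CountMatrix.from_tsv(out / "counts.tsv")
    truth = TruthSet.from_json(out / "truth.json")
    from .annotation import read_gtf

    genes = read_gtf(out / "genes.gtf")
    cats = pd.read_csv(out / "gene_categories.tsv", sep="\t")
    return SyntheticStudy(config, reference, grid, cohort, counts, truth, genes, cats)
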