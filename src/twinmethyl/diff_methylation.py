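"""Per-window two-group negative-binomial exact test, dispersion and FDR.

The per-window test is the classic conditional NB exact test for two-group
count comparisons (the procedure popularized for read-count data): sample
counts are scaled to a common effective library size, summed within groups,
and the two-sided p-value is computed conditionally on the total
``T = sA + sB`` as the probability mass of all splits ``(a, T - a)`` no more
likely than the observed one under the null of equal per-sample means.

The NB parameterization throughout is mean/dispersion with
``Var = mu + phi * mu**2``; ``phi = 0`` is the Poisson limit, in which the
conditional test reduces exactly to the binomial exact test on
``(sA, T)`` with success probability ``nA / (nA + nB)`` (equalized
libraries).  A sum of ``n`` iid NB(mu, phi) draws is NB(n*mu, phi/n), which
is what the split enumeration uses.

Twin pairing is deliberately not modeled here: the group comparison is
unpaired, matching the source design; the simulator plants within-pair
correlation precisely so tests can show the unpaired analysis stays
calibrated under it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .window_counts import CountMatrix

#: below this dispersion the NB pmf is evaluated as its Poisson limit
#: (gammaln differences at r = 1/phi > 1e10 would otherwise lose precision)
_POISSON_PHI = 1e-10

#: relative tolerance when comparing split probabilities to the observed one
#: (floating-point ties at symmetric splits must be included)
_TIE_RTOL = 1e-12


@dataclass
class DispersionModel:
    """Common NB dispersion, optionally blended with per-window estimates.

    ``phi`` is the pooled method-of-moments estimate; ``shrinkage`` is the
    weight on the common value when per-window moments are available
    (``1.0`` = common dispersion only, the default used everywhere).
    """

    phi: float
    shrinkage: float = 1.0
    phi_per_window: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.shrinkage <= 1:
            raise ValueError("shrinkage weight must be in [0, 1]")

    def window_phi(self, i: int) -> float:
        if self.phi_per_window is None or self.shrinkage == 1.0:
            return self.phi
        return (
            self.shrinkage * self.phi
            + (1 - self.shrinkage) * self.phi_per_window[i]
        )


def _nb_logpmf(k: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """log pmf of NB(mean, dispersion) at integer k; Poisson for tiny phi."""
    k = np.asarray(k, dtype=float)
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if phi < _POISSON_PHI:
        return k * np.log(mean) - mean - gammaln(k + 1)
    r = 1.0 / phi
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1)
        + r * np.log(r / (r + mean))
        + k * np.log(mean / (r + mean))
    )


def _scale_to_common(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Scale columns to the geometric-mean library size."""
    common = np.exp(np.mean(np.log(lib_sizes)))
    return counts * (common / lib_sizes)


def exact_test_sums(
    s_a: int, s_b: int, n_a: int, n_b: int, phi: float
) -> float:
    """Conditional exact p-value for equalized group sums.

    Under the null both groups share a per-sample mean ``mu0 = T/(nA+nB)``;
    the group sums are NB(nA*mu0, phi/nA) and NB(nB*mu0, phi/nB).  The
    two-sided p is the total conditional probability of splits whose
    probability does not exceed the observed split's.
    """
    if s_a < 0 or s_b < 0:
        raise ValueError("group sums must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    total = s_a + s_b
    if total == 0:
        return 1.0
    mu0 = total / (n_a + n_b)
    a = np.arange(total + 1)
    logp = _nb_logpmf(a, n_a * mu0, phi / n_a) + _nb_logpmf(
        total - a, n_b * mu0, phi / n_b
    )
    logp -= logsumexp(logp)
    obs = logp[s_a]
    # include splits whose probability <= observed (with a tie tolerance)
    keep = logp <= obs + np.log1p(_TIE_RTOL)
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def exact_test_window(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    phi: float,
    lib_sizes_a: np.ndarray,
    lib_sizes_b: np.ndarray,
) -> tuple[float, float]:
    """Exact test for one window from raw per-sample counts.

    Counts are scaled to the common (geometric-mean) library size, group
    summed and rounded to integers for the split enumeration.  Returns
    ``(p_value, log2fc)`` where the fold change is group B over group A on
    normalized means with a 0.5 pseudo-count.
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("counts must be non-negative")
    libs = np.concatenate([lib_sizes_a, lib_sizes_b]).astype(float)
    scaled = _scale_to_common(
        np.concatenate([counts_a, counts_b]), libs
    )
    n_a, n_b = len(counts_a), len(counts_b)
    s_a = int(np.rint(scaled[:n_a].sum()))
    s_b = int(np.rint(scaled[n_a:].sum()))
    p = exact_test_sums(s_a, s_b, n_a, n_b, phi)
    log2fc = float(np.log2((s_b / n_b + 0.5) / (s_a / n_a + 0.5)))
    if s_a + s_b == 0:
        log2fc = 0.0
    return p, log2fc


def estimate_common_dispersion(
    cm: CountMatrix,
    groups: tuple[list[str], list[str]],
    phi_override: float | None = None,
) -> DispersionModel:
    """Pooled method-of-moments common dispersion on library-scaled counts.

    Within each group the per-window sample mean m and variance v satisfy
    ``E[v - m] = phi * m**2`` under the NB model, so the pooled estimate is
    ``sum(v - m) / sum(m**2)`` across windows and groups, floored at zero.
    With a single sample per group the moments are undefined and a
    ``phi_override`` must be supplied.
    """
    if phi_override is not None:
        return DispersionModel(phi=max(0.0, float(phi_override)))
    group_a, group_b = groups
    usable = [g for g in (group_a, group_b) if len(g) >= 2]
    if not usable:
        raise ValueError(
            "need >=2 samples in at least one group to estimate dispersion "
            "(or supply phi_override)"
        )
    num = 0.0
    den = 0.0
    per_window = np.zeros(cm.n_windows)
    per_den = np.zeros(cm.n_windows)
    for g in usable:
        sub = cm.counts[g].to_numpy(dtype=float)
        scaled = _scale_to_common(sub, cm.lib_sizes[g].to_numpy(dtype=float))
        m = scaled.mean(axis=1)
        v = scaled.var(axis=1, ddof=1)
        num += float((v - m).sum())
        den += float((m**2).sum())
        per_window += v - m
        per_den += m**2
    phi = max(0.0, num / den) if den > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pw = np.where(per_den > 0, np.maximum(0.0, per_window / per_den), phi)
    return DispersionModel(phi=phi, phi_per_window=pw)


def test_all_windows(
    cm: CountMatrix,
    groups: tuple[list[str], list[str]],
    model: DispersionModel | None = None,
    grid: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the exact test on every window of a count matrix.

    ``groups`` is (group A ids, group B ids) — by pipeline convention the
    low and high discordance arms, so positive log2fc means higher coverage
    in the high arm.  Degenerate windows (total scaled count 0) are kept as
    p = 1 rows rather than dropped.

    Returns a frame with window, p, q (BH), log2fc, mean_a, mean_b — plus
    chrom/start/end when a grid is given.
    """
    group_a, group_b = groups
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if model is None:
        model = estimate_common_dispersion(cm, groups)
    sub = cm.counts[list(group_a) + list(group_b)].to_numpy(dtype=float)
    libs = cm.lib_sizes[list(group_a) + list(group_b)].to_numpy(dtype=float)
    scaled = _scale_to_common(sub, libs)
    n_a, n_b = len(group_a), len(group_b)
    s_a = np.rint(scaled[:, :n_a].sum(axis=1)).astype(np.int64)
    s_b = np.rint(scaled[:, n_a:].sum(axis=1)).astype(np.int64)

    p = np.empty(cm.n_windows)
    cache: dict[tuple[int, int, float], float] = {}
    for i in range(cm.n_windows):
        phi = model.window_phi(i)
        key = (int(s_a[i]), int(s_b[i]), phi)
        if key not in cache:
            cache[key] = exact_test_sums(key[0], key[1], n_a, n_b, phi)
        p[i] = cache[key]
    mean_a = s_a / n_a
    mean_b = s_b / n_b
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    log2fc[(s_a + s_b) == 0] = 0.0
    out = pd.DataFrame(
        {
            "window": cm.counts.index.to_numpy(),
            "p": p,
            "q": bh_fdr(p),
            "log2fc": log2fc,
            "mean_a": mean_a,
            "mean_b": mean_b,
        }
    )
    if grid is not None:
        coords = grid.set_index("window").loc[out["window"], ["chrom", "start", "end"]]
        out = pd.concat([coords.reset_index(drop=True), out], axis=1)
        out = out[["chrom", "start", "end", "window", "p", "q", "log2fc", "mean_a", "mean_b"]]
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p-rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
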