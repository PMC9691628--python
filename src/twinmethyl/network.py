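"""Weighted correlation network analysis of methylation window profiles.

From a samples x windows profile matrix (RPKM over the top windows by mean
coverage) the stage builds an unsigned weighted network, clusters windows
into modules and correlates module eigengenes with participant traits:

* adjacency  a_ij = |cor(x_i, x_j)|**beta (soft threshold beta, default 6
  for female runs and 9 for male runs);
* topological overlap  TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
  with l_ij = sum_u a_iu a_uj over u != i, j and connectivity
  k_i = sum_u a_iu; dissimilarity 1 - TOM drives average-linkage
  hierarchical clustering;
* module detection selects dendrogram branches that have at least
  ``min_module_size`` members, complete below the 0.99 quantile of merge
  heights, and are separated from the rest of the tree by a real branch
  gap (at least ``min_branch_depth``); nested candidates resolve to the
  branch with the largest gap (the module core), and everything else is
  grey.  This is the package's simplified stand-in for the reference
  dynamic tree cut: structureless dendrograms have no branch gaps, so
  noise yields no modules;
* the module eigengene is the first left singular vector of the z-scored
  member profiles (sign fixed so its mean correlation with members is
  positive); modules whose eigengene dissimilarity 1 - cor falls below
  ``merge_cut_height`` (default 0.25) are merged iteratively to a fixed
  point;
* module-trait association is the Pearson correlation of eigengene and
  trait across samples with the two-sided Student-t p-value on n - 2
  degrees of freedom (all samples treated as independent: twin pairing is
  deliberately ignored at this stage).

Large problems are handled blockwise: windows are pre-clustered into blocks
of at most ``max_block_size`` (k-means on their sample-space profiles),
modules are detected per block and then merged across blocks by eigengene
similarity.

:class:`CorrelationNetworkModules` wraps the whole stage as a
scikit-learn-style estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

GREY = -1  # unassigned-window label

#: reference-style module color names, assigned to modules by decreasing size
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white",
)


@dataclass
class NetworkConfig:
    """Tunable parameters of the network stage (defaults follow the study)."""

    power: float = 6.0  # 6 female / 9 male
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    max_block_size: int = 15_000
    top_n: int = 100_000
    cut_quantile: float = 0.99
    min_branch_depth: float = 0.005
    root_cut_height: float = 0.97
    random_state: int | None = 0

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


def adjacency(profiles: np.ndarray, power: float) -> tuple[np.ndarray, np.ndarray]:
    """Unsigned adjacency |cor|^beta between window profiles.

    ``profiles`` is samples x windows.  Zero-variance windows cannot be
    correlated; they are dropped with a warning.  Returns (adjacency over
    kept windows, integer indices of kept windows).
    """
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    var = X.var(axis=0)
    kept = np.flatnonzero(var > 0)
    if len(kept) < X.shape[1]:
        warnings.warn(
            f"dropped {X.shape[1] - len(kept)} zero-variance windows", stacklevel=2
        )
    cor = np.corrcoef(X[:, kept], rowvar=False)
    A = np.abs(cor) ** power
    np.fill_diagonal(A, 1.0)
    return A, kept


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1]."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    n = A.shape[0]
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=1)
    # l_ij = sum_{u != i,j} a_iu a_uj  (off-diagonal A removes u == i, j terms)
    L = off @ off
    num = L + off
    den = np.minimum.outer(k, k) + 1.0 - off
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    tom = np.clip(tom, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    diss: np.ndarray,
    min_module_size: int = 30,
    cut_quantile: float = 0.99,
    min_branch_depth: float = 0.005,
    root_cut_height: float = 0.97,
) -> np.ndarray:
    """Average-linkage clustering of a TOM dissimilarity into modules.

    A dendrogram branch becomes a module when (i) it has at least
    ``min_module_size`` leaves, (ii) it completes below the
    ``cut_quantile`` quantile of merge heights, and (iii) there is a real
    gap between the height at which the branch completes and the height at
    which it merges with anything else (at least ``min_branch_depth``
    dissimilarity units).  The gap requirement is what separates genuine
    co-methylation blocks — which finish merging early and only join the
    background near the top of the tree — from arbitrary chunks of a
    structureless dendrogram, whose merge heights form a continuum; cutting
    such a tree at any height produces clusters with essentially zero
    branch gap, which are demoted to grey.  Among nested qualifying
    branches the one with the largest gap wins, so a module core is
    preferred over the same core with stray background leaves attached;
    windows outside the selected cores stay grey (there is no post-hoc
    reassignment step).

    The dendrogram root has no parent to measure a gap against, so it is
    admitted as a single all-encompassing module only when the whole input
    is globally tight: its completing merge must lie below
    ``root_cut_height`` on the absolute TOM-dissimilarity scale (a
    structureless network completes at dissimilarity ~1).  This matters for
    blockwise runs, where a block can consist entirely of one module.

    Labels are 0..k-1 ordered by decreasing module size; grey is -1.
    """
    diss = np.asarray(diss, dtype=float)
    n = diss.shape[0]
    if n < min_module_size:
        warnings.warn("fewer windows than min_module_size; all grey", stacklevel=2)
        return np.full(n, GREY)
    Z = linkage(squareform(diss, checks=False), method="average")
    heights = Z[:, 2]
    cut = float(np.quantile(heights, cut_quantile))

    # per-node bookkeeping: leaves are 0..n-1, internal node of step i is n+i
    n_nodes = 2 * n - 1
    form = np.zeros(n_nodes)  # height at which the node's cluster completes
    size = np.ones(n_nodes, dtype=int)
    parent_h = np.full(n_nodes, np.inf)  # height where the node joins others
    children = np.full((n_nodes, 2), -1, dtype=int)
    for i, (a, b, h, _) in enumerate(Z):
        node = n + i
        a, b = int(a), int(b)
        form[node] = h
        size[node] = size[a] + size[b]
        children[node] = (a, b)
        parent_h[a] = parent_h[b] = h

    def branch_gap(node: int) -> float | None:
        """Qualification gap of a node, or None if it is not a module
        candidate.  The root's gap is -inf: it is a fallback only."""
        if node < n or size[node] < min_module_size:
            return None
        if np.isinf(parent_h[node]):  # the root: needs global tightness
            return -np.inf if form[node] <= root_cut_height else None
        if form[node] <= cut and parent_h[node] - form[node] >= min_branch_depth:
            return float(parent_h[node] - form[node])
        return None

    # Bottom-up selection of dominant branches.  Along a nested chain of
    # qualifying nodes the one with the largest gap wins, so a module core
    # is preferred over the same core with stray background leaves
    # attached.  Once two disjoint branches are selected in a subtree they
    # are final — their union is the merge step's decision, not the cut's.
    selected: list[int] = []
    # state per node: None | ("open", candidate_node, gap) | "closed"
    state: list = [None] * n_nodes
    for node in range(n, n_nodes):
        a, b = children[node]
        sa, sb = state[a], state[b]
        if sa is not None and sb is not None:
            for s in (sa, sb):
                if s != "closed":
                    selected.append(s[1])
            state[node] = "closed"
            continue
        s = sa if sa is not None else sb
        g = branch_gap(node)
        if s == "closed" or g is None:
            state[node] = s
        elif s is None or s[2] < g:
            state[node] = ("open", node, g)
        else:
            state[node] = s
    root_state = state[n_nodes - 1]
    if root_state not in (None, "closed"):
        selected.append(root_state[1])

    labels = np.full(n, GREY)
    members_of = []
    for node in selected:
        leaves = []
        sub = [node]
        while sub:
            x = sub.pop()
            if x < n:
                leaves.append(x)
            else:
                sub.extend(children[x])
        members_of.append(np.array(sorted(leaves)))
    members_of.sort(key=lambda m: (-len(m), int(m[0])))
    for new, members in enumerate(members_of):
        labels[members] = new
    return labels


def module_eigengene(profiles: np.ndarray) -> np.ndarray:
    """First left singular vector of z-scored member profiles.

    ``profiles`` is samples x members.  Each member is standardized across
    samples (ddof=1); the returned eigengene has unit norm and its sign is
    fixed so the mean correlation with member profiles is non-negative.  A
    single-member module yields that profile standardized and normalized.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("module must be non-empty")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance member profile")
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    e = U[:, 0]
    if (e @ Z).sum() < 0:
        e = -e
    return e


def eigengene_matrix(
    profiles: np.ndarray, labels: np.ndarray, names: list | None = None
) -> pd.DataFrame:
    """Samples x modules eigengene matrix (grey excluded)."""
    mods = sorted(set(labels) - {GREY})
    cols = {}
    for m in mods:
        cols[m if names is None else names[m]] = module_eigengene(
            profiles[:, labels == m]
        )
    return pd.DataFrame(cols)


def merge_modules(
    profiles: np.ndarray,
    labels: np.ndarray,
    merge_cut_height: float = 0.25,
) -> np.ndarray:
    """Iteratively merge modules with similar eigengenes.

    The closest pair of eigengenes (largest correlation) is merged whenever
    its dissimilarity 1 - cor is below ``merge_cut_height``; eigengenes are
    recomputed after every merge, so chains collapse to a fixed point.
    """
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {GREY})
        if len(mods) < 2:
            break
        me = eigengene_matrix(profiles, labels)
        cor = np.corrcoef(me.to_numpy(), rowvar=False)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_cut_height:
            break
        keep, absorb = sorted((mods[i], mods[j]))
        labels[labels == absorb] = keep
    return _relabel_by_size(labels)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    mods = sorted(set(labels) - {GREY})

    def sort_key(m):
        members = np.flatnonzero(labels == m)
        return (-len(members), int(members[0]))

    out = np.full(len(labels), GREY)
    for new, m in enumerate(sorted(mods, key=sort_key)):
        out[labels == m] = new
    return out


def module_colors(labels: np.ndarray) -> np.ndarray:
    """Human-readable color names for integer module labels (grey = -1)."""
    def color(m):
        if m == GREY:
            return "grey"
        return MODULE_COLORS[m] if m < len(MODULE_COLORS) else f"module_{m}"

    return np.array([color(m) for m in labels], dtype=object)


@dataclass
class ModuleTraitResult:
    """Module x trait Pearson correlations with Student-t p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_samples: int

    def filtered(self, p_filter: float = 0.001) -> "ModuleTraitResult":
        """Drop modules (rows) and traits (columns) with no correlation at
        p < p_filter."""
        keep_rows = (self.p < p_filter).any(axis=1)
        keep_cols = (self.p < p_filter).any(axis=0)
        return ModuleTraitResult(
            self.r.loc[keep_rows, keep_cols],
            self.p.loc[keep_rows, keep_cols],
            self.n_samples,
        )


def cor_pvalue_student(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation via the Student-t transform
    t = r * sqrt(n - 2) / sqrt(1 - r**2) on n - 2 degrees of freedom."""
    if n < 4:
        raise ValueError("need n >= 4 samples")
    if np.isnan(r):
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    p_filter: float = 0.001,
) -> tuple[ModuleTraitResult, ModuleTraitResult]:
    """Correlate every module eigengene with every numeric trait.

    Constant traits have undefined correlation and are reported NaN.
    Returns (full matrix, p < ``p_filter`` filtered view).
    """
    n = len(eigengenes)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if len(traits) != n:
        raise ValueError("eigengenes and traits must cover the same samples")
    r = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    for mod in eigengenes.columns:
        e = eigengenes[mod].to_numpy(dtype=float)
        for trait in traits.columns:
            t = traits[trait].to_numpy(dtype=float)
            if np.std(t) == 0 or np.std(e) == 0:
                r.loc[mod, trait] = np.nan
                p.loc[mod, trait] = np.nan
                continue
            rv = float(np.corrcoef(e, t)[0, 1])
            r.loc[mod, trait] = rv
            p.loc[mod, trait] = cor_pvalue_student(rv, n)
    full = ModuleTraitResult(r, p, n)
    return full, full.filtered(p_filter)


def _partition_blocks(
    X: np.ndarray, max_block_size: int, random_state: int | None
) -> list[np.ndarray]:
    """Pre-cluster windows (as points in sample space) into blocks of at most
    max_block_size, splitting oversize k-means clusters recursively."""
    n = X.shape[1]
    if n <= max_block_size:
        return [np.arange(n)]
    k = int(np.ceil(n / max_block_size))
    pts = ((X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))).T
    km = KMeans(n_clusters=k, n_init=4, random_state=random_state).fit(pts)
    blocks = []
    for lab in range(k):
        idx = np.flatnonzero(km.labels_ == lab)
        if len(idx) == 0:
            continue
        if len(idx) > max_block_size:
            for sub in _partition_blocks(
                X[:, idx], max_block_size, None if random_state is None else random_state + 1
            ):
                blocks.append(idx[sub])
        else:
            blocks.append(idx)
    return blocks


def blockwise_modules(
    profiles: np.ndarray, config: NetworkConfig | None = None
) -> np.ndarray:
    """Full module detection: (blockwise) adjacency -> TOM -> clustering ->
    eigengene merging.  Returns per-window labels (grey = -1); windows
    dropped for zero variance are grey."""
    cfg = config or NetworkConfig()
    X = np.asarray(profiles, dtype=float)
    n = X.shape[1]
    labels = np.full(n, GREY)
    A_all, kept = adjacency(X, cfg.power)
    Xk = X[:, kept]
    blocks = _partition_blocks(Xk, cfg.max_block_size, cfg.random_state)
    kept_labels = np.full(len(kept), GREY)
    offset = 0
    for block in sorted(blocks, key=lambda b: b[0]):
        A = A_all[np.ix_(block, block)] if len(blocks) > 1 else A_all
        tom = tom_similarity(A)
        bl = detect_modules(
            1.0 - tom,
            min_module_size=cfg.min_module_size,
            cut_quantile=cfg.cut_quantile,
            min_branch_depth=cfg.min_branch_depth,
            root_cut_height=cfg.root_cut_height,
        )
        assigned = bl != GREY
        kept_labels[block[assigned]] = bl[assigned] + offset
        if assigned.any():
            offset = kept_labels.max() + 1
    kept_labels = merge_modules(Xk, kept_labels, cfg.merge_cut_height)
    labels[kept] = kept_labels
    return labels


class CorrelationNetworkModules(BaseEstimator):
    """scikit-learn style estimator for the correlation-network stage.

    fit(X) clusters the columns (windows) of a samples x windows matrix
    into coexpression-style modules; ``fit_transform`` returns the samples
    x modules eigengene matrix, so the estimator composes with sklearn
    pipelines as a feature reducer.

    Attributes set by fit: ``labels_`` (per window; -1 = unassigned),
    ``module_colors_``, ``n_modules_``, ``eigengenes_``.
    """

    def __init__(
        self,
        power: float = 6.0,
        min_module_size: int = 30,
        merge_cut_height: float = 0.25,
        max_block_size: int = 15_000,
        cut_quantile: float = 0.99,
        min_branch_depth: float = 0.005,
        root_cut_height: float = 0.97,
        random_state: int | None = 0,
    ):
        self.power = power
        self.min_module_size = min_module_size
        self.merge_cut_height = merge_cut_height
        self.max_block_size = max_block_size
        self.cut_quantile = cut_quantile
        self.min_branch_depth = min_branch_depth
        self.root_cut_height = root_cut_height
        self.random_state = random_state

    def _config(self) -> NetworkConfig:
        return NetworkConfig(
            power=self.power,
            min_module_size=self.min_module_size,
            merge_cut_height=self.merge_cut_height,
            max_block_size=self.max_block_size,
            cut_quantile=self.cut_quantile,
            min_branch_depth=self.min_branch_depth,
            root_cut_height=self.root_cut_height,
            random_state=self.random_state,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.labels_ = blockwise_modules(X, self._config())
        self.module_colors_ = module_colors(self.labels_)
        self.n_modules_ = int(len(set(self.labels_) - {GREY}))
        names = [MODULE_COLORS[m] if m < len(MODULE_COLORS) else f"module_{m}"
                 for m in range(self.n_modules_)]
        self.eigengenes_ = eigengene_matrix(X, self.labels_, names=names)
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).eigengenes_.to_numpy()
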