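"""Non-parametric multivariate workflow for environmental sample tables.

The analysis chain mirrors the standard community-ecology toolkit:
square-root transform right-skewed covariates, normalise each variable to
zero mean and unit variance, build a Euclidean resemblance matrix, ordinate
(PCA, non-metric MDS), cluster hierarchically with similarity-profile
(SIMPROF) permutation tests as the stopping rule, screen single variables
with Spearman rank correlation, and search variable subsets whose
resemblance pattern best matches that of the response (the BEST / BIOENV
procedure with a global permutation test).

SIMPROF and BEST are implemented here in full: both are permutation
procedures on resemblance matrices and take explicit seeds; no hidden
global random state is used.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DEFAULT_SQRT_VARS",
    "DEFAULT_RESEMBLANCE_VARS",
    "ResemblanceMatrix",
    "SimprofNodeTest",
    "ClusterPartition",
    "BestResult",
    "transform_env",
    "normalize_env",
    "euclidean_resemblance",
    "pca",
    "nmds",
    "simprof_test",
    "cluster_simprof",
    "spearman_screen",
    "best_match",
]

#: right-skewed covariates square-root transformed before normalisation
DEFAULT_SQRT_VARS = ("salinity", "temperature", "chla", "NO3", "PO4")
#: covariates entering the resemblance matrix by default; location
#: (latitude, longitude, julian_day) and Boolean method flags are excluded
#: unless explicitly requested, since they inflate between-study distances
#: and cannot enter predictive algorithms.
DEFAULT_RESEMBLANCE_VARS = (
    "temperature", "salinity", "NO3", "PO4", "chla", "Kd", "zeta",
)


# ---------------------------------------------------------------------------
# resemblance construction


@dataclass(frozen=True)
class ResemblanceMatrix:
    """Symmetric Euclidean distance matrix among samples."""

    values: np.ndarray
    labels: list

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("resemblance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count must match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("resemblance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("resemblance matrix must have a zero diagonal")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def condensed(self) -> np.ndarray:
        """Lower-triangle distances in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def transform_env(
    table: pd.DataFrame, sqrt_vars: Sequence[str] = DEFAULT_SQRT_VARS
) -> pd.DataFrame:
    """Square-root transform the listed variables (variance stabilisation).

    Variables absent from the table are ignored; a negative value in a
    listed variable is an error (the transform targets non-negative,
    right-skewed covariates).
    """
    out = table.copy()
    for var in sqrt_vars:
        if var not in out.columns:
            continue
        col = out[var].astype(float)
        if (col.dropna() < 0).any():
            raise ValueError(f"negative value in sqrt-transform variable {var!r}")
        out[var] = np.sqrt(col)
    return out


def normalize_env(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Normalise each variable to mean 0 and SD 1 (SD denominator n-1).

    A constant column cannot be normalised and raises an error naming it.
    Missing values are ignored in the mean/SD and propagate unchanged.
    """
    out = table.copy()
    cols = list(columns) if columns is not None else [
        c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])
    ]
    for c in cols:
        col = out[c].astype(float)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot normalise constant column {c!r}")
        out[c] = (col - col.mean()) / sd
    return out


def euclidean_resemblance(
    table: pd.DataFrame, variables: Sequence[str] | None = None
) -> ResemblanceMatrix:
    """Euclidean distances between all sample pairs over the given variables.

    Rows with missing values among the selected variables are dropped
    (complete-case) with a warning stating how many.
    """
    variables = list(variables) if variables is not None else list(table.columns)
    sub = table[variables]
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        warnings.warn(f"dropped {dropped} incomplete rows from resemblance", stacklevel=2)
    if len(complete) < 2:
        raise ValueError("need at least 2 complete rows for a resemblance matrix")
    d = squareform(pdist(complete.to_numpy(dtype=float), metric="euclidean"))
    return ResemblanceMatrix(values=d, labels=list(complete.index))


# ---------------------------------------------------------------------------
# ordination


def pca(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Principal component analysis of a normalised variable table.

    Returns ``(loadings, variance_fractions, scores)``. Loadings columns
    are orthonormal eigenvectors with a fixed sign convention (the
    largest-magnitude loading of each component is positive). Warns when
    n <= p (degenerate smallest components).
    """
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        warnings.warn(f"n={n} <= p={p}: PCA is rank degenerate", stacklevel=2)
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt.T.copy()
    # sign convention: largest-|loading| entry positive per component
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
    fractions = s**2 / np.sum(s**2)
    pcs = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    scores = Xc @ loadings
    return (
        pd.DataFrame(loadings, index=table.columns, columns=pcs),
        fractions,
        pd.DataFrame(scores, index=table.index, columns=pcs),
    )


def _kruskal_stress1(dist_condensed: np.ndarray, embedding: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding against target dissimilarities."""
    from sklearn.isotonic import IsotonicRegression

    d_embed = pdist(embedding)
    order = np.argsort(dist_condensed, kind="stable")
    iso = IsotonicRegression()
    disparities = np.empty_like(d_embed)
    disparities[order] = iso.fit_transform(np.arange(order.size), d_embed[order])
    denom = float(np.sum(d_embed**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d_embed - disparities) ** 2) / denom))


def nmds(
    dist: ResemblanceMatrix,
    dims: int = 2,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 300,
) -> tuple[pd.DataFrame, float]:
    """Non-metric multidimensional scaling of a resemblance matrix.

    Runs ``n_restarts`` random starts of SMACOF non-metric scaling and
    returns the configuration with the lowest Kruskal stress-1 as
    ``(configuration, stress)``. Deterministic for a given seed.
    """
    from sklearn.manifold import MDS

    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best_conf, best_stress = None, np.inf
    cond = dist.condensed
    for _ in range(n_restarts):
        mds = MDS(
            n_components=dims, metric="precomputed", metric_mds=False,
            init="random", n_init=1, max_iter=max_iter,
            random_state=int(rng.integers(2**31 - 1)),
            normalized_stress=True, eps=1e-9,
        )
        conf = mds.fit_transform(dist.values)
        stress = _kruskal_stress1(cond, conf)
        if stress < best_stress:
            best_conf, best_stress = conf, stress
    cols = [f"MDS{i + 1}" for i in range(dims)]
    return pd.DataFrame(best_conf, index=dist.labels, columns=cols), best_stress


# ---------------------------------------------------------------------------
# SIMPROF-gated hierarchical clustering


@dataclass(frozen=True)
class SimprofNodeTest:
    """Result of one similarity-profile test at a dendrogram node."""

    node_id: int
    n: int
    pi: float
    p_value: float
    split: bool
    reason: str = "tested"  # {'tested', 'too_small', 'leaf'}


@dataclass(frozen=True)
class ClusterPartition:
    """SIMPROF-gated grouping: dendrogram plus per-node test results."""

    linkage: np.ndarray
    labels: list
    groups: pd.Series          #: sample label -> group id (1-based)
    tests: list[SimprofNodeTest] = field(default_factory=list)
    alpha: float = 0.005

    @property
    def n_groups(self) -> int:
        return int(self.groups.nunique())

    def to_newick(self) -> str:
        """Nested-parenthesis text rendering of the dendrogram."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node):
            if node.is_leaf():
                return str(self.labels[node.id])
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.4g}"

        return walk(tree) + ";"


def _permute_columns(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each column independently across rows (the SIMPROF null)."""
    idx = np.argsort(rng.random(X.shape), axis=0)
    return np.take_along_axis(X, idx, axis=0)


def _sorted_profile(X: np.ndarray) -> np.ndarray:
    return np.sort(pdist(X))


def simprof_test(
    X: np.ndarray,
    n_perm_profile: int = 999,
    n_perm_null: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Similarity-profile permutation test for multivariate structure.

    The observed profile is the ordered vector of pairwise Euclidean
    distances among the rows of ``X``. Under the null of no structure each
    variable's values are exchangeable across samples, so a mean null
    profile is built from ``n_perm_profile`` independent column
    permutations; the statistic pi is the summed absolute departure of a
    profile from that mean profile. ``n_perm_null`` further permutations
    give the null distribution of pi, and
    p = (#(pi_null >= pi_obs) + 1) / (n_perm_null + 1).

    Returns ``(pi, p_value)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("SIMPROF needs at least 3 samples")
    obs = _sorted_profile(X)
    mean_profile = np.zeros_like(obs)
    for _ in range(n_perm_profile):
        mean_profile += _sorted_profile(_permute_columns(X, rng))
    mean_profile /= n_perm_profile
    pi_obs = float(np.abs(obs - mean_profile).sum())
    null = np.empty(n_perm_null)
    for i in range(n_perm_null):
        null[i] = np.abs(_sorted_profile(_permute_columns(X, rng)) - mean_profile).sum()
    p = (np.count_nonzero(null >= pi_obs) + 1) / (n_perm_null + 1)
    return pi_obs, float(p)


def cluster_simprof(
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    alpha: float = 0.005,
    n_perm_profile: int = 999,
    n_perm_null: int = 999,
    seed: int | None = None,
    linkage_method: str = "average",
) -> ClusterPartition:
    """Hierarchical clustering with SIMPROF tests as the stopping rule.

    A group-average (UPGMA) dendrogram is built on Euclidean distances
    over the (already transformed/normalised) ``variables``; the tree is
    then traversed top-down and a node is split into its children only
    when its SIMPROF p-value falls below ``alpha`` (default 0.005). Nodes
    with fewer than 3 samples are terminal by construction. Because the
    permutation operates on the variables, the variable table — not just
    the resemblance matrix — is required.
    """
    variables = list(variables) if variables is not None else list(table.columns)
    data = table[variables].dropna()
    X = data.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 complete rows")
    rng = np.random.default_rng(seed)
    Z = hierarchy.linkage(pdist(X), method=linkage_method)
    tree = hierarchy.to_tree(Z)
    labels = list(data.index)

    groups = np.zeros(X.shape[0], dtype=int)
    tests: list[SimprofNodeTest] = []
    next_group = itertools.count(1)

    def assign(node, gid):
        groups[node.pre_order(lambda leaf: leaf.id)] = gid

    stack = [tree]
    while stack:
        node = stack.pop()
        members = node.pre_order(lambda leaf: leaf.id)
        if node.is_leaf():
            tests.append(SimprofNodeTest(node.id, 1, 0.0, 1.0, False, "leaf"))
            assign(node, next(next_group))
            continue
        if len(members) < 3:
            tests.append(SimprofNodeTest(node.id, len(members), 0.0, 1.0, False, "too_small"))
            assign(node, next(next_group))
            continue
        pi, p = simprof_test(X[members], n_perm_profile, n_perm_null, rng)
        split = p < alpha
        tests.append(SimprofNodeTest(node.id, len(members), pi, p, split))
        if split:
            stack.append(node.right)
            stack.append(node.left)
        else:
            assign(node, next(next_group))

    # renumber groups in order of first appearance for stable output
    seen: dict[int, int] = {}
    renumbered = np.array([seen.setdefault(g, len(seen) + 1) for g in groups])
    return ClusterPartition(
        linkage=Z, labels=labels,
        groups=pd.Series(renumbered, index=labels, name="cluster"),
        tests=tests, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# variable screening and subset selection


def spearman_screen(
    table: pd.DataFrame,
    response: str = "phi_ec",
    predictors: Sequence[str] | None = None,
    group: str | None = None,
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman rank correlation of each predictor against the response.

    Computed per group when ``group`` names a column (e.g. ``study_id``)
    plus a pooled "global" row set. Returns a tidy frame with columns
    group, variable, rho, p_value, n, sig_05, sig_01. Variables with all
    tied values (rho undefined) report NaN. Ties are handled by average
    ranks (scipy default).
    """
    preds = list(predictors) if predictors is not None else [
        c for c in table.columns
        if c != response and c != group and pd.api.types.is_numeric_dtype(table[c])
    ]
    groupings: list[tuple[str, pd.DataFrame]] = [("global", table)]
    if group is not None:
        groupings += [(str(g), sub) for g, sub in table.groupby(group, sort=True)]
    rows = []
    for gname, sub in groupings:
        for var in preds:
            pair = sub[[var, response]].dropna()
            n = len(pair)
            if n < min_n:
                rows.append((gname, var, np.nan, np.nan, n))
                continue
            x = pair[var].to_numpy(dtype=float)
            y = pair[response].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rows.append((gname, var, np.nan, np.nan, n))
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append((gname, var, float(rho), float(p), n))
    out = pd.DataFrame(rows, columns=["group", "variable", "rho", "p_value", "n"])
    out["sig_05"] = out["p_value"] < 0.05
    out["sig_01"] = out["p_value"] < 0.01
    return out


@dataclass(frozen=True)
class BestResult:
    """Outcome of the BEST/BIOENV subset search with its global test."""

    best_subset: tuple[str, ...]
    rho: float
    p_value: float
    table: pd.DataFrame  #: all searched subsets ranked by rho
    n_perm: int


def _subset_rho(env: np.ndarray, cols: tuple[int, ...], phi_ranks: np.ndarray) -> float:
    d = pdist(env[:, cols])
    r = stats.rankdata(d)
    rc = r - r.mean()
    pc = phi_ranks - phi_ranks.mean()
    denom = np.sqrt(np.sum(rc**2) * np.sum(pc**2))
    if denom == 0:
        return 0.0
    return float(np.sum(rc * pc) / denom)


def best_match(
    env_table: pd.DataFrame,
    phi_values: Sequence[float] | pd.Series,
    max_subset_size: int = 5,
    n_perm: int = 99,
    seed: int | None = None,
    subset_cap: int = 2**15,
) -> BestResult:
    """BEST/BIOENV: which environmental variable subset best matches Phi_e,C?

    For every non-empty subset of columns of ``env_table`` (normalised
    scale) up to ``max_subset_size``, the Euclidean resemblance among
    samples on that subset is rank-correlated (Spearman) against the
    Euclidean resemblance built from the scalar Phi_e,C values; the
    best subset maximises rho. Global significance: the sample labels of
    the environmental table are permuted ``n_perm`` times (default 99) and
    the full subset search repeated, giving the null distribution of the
    maximal rho; p = (#(rho_perm >= rho_obs) + 1)/(n_perm + 1), assessed
    at p < 0.01 by convention.
    """
    env = env_table.dropna()
    phi = pd.Series(np.asarray(phi_values, dtype=float), index=env_table.index)
    phi = phi.loc[env.index]
    if phi.isna().any():
        keep = phi.notna()
        env, phi = env[keep], phi[keep]
    X = env.to_numpy(dtype=float)
    n, p = X.shape
    if n < 4:
        raise ValueError("need at least 4 complete samples")

    k_max = min(max_subset_size, p)
    subsets = [
        cols
        for r in range(1, k_max + 1)
        for cols in itertools.combinations(range(p), r)
    ]
    if len(subsets) > subset_cap:
        raise ValueError(
            f"{len(subsets)} subsets exceeds cap {subset_cap}; lower max_subset_size"
        )

    phi_d = pdist(phi.to_numpy().reshape(-1, 1))
    phi_ranks = stats.rankdata(phi_d)

    rhos = np.array([_subset_rho(X, cols, phi_ranks) for cols in subsets])
    best_i = int(np.argmax(rhos))
    rho_obs = float(rhos[best_i])

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        Xp = X[rng.permutation(n)]
        rho_perm = max(_subset_rho(Xp, cols, phi_ranks) for cols in subsets)
        if rho_perm >= rho_obs:
            exceed += 1
    p_value = (exceed + 1) / (n_perm + 1)

    names = list(env.columns)
    tab = pd.DataFrame(
        {
            "subset": [tuple(names[i] for i in cols) for cols in subsets],
            "size": [len(cols) for cols in subsets],
            "rho": rhos,
        }
    ).sort_values("rho", ascending=False, ignore_index=True)
    return BestResult(
        best_subset=tuple(names[i] for i in subsets[best_i]),
        rho=rho_obs, p_value=float(p_value), table=tab, n_perm=n_perm,
    )
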