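"""Recursive model-based clustering of samples into subtypes.

Samples are represented over the candidate-gene union (by default the
binary mutated/not profile; raw or log counts by option) and clustered with diagonal-covariance Gaussian mixtures fitted by EM.
The number of components at each node is chosen by BIC (Mclust sign
convention, maximized: 2 logL - n_params ln n). Clustering is applied
recursively: each selected component becomes a child node and is clustered
again, until (a) BIC selects a single component, (b) the largest child would
hold more than ``dominant_fraction`` (default 95%) of the node's samples --
in which case the split is discarded and the node kept as a leaf, treating
the residual children as outliers -- (c) the node is smaller than
``min_node``, or (d) a depth limit is reached. Leaves are the subtypes,
labelled C1..Cn in depth-first order.

EM numerical details: k-means++ seeding of the component means, several
seeded restarts keeping the best log-likelihood, and a variance floor. For
integer-valued representations the floor is at least 1/12 (the variance of
rounding to the integer grid): a diagonal Gaussian narrower than one count
bin is meaningless, and without this floor BIC rewards degenerate
single-feature splits on discrete data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .io_profiles import CohortMatrix

LOG2PI = float(np.log(2.0 * np.pi))


def build_features(
    matrix: CohortMatrix,
    candidate_genes: list[str],
    representation: str = "binary",
) -> pd.DataFrame:
    """Sample x candidate-gene feature matrix.

    representation: 'binary' (mutated or not, the default), 'counts'
    (raw mutation counts), or 'log1p' (ln(1 + count)).
    """
    if not candidate_genes:
        raise ValueError("candidate gene set is empty")
    missing = [g for g in candidate_genes if g not in matrix.counts.columns]
    if missing:
        raise KeyError(f"candidate genes not in matrix: {missing[:5]}...")
    X = matrix.counts[list(candidate_genes)].astype(float)
    if representation == "counts":
        return X
    if representation == "binary":
        return (X > 0).astype(float)
    if representation == "log1p":
        return np.log1p(X)
    raise ValueError(f"unknown representation {representation!r}")


@dataclass
class GmmModel:
    """A fitted diagonal/spherical Gaussian mixture."""

    K: int
    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    variances: np.ndarray  # (K, d)
    log_likelihood: float
    bic: float
    n_params: int
    ll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """Per-sample, per-component weighted log densities (n, K)."""
        X = np.atleast_2d(X)
        n, d = X.shape
        out = np.empty((n, self.K))
        for k in range(self.K):
            v = self.variances[k]
            out[:, k] = (np.log(self.weights[k])
                         - 0.5 * np.sum(np.log(v) + LOG2PI)
                         - 0.5 * np.sum((X - self.means[k]) ** 2 / v, axis=1))
        return out

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        """Posterior component memberships; rows sum to 1."""
        logd = self.log_density(X)
        return np.exp(logd - logsumexp(logd, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.log_density(X), axis=1)


def _n_params(K: int, d: int, covariance: str) -> int:
    var_params = d if covariance == "diagonal" else 1
    return (K - 1) + K * d + K * var_params


def _floor(var: np.ndarray, var_floor: float) -> np.ndarray:
    return np.maximum(var, var_floor)


def default_var_floor(X: np.ndarray, rel: float = 1e-6) -> float:
    """Variance floor: rel x mean overall feature variance, but at least 1/12
    when the data are integer-valued (discreteness floor)."""
    overall = float(np.mean(np.var(X, axis=0)))
    floor = rel * max(overall, 1e-12)
    if np.allclose(X, np.round(X)):
        floor = max(floor, 1.0 / 12.0)
    return floor


def _em_once(
    X: np.ndarray,
    K: int,
    covariance: str,
    max_iter: int,
    tol: float,
    var_floor: float,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    n, d = X.shape
    means, _ = kmeans_plusplus(
        X, n_clusters=K, random_state=int(rng.integers(2**31 - 1)))
    overall = np.var(X, axis=0)
    if covariance == "spherical":
        var = np.full((K, d), max(float(overall.mean()), var_floor))
    else:
        var = np.tile(_floor(overall, var_floor), (K, 1))
    weights = np.full(K, 1.0 / K)

    trace = []
    prev = -np.inf
    converged = False
    model = GmmModel(K, weights, means, var, -np.inf, np.nan, 0)
    for _ in range(max_iter):
        logd = model.log_density(X)
        norm = logsumexp(logd, axis=1)
        ll = float(norm.sum())
        if not np.isfinite(ll):
            return -np.inf, weights, means, var, np.array(trace), False
        trace.append(ll)
        resp = np.exp(logd - norm[:, None])
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        if covariance == "diagonal":
            sq = (resp.T @ (X * X)) / nk[:, None] - means**2
            var = _floor(sq, var_floor)
        else:
            sq = ((resp.T @ (X * X)) / nk[:, None] - means**2).mean(axis=1)
            var = _floor(np.tile(sq[:, None], (1, X.shape[1])), var_floor)
        model = GmmModel(K, weights, means, var, ll, np.nan, 0)
        if ll - prev < tol * max(1.0, abs(ll)) and ll >= prev:
            converged = True
            break
        prev = ll
    logd = model.log_density(X)
    ll = float(logsumexp(logd, axis=1).sum())
    trace.append(ll)
    return ll, weights, means, var, np.array(trace), converged


def fit_gmm(
    X: np.ndarray | pd.DataFrame,
    K: int,
    covariance: str = "diagonal",
    restarts: int = 5,
    max_iter: int = 300,
    tol: float = 1e-7,
    var_floor: float | None = None,
    seed: int = 0,
) -> GmmModel:
    """Fit a K-component Gaussian mixture by seeded multi-restart EM.

    The best log-likelihood across restarts is kept; within each run the
    log-likelihood is nondecreasing. K=1 is handled in closed form (mean =
    sample mean, variance = floored sample variance).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one feature")
    n, d = X.shape
    if n < K:
        raise ValueError(f"n_samples={n} < K={K}")
    if covariance not in ("diagonal", "spherical"):
        raise ValueError("covariance must be 'diagonal' or 'spherical'")
    if var_floor is None:
        var_floor = default_var_floor(X)

    if K == 1:
        mean = X.mean(axis=0, keepdims=True)
        if covariance == "diagonal":
            var = _floor(X.var(axis=0, keepdims=True), var_floor)
        else:
            var = np.full((1, d), max(float(X.var(axis=0).mean()), var_floor))
        ll = float(-0.5 * np.sum(np.log(var) + LOG2PI)) * n
        ll += float(-0.5 * np.sum((X - mean) ** 2 / var))
        np_ = _n_params(1, d, covariance)
        return GmmModel(1, np.ones(1), mean, var, ll,
                        2 * ll - np_ * np.log(n), np_,
                        ll_trace=np.array([ll]))

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        ll, w, m, v, trace, conv = _em_once(
            X, K, covariance, max_iter, tol, var_floor, rng)
        if np.isfinite(ll) and (best is None or ll > best[0]):
            best = (ll, w, m, v, trace, conv)
    if best is None:
        raise RuntimeError("EM failed to produce a finite likelihood "
                           f"after {restarts} restarts")
    ll, w, m, v, trace, conv = best
    np_ = _n_params(K, d, covariance)
    return GmmModel(K, w, m, v, ll, 2 * ll - np_ * np.log(n), np_,
                    ll_trace=trace, converged=conv)


def select_k_by_bic(
    X: np.ndarray | pd.DataFrame,
    k_max: int = 9,
    k_min: int = 1,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[GmmModel, pd.DataFrame]:
    """Fit K = k_min..k_max and return the BIC-maximal model plus the trace.

    BIC follows the Mclust sign convention (2 logL - n_params ln n,
    maximized). Exact ties are broken toward smaller K.
    """
    X = np.asarray(X, dtype=float)
    k_top = min(k_max, X.shape[0])
    best: GmmModel | None = None
    rows = []
    for K in range(k_min, k_top + 1):
        try:
            model = fit_gmm(X, K, seed=seed + K, **fit_kwargs)
        except (ValueError, RuntimeError):
            continue
        rows.append({"K": K, "log_likelihood": model.log_likelihood,
                     "bic": model.bic, "n_params": model.n_params})
        if best is None or model.bic > best.bic:  # strict: ties keep smaller K
            best = model
    if best is None:
        raise RuntimeError("all mixture fits failed")
    return best, pd.DataFrame(rows)


def dominant_child_fraction(child_sizes: np.ndarray | list[int]) -> float:
    """Fraction of the parent's samples held by the largest child."""
    sizes = np.asarray(child_sizes, dtype=float)
    return float(sizes.max() / sizes.sum())


@dataclass
class ClusterConfig:
    """Knobs of the recursive clustering, with the study's defaults."""

    k_max: int = 9
    dominant_fraction: float = 0.95
    min_node: int = 20
    max_depth: int | None = None
    representation: str = "binary"
    covariance: str = "diagonal"
    restarts: int = 5
    max_iter: int = 300
    tol: float = 1e-7
    var_floor: float | None = None
    seed: int = 0


@dataclass
class TreeNode:
    id: str
    sample_ids: list[str]
    depth: int
    model: GmmModel | None = None
    bic_trace: pd.DataFrame | None = None
    children: list["TreeNode"] = field(default_factory=list)
    leaf_reason: str | None = None
    label: str | None = None  # subtype label, leaves only

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class SubtypeTree:
    """Recursive clustering tree; leaves carry subtype labels C1..Cn."""

    root: TreeNode
    config: ClusterConfig

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def to_dict(self) -> dict:
        def walk(node: TreeNode) -> dict:
            d = {
                "id": node.id,
                "n_samples": len(node.sample_ids),
                "depth": node.depth,
                "leaf_reason": node.leaf_reason,
                "label": node.label,
                "children": [walk(c) for c in node.children],
            }
            if node.bic_trace is not None:
                d["bic_trace"] = node.bic_trace.to_dict(orient="list")
            if node.is_leaf:
                d["sample_ids"] = list(node.sample_ids)
            return d

        return walk(self.root)


def recursive_cluster(
    features: pd.DataFrame, config: ClusterConfig | None = None
) -> SubtypeTree:
    """Grow the subtype tree by recursive BIC-selected mixture splits."""
    if features.empty:
        raise ValueError("feature matrix is empty")
    config = config or ClusterConfig()
    X_all = features.to_numpy(dtype=float)
    var_floor = (config.var_floor if config.var_floor is not None
                 else default_var_floor(X_all))
    master = np.random.SeedSequence(config.seed)

    def split(node: TreeNode, seed_seq: np.random.SeedSequence) -> None:
        n = len(node.sample_ids)
        if n < config.min_node:
            node.leaf_reason = "min_node"
            return
        if config.max_depth is not None and node.depth >= config.max_depth:
            node.leaf_reason = "max_depth"
            return
        X = features.loc[node.sample_ids].to_numpy(dtype=float)
        node_seed = int(seed_seq.generate_state(1)[0] % (2**31 - 1))
        model, trace = select_k_by_bic(
            X, k_max=config.k_max, seed=node_seed,
            covariance=config.covariance, restarts=config.restarts,
            max_iter=config.max_iter, tol=config.tol, var_floor=var_floor)
        node.model = model
        node.bic_trace = trace
        if model.K == 1:
            node.leaf_reason = "bic_k1"
            return
        assign = model.predict(X)
        sizes = np.bincount(assign, minlength=model.K)
        occupied = np.flatnonzero(sizes > 0)
        if len(occupied) < 2:
            node.leaf_reason = "bic_k1"
            return
        if dominant_child_fraction(sizes[occupied]) > config.dominant_fraction:
            # the split is a dominant child plus residual outlier clusters:
            # discard it and keep the node as a subtype
            node.leaf_reason = "dominant_child"
            return
        ids = np.asarray(node.sample_ids)
        children_seeds = seed_seq.spawn(len(occupied))
        for ci, k in enumerate(occupied):
            child = TreeNode(
                id=f"{node.id}.{ci + 1}",
                sample_ids=list(ids[assign == k]),
                depth=node.depth + 1,
            )
            node.children.append(child)
        for child, s in zip(node.children, children_seeds):
            split(child, s)

    root = TreeNode(id="1", sample_ids=list(features.index), depth=0)
    split(root, master)
    tree = SubtypeTree(root=root, config=config)
    for i, leaf in enumerate(tree.leaves()):
        leaf.label = f"C{i + 1}"
    return tree


def label_samples(tree: SubtypeTree) -> pd.Series:
    """sample_id -> subtype label (C1..Cn, leaves in depth-first order)."""
    leaves = tree.leaves()
    if any(leaf.label is None for leaf in leaves):
        raise ValueError("tree is not finalized: leaves lack labels")
    mapping: dict[str, str] = {}
    for leaf in leaves:
        for s in leaf.sample_ids:
            mapping[s] = leaf.label
    return pd.Series(mapping, name="subtype").reindex(tree.root.sample_ids)
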