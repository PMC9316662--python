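"""Mutational-signature extraction by non-negative matrix factorization.

Per-sample 96-channel trinucleotide substitution catalogs (whole-genome,
mitochondria excluded) are factorized as M ~ W H with W a 96 x N
column-stochastic signature matrix and H the per-sample exposures. NMF is
fitted with multiplicative updates minimizing the Frobenius error (KL
available by flag); the number of signatures N is chosen over a declared
range by combining an error elbow (second difference of the reconstruction
error) with a bootstrap stability score (silhouette-like mean cosine of
optimally matched signatures across resampled fits). Extracted signatures
are matched to reference (COSMIC-style) catalogs by angular similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io_profiles import (
    MITOCHONDRIAL,
    MOTIF_CLASSES,
    MutationRecord,
    extract_motif,
)

_EPS = 1e-12


def build_motif_matrix(
    records: list[MutationRecord], reference
) -> tuple[pd.DataFrame, int]:
    """Tally genome-wide SNVs into a sample x 96 motif-count matrix.

    Mitochondrial records are excluded (their mutational processes differ
    and reference catalogs are nuclear). Returns (matrix, n_skipped) where
    skipped records had unresolvable contexts. Row sums equal each sample's
    retained SNV count.
    """
    samples = sorted({r.sample_id for r in records})
    counts = pd.DataFrame(0, index=samples, columns=list(MOTIF_CLASSES),
                          dtype=np.int64)
    skipped = 0
    for rec in records:
        if rec.chromosome in MITOCHONDRIAL:
            skipped += 1
            continue
        try:
            idx = extract_motif(rec, reference)
        except ValueError:
            skipped += 1
            continue
        counts.iloc[counts.index.get_loc(rec.sample_id), idx] += 1
    return counts, skipped


def nmf(
    M: np.ndarray,
    N: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    objective: str = "frobenius",
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Multiplicative-update NMF: M (d x n) ~ W (d x N) H (N x n).

    Returns (W, H, relative_error, objective_trace). The objective is
    nonincreasing across iterations; W is renormalized column-stochastic
    with H rescaled compensatingly, so W@H is unchanged.
    """
    M = np.asarray(M, dtype=float)
    if (M < 0).any():
        raise ValueError("M must be nonnegative")
    if M.sum() == 0:
        raise ValueError("M is all zero")
    d, n = M.shape
    if not 1 <= N <= min(d, n):
        raise ValueError(f"N must lie in [1, {min(d, n)}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(M.mean() / N)
    W = rng.random((d, N)) * scale + _EPS
    H = rng.random((N, n)) * scale + _EPS

    def frob(Wc, Hc):
        return float(np.linalg.norm(M - Wc @ Hc, "fro") ** 2)

    def kl(Wc, Hc):
        R = Wc @ Hc
        return float(np.sum(M * (np.log((M + _EPS) / (R + _EPS))) - M + R))

    obj = frob if objective == "frobenius" else kl
    if objective not in ("frobenius", "kl"):
        raise ValueError("objective must be 'frobenius' or 'kl'")
    trace = [obj(W, H)]
    for _ in range(max_iter):
        if objective == "frobenius":
            H *= (W.T @ M) / (W.T @ W @ H + _EPS)
            W *= (M @ H.T) / (W @ H @ H.T + _EPS)
        else:
            R = W @ H + _EPS
            H *= (W.T @ (M / R)) / (W.sum(axis=0)[:, None] + _EPS)
            R = W @ H + _EPS
            W *= ((M / R) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        trace.append(obj(W, H))
        if trace[-2] - trace[-1] <= tol * max(trace[0], _EPS):
            break
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    W = W / col
    H = H * col[:, None]
    rel = float(np.linalg.norm(M - W @ H, "fro") / np.linalg.norm(M, "fro"))
    return W, H, rel, np.asarray(trace)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(np.dot(u, v) / (nu * nv))


def match_signatures(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal 1-1 cosine matching of signature sets (columns of A, B).

    Returns (permutation of B's columns matched to A's, matched cosines).
    """
    ka, kb = A.shape[1], B.shape[1]
    sim = np.zeros((ka, kb))
    for i in range(ka):
        for j in range(kb):
            sim[i, j] = cosine_similarity(A[:, i], B[:, j])
    rows, cols = linear_sum_assignment(-np.nan_to_num(sim, nan=-1.0))
    return cols, sim[rows, cols]


@dataclass
class SignatureSet:
    """Extracted signatures for one sample group (e.g. a subtype)."""

    label: str
    W: pd.DataFrame  # 96 x N, column-stochastic
    H: pd.DataFrame  # N x samples, exposures
    chosen_N: int
    metrics: pd.DataFrame  # per-N reconstruction error and stability
    reconstruction_error: float

    @property
    def signature_names(self) -> list[str]:
        return list(self.W.columns)


def select_num_signatures(
    M: pd.DataFrame | np.ndarray,
    n_range: tuple[int, int] = (2, 15),
    n_boot: int = 5,
    restarts: int = 3,
    stability_threshold: float = 0.8,
    seed: int = 0,
    max_iter: int = 400,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of signatures by error elbow plus stability.

    For each N in the range: the reconstruction error is averaged over
    bootstrap resamples of the samples, and stability is the mean cosine of
    optimally matched signatures between restarted fits and a reference fit
    (a silhouette-like cohesion score). The chosen N maximizes the second
    difference of the error curve (the elbow) among N whose stability
    reaches ``stability_threshold``; if none qualifies, the most stable N
    wins. The full metric trace is returned for manual override.
    """
    M = np.asarray(M, dtype=float).T if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=float)
    # internal orientation: channels x samples
    if M.shape[0] != 96 and M.shape[1] == 96:
        M = M.T
    d, n = M.shape
    lo, hi = n_range
    hi = min(hi, min(d, n) - 1)
    if hi < lo:
        raise ValueError("not enough samples for the requested N range")
    rng = np.random.default_rng(seed)
    rows = []
    for N in range(lo, hi + 1):
        W_ref, _, err_ref, _ = nmf(M, N, seed=int(rng.integers(2**31 - 1)),
                                   max_iter=max_iter)
        cosines = []
        for _ in range(restarts):
            W_r, _, err_r, _ = nmf(M, N, seed=int(rng.integers(2**31 - 1)),
                                   max_iter=max_iter)
            err_ref = min(err_ref, err_r)
            _, matched = match_signatures(W_ref, W_r)
            cosines.extend(matched)
        errs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Mb = M[:, idx]
            if Mb.sum() == 0:
                continue
            _, _, err_b, _ = nmf(Mb, N, seed=int(rng.integers(2**31 - 1)),
                                 max_iter=max_iter)
            errs.append(err_b)
        rows.append({
            "N": N,
            "reconstruction_error": err_ref,
            "bootstrap_error": float(np.mean(errs)) if errs else np.nan,
            "stability": float(np.nanmean(cosines)),
        })
    metrics = pd.DataFrame(rows)
    err = metrics["bootstrap_error"].fillna(
        metrics["reconstruction_error"]).to_numpy()
    curvature = np.full(len(metrics), -np.inf)
    if len(metrics) >= 3:
        curvature[1:-1] = err[:-2] - 2 * err[1:-1] + err[2:]
    elif len(metrics) > 0:
        curvature[:] = 0.0
    metrics["elbow_curvature"] = curvature
    stable = metrics["stability"] >= stability_threshold
    pool = metrics[stable] if stable.any() else metrics
    if stable.any():
        chosen = int(pool.loc[pool["elbow_curvature"].idxmax(), "N"])
    else:
        chosen = int(pool.loc[pool["stability"].idxmax(), "N"])
    return chosen, metrics


def extract_signatures(
    motif_matrix: pd.DataFrame,
    label: str,
    n_range: tuple[int, int] = (2, 15),
    seed: int = 0,
    **select_kwargs,
) -> SignatureSet:
    """Full per-group extraction: choose N, fit, package the SignatureSet."""
    M = motif_matrix.to_numpy(dtype=float).T  # channels x samples
    chosen, metrics = select_num_signatures(
        M, n_range=n_range, seed=seed, **select_kwargs)
    W, H, err, _ = nmf(M, chosen, seed=seed)
    names = [f"{label}.S{j + 1}" for j in range(chosen)]
    return SignatureSet(
        label=label,
        W=pd.DataFrame(W, index=list(MOTIF_CLASSES), columns=names),
        H=pd.DataFrame(H, index=names, columns=list(motif_matrix.index)),
        chosen_N=chosen,
        metrics=metrics,
        reconstruction_error=err,
    )


def load_reference_signatures(path) -> pd.DataFrame:
    """Read a COSMIC-format signature TSV: 96 rows x named columns.

    The first column holds the motif class ("A[C>A]A" style); rows are
    reordered to the canonical channel order and columns normalized to sum
    to 1.
    """
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    df = df.set_index(type_col)
    missing = set(MOTIF_CLASSES) - set(df.index)
    if missing:
        raise ValueError(f"reference is missing channels, e.g. {sorted(missing)[:3]}")
    df = df.loc[list(MOTIF_CLASSES)].astype(float)
    return df / df.sum(axis=0)


def angular_similarity(
    W: pd.DataFrame, reference: pd.DataFrame, form: str = "cosine"
) -> pd.DataFrame:
    """Similarity of extracted signatures (columns of W) to references.

    ``form='cosine'`` (the field's standard) gives the cosine of the two
    96-vectors, in [0, 1] for nonnegative inputs; ``form='angular'`` gives
    1 - theta/pi. Zero vectors yield NaN.
    """
    if list(W.index) != list(MOTIF_CLASSES) or list(reference.index) != list(MOTIF_CLASSES):
        raise ValueError("signature matrices must use the canonical 96-channel order")
    out = pd.DataFrame(index=W.columns, columns=reference.columns, dtype=float)
    for ours in W.columns:
        for ref in reference.columns:
            c = cosine_similarity(W[ours].to_numpy(), reference[ref].to_numpy())
            if form == "angular" and not np.isnan(c):
                c = 1.0 - np.arccos(np.clip(c, -1.0, 1.0)) / np.pi
            out.loc[ours, ref] = c
    return out
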