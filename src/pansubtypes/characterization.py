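"""Per-subtype descriptive and inferential statistics.

Covers the mutational-load profiles, one-vs-rest Fisher tests for genes and
gene-motifs with ranked top lists, overlap matrices between subtypes'
top-100 lists, and consequence-type frequency tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_profiles import CohortMatrix, MutationRecord, extract_motif, MOTIF_CLASSES


def mutational_load(
    matrix: CohortMatrix, labels: pd.Series, min_mutations: int = 1
) -> pd.DataFrame:
    """Gene x subtype fraction of samples with >= min_mutations in the gene.

    min_mutations=1 is the headline load; min_mutations=3 is the
    at-least-three-mutations variant used to separate look-alike subtypes.
    """
    if min_mutations < 1:
        raise ValueError("min_mutations must be >= 1")
    labels = labels.reindex(matrix.sample_ids)
    if labels.isna().any():
        raise ValueError("labels must cover every sample in the matrix")
    out = {}
    for subtype, idx in sorted(labels.groupby(labels).groups.items()):
        if len(idx) == 0:
            raise ValueError(f"subtype {subtype!r} is empty")
        sub = matrix.counts.loc[list(idx)]
        out[subtype] = (sub >= min_mutations).mean(axis=0)
    return pd.DataFrame(out)


@dataclass(frozen=True)
class Contingency2x2:
    """One-vs-rest 2x2 table: (in-subtype, out-subtype) x (mutated, not)."""

    a: int  # in-subtype, mutated
    b: int  # in-subtype, unmutated
    c: int  # out-subtype, mutated
    d: int  # out-subtype, unmutated

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")


def fisher_exact(
    table: Contingency2x2, alternative: str = "greater"
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table; returns (p_value, odds_ratio).

    The p-value comes from the exact (hypergeometric) conditional
    distribution. The odds ratio is the sample odds ratio ad/bc, reported as
    NaN when undefined (a zero margin) and inf when only bc = 0.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b + c + d == 0:
        return 1.0, float("nan")
    alt = {"greater": "greater", "two_sided": "two-sided"}.get(alternative)
    if alt is None:
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alt)
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    return float(p), odds


def _rank_key(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic top-list order: p asc, odds desc (NaN last), id asc."""
    key = df.copy()
    key["_odds_sort"] = -key["odds_ratio"].fillna(-np.inf)
    return key.sort_values(
        ["p_value", "_odds_sort", "feature"], kind="mergesort"
    ).drop(columns="_odds_sort")


def subtype_feature_tests(
    presence: pd.DataFrame,
    labels: pd.Series,
    top: int = 100,
    alternative: str = "greater",
) -> dict[str, pd.DataFrame]:
    """One-vs-rest Fisher tests of every feature in every subtype.

    ``presence`` is a sample x feature 0/1 matrix (a sample "has" a feature
    if it carries >= 1 qualifying mutation); features may be genes or
    (gene, motif-class) pairs. Returns one ranked table per subtype,
    truncated to ``top`` rows, ordered by p-value, then descending odds
    ratio, then feature id.
    """
    labels = labels.reindex(presence.index)
    if labels.isna().any():
        raise ValueError("labels must cover every sample")
    subtypes = sorted(labels.unique())
    if len(subtypes) < 2:
        raise ValueError("need >= 2 subtypes for one-vs-rest tests")
    pres = (presence.to_numpy() > 0).astype(np.int64)
    n = pres.shape[0]
    col_tot = pres.sum(axis=0)
    out: dict[str, pd.DataFrame] = {}
    for subtype in subtypes:
        mask = (labels == subtype).to_numpy()
        n_in = int(mask.sum())
        a = pres[mask].sum(axis=0)
        b = n_in - a
        c = col_tot - a
        d = (n - n_in) - c
        # P(X >= a) with X ~ Hypergeom(N=n, K=col_tot, n=n_in)
        if alternative == "greater":
            p = stats.hypergeom.sf(a - 1, n, col_tot, n_in)
        elif alternative == "two_sided":
            p = np.array([
                fisher_exact(Contingency2x2(*t), "two_sided")[0]
                for t in zip(a, b, c, d)
            ])
        else:
            raise ValueError("alternative must be 'greater' or 'two_sided'")
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c)
        odds = np.where((b * c == 0) & (a * d > 0), np.inf, odds)
        odds = np.where((b * c == 0) & (a * d == 0), np.nan, odds)
        df = pd.DataFrame({
            "feature": presence.columns,
            "a": a, "b": b, "c": c, "d": d,
            "p_value": np.clip(p, 0.0, 1.0),
            "odds_ratio": odds,
        })
        out[subtype] = _rank_key(df).head(top).reset_index(drop=True)
    return out


def pairwise_overlap(toplists: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Subtype x subtype counts of shared top-list features.

    Symmetric with the list length on the diagonal.
    """
    if len(toplists) < 2:
        raise ValueError("need at least two top lists")
    names = sorted(toplists)
    sets = {s: set(toplists[s]["feature"]) for s in names}
    mat = pd.DataFrame(0, index=names, columns=names, dtype=np.int64)
    for i in names:
        for j in names:
            mat.loc[i, j] = len(sets[i] & sets[j])
    return mat


def build_gene_motif_presence(
    records: list[MutationRecord],
    reference,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Sample x (gene, motif-class) presence matrix.

    A feature "GENE|A[C>T]G" is present in a sample if the sample carries at
    least one mutation of that trinucleotide class in that gene. Records
    whose motif cannot be resolved (ambiguous flank) are skipped.
    """
    keep = set(genes) if genes is not None else None
    cells: set[tuple[str, str]] = set()
    for rec in records:
        if keep is not None and rec.gene_id not in keep:
            continue
        try:
            idx = extract_motif(rec, reference)
        except ValueError:
            continue
        cells.add((rec.sample_id, f"{rec.gene_id}|{MOTIF_CLASSES[idx]}"))
    if not cells:
        return pd.DataFrame(dtype=np.int64)
    df = pd.DataFrame(sorted(cells), columns=["sample_id", "feature"])
    df["x"] = 1
    return df.pivot_table(index="sample_id", columns="feature", values="x",
                          fill_value=0).astype(np.int64)


def consequence_frequencies(
    records: list[MutationRecord],
    labels: pd.Series,
    impact_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Subtype x consequence-type fraction table; rows sum to 1.

    Consequence strings absent from ``impact_map`` (including empty ones)
    are binned as "Unavailable".
    """
    impact_map = impact_map or {}
    rows = []
    for rec in records:
        subtype = labels.get(rec.sample_id)
        if subtype is None:
            raise ValueError(f"sample {rec.sample_id!r} has no subtype label")
        cons = rec.consequence if rec.consequence in impact_map else "Unavailable"
        rows.append((subtype, cons))
    df = pd.DataFrame(rows, columns=["subtype", "consequence"])
    table = pd.crosstab(df["subtype"], df["consequence"], normalize="index")
    return table.sort_index()


def load_impact_map(path) -> dict[str, str]:
    """Read a consequence -> impact TSV (Ensembl-style)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["consequence"], df["impact"]))
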