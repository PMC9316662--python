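"""Local gene-set over-representation analysis.

Each subtype's top gene list is tested against user-supplied GMT collections
with the hypergeometric upper tail, then Benjamini-Hochberg corrected across
all terms of the collection. Terms with FDR (q) below 0.05 are flagged
significant. The universe defaults to the full coding-gene catalog of the
run, not the candidate union, so terms are not biased toward the selection
itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. one ontology branch or pathway source)."""

    sets: dict[str, frozenset[str]]
    domain: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, domain: str = "") -> GeneSetCollection:
    """Parse a GMT file (term, description, members...).

    Duplicate members within a set are collapsed; an empty member list or a
    repeated set name is an error naming the line.
    """
    sets: dict[str, frozenset[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
            raise ValueError(f"{path}:{i}: GMT line needs a name, description "
                             "and at least one member")
        name = parts[0]
        if name in sets:
            raise ValueError(f"{path}:{i}: duplicate set name {name!r}")
        members = frozenset(p for p in parts[2:] if p.strip())
        sets[name] = members
    return GeneSetCollection(sets=sets, domain=domain)


def enrich(
    query: list[str],
    collection: GeneSetCollection,
    universe: list[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each set.

    Sets are intersected with the universe before testing; the p-value is
    P(X >= k) for the overlap k. BH correction runs across all terms of the
    collection. Zero-overlap terms are reported with p = 1 and never
    flagged significant. Results are sorted by q then p then term.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe is empty")
    q_set = set(query)
    if not q_set <= uni:
        raise ValueError("query must be a subset of the universe")
    N = len(uni)
    n_query = len(q_set)
    rows = []
    for term, members in sorted(collection.sets.items()):
        m = members & uni
        k = len(m & q_set)
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, len(m), n_query))
        rows.append({
            "term": term, "overlap": k, "set_size": len(m),
            "query_size": n_query, "universe_size": N, "p_value": p,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q_value=[], significant=[])
    _, qvals, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["q_value"] = qvals
    df["significant"] = (df["q_value"] < fdr_threshold) & (df["overlap"] > 0)
    return df.sort_values(["q_value", "p_value", "term"],
                          kind="mergesort").reset_index(drop=True)
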