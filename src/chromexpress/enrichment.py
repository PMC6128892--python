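"""Hypergeometric enrichment of DE gene lists and generic term enrichment.

The question for each (DE direction, expression class) cell: drawing
``n`` genes (the DE list) without replacement from a universe of ``N``
classified genes of which ``K`` belong to the class, how surprising is an
overlap of at least ``k``?  The upper-tail p-value P(X >= k) is exact;
significance is called at p < 0.01.  The universe is every gene with an
expression profile, including unclassified ones.

Generic term enrichment applies the same test per term and orders the
output by the average log2 fold change of the list genes in each term,
so the most strongly shifted categories lead the table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ENRICH_ALPHA = 0.01


@dataclass(frozen=True)
class EnrichmentTest:
    universe_size: int   # N
    class_size: int      # K
    draw_size: int       # n
    overlap: int         # k
    p_value: float
    significant: bool


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    X counts class members among n draws without replacement from a
    universe of N containing K class members.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent arguments N={N}, K={K}, n={n}, k={k}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")
    # survival function is exclusive, so shift by one for P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def test_overlap(N: int, K: int, n: int, k: int, alpha: float = ENRICH_ALPHA) -> EnrichmentTest:
    p = hypergeom_upper(N, K, n, k)
    return EnrichmentTest(N, K, n, k, p, p < alpha)


def enrich_de_lists(
    up_list: list[str],
    down_list: list[str],
    class_labels: pd.DataFrame,
    alpha: float = ENRICH_ALPHA,
) -> pd.DataFrame:
    """Class enrichment of the up- and down-regulated lists.

    One row per (direction, class label present); the universe N is all
    classified genes including class ``none``.  A list gene absent from
    the universe is an error naming the offenders.
    """
    universe = class_labels["gene_id"]
    if universe.duplicated().any():
        raise ValueError("duplicate gene_id in class labels")
    universe_set = set(universe)
    N = len(universe_set)
    label_of = dict(zip(class_labels["gene_id"], class_labels["class_label"]))
    rows = []
    for direction, gene_list in (("up", up_list), ("down", down_list)):
        unknown = sorted(set(gene_list) - universe_set)
        if unknown:
            raise ValueError(
                f"{direction} list contains gene(s) outside the classified "
                f"universe: {unknown[:10]}"
            )
        n = len(set(gene_list))
        list_labels = pd.Series([label_of[g] for g in set(gene_list)], dtype=object)
        for label in sorted(set(label_of.values())):
            K = sum(1 for v in label_of.values() if v == label)
            k = int((list_labels == label).sum())
            p = hypergeom_upper(N, K, n, k)
            rows.append(
                {
                    "direction": direction,
                    "class_label": label,
                    "N": N,
                    "K": K,
                    "n": n,
                    "k": k,
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
    out = pd.DataFrame(rows)
    out["p_bh"] = stats.false_discovery_control(out["p_value"].to_numpy(), method="bh")
    return out


def term_enrichment(
    gene_list: list[str],
    term_map: pd.DataFrame,
    de_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment, ordered by mean log2 fold change.

    *term_map* is a two-column frame (gene_id, term_id); the universe is
    every gene appearing in it.  Each term row carries the overlap k, the
    term size K, the upper-tail p, and the mean log2fc of list genes in
    the term (taken from *de_table*); the output is sorted by that mean,
    descending, with ties broken by term id.  Terms with no universe genes
    cannot occur by construction; an empty map yields an empty table.
    """
    for col in ("gene_id", "term_id"):
        if col not in term_map.columns:
            raise ValueError(f"term map missing column {col!r}")
    if term_map.empty:
        return pd.DataFrame(columns=["term_id", "k", "K", "n", "N", "p_value", "mean_log2fc"])
    universe = set(term_map["gene_id"])
    N = len(universe)
    listed = set(gene_list) & universe
    n = len(listed)
    fc_of = dict(zip(de_table["gene_id"], de_table["log2fc"]))
    rows = []
    for term_id, sub in term_map.groupby("term_id"):
        members = set(sub["gene_id"])
        K = len(members)
        hits = listed & members
        k = len(hits)
        p = hypergeom_upper(N, K, n, k)
        fcs = [fc_of[g] for g in hits if g in fc_of]
        mean_fc = float(np.mean(fcs)) if fcs else np.nan
        rows.append(
            {"term_id": term_id, "k": k, "K": K, "n": n, "N": N,
             "p_value": p, "mean_log2fc": mean_fc}
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["mean_log2fc", "term_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return out
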