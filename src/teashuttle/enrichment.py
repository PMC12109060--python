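"""Gene Ontology over-representation analysis of overlap gene sets.

For a query of n genes drawn from a universe of N annotated genes, a term
annotating K genes and overlapping the query in k genes is scored by the
upper-tail hypergeometric probability

    p = P(X >= k),    X ~ Hypergeom(N, K, n)

and the fold enrichment FE = (k/n) / (K/N).  An optional EASE variant
(the conservative modified Fisher statistic used by the DAVID service)
scores the tail with one overlap gene removed.  Significant terms
(p < 0.05, uncorrected by default to match common reporting practice;
Benjamini-Hochberg available behind a flag) are ranked by descending
-log10 p and truncated to the top 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidDBError

GO_CATEGORIES = ("BP", "CC", "MF")
ALPHA = 0.05
TOP_N = 20


@dataclass
class GeneSetDB:
    """GO-style term collection with its gene universe.

    ``terms`` maps term_id -> (name, category, gene set); the universe
    defaults to the union of all term genes and may be overridden with a
    platform gene list to mimic a measured background.
    """

    terms: dict[str, tuple[str, str, set[str]]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.universe:
            self.universe = set().union(
                *(genes for _, _, genes in self.terms.values())) \
                if self.terms else set()
        for tid, (_, cat, genes) in self.terms.items():
            if cat not in GO_CATEGORIES:
                raise ValueError(f"{tid}: category {cat!r} not in "
                                 f"{GO_CATEGORIES}")
            if not genes <= self.universe:
                raise ValueError(f"{tid}: genes outside universe")


def hypergeom_tail(k: int, n_universe: int, n_term: int,
                   n_query: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, n_universe, n_term, n_query))


def enrich(query: set[str], db: GeneSetDB,
           ease: bool = False) -> pd.DataFrame:
    """One row per term overlapping the query.

    Query genes outside the universe are dropped (their count is recorded
    in the DataFrame ``attrs``).  Columns: term_id, name, category,
    n_query, n_term, n_overlap, fold_enrichment, p_value, neg_log10_p.
    """
    if not db.universe:
        raise InvalidDBError("empty gene universe")
    dropped = len(set(query) - db.universe)
    q = set(query) & db.universe
    n, big_n = len(q), len(db.universe)
    rows = []
    for tid, (name, cat, genes) in db.terms.items():
        k = len(q & genes)
        if k < 1:
            continue
        big_k = len(genes)
        tail_k = k - 1 if ease else k
        p = hypergeom_tail(tail_k, big_n, big_k, n)
        fe = (k / n) / (big_k / big_n)
        rows.append({"term_id": tid, "name": name, "category": cat,
                     "n_query": n, "n_term": big_k, "n_overlap": k,
                     "fold_enrichment": fe, "p_value": p,
                     "neg_log10_p": -np.log10(p) if p > 0 else np.inf})
    out = pd.DataFrame(rows, columns=["term_id", "name", "category",
                                      "n_query", "n_term", "n_overlap",
                                      "fold_enrichment", "p_value",
                                      "neg_log10_p"])
    out.attrs["n_query_dropped"] = dropped
    return out


def rank_terms(rows: pd.DataFrame, alpha: float = ALPHA, top: int = TOP_N,
               adjust: bool = False) -> pd.DataFrame:
    """Significant terms ranked by descending -log10 p, truncated.

    The significance filter is strict (p < alpha) on raw p-values unless
    ``adjust`` applies Benjamini-Hochberg first; ties in p break on
    term_id for deterministic output.
    """
    out = rows.copy()
    if out.empty:
        return out
    if adjust:
        out["adj_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out[out["adj_p"] < alpha]
    else:
        out = out[out["p_value"] < alpha]
    out = out.sort_values(["neg_log10_p", "term_id"],
                          ascending=[False, True], kind="stable")
    return out.head(top).reset_index(drop=True)
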