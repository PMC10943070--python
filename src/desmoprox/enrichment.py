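"""Hypergeometric overrepresentation analysis of prey sets.

Given a term -> gene annotation (simple 3-column TSV or GAF 2.x), each term
with at least one query hit is tested with the hypergeometric upper tail

    p = sum_{x=k}^{min(n,K)} C(K,x) C(N-K,n-x) / C(N,n)

(k query hits, n query size, K term size, N universe size), adjusted per
ontology category with Benjamini-Hochberg.  Only overrepresentation is
tested.  Annotation files are taken as already propagated over the ontology
graph.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)

CATEGORIES = ("cellular_component", "molecular_function", "biological_process")
_GAF_ASPECT = {"C": "cellular_component", "F": "molecular_function", "P": "biological_process"}


@dataclass
class AnnotationTable:
    """term -> (name, category, member gene symbols), symbols uppercased."""

    terms: pd.DataFrame  # columns: term, name, category
    members: dict  # term -> frozenset of symbols

    def __post_init__(self) -> None:
        empty = [t for t, m in self.members.items() if not m]
        if empty:
            raise InputError(f"terms with no member genes: {empty}")

    @property
    def universe(self) -> frozenset:
        out: set = set()
        for m in self.members.values():
            out |= m
        return frozenset(out)

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        """3-column tab-delimited: term, category, gene (one gene per row)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["term", "category", "gene"], dtype=str)
        return cls._from_long(df)

    @classmethod
    def from_gaf(cls, path) -> "AnnotationTable":
        """GAF 2.x: column 3 = symbol, 5 = term ID, 9 = aspect (C/F/P)."""
        rows = []
        with open(path) as handle:
            for line in handle:
                if line.startswith("!") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 9:
                    continue
                rows.append(
                    dict(term=cols[4], category=_GAF_ASPECT.get(cols[8], cols[8]), gene=cols[2])
                )
        if not rows:
            raise InputError(f"no annotation rows parsed from {path}")
        return cls._from_long(pd.DataFrame(rows))

    @classmethod
    def _from_long(cls, df: pd.DataFrame) -> "AnnotationTable":
        df = df.copy()
        df["gene"] = df["gene"].str.upper()
        members = {
            term: frozenset(grp["gene"]) for term, grp in df.groupby("term", sort=True)
        }
        terms = (
            df.groupby("term", sort=True)
            .agg(category=("category", "first"))
            .reset_index()
        )
        terms["name"] = terms["term"]
        return cls(terms=terms[["term", "name", "category"]], members=members)


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n), computed stably."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise InputError(f"invalid hypergeometric bounds k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query,
    annotation: AnnotationTable,
    universe=None,
    top_n: int = 10,
) -> pd.DataFrame:
    """Overrepresentation test of ``query`` against every annotated term.

    Universe defaults to all genes in the annotation.  Query symbols outside
    the universe are dropped with a warning.  Results (one row per term with
    k >= 1) are BH-adjusted within each category, sorted by adjusted p
    ascending (ties: gene ratio descending, then term ID), top_n per
    category.
    """
    universe = frozenset(s.upper() for s in universe) if universe is not None else annotation.universe
    if not universe:
        raise InputError("empty universe")
    query = {s.upper() for s in query}
    dropped = query - universe
    if dropped:
        logger.warning("enrich: %d query symbols outside universe dropped: %s", len(dropped), sorted(dropped))
    query &= universe
    n, N = len(query), len(universe)

    rows = []
    for term_row in annotation.terms.itertuples(index=False):
        members = annotation.members[term_row.term] & universe
        hits = sorted(query & members)
        k, K = len(hits), len(members)
        if k == 0 or K == 0:
            continue
        rows.append(
            dict(
                term=term_row.term,
                name=term_row.name,
                category=term_row.category,
                k=k,
                n=n,
                K=K,
                N=N,
                p=hypergeometric_p(k, n, K, N),
                gene_ratio=k / n,
                hits=",".join(hits),
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "category", "k", "n", "K", "N", "p", "p_adjust", "gene_ratio", "hits"]
        )
    df = pd.DataFrame(rows)
    pieces = []
    for _, grp in df.groupby("category", sort=True):
        grp = grp.copy()
        grp["p_adjust"] = multipletests(grp["p"], method="fdr_bh")[1]
        grp = grp.sort_values(
            ["p_adjust", "gene_ratio", "term"],
            ascending=[True, False, True],
            kind="mergesort",
        ).head(top_n)
        pieces.append(grp)
    return pd.concat(pieces, ignore_index=True)
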